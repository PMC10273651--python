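"""TMM factors and noise-cloud DE probabilities."""

import numpy as np
import pandas as pd
import pytest

from circsam.diffexp import (
    consecutive_pairs,
    de_probability,
    expression_pattern_sets,
    normalized_counts,
    tmm_factors,
    DEResult,
)


def _design(conds=("A", "B"), reps=3):
    rows = [(f"{c}_r{i+1}", c, f"r{i+1}") for c in conds for i in range(reps)]
    return pd.DataFrame(rows, columns=["sample", "condition", "replicate"])


def test_tmm_identical_columns():
    c = pd.DataFrame({"a": [10, 20, 30, 40], "b": [10, 20, 30, 40]})
    assert tmm_factors(c).tolist() == pytest.approx([1.0, 1.0])


def test_tmm_scaling_invariance():
    c = pd.DataFrame({"a": [10, 20, 30, 40], "b": [20, 40, 60, 80]})
    n = normalized_counts(c)
    assert np.allclose(n["a"], n["b"])


def test_tmm_hand_oracle_four_genes():
    # doubly spelled-out TMM arithmetic on a 4-gene, 2-sample toy where one
    # gene is shifted; trim 0.30 keeps the middle 2 genes by M rank
    c = pd.DataFrame({"a": [100, 200, 300, 400], "b": [100, 200, 300, 1400]})
    na, nb = 1000.0, 2000.0
    M = np.log2((c["b"] / nb) / (c["a"] / na)).to_numpy()
    A = 0.5 * np.log2((c["b"] / nb) * (c["a"] / na)).to_numpy()
    w = ((nb - c["b"]) / (nb * c["b"]) + (na - c["a"]) / (na * c["a"])).to_numpy()
    order = np.argsort(M)
    keep = sorted(order[1:3])  # drop lowest and highest M (floor(4*0.3)=1 each side)
    keep = [i for i in keep]  # trim_A drops nothing: floor(4*0.05)=0
    expected_b = 2 ** (np.sum(M[keep] / w[keep]) / np.sum(1.0 / w[keep]))
    # rescale both factors to geometric mean 1
    f_raw = np.array([1.0, expected_b])
    f_exp = f_raw / np.exp(np.mean(np.log(f_raw)))
    got = tmm_factors(c).to_numpy()
    assert got == pytest.approx(f_exp)


def test_tmm_all_zero_sample_errors():
    c = pd.DataFrame({"a": [1, 2], "b": [0, 0]})
    with pytest.raises(ValueError):
        tmm_factors(c)


def test_identical_counts_give_q_zero():
    rng = np.random.default_rng(1)
    base = rng.integers(10, 100, size=10)
    counts = pd.DataFrame(
        {f"{c}_r{i+1}": base for c in ("A", "B") for i in range(3)},
        index=[f"c{i}" for i in range(10)],
    )
    res = de_probability(counts, _design(), ("A", "B"))
    for r in res:
        assert r.M == 0.0 and r.D == 0.0 and r.q == 0.0 and not r.called


def test_q_matches_brute_force_enumeration():
    rng = np.random.default_rng(0)
    counts = pd.DataFrame(
        rng.integers(1, 200, size=(10, 6)),
        index=[f"c{i}" for i in range(10)],
        columns=_design()["sample"],
    )
    design = _design()
    res = de_probability(counts, design, ("A", "B"))
    norm = normalized_counts(counts)
    a = norm[[f"A_r{i+1}" for i in range(3)]].to_numpy(float)
    b = norm[[f"B_r{i+1}" for i in range(3)]].to_numpy(float)
    k = 0.5
    noise = []
    for mat in (a, b):
        for i in range(3):
            for j in range(i + 1, 3):
                for g in range(10):
                    xi, xj = max(mat[g, i], k), max(mat[g, j], k)
                    noise.append((abs(np.log2(xi / xj)), abs(mat[g, i] - mat[g, j])))
    for g, r in enumerate(res):
        mA, mB = max(a[g].mean(), k), max(b[g].mean(), k)
        M, D = np.log2(mB / mA), abs(b[g].mean() - a[g].mean())
        q = sum(1 for mm, dd in noise if mm < abs(M) and dd < D) / len(noise)
        assert r.q == pytest.approx(q, abs=1e-12)
        assert r.M == pytest.approx(M)


def test_q_monotone_in_signal():
    rng = np.random.default_rng(2)
    counts = pd.DataFrame(
        rng.integers(20, 200, size=(20, 6)), columns=_design()["sample"]
    )
    res = de_probability(counts, _design(), ("A", "B"))
    rs = sorted(res, key=lambda r: (abs(r.M), r.D))
    for r1, r2 in zip(rs, rs[1:]):
        if abs(r1.M) <= abs(r2.M) and r1.D <= r2.D:
            assert r1.q <= r2.q


def test_column_permutation_invariance():
    rng = np.random.default_rng(3)
    design = _design()
    counts = pd.DataFrame(
        rng.integers(5, 500, size=(15, 6)), columns=design["sample"]
    )
    res1 = de_probability(counts, design, ("A", "B"))
    shuffled = counts[list(reversed(counts.columns))]
    res2 = de_probability(shuffled, design, ("A", "B"))
    for r1, r2 in zip(res1, res2):
        assert r1.q == pytest.approx(r2.q)
        assert r1.M == pytest.approx(r2.M)


def test_planted_fold_change_eight_called(tmp_path):
    from circsam.simulate import SimConfig, generate_dataset

    # low-noise setting: 8-fold shifts against a tight NB dispersion
    cfg = SimConfig(seed=9, fold_change=8.0, nb_dispersion=0.02)
    res = generate_dataset(cfg, tmp_path)
    counts = pd.read_csv(res.paths["counts"], sep="\t", index_col=0)
    design = pd.read_csv(res.paths["design"], sep="\t")
    factors = tmm_factors(counts)
    planted = {t.circ_id: t.de_pair for t in res.circ_truth if t.de_pair not in ("", "all")}
    hits = 0
    for pair in consecutive_pairs(design):
        name = f"{pair[0]}:{pair[1]}"
        for r in de_probability(counts, design, pair, factors=factors):
            if planted.get(r.circ_id) == name and r.called:
                hits += 1
    assert hits >= 0.9 * len(planted)


def test_expression_pattern_sets():
    def mk(cid, pair, m, q):
        return DEResult(cid, pair, m, abs(m) * 10, q, q >= 0.8)

    results = {
        "SD0:SD2": [mk("x", ("SD0", "SD2"), 2.0, 0.9), mk("y", ("SD0", "SD2"), -1.0, 0.95),
                    mk("z", ("SD0", "SD2"), 1.0, 0.85)],
        "SD2:SD4": [mk("y", ("SD2", "SD4"), -1.5, 0.9), mk("z", ("SD2", "SD4"), 0.5, 0.81)],
        "SD4:SD6": [mk("z", ("SD4", "SD6"), 2.0, 0.99)],
    }
    sets = expression_pattern_sets(results)
    assert sets["n_called"] == 3
    assert sets["treatment_specific"] == ["x"]
    assert sets["common"] == ["z"]
    assert sets["tallies"]["SD0:SD2"] == {"up": 2, "down": 1}
    assert sum(sets["venn"].values()) == sets["n_called"]
    with pytest.raises(ValueError):
        expression_pattern_sets({"only": []})
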