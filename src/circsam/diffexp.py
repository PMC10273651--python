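"""TMM normalization and noise-cloud differential expression probabilities.

The DE statistic follows the replicate-using empirical scheme: for a
condition pair, each feature's signal is (M, D) computed from TMM-normalized
condition means (M = log2 ratio of later over earlier, D = absolute
difference); the noise cloud pools (|M|, D) from every within-condition
replicate-vs-replicate contrast of the two conditions; q is the fraction of
noise points strictly dominated by the signal. A feature is called
differentially expressed at q >= 0.8 by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class DEResult:
    circ_id: str
    pair: tuple[str, str]
    M: float  # log2(mean_later / mean_earlier), TMM-normalized
    D: float  # |mean_later - mean_earlier|
    q: float
    called: bool


def _upper_quartile(counts: np.ndarray, libsize: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = counts / libsize
    return np.percentile(frac, 75, axis=0)


def tmm_factors(
    counts: pd.DataFrame, trim_M: float = 0.30, trim_A: float = 0.05
) -> pd.Series:
    """Trimmed-mean-of-M-values scaling factors, geometric mean 1.

    Reference sample: upper quartile of count/library-size closest to the
    mean upper quartile. Rows with a zero in either sample are excluded from
    each pairwise comparison; the top/bottom ``trim_M`` by M and ``trim_A``
    by A are trimmed; the factor is 2 to the precision-weighted mean M.
    """
    x = counts.to_numpy(dtype=float)
    if (x < 0).any():
        raise ValueError("negative counts")
    lib = x.sum(axis=0)
    if (lib <= 0).any():
        bad = counts.columns[lib <= 0].tolist()
        raise ValueError(f"samples with zero library size: {bad}")
    uq = _upper_quartile(x, lib)
    ref = int(np.argmin(np.abs(uq - uq.mean())))

    factors = np.ones(x.shape[1])
    xr, nr = x[:, ref], lib[ref]
    for j in range(x.shape[1]):
        if j == ref:
            continue
        xj, nj = x[:, j], lib[j]
        keep = (xj > 0) & (xr > 0)
        if keep.sum() == 0:
            factors[j] = 1.0
            continue
        pj, pr = xj[keep] / nj, xr[keep] / nr
        M = np.log2(pj / pr)
        A = 0.5 * np.log2(pj * pr)
        w = (nj - xj[keep]) / (nj * xj[keep]) + (nr - xr[keep]) / (nr * xr[keep])
        # double trim: drop tails of M and of A
        n = M.size
        lo_m, hi_m = int(np.floor(n * trim_M)) + 1, n - int(np.floor(n * trim_M))
        lo_a, hi_a = int(np.floor(n * trim_A)) + 1, n - int(np.floor(n * trim_A))
        rank_m = M.argsort().argsort() + 1
        rank_a = A.argsort().argsort() + 1
        sel = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
        if sel.sum() == 0 or w[sel].sum() == 0:
            factors[j] = 1.0
            continue
        factors[j] = 2 ** (np.sum(M[sel] / w[sel]) / np.sum(1.0 / w[sel]))
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


def normalized_counts(counts: pd.DataFrame, factors: pd.Series | None = None) -> pd.DataFrame:
    """Counts scaled to a common effective library size (TMM-adjusted CPM-like)."""
    if factors is None:
        factors = tmm_factors(counts)
    lib = counts.sum(axis=0).to_numpy(dtype=float)
    eff = lib * factors.to_numpy()
    scale = lib.mean() / eff
    return counts * scale


def read_design(path) -> pd.DataFrame:
    design = pd.read_csv(path, sep="\t")
    need = {"sample", "condition", "replicate"}
    if not need <= set(design.columns):
        raise ValueError(f"design must have columns {sorted(need)}")
    return design


def de_probability(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    pair: tuple[str, str],
    k_pseudo: float = 0.5,
    q_threshold: float = 0.8,
    factors: pd.Series | None = None,
) -> list[DEResult]:
    """Noise-cloud DE probabilities for one ordered condition pair (earlier, later)."""
    cond_a, cond_b = pair
    norm = normalized_counts(counts, factors)
    all_conds = list(dict.fromkeys(design["condition"]))
    cols = {
        c: design.loc[design["condition"] == c, "sample"].tolist() for c in all_conds
    }
    for c in pair:
        if len(cols.get(c, [])) < 2:
            raise ValueError(f"condition {c!r} needs >= 2 replicates")
    for c, samples in cols.items():
        missing = set(samples) - set(counts.columns)
        if missing:
            raise ValueError(f"samples missing from counts: {sorted(missing)}")

    a = norm[cols[cond_a]].to_numpy(dtype=float)
    b = norm[cols[cond_b]].to_numpy(dtype=float)
    mean_a = np.maximum(a.mean(axis=1), k_pseudo)
    mean_b = np.maximum(b.mean(axis=1), k_pseudo)
    M = np.log2(mean_b / mean_a)
    D = np.abs(b.mean(axis=1) - a.mean(axis=1))

    # noise: within-condition replicate contrasts pooled over every condition
    noise_m, noise_d = [], []
    for c in all_conds:
        mat = norm[cols[c]].to_numpy(dtype=float)
        r = mat.shape[1]
        for i in range(r):
            for j in range(i + 1, r):
                xi = np.maximum(mat[:, i], k_pseudo)
                xj = np.maximum(mat[:, j], k_pseudo)
                noise_m.append(np.abs(np.log2(xi / xj)))
                noise_d.append(np.abs(mat[:, i] - mat[:, j]))
    if not noise_m:
        raise ValueError("empty noise cloud")
    nm = np.concatenate(noise_m)
    nd = np.concatenate(noise_d)

    out = []
    absM = np.abs(M)
    for i, circ_id in enumerate(counts.index):
        q = float(np.mean((nm < absM[i]) & (nd < D[i])))
        out.append(
            DEResult(
                circ_id=str(circ_id),
                pair=pair,
                M=float(M[i]),
                D=float(D[i]),
                q=q,
                called=bool(q >= q_threshold),
            )
        )
    return out


def consecutive_pairs(design: pd.DataFrame) -> list[tuple[str, str]]:
    """Ordered consecutive condition pairs, in order of first appearance."""
    conds = list(dict.fromkeys(design["condition"]))
    return list(zip(conds, conds[1:]))


def expression_pattern_sets(
    results_by_pair: dict[str, list[DEResult]],
) -> dict:
    """Venn decomposition of DE calls across comparisons.

    Returns per-comparison up/down tallies, the Venn partition over
    comparison combinations, the treatment-specific set (called in exactly
    one comparison) and the common set (called in all).
    """
    if len(results_by_pair) < 2:
        raise ValueError("need at least two comparisons")
    called: dict[str, set[str]] = {
        name: {r.circ_id for r in results if r.called}
        for name, results in results_by_pair.items()
    }
    tallies = {
        name: {
            "up": sum(1 for r in results if r.called and r.M > 0),
            "down": sum(1 for r in results if r.called and r.M < 0),
        }
        for name, results in results_by_pair.items()
    }
    all_called = sorted(set().union(*called.values()))
    venn: dict[frozenset[str], int] = {}
    specific, common = [], []
    names = list(results_by_pair)
    for cid in all_called:
        membership = frozenset(n for n in names if cid in called[n])
        venn[membership] = venn.get(membership, 0) + 1
        if len(membership) == 1:
            specific.append(cid)
        if len(membership) == len(names):
            common.append(cid)
    return {
        "n_called": len(all_called),
        "tallies": tallies,
        "venn": venn,
        "treatment_specific": specific,
        "common": common,
    }


def de_results_to_frame(results: list[DEResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "circ_id": [r.circ_id for r in results],
            "pair": [f"{r.pair[0]}:{r.pair[1]}" for r in results],
            "M": [r.M for r in results],
            "D": [r.D for r in results],
            "q": [r.q for r in results],
            "called": [r.called for r in results],
        }
    )
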