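"""RCM alignment, duplex energies, rank-sum test, control sampling."""

import math
import random

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from circsam.flanking import (
    NN_STACK_KCAL,
    ScoringScheme,
    catalog_exon_count_distribution,
    duplex_energy,
    flanking_introns,
    flanking_window,
    rcm_scan,
    sample_control_exons,
    wilcoxon_rank_sum,
)
from circsam.genome import Genome, Interval, reverse_complement
from conftest import sw_local_affine

SCHEME1 = ScoringScheme(min_score=1)


def test_rcm_scan_perfect_element():
    elem = "ACGTACGTACGTACGTACGT"  # 20 nt
    up = "TTTT" + elem + "TTTT"
    down = "TTTT" + reverse_complement(elem) + "TTTT"
    hit = rcm_scan(up, down)
    assert hit.matched_bases == 20
    assert hit.raw_score == 40
    assert hit.bitscore == pytest.approx((0.625 * 40 - math.log(0.41)) / math.log(2))
    assert up[slice(*hit.up_segment)] == elem
    assert down[slice(*hit.down_segment)] == reverse_complement(elem)


def test_rcm_scan_no_complementarity():
    assert rcm_scan("A" * 40, "A" * 40) is None  # revcomp(down) is all T


def test_rcm_scan_rejects_bad_alphabet():
    with pytest.raises(ValueError):
        rcm_scan("ACGU", "ACGT")
    with pytest.raises(ValueError):
        rcm_scan("", "ACGT")


def test_rcm_scan_matches_exhaustive_dp():
    rng = random.Random(7)
    for _ in range(60):
        a = "".join(rng.choice("ACGT") for _ in range(rng.randint(5, 30)))
        b = "".join(rng.choice("ACGT") for _ in range(rng.randint(5, 30)))
        expected = sw_local_affine(a, reverse_complement(b))
        hit = rcm_scan(a, b, SCHEME1)
        if expected >= 1:
            assert hit is not None and hit.raw_score == expected
        else:
            assert hit is None


@given(st.integers(0, 10**9))
@settings(max_examples=30, deadline=None, derandomize=True)
def test_rcm_strand_symmetry(seed):
    rng = random.Random(seed)
    a = "".join(rng.choice("ACGT") for _ in range(rng.randint(10, 40)))
    b = "".join(rng.choice("ACGT") for _ in range(rng.randint(10, 40)))
    h1 = rcm_scan(a, b, SCHEME1)
    h2 = rcm_scan(reverse_complement(b), reverse_complement(a), SCHEME1)
    s1 = h1.raw_score if h1 else 0
    s2 = h2.raw_score if h2 else 0
    assert s1 == s2


def test_duplex_energy_gc_stronger_than_at():
    gc = duplex_energy("GCGCGC", reverse_complement("GCGCGC"))
    at = duplex_energy("ATATAT", reverse_complement("ATATAT"))
    assert gc < at < 0


def test_duplex_energy_hand_summed_20mer():
    seq = "ACGTGCATTGCACGTAGCTA"
    expected = sum(NN_STACK_KCAL[seq[i : i + 2]] for i in range(19))
    got = duplex_energy(seq, reverse_complement(seq))
    assert got == pytest.approx(expected)


def test_duplex_energy_degenerate():
    assert duplex_energy("", "ACGT") is None
    # no complementarity at all -> no stacks counted
    assert duplex_energy("AAAA", "AAAA") == 0.0


def test_wilcoxon_exact_separated():
    _, p = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6], alternative="less")
    assert p == pytest.approx(1 / 20)
    _, p2 = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6], alternative="two-sided")
    assert p2 == pytest.approx(2 / 20)


def test_wilcoxon_identical_samples():
    _, p = wilcoxon_rank_sum([1, 2, 3], [1, 2, 3])
    assert p == pytest.approx(1.0, abs=1e-9)


def test_wilcoxon_branch_agreement_6plus6():
    rng = random.Random(5)
    for _ in range(20):
        x = [rng.random() for _ in range(6)]
        y = [rng.random() + 0.3 for _ in range(6)]
        _, pe = wilcoxon_rank_sum(x, y, method="exact")
        _, pa = wilcoxon_rank_sum(x, y, method="asymptotic")
        assert abs(pe - pa) <= 0.02


def test_wilcoxon_large_shift():
    rng = np.random.default_rng(0)
    x = rng.normal(0, 1, 200)
    y = rng.normal(3, 1, 200)
    _, p = wilcoxon_rank_sum(x, y, alternative="less")
    assert p < 1e-6


def test_wilcoxon_empty_errors():
    with pytest.raises(ValueError):
        wilcoxon_rank_sum([], [1.0])


def test_flanking_introns_plus_and_minus(toy_genes):
    plus, minus = toy_genes
    up, down = flanking_introns(plus, [2])
    assert (up.start, up.end) == (200, 300)
    assert (down.start, down.end) == (400, 500)
    # run includes first exon -> no upstream intron
    up2, down2 = flanking_introns(plus, [1, 2])
    assert up2 is None and (down2.start, down2.end) == (400, 500)
    # minus strand: upstream intron of exon rank 2 is genomically downstream
    upm, downm = flanking_introns(minus, [2])
    assert (upm.start, upm.end) == (700, 900)
    assert (downm.start, downm.end) == (400, 600)


def test_flanking_window_clipping(toy_genome):
    iv = Interval("Chr1", 50, 100, "+")
    up, down = flanking_window(toy_genome, iv, width=2000)
    assert len(up) == 50  # clipped at chromosome start, not an error
    assert len(down) == 1100
    assert flanking_window(toy_genome, iv, width=0) == ("", "")
    # minus strand swaps and reverse-complements the windows
    ivm = Interval("Chr1", 50, 100, "-")
    upm, downm = flanking_window(toy_genome, ivm, width=10)
    assert upm == reverse_complement(toy_genome.chromosomes["Chr1"][100:110])
    assert downm == reverse_complement(toy_genome.chromosomes["Chr1"][40:50])


def test_control_sampling_matches_distribution(sim_default):
    genes = sim_default.genes
    excluded = {g for t in sim_default.circ_truth for g in t.gene_ids}
    dist = {1: 0.5, 2: 0.5}
    controls = sample_control_exons(genes, excluded, dist, n_controls=10, seed=1)
    counts = {k: sum(1 for c in controls if c.exon_count == k) for k in dist}
    assert counts == {1: 5, 2: 5}
    assert all(c.gene_id not in excluded for c in controls)
    # consecutive exon ranks
    for c in controls:
        assert c.exon_indices == list(range(c.exon_indices[0], c.exon_indices[-1] + 1))


def test_control_sampling_errors(sim_default):
    genes = sim_default.genes
    every = {g.gene_id for g in genes}
    with pytest.raises(ValueError):
        sample_control_exons(genes, every, {1: 1.0}, n_controls=5, seed=1)
    with pytest.raises(ValueError, match="stratum"):
        # no gene provides 40 consecutive exons -> stratum empty
        sample_control_exons(genes, set(), {40: 1.0}, n_controls=5, seed=1)


def test_catalog_distribution_caps_at_six():
    dist = catalog_exon_count_distribution([1, 2, 2, 9, 14])
    assert dist == {1: 0.2, 2: 0.4, 6: 0.4}
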