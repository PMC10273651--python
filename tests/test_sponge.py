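"""Plant miRNA target scoring, junction-aware scanning, ceRNA network."""

import random

import pytest

from circsam.genome import read_fasta_dict, reverse_complement
from circsam.sponge import (
    MiRNA,
    TargetSite,
    build_cerna_network,
    circular_sequence,
    scan_transcript,
    score_mirna_site,
)

MIRNA = "ACGTACGTACGTACGTACGTA"  # 21 nt


def _with_wobble(mirna: str, position: int) -> str:
    """Perfect site with a single G:U pair at the given miRNA position."""
    site = list(reverse_complement(mirna))
    j = len(mirna) - position  # reversed-frame index of that position
    c = reverse_complement(mirna)[j]
    repl = {"C": "T", "A": "G"}  # keeps the pair a wobble, not a mismatch
    assert c in repl, "choose a position where the miRNA base is G or U"
    site[j] = repl[c]
    return "".join(site)


def test_perfect_complement_scores_zero():
    assert score_mirna_site(MIRNA, reverse_complement(MIRNA)) == 0.0


def test_single_wobble_in_core_costs_one():
    # this miRNA has G at position 5; G:U wobble there is doubled: 0.5 * 2
    mirna = "ACGTGCGTACGTACGTACGTA"
    window = _with_wobble(mirna, 5)
    assert score_mirna_site(mirna, window) == 1.0


def test_mismatch_outside_core_plus_core_wobble():
    window = list(_with_wobble(MIRNA, 3))  # G:U at position 3 -> 1.0
    j = len(MIRNA) - 15  # mismatch at position 15 -> +1 undoubled
    window[j] = {"A": "C", "C": "A", "G": "T", "T": "G"}[window[j]]
    assert score_mirna_site(MIRNA, "".join(window)) == 2.0


def test_window_length_bounds():
    with pytest.raises(ValueError):
        score_mirna_site(MIRNA, "ACGT")
    with pytest.raises(ValueError):
        score_mirna_site(MIRNA, "A" * 30)


def test_bulged_windows_scored():
    site = reverse_complement(MIRNA)
    bulged = site[:10] + "G" + site[10:]  # one extra target base
    pen = score_mirna_site(MIRNA, bulged)
    assert 0 < pen <= 2.0  # one bulge, possibly doubled
    shorter = site[:10] + site[11:]  # one unpaired miRNA base
    pen2 = score_mirna_site(MIRNA, shorter)
    assert 0 < pen2 <= 2.0


def test_scan_finds_planted_interior_site():
    rng = random.Random(1)
    bg = "".join(rng.choice("ACGT") for _ in range(300))
    site = reverse_complement(MIRNA)
    seq = bg[:100] + site + bg[100:]
    hits = scan_transcript({"m1": MIRNA}, "tx", seq, circular=False, cutoff=4.0)
    assert any(h.start == 100 and h.penalty_score == 0.0 for h in hits)


def test_scan_penalties_match_isolated_scoring():
    rng = random.Random(2)
    seq = "".join(rng.choice("ACGT") for _ in range(400))
    site = reverse_complement(MIRNA)
    seq = seq[:50] + site + seq[50:]
    for circ in (False, True):
        ext = seq + seq[: len(MIRNA)] if circ else seq
        for h in scan_transcript({"m1": MIRNA}, "tx", seq, circular=circ, cutoff=6.0):
            window = ext[h.start : h.start + h.window_length]
            assert score_mirna_site(MIRNA, window) == pytest.approx(h.penalty_score)


def test_junction_spanning_site_only_in_circular_mode():
    rng = random.Random(3)
    bg = "".join(rng.choice("ACGT") for _ in range(200))
    site = reverse_complement(MIRNA)
    k = 10
    seq = site[k:] + bg + site[:k]  # wraps around the seam
    circ_hits = scan_transcript({"m1": MIRNA}, "c", seq, circular=True, cutoff=0.0)
    assert any(h.spans_junction and h.penalty_score == 0.0 for h in circ_hits)
    lin_hits = scan_transcript({"m1": MIRNA}, "c", seq, circular=False, cutoff=0.0)
    assert lin_hits == []


def test_rotation_invariance_of_circular_scan():
    rng = random.Random(4)
    bg = "".join(rng.choice("ACGT") for _ in range(150))
    site = reverse_complement(MIRNA)
    seq = bg[:40] + site + bg[40:]
    baseline = scan_transcript({"m1": MIRNA}, "c", seq, circular=True, cutoff=1.0)
    L = len(seq)
    for shift in (13, 77, 170):
        rotated = seq[shift:] + seq[:shift]
        hits = scan_transcript({"m1": MIRNA}, "c", rotated, circular=True, cutoff=1.0)
        assert {(h.mirna, h.penalty_score) for h in hits} == {
            (h.mirna, h.penalty_score) for h in baseline
        }
        ext = rotated + rotated[: len(MIRNA)]
        assert {ext[h.start : h.start + h.window_length] for h in hits} == {
            (seq + seq[: len(MIRNA)])[h.start : h.start + h.window_length]
            for h in baseline
        }


def test_linear_sites_subset_of_circular():
    rng = random.Random(5)
    seq = "".join(rng.choice("ACGT") for _ in range(500))
    lin = scan_transcript({"m1": MIRNA}, "t", seq, circular=False, cutoff=8.0)
    circ = scan_transcript({"m1": MIRNA}, "t", seq, circular=True, cutoff=8.0)
    lin_keys = {(h.mirna, h.start) for h in lin}
    circ_keys = {(h.mirna, h.start) for h in circ}
    assert lin_keys <= circ_keys


def test_cutoff_zero_without_perfect_site_is_empty():
    assert scan_transcript({"m1": MIRNA}, "t", "A" * 100, circular=False, cutoff=0.0) == []


def test_planted_sites_recovered(sim_default):
    mirnas = read_fasta_dict(sim_default.paths["mirnas"])
    genes = {g.gene_id: g for g in sim_default.genes}
    by_circ: dict[str, list] = {}
    for s in sim_default.site_truth:
        by_circ.setdefault(s.transcript_id, []).append(s)
    checked = 0
    for t in sim_default.circ_truth:
        planted = by_circ.get(t.circ_id)
        if not planted:
            continue
        seq = circular_sequence(t.exon_indices, genes[t.gene_ids[0]], sim_default.genome)
        assert len(seq) == t.mature_length
        hits = scan_transcript(mirnas, t.circ_id, seq, circular=True, cutoff=4.0)
        keys = {(h.mirna, h.start) for h in hits}
        for s in planted:
            assert (s.mirna, s.offset) in keys
            checked += 1
    assert checked >= 10


def test_network_counting():
    def site(src, mir, tid=None):
        return TargetSite(tid or src, mir, 0, 21, 0.0, "", False)

    circ_sites = [site("circ1", "mirA"), site("circ1", "mirB")]
    mrna_sites = [site("g1", "mirA", "g1"), site("g2", "mirA", "g2"),
                  site("g3", "mirA", "g3"), site("g1", "mirB", "g1"),
                  site("g4", "mirB", "g4"), site("g5", "mirB", "g5")]
    net = build_cerna_network(circ_sites, mrna_sites)
    assert len(net["edges"]) == 2 + 6
    assert net["mirnas_per_circ_hist"] == {2: 1}
    assert net["circs_per_mirna_hist"] == {1: 2}
    empty = build_cerna_network([], [])
    assert len(empty["edges"]) == 0
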