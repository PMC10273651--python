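"""Flanking-intron analysis: control-exon null, reverse-complement matches,
duplex stacking energy and rank-sum enrichment tests.

The reverse-complement match (RCM) statistic is the best Smith-Waterman local
alignment between the upstream flanking sequence and the reverse complement
of the downstream flanking sequence, under a blastn-like scheme (match +2,
mismatch -3, affine gaps), normalized to a Karlin-Altschul bitscore
(lambda*S - ln K)/ln 2. Duplex stability of the matched segments is
approximated by a nearest-neighbor stacking-energy sum; see docs/methods.md
for the embedded parameter table and its provenance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import stats
from Bio import Align
from Bio.Align import substitution_matrices

from .genome import (
    GeneModel,
    Genome,
    Interval,
    VALID_ALPHABET,
    extract_sequence,
    reverse_complement,
)


@dataclass(frozen=True)
class ScoringScheme:
    match: int = 2
    mismatch: int = -3
    gap_open: int = -5  # score of the first gapped position
    gap_extend: int = -2  # each subsequent gapped position
    lam: float = 0.625  # Karlin-Altschul lambda per score unit
    k: float = 0.41
    min_score: int = 16  # raw-score floor below which no hit is reported

    def __post_init__(self) -> None:
        if not (self.match > 0 > self.mismatch):
            raise ValueError("need match > 0 > mismatch")
        if self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("gap penalties must be <= 0")
        if self.lam <= 0 or self.k <= 0:
            raise ValueError("lambda and K must be positive")

    def bitscore(self, raw_score: float) -> float:
        return (self.lam * raw_score - math.log(self.k)) / math.log(2)


@dataclass
class RCMHit:
    matched_bases: int
    raw_score: int
    bitscore: float
    duplex_energy_kcal_mol: float | None
    up_segment: tuple[int, int]  # offsets within the upstream sequence
    down_segment: tuple[int, int]  # offsets within the downstream sequence


@dataclass
class ControlExon:
    gene_id: str
    exon_indices: list[int]  # consecutive 1-based ranks, transcription order
    locus: Interval
    exon_count: int


@lru_cache(maxsize=8)
def _aligner(scheme: ScoringScheme) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    matrix = substitution_matrices.Array("ACGTN", dims=2)
    for a in "ACGTN":
        for b in "ACGTN":
            # N is a universal mismatch, even against N
            matrix[a, b] = float(scheme.match) if (a == b and a != "N") else float(scheme.mismatch)
    aligner.substitution_matrix = matrix
    aligner.open_gap_score = float(scheme.gap_open)
    aligner.extend_gap_score = float(scheme.gap_extend)
    return aligner


# ---------------------------------------------------------------------------
# nearest-neighbor duplex stacking energies (RNA, kcal/mol, 37 C)
# Watson-Crick stack free energies keyed by the 5'->3' dinucleotide of the
# upper strand; the lower strand is its exact complement.
NN_STACK_KCAL = {
    "AA": -0.93, "TT": -0.93,
    "AT": -1.10,
    "TA": -1.33,
    "CT": -2.08, "AG": -2.08,
    "CA": -2.11, "TG": -2.11,
    "GT": -2.24, "AC": -2.24,
    "GA": -2.35, "TC": -2.35,
    "CG": -2.36,
    "GG": -3.26, "CC": -3.26,
    "GC": -3.42,
}


def _check_seq(seq: str, name: str) -> None:
    if not seq:
        raise ValueError(f"{name} sequence is empty")
    bad = set(seq) - VALID_ALPHABET
    if bad:
        raise ValueError(f"{name} contains non-ACGTN symbols {sorted(bad)}")


def _aligned_match_runs(aln, up: str, down_rc: str) -> tuple[int, list[list[bool]]]:
    """Matched-base count and per-block match masks of a local alignment."""
    matched = 0
    masks: list[list[bool]] = []
    for (ts, te), (qs, qe) in zip(aln.aligned[0], aln.aligned[1]):
        mask = []
        for i in range(te - ts):
            ok = up[ts + i] == down_rc[qs + i] and up[ts + i] != "N"
            mask.append(ok)
            matched += ok
        masks.append(mask)
    return matched, masks


def _stack_energy(aln, up: str, down_rc: str) -> float:
    """Sum NN stack terms over consecutive matched, ungapped aligned pairs."""
    energy = 0.0
    for (ts, te), (qs, qe) in zip(aln.aligned[0], aln.aligned[1]):
        for i in range(te - ts - 1):
            a, b = up[ts + i], up[ts + i + 1]
            if (
                up[ts + i] == down_rc[qs + i]
                and up[ts + i + 1] == down_rc[qs + i + 1]
                and a != "N"
                and b != "N"
            ):
                energy += NN_STACK_KCAL[a + b]
    return energy


def rcm_scan(up_seq: str, down_seq: str, scheme: ScoringScheme = ScoringScheme()) -> RCMHit | None:
    """Best local alignment of ``up_seq`` vs revcomp(``down_seq``).

    Returns None (no hit) when the best raw score is below
    ``scheme.min_score``.
    """
    _check_seq(up_seq, "upstream")
    _check_seq(down_seq, "downstream")
    down_rc = reverse_complement(down_seq)
    aligner = _aligner(scheme)
    alignments = aligner.align(up_seq, down_rc)
    try:
        aln = alignments[0]
    except IndexError:
        return None
    raw = int(aln.score)
    if raw < scheme.min_score:
        return None
    matched, _ = _aligned_match_runs(aln, up_seq, down_rc)
    energy = _stack_energy(aln, up_seq, down_rc)
    t_blocks, q_blocks = aln.aligned
    t0, t1 = int(t_blocks[0][0]), int(t_blocks[-1][1])
    q0, q1 = int(q_blocks[0][0]), int(q_blocks[-1][1])
    # map revcomp coordinates back onto the original downstream sequence
    d0, d1 = len(down_seq) - q1, len(down_seq) - q0
    return RCMHit(
        matched_bases=matched,
        raw_score=raw,
        bitscore=scheme.bitscore(raw),
        duplex_energy_kcal_mol=energy,
        up_segment=(t0, t1),
        down_segment=(d0, d1),
    )


def duplex_energy(
    up_segment_seq: str, down_segment_seq: str, scheme: ScoringScheme = ScoringScheme()
) -> float | None:
    """Nearest-neighbor stacking-energy estimate for two matched segments.

    Aligns the segments the same way :func:`rcm_scan` does and sums stack
    terms over consecutive complementary pairs; gapped or mismatched
    positions contribute nothing. Empty input yields None (undefined).
    """
    if not up_segment_seq or not down_segment_seq:
        return None
    _check_seq(up_segment_seq, "upstream segment")
    _check_seq(down_segment_seq, "downstream segment")
    down_rc = reverse_complement(down_segment_seq)
    aligner = _aligner(scheme)
    alignments = aligner.align(up_segment_seq, down_rc)
    try:
        aln = alignments[0]
    except IndexError:
        return 0.0
    return _stack_energy(aln, up_segment_seq, down_rc)


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum


def wilcoxon_rank_sum(
    x, y, alternative: str = "two-sided", method: str | None = None
) -> tuple[float, float]:
    """Mann-Whitney U test of x against y.

    Branch rule: exact enumeration when the pooled sample has <= 12
    observations and no ties, otherwise the normal approximation with tie
    and continuity corrections. ``method`` ('exact'/'asymptotic') overrides.
    Returns (U statistic of x, p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if method is None:
        pooled = np.concatenate([x, y])
        tie_free = np.unique(pooled).size == pooled.size
        method = "exact" if (pooled.size <= 12 and tie_free) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# control-exon null


def sample_control_exons(
    genes: list[GeneModel],
    excluded_gene_ids: set[str],
    target_exon_count_distribution: dict[int, float],
    n_controls: int,
    n_genes: int = 10_000,
    seed: int = 0,
    max_run: int = 6,
) -> list[ControlExon]:
    """Simulated linearly-spliced exon runs matched to the catalog.

    (i) samples ``min(n_genes, eligible)`` non-circ genes without
    replacement; (ii) enumerates every run of 1..``max_run`` consecutive
    exons in the sampled genes; (iii) draws controls so exon-count
    proportions match ``target_exon_count_distribution`` using
    largest-remainder rounding. Deterministic under ``seed``.
    """
    total = sum(target_exon_count_distribution.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError("target distribution must sum to 1")
    rng = np.random.default_rng(seed)
    eligible = [g for g in genes if g.gene_id not in excluded_gene_ids]
    if not eligible:
        raise ValueError("no eligible genes after exclusion")
    order = rng.permutation(len(eligible))
    sampled = [eligible[i] for i in order[: min(n_genes, len(eligible))]]

    runs: dict[int, list[tuple[GeneModel, int, int]]] = {k: [] for k in range(1, max_run + 1)}
    for g in sampled:
        for k in range(1, min(max_run, g.n_exons) + 1):
            for lo in range(1, g.n_exons - k + 2):  # 1-based first rank
                runs[k].append((g, lo, lo + k - 1))

    quotas = _largest_remainder(target_exon_count_distribution, n_controls)
    controls: list[ControlExon] = []
    for k in sorted(quotas):
        q = quotas[k]
        if q == 0:
            continue
        pool = runs.get(k, [])
        if not pool:
            raise ValueError(f"exon-count stratum {k} is empty among sampled genes")
        if len(pool) < q:
            raise ValueError(
                f"exon-count stratum {k} has only {len(pool)} runs, {q} requested"
            )
        for i in rng.choice(len(pool), size=q, replace=False):
            g, lo, hi = pool[int(i)]
            exon_ivs = [g.exons[r - 1] for r in range(lo, hi + 1)]
            locus = Interval(
                g.chromosome,
                min(iv.start for iv in exon_ivs),
                max(iv.end for iv in exon_ivs),
                g.strand,
            )
            controls.append(ControlExon(g.gene_id, list(range(lo, hi + 1)), locus, hi - lo + 1))
    return controls


def _largest_remainder(dist: dict[int, float], n: int) -> dict[int, int]:
    ks = sorted(dist)
    raw = {k: n * dist[k] for k in ks}
    out = {k: int(math.floor(raw[k])) for k in ks}
    short = n - sum(out.values())
    remainders = sorted(ks, key=lambda k: (-(raw[k] - out[k]), k))
    for k in remainders[:short]:
        out[k] += 1
    return out


def catalog_exon_count_distribution(exon_counts, cap: int = 6) -> dict[int, float]:
    """Exon-count proportions of the catalog, counts above ``cap`` pooled."""
    counts = [min(int(c), cap) for c in exon_counts if c >= 1]
    if not counts:
        raise ValueError("no exonic circRNAs to match")
    dist: dict[int, float] = {}
    for c in counts:
        dist[c] = dist.get(c, 0) + 1
    return {k: v / len(counts) for k, v in sorted(dist.items())}


# ---------------------------------------------------------------------------
# flanking extraction


def flanking_introns(
    gene: GeneModel, exon_indices: list[int]
) -> tuple[Interval | None, Interval | None]:
    """(upstream, downstream) flanking introns of a consecutive exon run.

    Indices are 1-based ranks in transcription order. Upstream = the intron
    immediately 5' of the first exon of the run; absent when the run touches
    the gene's terminal exon on that side (or the gene has no introns).
    """
    if not exon_indices:
        raise ValueError("exon_indices is empty")
    lo, hi = min(exon_indices), max(exon_indices)
    introns = gene.introns()
    up = introns[lo - 2] if lo >= 2 else None
    down = introns[hi - 1] if hi <= len(introns) else None
    return up, down


def flanking_window(
    genome: Genome, locus: Interval, width: int = 2000
) -> tuple[str, str]:
    """Immediate ``width`` nt upstream/downstream of a locus, transcription
    orientation, clipped at chromosome ends."""
    if width == 0:
        return "", ""
    clen = genome.length(locus.chromosome)
    left = Interval(locus.chromosome, max(0, locus.start - width), locus.start, locus.strand) \
        if locus.start > 0 else None
    right = Interval(locus.chromosome, locus.end, min(clen, locus.end + width), locus.strand) \
        if locus.end < clen else None
    left_seq = extract_sequence(genome, left) if left else ""
    right_seq = extract_sequence(genome, right) if right else ""
    if locus.strand == "-":
        return right_seq, left_seq
    return left_seq, right_seq


# ---------------------------------------------------------------------------
# Fig-4-style report


def _section(x, y, alternative="two-sided") -> dict:
    if len(x) == 0 or len(y) == 0:
        return {"n_circ": len(x), "n_control": len(y), "U": None, "p": None,
                "median_circ": None, "median_control": None}
    u, p = wilcoxon_rank_sum(x, y, alternative=alternative)
    return {
        "n_circ": len(x),
        "n_control": len(y),
        "median_circ": float(np.median(x)),
        "median_control": float(np.median(y)),
        "U": u,
        "p": p,
    }


def run_flanking_comparison(
    circ_items: list[tuple[GeneModel, list[int]]],
    control_items: list[ControlExon],
    genome: Genome,
    genes_by_id: dict[str, GeneModel],
    scheme: ScoringScheme = ScoringScheme(),
    bins: tuple[float, ...] = (0, 500, 1000, 2000, 5000, math.inf),
    window_width: int = 2000,
    min_bin_n: int = 3,
    include_windows: bool = True,
) -> dict:
    """Compare circRNA flanking introns/windows against the control null.

    Sections: intron_length, matched_bases, bitscore, per-length-bin
    bitscores, 2-kb-window bitscore (optional) and duplex energy; each
    carries n, medians, the U statistic and the rank-sum p. No-hit pairs
    contribute 0 matched bases and 0 bitscore; duplex energy is compared on
    pairs with a hit only.
    """
    if not circ_items or not control_items:
        raise ValueError("both circRNA and control sets must be non-empty")

    def _measure(gene: GeneModel, exon_indices: list[int], locus: Interval | None):
        up_iv, down_iv = flanking_introns(gene, exon_indices)
        rec = {
            "intron_lengths": [],
            "matched": None,
            "bitscore": None,
            "energy": None,
            "mean_len": None,
            "win_bitscore": None,
        }
        if up_iv is not None:
            rec["intron_lengths"].append(up_iv.length)
        if down_iv is not None:
            rec["intron_lengths"].append(down_iv.length)
        if up_iv is not None and down_iv is not None:
            up_seq = extract_sequence(genome, up_iv)
            down_seq = extract_sequence(genome, down_iv)
            hit = rcm_scan(up_seq, down_seq, scheme)
            rec["matched"] = hit.matched_bases if hit else 0
            rec["bitscore"] = hit.bitscore if hit else 0.0
            rec["energy"] = hit.duplex_energy_kcal_mol if hit else None
            rec["mean_len"] = 0.5 * (up_iv.length + down_iv.length)
        if include_windows and locus is not None:
            up_w, down_w = flanking_window(genome, locus, window_width)
            if up_w and down_w:
                whit = rcm_scan(up_w, down_w, scheme)
                rec["win_bitscore"] = whit.bitscore if whit else 0.0
        return rec

    def _locus(gene: GeneModel, exon_indices: list[int]) -> Interval:
        ivs = [gene.exons[r - 1] for r in exon_indices]
        return Interval(
            gene.chromosome,
            min(iv.start for iv in ivs),
            max(iv.end for iv in ivs),
            gene.strand,
        )

    circ_recs = [
        _measure(g, idx, _locus(g, idx)) for g, idx in circ_items
    ]
    ctrl_recs = [
        _measure(genes_by_id[c.gene_id], c.exon_indices, c.locus) for c in control_items
    ]

    def _vals(recs, key):
        return [r[key] for r in recs if r[key] is not None]

    def _flat_lengths(recs):
        return [v for r in recs for v in r["intron_lengths"]]

    report = {
        "intron_length": _section(_flat_lengths(circ_recs), _flat_lengths(ctrl_recs)),
        "matched_bases": _section(_vals(circ_recs, "matched"), _vals(ctrl_recs, "matched")),
        "bitscore": _section(_vals(circ_recs, "bitscore"), _vals(ctrl_recs, "bitscore")),
        "duplex_energy": _section(_vals(circ_recs, "energy"), _vals(ctrl_recs, "energy")),
        "length_bins": {},
    }
    if include_windows:
        report["window_bitscore"] = _section(
            _vals(circ_recs, "win_bitscore"), _vals(ctrl_recs, "win_bitscore")
        )

    edges = list(bins)
    for lo, hi in zip(edges, edges[1:]):
        label = f"[{int(lo)},{'inf' if math.isinf(hi) else int(hi)})"
        cx = [r["bitscore"] for r in circ_recs
              if r["mean_len"] is not None and lo <= r["mean_len"] < hi]
        cy = [r["bitscore"] for r in ctrl_recs
              if r["mean_len"] is not None and lo <= r["mean_len"] < hi]
        if len(cx) < min_bin_n or len(cy) < min_bin_n:
            report["length_bins"][label] = {
                "n_circ": len(cx), "n_control": len(cy), "tested": False,
            }
        else:
            sec = _section(cx, cy)
            sec["tested"] = True
            report["length_bins"][label] = sec
    return report
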