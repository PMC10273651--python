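"""Consensus back-splice-junction catalog from per-tool call tables.

A locus is supported for a (tool, condition) when it is seen in at least
``min_replicates`` biological replicates and at least one replicate reports
``min_reads`` back-spliced reads (a pooled-read variant is available).
Supported loci from all tools and conditions are merged into a unique catalog
keyed by exact BSJ coordinates, with tool-overlap (Venn) accounting and an
optional cross-catalog tissue-specificity comparison.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .genome import Genome, Interval, extract_sequence, locus_id, parse_locus_id

CALL_COLUMNS = ["chrom", "start", "end", "strand", "reads", "tool", "condition", "replicate"]


@dataclass(frozen=True)
class CircCall:
    locus: Interval
    tool: str
    condition: str
    replicate: str
    bsj_reads: int

    def __post_init__(self) -> None:
        if self.bsj_reads < 0:
            raise ValueError("bsj_reads must be >= 0")


@dataclass
class CircRNA:
    circ_id: str
    locus: Interval
    tools_supporting: set[str] = field(default_factory=set)
    conditions_detected: set[str] = field(default_factory=set)
    max_reads: int = 0
    sam_specific: bool | None = None


def read_calls(path_or_dir: str | os.PathLike) -> list[CircCall]:
    """Load call TSVs (one file, or every ``*.tsv`` in a directory).

    Columns: chrom, start (1-based inclusive), end, strand, reads, tool,
    condition, replicate. Coordinates are converted to 0-based half-open.
    """
    p = Path(path_or_dir)
    files = sorted(p.glob("*.tsv")) if p.is_dir() else [p]
    if not files:
        raise FileNotFoundError(f"no call tables under {p}")
    calls: list[CircCall] = []
    for f in files:
        df = pd.read_csv(f, sep="\t")
        missing = set(CALL_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"{f}: missing columns {sorted(missing)}")
        for row in df.itertuples(index=False):
            calls.append(
                CircCall(
                    locus=Interval(str(row.chrom), int(row.start) - 1, int(row.end), str(row.strand)),
                    tool=str(row.tool),
                    condition=str(row.condition),
                    replicate=str(row.replicate),
                    bsj_reads=int(row.reads),
                )
            )
    return calls


def _key(iv: Interval) -> tuple[str, int, int]:
    # strand ignored: detectors report it inconsistently
    return (iv.chromosome, iv.start, iv.end)


def filter_supported(
    calls: list[CircCall],
    design: dict[str, set[str]],
    min_replicates: int = 3,
    min_reads: int = 2,
    pooled_reads: bool = False,
) -> dict[tuple[str, str], dict[tuple[str, int, int], int]]:
    """Per-(tool, condition) supported loci with their max replicate read count.

    ``design`` maps condition -> declared replicate labels; a call carrying an
    undeclared replicate is an error. With ``pooled_reads`` the read rule is
    sum-across-replicates >= min_reads instead of max >= min_reads.
    """
    seen: dict[tuple[str, str], dict[tuple[str, int, int], dict[str, int]]] = {}
    for c in calls:
        if c.condition not in design:
            raise ValueError(f"condition {c.condition!r} not in design")
        if c.replicate not in design[c.condition]:
            raise ValueError(
                f"replicate {c.replicate!r} not declared for condition {c.condition!r}"
            )
        reps = seen.setdefault((c.tool, c.condition), {}).setdefault(_key(c.locus), {})
        reps[c.replicate] = max(reps.get(c.replicate, 0), c.bsj_reads)

    out: dict[tuple[str, str], dict[tuple[str, int, int], int]] = {}
    for tc, loci in seen.items():
        kept = {}
        for key, reps in loci.items():
            if len(reps) < min_replicates:
                continue
            pooled = sum(reps.values())
            best = max(reps.values())
            if (pooled if pooled_reads else best) < min_reads:
                continue
            kept[key] = best
        out[tc] = kept
    return out


def merge_tools_and_conditions(
    supported: dict[tuple[str, str], dict[tuple[str, int, int], int]],
) -> tuple[list[CircRNA], dict[frozenset[str], int]]:
    """Deduplicate supported loci into a catalog plus a tool-combination partition.

    The Venn map keys are frozensets of tool names; its counts partition the
    catalog (every circRNA counted once, under the full set of tools that
    support it).
    """
    by_locus: dict[tuple[str, int, int], CircRNA] = {}
    for (tool, condition), loci in supported.items():
        for key, best in loci.items():
            chrom, start, end = key
            circ = by_locus.get(key)
            if circ is None:
                iv = Interval(chrom, start, end, ".")
                circ = CircRNA(circ_id=locus_id(iv), locus=iv)
                by_locus[key] = circ
            circ.tools_supporting.add(tool)
            circ.conditions_detected.add(condition)
            circ.max_reads = max(circ.max_reads, best)

    catalog = sorted(by_locus.values(), key=lambda c: _key(c.locus))
    venn: dict[frozenset[str], int] = {}
    for c in catalog:
        k = frozenset(c.tools_supporting)
        venn[k] = venn.get(k, 0) + 1
    return catalog, venn


def catalog_to_frame(catalog: list[CircRNA]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "circ_id": [c.circ_id for c in catalog],
            "chrom": [c.locus.chromosome for c in catalog],
            "start": [c.locus.start + 1 for c in catalog],
            "end": [c.locus.end for c in catalog],
            "tools": [",".join(sorted(c.tools_supporting)) for c in catalog],
            "conditions": [",".join(sorted(c.conditions_detected)) for c in catalog],
            "max_reads": [c.max_reads for c in catalog],
            "sam_specific": [c.sam_specific for c in catalog],
        }
    )


def catalog_from_frame(df: pd.DataFrame) -> list[CircRNA]:
    out = []
    for row in df.itertuples(index=False):
        iv = Interval(str(row.chrom), int(row.start) - 1, int(row.end), ".")
        out.append(
            CircRNA(
                circ_id=locus_id(iv),
                locus=iv,
                tools_supporting=set(str(row.tools).split(",")) if row.tools else set(),
                conditions_detected=set(str(row.conditions).split(",")) if row.conditions else set(),
                max_reads=int(row.max_reads),
            )
        )
    return out


# ---------------------------------------------------------------------------
# tissue-specificity comparison against another catalog


def _global_identity(a: str, b: str) -> float:
    """Percent identity of a Needleman-Wunsch global alignment.

    Match +1, mismatch -1, gap -2; identity = matches / alignment length.
    """
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    matrix = substitution_matrices.Array("ACGTN", dims=2)
    for x in "ACGTN":
        for y in "ACGTN":
            matrix[x, y] = 1.0 if (x == y and x != "N") else -1.0
    aligner.substitution_matrix = matrix
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    aln = aligner.align(a, b)[0]
    matches = 0
    length = 0
    ta, qa = aln.aligned
    prev_t_end = prev_q_end = 0
    first = True
    for (ts, te), (qs, qe) in zip(ta, qa):
        if not first:
            length += max(ts - prev_t_end, qs - prev_q_end)
        first = False
        for i in range(te - ts):
            length += 1
            if a[ts + i] == b[qs + i] and a[ts + i] != "N":
                matches += 1
        prev_t_end, prev_q_end = te, qe
    # terminal gaps count toward alignment length in a global alignment
    if ta.size:
        length += ta[0][0] + qa[0][0]
        length += (len(a) - prev_t_end) + (len(b) - prev_q_end)
    else:
        length = max(len(a), len(b))
    return matches / length if length else 0.0


def tissue_overlap(
    catalog: list[CircRNA],
    other_ids: list[str],
    genome: Genome,
    other_genome: Genome | None = None,
    identity_threshold: float = 0.90,
) -> None:
    """Flag catalog circRNAs absent from another tissue catalog.

    A circRNA is non-specific when some other-catalog locus on the same
    chromosome yields >``identity_threshold`` global identity between the two
    genomic sequences. Sets ``sam_specific`` in place.
    """
    other_genome = other_genome or genome
    others = [parse_locus_id(cid) for cid in other_ids]
    other_seqs = [(iv.chromosome, extract_sequence(other_genome, iv)) for iv in others]
    for circ in catalog:
        seq = extract_sequence(genome, circ.locus)
        circ.sam_specific = True
        for chrom, oseq in other_seqs:
            if chrom != circ.locus.chromosome:
                continue  # same-chromosome gate
            if _global_identity(seq, oseq) > identity_threshold:
                circ.sam_specific = False
                break
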