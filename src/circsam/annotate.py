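"""Genomic classification of catalog circRNAs (origin, exon composition).

Categories follow the operational definition used for back-splice catalogs:
*exonic* when the BSJ interval overlaps at least one annotated exon,
*intronic* when it lies entirely inside a single intron, *intergenic* when it
overlaps no gene. Exon membership uses exact splice-site equality at the BSJ
boundaries with a configurable symmetric slack (detector junction wobble).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import GeneModel, Interval
from .consensus import CircRNA
from .flanking import wilcoxon_rank_sum


@dataclass
class CircAnnotation:
    circ_id: str
    locus: Interval
    category: str  # exonic | intronic | intergenic
    utr_overlap: set[str] = field(default_factory=set)  # subset of {"5UTR","3UTR"}
    parent_genes: list[str] = field(default_factory=list)
    exon_indices: list[int] = field(default_factory=list)  # 1-based ranks, first parent
    exon_count: int = 0
    exon_position_class: str = ""  # first | middle | last | single_exon_gene | mixed
    genomic_span_nt: int = 0
    mature_length_nt: int = 0
    partial: bool = False  # genic overlap without clean exon structure

    def __post_init__(self) -> None:
        if self.category == "intergenic" and self.parent_genes:
            raise ValueError("intergenic circRNA cannot have parent genes")


def percentage(count: int, total: int) -> float:
    """100*count/total rounded to 2 decimals (the catalog-summary convention)."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round(100.0 * count / total, 2)


def _counted_exons(circ_iv: Interval, gene: GeneModel, slack: int) -> list[int]:
    """1-based transcription-order ranks of exons belonging to the circle.

    An exon belongs when fully inside the BSJ interval, or when it is a
    boundary exon whose splice site coincides (within ``slack``) with a BSJ
    coordinate and the rest of it lies inside.
    """
    ranks = []
    for rank, ex in enumerate(gene.exons, start=1):
        if ex.chromosome != circ_iv.chromosome:
            continue
        inside = ex.start >= circ_iv.start and ex.end <= circ_iv.end
        left_touch = abs(ex.start - circ_iv.start) <= slack and ex.end <= circ_iv.end + slack
        right_touch = abs(ex.end - circ_iv.end) <= slack and ex.start >= circ_iv.start - slack
        if inside or left_touch or right_touch:
            ranks.append(rank)
    return ranks


def exon_composition(
    circ_iv: Interval, gene: GeneModel, slack: int = 0
) -> tuple[int, str, int]:
    """(exon_count, exon_position_class, mature_length_nt) for a single parent."""
    ranks = _counted_exons(circ_iv, gene, slack)
    if not ranks:
        raise ValueError(
            f"no exon of {gene.gene_id} matches {circ_iv}; circRNA is not exonic here"
        )
    n = gene.n_exons
    if n == 1:
        pclass = "single_exon_gene"
    else:
        has_first, has_last = 1 in ranks, n in ranks
        if has_first and has_last:
            pclass = "mixed"
        elif has_first:
            pclass = "first"
        elif has_last:
            pclass = "last"
        else:
            pclass = "middle"
    mature = 0
    for rank in ranks:
        ex = gene.exons[rank - 1]
        mature += min(ex.end, circ_iv.end) - max(ex.start, circ_iv.start)
    return len(ranks), pclass, mature


def classify_origin(
    circ: CircRNA, genes: list[GeneModel], slack: int = 0
) -> CircAnnotation:
    """Classify one circRNA by genomic origin against the gene models."""
    iv = circ.locus
    ann = CircAnnotation(
        circ_id=circ.circ_id,
        locus=iv,
        category="intergenic",
        genomic_span_nt=iv.length,
    )
    chrom_genes = [g for g in genes if g.chromosome == iv.chromosome]
    if not chrom_genes and genes:
        known = {g.chromosome for g in genes}
        if iv.chromosome not in known:
            warnings.warn(
                f"{circ.circ_id}: chromosome {iv.chromosome!r} absent from annotation; "
                "classified intergenic",
                stacklevel=2,
            )
            return ann

    exon_parents: list[GeneModel] = []
    span_parents: list[GeneModel] = []
    for g in chrom_genes:
        if not g.span.overlaps(iv):
            continue
        span_parents.append(g)
        if any(ex.overlaps(iv) for ex in g.exons):
            exon_parents.append(g)

    if exon_parents:
        ann.category = "exonic"
        ann.parent_genes = [g.gene_id for g in exon_parents]
        total_count = 0
        total_mature = 0
        for g in exon_parents:
            try:
                cnt, pclass, mat = exon_composition(iv, g, slack)
            except ValueError:
                ann.partial = True
                continue
            total_count += cnt
            total_mature += mat
            if g is exon_parents[0]:
                ann.exon_indices = _counted_exons(iv, g, slack)
                ann.exon_position_class = pclass
        if len(exon_parents) > 1:
            ann.exon_position_class = "mixed"
        ann.exon_count = total_count
        ann.mature_length_nt = total_mature
        for g in exon_parents:
            if any(u.overlaps(iv) for u in g.utr5):
                ann.utr_overlap.add("5UTR")
            if any(u.overlaps(iv) for u in g.utr3):
                ann.utr_overlap.add("3UTR")
        if ann.exon_count == 0:
            # exon overlap existed but no exon is cleanly contained
            ann.partial = True
        return ann

    if span_parents:
        for g in span_parents:
            for intron in g.introns():
                if intron.contains(iv):
                    ann.category = "intronic"
                    ann.parent_genes = [g.gene_id]
                    return ann
        # inside a gene body without clean intron containment
        ann.category = "intronic"
        ann.parent_genes = [span_parents[0].gene_id]
        ann.partial = True
    return ann


def annotate_catalog(
    catalog: list[CircRNA], genes: list[GeneModel], slack: int = 0
) -> list[CircAnnotation]:
    return [classify_origin(c, genes, slack) for c in catalog]


def isoform_groups(annotations: list[CircAnnotation]) -> dict[int, int]:
    """Histogram: number of circRNA isoforms per circ-producing gene.

    Returns {isoform_count: n_genes}; multi-gene circRNAs count once per
    constituent gene.
    """
    per_gene: dict[str, int] = {}
    for a in annotations:
        for g in a.parent_genes:
            per_gene[g] = per_gene.get(g, 0) + 1
    hist: dict[int, int] = {}
    for n in per_gene.values():
        hist[n] = hist.get(n, 0) + 1
    return hist


def multi_gene_circs(annotations: list[CircAnnotation]) -> list[CircAnnotation]:
    """circRNAs whose BSJ interval overlaps exons of two or more genes."""
    return [a for a in annotations if a.category == "exonic" and len(a.parent_genes) >= 2]


def summarize_catalog(annotations: list[CircAnnotation]) -> dict:
    """Catalog-level characterization tables.

    Includes category percentages (summing to 100 up to rounding), chromosome
    and exon-count distributions, span/mature length arrays, and the
    single-exon vs multi-exon exon-length comparison (Wilcoxon rank-sum).
    The 2-4-exon and middle-exon shares are reported against all three
    candidate denominators (all, exonic, multi-exon circRNAs) since catalogs
    differ in which they quote.
    """
    if not annotations:
        raise ValueError("empty catalog")
    n = len(annotations)
    cat_counts: dict[str, int] = {}
    chrom_counts: dict[str, int] = {}
    exon_hist: dict[int, int] = {}
    for a in annotations:
        cat_counts[a.category] = cat_counts.get(a.category, 0) + 1
        chrom_counts[a.locus.chromosome] = chrom_counts.get(a.locus.chromosome, 0) + 1
        if a.category == "exonic":
            exon_hist[a.exon_count] = exon_hist.get(a.exon_count, 0) + 1

    exonic = [a for a in annotations if a.category == "exonic"]
    multi = [a for a in exonic if a.exon_count >= 2]
    n_2to4 = sum(1 for a in exonic if 2 <= a.exon_count <= 4)
    n_middle = sum(1 for a in multi if a.exon_position_class == "middle")

    se_lengths = [a.mature_length_nt for a in exonic if a.exon_count == 1]
    me_lengths: list[int] = []
    for a in multi:
        me_lengths.append(a.mature_length_nt // a.exon_count)  # mean exon length

    se_me = None
    if se_lengths and me_lengths:
        stat, p = wilcoxon_rank_sum(se_lengths, me_lengths, alternative="two-sided")
        se_me = {
            "n_se": len(se_lengths),
            "n_me": len(me_lengths),
            "median_se": float(np.median(se_lengths)),
            "median_me": float(np.median(me_lengths)),
            "U": stat,
            "p": p,
        }

    def _safe_pct(k: int, d: int) -> float | None:
        return percentage(k, d) if d else None

    return {
        "n": n,
        "category_counts": cat_counts,
        "category_percent": {k: percentage(v, n) for k, v in cat_counts.items()},
        "chromosome_counts": dict(sorted(chrom_counts.items())),
        "exon_count_histogram": dict(sorted(exon_hist.items())),
        "span_lengths": [a.genomic_span_nt for a in annotations],
        "mature_lengths": [a.mature_length_nt for a in exonic],
        "pct_2to4_exons": {
            "all": _safe_pct(n_2to4, n),
            "exonic": _safe_pct(n_2to4, len(exonic)),
            "multi_exon": _safe_pct(n_2to4, len(multi)),
        },
        "pct_middle_exons": {
            "all": _safe_pct(n_middle, n),
            "exonic": _safe_pct(n_middle, len(exonic)),
            "multi_exon": _safe_pct(n_middle, len(multi)),
        },
        "se_vs_me_exon_length": se_me,
    }


def annotations_to_frame(annotations: list[CircAnnotation]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "circ_id": [a.circ_id for a in annotations],
            "category": [a.category for a in annotations],
            "parent_genes": [",".join(a.parent_genes) for a in annotations],
            "exon_indices": [",".join(map(str, a.exon_indices)) for a in annotations],
            "exon_count": [a.exon_count for a in annotations],
            "position_class": [a.exon_position_class for a in annotations],
            "utr_overlap": [",".join(sorted(a.utr_overlap)) for a in annotations],
            "span_nt": [a.genomic_span_nt for a in annotations],
            "mature_nt": [a.mature_length_nt for a in annotations],
            "partial": [a.partial for a in annotations],
        }
    )
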