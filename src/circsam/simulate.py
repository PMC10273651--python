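"""Self-contained synthetic dataset with planted ground truth.

Generates a toy multi-chromosome genome with multi-exon genes, plants
circRNAs (consecutive exon runs, mostly 2-4 middle exons), reverse
complementary elements in the flanking introns of a configurable fraction of
them, a 4-condition x 3-replicate short-day design of per-tool back-splice
call tables with dropout and noise, a negative-binomial BSJ count matrix with
planted fold changes, miRNAs with planted binding sites (including one
spanning the back-splice junction), gene transcripts, and a GO annotation map
enriched for circRNA parent genes.

All sequence construction happens in transcription space (5'->3' of the
pre-mRNA); minus-strand genes are reverse-complemented once at chromosome
assembly, so planted elements behave identically on either strand.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import (
    Genome,
    Interval,
    locus_id,
    reverse_complement,
    write_fasta_dict,
    write_genome,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

DEFAULT_TOOLS = ("ciri2", "find_circ", "circexplorer2", "circminer")
DEFAULT_CONDITIONS = ("SD0", "SD2", "SD4", "SD6")


class GeometryError(ValueError):
    """Planted features do not fit the configured chromosome geometry."""


@dataclass
class SimConfig:
    """All knobs of the generator; ``seed`` fully determines every output byte."""

    seed: int = 1
    n_chromosomes: int = 4
    chromosome_length_nt: int = 300_000
    n_genes: int = 160
    exons_per_gene_range: tuple[int, int] = (1, 9)
    exon_length_range: tuple[int, int] = (90, 300)
    intron_length_range: tuple[int, int] = (80, 600)
    # circRNA parent genes carry longer introns (length asymmetry of real data)
    circ_intron_length_range: tuple[int, int] = (600, 2500)
    n_circ_true: int = 40
    circ_exon_count_distribution: dict[int, float] = field(
        default_factory=lambda: {1: 0.08, 2: 0.26, 3: 0.26, 4: 0.18, 5: 0.12, 6: 0.10}
    )
    n_single_exon_gene_circs: int = 2
    n_multigene_circs: int = 2
    n_isoform_extra: int = 3  # parent genes hosting a second circ isoform
    rcm_fraction: float = 0.8
    rcm_element_length: int = 60
    rcm_identity: float = 1.0
    conditions: tuple[str, ...] = DEFAULT_CONDITIONS
    n_replicates: int = 3
    tools: tuple[str, ...] = DEFAULT_TOOLS
    dropout_rate: float = 0.05
    noise_call_rate: float = 0.1  # expected noise loci per (tool, condition)
    de_fraction: float = 0.3
    n_common_de: int = 2  # circs stepped at every consecutive pair
    fold_change: float = 4.0
    nb_dispersion: float = 0.05
    count_mean_range: tuple[float, float] = (100.0, 300.0)
    n_mirnas: int = 10
    mirna_length: int = 21
    n_sponge_circs: int = 12
    max_sites_per_circ: int = 4
    mrna_targets_per_mirna: tuple[int, int] = (2, 5)
    n_go_terms: int = 15
    genes_per_term_range: tuple[int, int] = (8, 30)
    intergenic_gap_range: tuple[int, int] = (300, 1500)
    utr_length: int = 30

    def __post_init__(self) -> None:
        for name in ("dropout_rate", "rcm_fraction", "de_fraction", "rcm_identity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0,1]")
        total = sum(self.circ_exon_count_distribution.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("circ_exon_count_distribution must sum to 1")


@dataclass
class CircTruth:
    circ_id: str
    chromosome: str
    start: int  # 0-based half-open, genomic
    end: int
    strand: str
    gene_ids: list[str]
    exon_indices: list[int]  # 1-based ranks in the first parent gene
    exon_count: int
    rcm_planted: bool
    de_pair: str  # "", "SD0:SD2", ... or "all"
    de_direction: str  # "", "up", "down"
    fold_change: float
    mature_length: int


@dataclass
class SiteTruth:
    transcript_id: str  # circ_id or gene_id
    mirna: str
    offset: int  # start on the (mature/spliced) transcript
    spans_junction: bool
    exact: bool


@dataclass
class SimResult:
    config: SimConfig
    outdir: Path
    paths: dict[str, Path]
    circ_truth: list[CircTruth]
    site_truth: list[SiteTruth]
    noise_loci: list[str]
    genome: "Genome" = None
    genes: list = field(default_factory=list)  # GeneModel, transcription-order exons


# ---------------------------------------------------------------------------
# sequence helpers


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, size=n)].tobytes().decode()


def _mutate(rng: np.random.Generator, seq: str, identity: float) -> str:
    n_mut = int(round((1.0 - identity) * len(seq)))
    if n_mut == 0:
        return seq
    pos = rng.choice(len(seq), size=n_mut, replace=False)
    out = list(seq)
    for p in pos:
        out[p] = "ACGT"[(("ACGT".index(out[p])) + int(rng.integers(1, 4))) % 4]
    return "".join(out)


@dataclass
class _GeneDraft:
    gene_id: str
    chromosome: str
    strand: str
    exon_seqs: list[str]
    intron_seqs: list[str]
    is_circ_parent: bool = False
    # filled at assembly: genomic exon intervals in transcription order
    exon_ivs: list[Interval] = field(default_factory=list)

    @property
    def n_exons(self) -> int:
        return len(self.exon_seqs)

    def pre_mrna(self) -> str:
        parts = []
        for i, e in enumerate(self.exon_seqs):
            parts.append(e)
            if i < len(self.intron_seqs):
                parts.append(self.intron_seqs[i])
        return "".join(parts)

    def spliced(self) -> str:
        return "".join(self.exon_seqs)


# ---------------------------------------------------------------------------
# main generator


def generate_dataset(cfg: SimConfig, outdir: str | os.PathLike) -> SimResult:
    """Write the complete synthetic dataset under ``outdir``.

    Deterministic: the same config (including seed) produces byte-identical
    files. Raises :class:`GeometryError` before writing anything if the
    planted genes cannot fit the configured chromosomes.
    """
    rng = np.random.default_rng(cfg.seed)
    outdir = Path(outdir)

    drafts = _draft_genes(cfg, rng)
    circ_plan = _plan_circs(cfg, rng, drafts)
    _plant_rcm(cfg, rng, drafts, circ_plan)
    mirnas, site_truth = _plant_sites(cfg, rng, drafts, circ_plan)
    genome = _assemble(cfg, rng, drafts)
    circ_truth = _finalize_circ_truth(cfg, rng, drafts, circ_plan)

    # site truth was recorded against plan keys before loci existed
    key_to_id = {
        _plan_circ_key(p): t.circ_id for p, t in zip(circ_plan, circ_truth)
    }
    for s in site_truth:
        if s.transcript_id.startswith("plan:"):
            s.transcript_id = key_to_id[s.transcript_id]

    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "calls").mkdir(exist_ok=True)
    paths: dict[str, Path] = {}

    paths["genome"] = outdir / "genome.fa"
    write_genome(genome, paths["genome"])
    paths["annotation"] = outdir / "annotation.gff3"
    _write_gff3(cfg, drafts, paths["annotation"])

    calls, noise_loci = _make_calls(cfg, rng, circ_truth, genome)
    paths["calls_dir"] = outdir / "calls"
    for tool in cfg.tools:
        sub = calls[calls["tool"] == tool]
        sub.to_csv(outdir / "calls" / f"{tool}.tsv", sep="\t", index=False)

    counts, design = _make_counts(cfg, rng, circ_truth)
    paths["counts"] = outdir / "counts.tsv"
    counts.to_csv(paths["counts"], sep="\t")
    paths["design"] = outdir / "design.tsv"
    design.to_csv(paths["design"], sep="\t", index=False)

    paths["mirnas"] = outdir / "mirnas.fa"
    write_fasta_dict({k: v.replace("T", "U") for k, v in mirnas.items()}, paths["mirnas"])
    paths["transcripts"] = outdir / "transcripts.fa"
    write_fasta_dict({d.gene_id: d.spliced() for d in drafts}, paths["transcripts"])

    go_map, go_terms = _make_go(cfg, rng, drafts, circ_truth)
    paths["go_map"] = outdir / "go_map.tsv"
    go_map.to_csv(paths["go_map"], sep="\t", index=False)
    paths["go_terms"] = outdir / "go_terms.tsv"
    go_terms.to_csv(paths["go_terms"], sep="\t", index=False)

    paths["truth"] = outdir / "truth.tsv"
    truth_df = pd.DataFrame(
        [
            {
                **dataclasses.asdict(t),
                "gene_ids": ",".join(t.gene_ids),
                "exon_indices": ",".join(map(str, t.exon_indices)),
            }
            for t in circ_truth
        ]
    )
    truth_df.to_csv(paths["truth"], sep="\t", index=False)
    paths["site_truth"] = outdir / "truth_sites.tsv"
    pd.DataFrame([dataclasses.asdict(s) for s in site_truth]).to_csv(
        paths["site_truth"], sep="\t", index=False
    )

    return SimResult(
        config=cfg,
        outdir=outdir,
        paths=paths,
        circ_truth=circ_truth,
        site_truth=site_truth,
        noise_loci=noise_loci,
        genome=genome,
        genes=[_to_gene_model(cfg, d) for d in drafts],
    )


def _to_gene_model(cfg: SimConfig, d: _GeneDraft):
    from .genome import GeneModel

    parts = dict(_cds_utrs(cfg, d))
    return GeneModel(
        gene_id=d.gene_id,
        chromosome=d.chromosome,
        strand=d.strand,
        exons=list(d.exon_ivs),
        cds_intervals=parts.get("CDS", []),
        utr5=parts.get("five_prime_UTR", []),
        utr3=parts.get("three_prime_UTR", []),
    )


# ---------------------------------------------------------------------------
# stage 1: gene drafts and circRNA plan


def _draft_genes(cfg: SimConfig, rng: np.random.Generator) -> list[_GeneDraft]:
    per_chrom = cfg.n_genes // cfg.n_chromosomes
    drafts: list[_GeneDraft] = []
    lo_e, hi_e = cfg.exons_per_gene_range
    for g in range(cfg.n_genes):
        chrom = f"Chr{(g // per_chrom) % cfg.n_chromosomes + 1:02d}"
        n_ex = int(rng.integers(lo_e, hi_e + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        drafts.append(
            _GeneDraft(
                gene_id=f"Gene{g + 1:04d}",
                chromosome=chrom,
                strand=strand,
                exon_seqs=[
                    _random_seq(rng, int(rng.integers(*cfg.exon_length_range)))
                    for _ in range(n_ex)
                ],
                intron_seqs=[
                    _random_seq(rng, int(rng.integers(*cfg.intron_length_range)))
                    for _ in range(n_ex - 1)
                ],
            )
        )
    return drafts


@dataclass
class _CircPlan:
    gene_idx: list[int]  # indices into drafts (1 normally, 2-3 for multi-gene)
    exon_lo: int  # 0-based first exon index in first gene, transcription order
    exon_hi: int  # 0-based last exon index (inclusive) in last gene
    rcm: bool = False


def _plan_circs(cfg: SimConfig, rng: np.random.Generator, drafts: list[_GeneDraft]) -> list[_CircPlan]:
    ks = sorted(cfg.circ_exon_count_distribution)
    probs = np.array([cfg.circ_exon_count_distribution[k] for k in ks])
    n_single_gene = cfg.n_circ_true - cfg.n_multigene_circs
    counts = rng.multinomial(n_single_gene, probs)
    wanted = [k for k, c in zip(ks, counts) for _ in range(c)]
    rng.shuffle(wanted)

    plans: list[_CircPlan] = []
    used: set[int] = set()

    # single-exon-gene circs take over the 1-exon quota first
    n_seg = min(cfg.n_single_exon_gene_circs, sum(1 for w in wanted if w == 1))
    seg_pool = [i for i, d in enumerate(drafts) if d.n_exons == 1]
    rng.shuffle(seg_pool)
    for i in seg_pool[:n_seg]:
        wanted.remove(1)
        used.add(i)
        drafts[i].is_circ_parent = True
        plans.append(_CircPlan([i], 0, 0))

    # remaining circs: middle consecutive exon runs (flanking introns exist)
    order = list(rng.permutation(len(drafts)))
    for k in wanted:
        host = next(
            (i for i in order if i not in used and drafts[i].n_exons >= k + 2), None
        )
        if host is None:
            raise GeometryError(f"no gene with >= {k + 2} exons left to host a {k}-exon circ")
        used.add(host)
        drafts[host].is_circ_parent = True
        lo = int(rng.integers(1, drafts[host].n_exons - k))
        plans.append(_CircPlan([host], lo, lo + k - 1))

    # multi-gene circs: adjacent same-index pairs forced onto '+' strand
    for m in range(cfg.n_multigene_circs):
        pair = next(
            (
                i
                for i in order
                if i not in used
                and i + 1 not in used
                and i + 1 < len(drafts)
                and drafts[i].chromosome == drafts[i + 1].chromosome
                and drafts[i].n_exons >= 2
                and drafts[i + 1].n_exons >= 2
            ),
            None,
        )
        if pair is None:
            raise GeometryError("no adjacent gene pair available for a multi-gene circ")
        used.update((pair, pair + 1))
        for j in (pair, pair + 1):
            drafts[j].strand = "+"
            drafts[j].is_circ_parent = True
        plans.append(_CircPlan([pair, pair + 1], drafts[pair].n_exons - 1, 0))

    # second isoforms on a few existing single-gene parents
    hosts = [
        p for p in plans if len(p.gene_idx) == 1 and drafts[p.gene_idx[0]].n_exons >= 5
    ]
    for p in hosts[: cfg.n_isoform_extra]:
        d = drafts[p.gene_idx[0]]
        lo = 1 if p.exon_lo != 1 else 2
        if lo + 1 >= d.n_exons - 1 or (lo == p.exon_lo and lo + 1 == p.exon_hi):
            continue
        plans.append(_CircPlan([p.gene_idx[0]], lo, lo + 1))

    # longer introns for every circ-parent gene
    lo_i, hi_i = cfg.circ_intron_length_range
    for d in drafts:
        if d.is_circ_parent:
            d.intron_seqs = [
                _random_seq(rng, int(rng.integers(lo_i, hi_i))) for _ in d.intron_seqs
            ]
    return plans


def _plant_rcm(
    cfg: SimConfig, rng: np.random.Generator, drafts: list[_GeneDraft], plans: list[_CircPlan]
) -> None:
    """Insert reverse-complementary element pairs into flanking introns."""
    eligible = [
        p
        for p in plans
        if len(p.gene_idx) == 1
        and p.exon_lo >= 1
        and p.exon_hi <= drafts[p.gene_idx[0]].n_exons - 2
    ]
    n_plant = int(round(cfg.rcm_fraction * len(eligible)))
    chosen = list(rng.permutation(len(eligible))[:n_plant])
    used_introns: set[tuple[int, int]] = set()
    for ci in chosen:
        p = eligible[ci]
        d = drafts[p.gene_idx[0]]
        up_i, down_i = p.exon_lo - 1, p.exon_hi
        gi = p.gene_idx[0]
        if (gi, up_i) in used_introns or (gi, down_i) in used_introns:
            continue  # isoform circs may share flanking introns; keep elements intact
        used_introns.update({(gi, up_i), (gi, down_i)})
        elem = _random_seq(rng, cfg.rcm_element_length)
        up = d.intron_seqs[up_i]
        down = d.intron_seqs[down_i]
        if len(up) < len(elem) or len(down) < len(elem):
            continue
        pu = int(rng.integers(0, len(up) - len(elem) + 1))
        pdn = int(rng.integers(0, len(down) - len(elem) + 1))
        d.intron_seqs[up_i] = up[:pu] + elem + up[pu + len(elem) :]
        mate = _mutate(rng, reverse_complement(elem), cfg.rcm_identity)
        d.intron_seqs[down_i] = down[:pdn] + mate + down[pdn + len(mate) :]
        p.rcm = True


# ---------------------------------------------------------------------------
# stage 2: miRNAs and binding sites


def _plant_sites(
    cfg: SimConfig, rng: np.random.Generator, drafts: list[_GeneDraft], plans: list[_CircPlan]
):
    mirnas = {
        f"syn-miR{i + 1:03d}": _random_seq(rng, cfg.mirna_length)
        for i in range(cfg.n_mirnas)
    }
    names = list(mirnas)
    site_truth: list[SiteTruth] = []

    def _write_into_exon(d: _GeneDraft, exon_idx: int, pos: int, payload: str) -> None:
        e = d.exon_seqs[exon_idx]
        d.exon_seqs[exon_idx] = e[:pos] + payload + e[pos + len(payload) :]

    # sponge circs: single-gene circs only; distinct miRNAs per circ
    single = [p for p in plans if len(p.gene_idx) == 1]
    order = list(rng.permutation(len(single)))
    n_sponge = min(cfg.n_sponge_circs, len(single))
    junction_done = False
    for rank, oi in enumerate(order[:n_sponge]):
        p = single[oi]
        d = drafts[p.gene_idx[0]]
        n_sites = 1 + int(rng.integers(0, cfg.max_sites_per_circ))
        site_mirnas = [names[i] for i in rng.choice(len(names), size=min(n_sites, len(names)), replace=False)]
        mature_len = sum(
            len(d.exon_seqs[i]) for i in range(p.exon_lo, p.exon_hi + 1)
        )
        taken: list[tuple[int, int]] = []  # occupied mature-coordinate ranges
        for mi, mname in enumerate(site_mirnas):
            site = reverse_complement(mirnas[mname])
            if cfg.mirna_length > mature_len:
                raise GeometryError("miRNA longer than mature circRNA")
            exact = bool(rng.random() < 0.7)
            if not exact:
                # site[2] pairs miRNA position n-2 (=19), outside the doubled core
                site = site[:2] + _flip_base(site[2]) + site[3:]
            if not junction_done and mi == 0 and p.exon_hi > p.exon_lo:
                # split across the back-splice seam
                k = len(site) // 2
                first_e, last_e = p.exon_lo, p.exon_hi
                _write_into_exon(d, last_e, len(d.exon_seqs[last_e]) - k, site[:k])
                _write_into_exon(d, first_e, 0, site[k:])
                site_truth.append(
                    SiteTruth(_plan_circ_key(p), mname, mature_len - k, True, exact)
                )
                taken.append((0, len(site) - k))
                taken.append((mature_len - k, mature_len))
                junction_done = True
                continue
            # interior placement within one circ exon, non-overlapping
            for _ in range(20):
                ei = int(rng.integers(p.exon_lo, p.exon_hi + 1))
                elen = len(d.exon_seqs[ei])
                if elen < len(site) + 2:
                    continue
                pos = int(rng.integers(1, elen - len(site)))
                mpos = sum(len(d.exon_seqs[i]) for i in range(p.exon_lo, ei)) + pos
                if any(mpos < b and a < mpos + len(site) for a, b in taken):
                    continue
                _write_into_exon(d, ei, pos, site)
                site_truth.append(SiteTruth(_plan_circ_key(p), mname, mpos, False, exact))
                taken.append((mpos, mpos + len(site)))
                break

    # mRNA targets for the miRNAs, planted into non-parent gene transcripts;
    # occupied ranges are tracked so sites never overwrite each other
    pool = [d for d in drafts if not d.is_circ_parent]
    occupied: dict[str, list[tuple[int, int]]] = {}
    lo_t, hi_t = cfg.mrna_targets_per_mirna
    used_mirnas = sorted({s.mirna for s in site_truth})
    for mname in used_mirnas:
        n_t = int(rng.integers(lo_t, hi_t + 1))
        for di in rng.choice(len(pool), size=min(n_t, len(pool)), replace=False):
            d = pool[di]
            site = reverse_complement(mirnas[mname])
            taken = occupied.setdefault(d.gene_id, [])
            for _ in range(10):
                ei = int(rng.integers(0, d.n_exons))
                if len(d.exon_seqs[ei]) < len(site) + 2:
                    continue
                pos = int(rng.integers(1, len(d.exon_seqs[ei]) - len(site)))
                offset = sum(len(d.exon_seqs[i]) for i in range(ei)) + pos
                if any(offset < b and a < offset + len(site) for a, b in taken):
                    continue
                _write_into_exon(d, ei, pos, site)
                taken.append((offset, offset + len(site)))
                site_truth.append(SiteTruth(d.gene_id, mname, offset, False, True))
                break
    return mirnas, site_truth


def _flip_base(b: str) -> str:
    return {"A": "C", "C": "A", "G": "T", "T": "G"}[b]


def _plan_circ_key(p: _CircPlan) -> str:
    # temporary key resolved to a locus id after assembly
    return f"plan:{p.gene_idx[0]}:{p.exon_lo}:{p.exon_hi}:{len(p.gene_idx)}"


# ---------------------------------------------------------------------------
# stage 3: chromosome assembly


def _assemble(cfg: SimConfig, rng: np.random.Generator, drafts: list[_GeneDraft]):
    by_chrom: dict[str, list[_GeneDraft]] = {}
    for d in drafts:
        by_chrom.setdefault(d.chromosome, []).append(d)

    chrom_seqs: dict[str, str] = {}
    for chrom in sorted(by_chrom):
        parts: list[str] = []
        pos = 0
        for d in by_chrom[chrom]:
            gap = int(rng.integers(*cfg.intergenic_gap_range))
            parts.append(_random_seq(rng, gap))
            pos += gap
            pre = d.pre_mrna()
            L = len(pre)
            # transcription-order cumulative exon offsets within the pre-mRNA
            cum = 0
            offsets = []
            for i, e in enumerate(d.exon_seqs):
                offsets.append((cum, cum + len(e)))
                cum += len(e)
                if i < len(d.intron_seqs):
                    cum += len(d.intron_seqs[i])
            if d.strand == "+":
                parts.append(pre)
                d.exon_ivs = [
                    Interval(chrom, pos + a, pos + b, "+") for a, b in offsets
                ]
            else:
                parts.append(reverse_complement(pre))
                d.exon_ivs = [
                    Interval(chrom, pos + L - b, pos + L - a, "-") for a, b in offsets
                ]
            pos += L
            if pos > cfg.chromosome_length_nt:
                raise GeometryError(
                    f"genes overflow {chrom}: need {pos} > {cfg.chromosome_length_nt} nt"
                )
        parts.append(_random_seq(rng, cfg.chromosome_length_nt - pos))
        chrom_seqs[chrom] = "".join(parts)
    return Genome(chrom_seqs)


def _finalize_circ_truth(
    cfg: SimConfig, rng: np.random.Generator, drafts: list[_GeneDraft], plans: list[_CircPlan]
) -> list[CircTruth]:
    truths: list[CircTruth] = []
    for p in plans:
        d0 = drafts[p.gene_idx[0]]
        if len(p.gene_idx) == 1:
            ivs = d0.exon_ivs[p.exon_lo : p.exon_hi + 1]
            gene_ids = [d0.gene_id]
            exon_indices = list(range(p.exon_lo + 1, p.exon_hi + 2))
            mature = sum(len(d0.exon_seqs[i]) for i in range(p.exon_lo, p.exon_hi + 1))
        else:
            d1 = drafts[p.gene_idx[-1]]
            ivs = d0.exon_ivs[p.exon_lo :] + d1.exon_ivs[: p.exon_hi + 1]
            gene_ids = [drafts[i].gene_id for i in p.gene_idx]
            exon_indices = list(range(p.exon_lo + 1, d0.n_exons + 1))
            mature = sum(iv.length for iv in ivs)
        start = min(iv.start for iv in ivs)
        end = max(iv.end for iv in ivs)
        iv = Interval(d0.chromosome, start, end, d0.strand)
        truths.append(
            CircTruth(
                circ_id=locus_id(iv),
                chromosome=d0.chromosome,
                start=start,
                end=end,
                strand=d0.strand,
                gene_ids=gene_ids,
                exon_indices=exon_indices,
                exon_count=len(ivs),
                rcm_planted=p.rcm,
                de_pair="",
                de_direction="",
                fold_change=1.0,
                mature_length=mature,
            )
        )

    # assign planted differential expression
    idx = list(rng.permutation(len(truths)))
    n_de = int(round(cfg.de_fraction * len(truths)))
    pairs = [
        f"{a}:{b}" for a, b in zip(cfg.conditions, cfg.conditions[1:])
    ]
    for j, ti in enumerate(idx[:n_de]):
        t = truths[ti]
        t.de_pair = pairs[j % len(pairs)]
        t.de_direction = "up" if rng.random() < 0.5 else "down"
        t.fold_change = cfg.fold_change
    for ti in idx[n_de : n_de + cfg.n_common_de]:
        t = truths[ti]
        t.de_pair = "all"
        t.de_direction = "up"
        t.fold_change = cfg.fold_change
    return truths


# ---------------------------------------------------------------------------
# stage 4: tool call tables, counts, GO


def _make_calls(cfg: SimConfig, rng: np.random.Generator, truths: list[CircTruth], genome: Genome):
    rows = []
    replicates = [f"r{i + 1}" for i in range(cfg.n_replicates)]
    for tool in cfg.tools:
        for cond in cfg.conditions:
            for t in truths:
                for rep in replicates:
                    if rng.random() < cfg.dropout_rate:
                        continue
                    reads = 2 + int(rng.poisson(8))
                    rows.append(
                        (t.chromosome, t.start + 1, t.end, t.strand, reads, tool, cond, rep)
                    )
            # noise loci: appear in too few replicates or with too few reads
            n_noise = int(rng.poisson(cfg.noise_call_rate * len(truths)))
            for _ in range(n_noise):
                chrom = sorted(genome.chromosomes)[
                    int(rng.integers(0, len(genome.chromosomes)))
                ]
                s = int(rng.integers(0, genome.length(chrom) - 500))
                e = s + int(rng.integers(150, 500))
                if rng.random() < 0.5:
                    # few replicates, decent reads
                    for rep in replicates[: cfg.n_replicates - 1][
                        : int(rng.integers(1, max(2, cfg.n_replicates)))
                    ]:
                        rows.append((chrom, s + 1, e, "+", 2 + int(rng.poisson(3)), tool, cond, rep))
                else:
                    # all replicates, single-read support
                    for rep in replicates:
                        rows.append((chrom, s + 1, e, "+", 1, tool, cond, rep))
    df = pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "strand", "reads", "tool", "condition", "replicate"],
    )
    truth_ids = {t.circ_id for t in truths}
    noise = sorted(
        {
            f"{r.chrom}:{r.start}-{r.end}"
            for r in df.itertuples()
            if f"{r.chrom}:{r.start}-{r.end}" not in truth_ids
        }
    )
    return df, noise


def _make_counts(cfg: SimConfig, rng: np.random.Generator, truths: list[CircTruth]):
    conds = list(cfg.conditions)
    samples = [
        (f"{c}_r{i + 1}", c, f"r{i + 1}")
        for c in conds
        for i in range(cfg.n_replicates)
    ]
    lo, hi = np.log(cfg.count_mean_range[0]), np.log(cfg.count_mean_range[1])
    mat = np.zeros((len(truths), len(samples)), dtype=int)
    for r, t in enumerate(truths):
        base = float(np.exp(rng.uniform(lo, hi)))
        means = np.full(len(conds), base)
        if t.de_pair == "all":
            # zigzag so every consecutive pair differs by the fold change
            # without compounding across the series
            step = t.fold_change if t.de_direction == "up" else 1.0 / t.fold_change
            for k in range(1, len(conds)):
                means[k] = base * step if k % 2 else base
        elif t.de_pair:
            later = t.de_pair.split(":")[1]
            ki = conds.index(later)
            fc = t.fold_change if t.de_direction == "up" else 1.0 / t.fold_change
            means[ki:] = base * fc
        for j, (_, c, _) in enumerate(samples):
            mu = means[conds.index(c)]
            n_nb = 1.0 / cfg.nb_dispersion
            p_nb = n_nb / (n_nb + mu)
            mat[r, j] = int(rng.negative_binomial(n_nb, p_nb))
    counts = pd.DataFrame(
        mat, index=[t.circ_id for t in truths], columns=[s[0] for s in samples]
    )
    counts.index.name = "circ_id"
    design = pd.DataFrame(
        [(s, c, r) for s, c, r in samples], columns=["sample", "condition", "replicate"]
    )
    return counts, design


def _make_go(cfg: SimConfig, rng: np.random.Generator, drafts: list[_GeneDraft], truths: list[CircTruth]):
    all_genes = [d.gene_id for d in drafts]
    parents = sorted({g for t in truths for g in t.gene_ids})
    rows = []
    terms = []
    namespaces = ["BP", "MF", "CC"]
    for i in range(cfg.n_go_terms):
        tid = f"GO:{i + 1:07d}"
        ns = namespaces[i % 3]
        parent = f"GO:{(i - 3) + 1:07d}" if i >= 3 and i % 5 == 0 else ""
        terms.append((tid, f"synthetic term {i + 1}", ns, parent))
        if i == 0:
            # planted enrichment: most circ parent genes plus a few background
            members = list(parents[: int(0.7 * len(parents))])
            extra = rng.choice(len(all_genes), size=5, replace=False)
            members += [all_genes[j] for j in extra]
        else:
            k = int(rng.integers(*cfg.genes_per_term_range))
            members = [all_genes[j] for j in rng.choice(len(all_genes), size=k, replace=False)]
        for g in sorted(set(members)):
            rows.append((g, tid))
    go_map = pd.DataFrame(rows, columns=["gene_id", "term_id"])
    go_terms = pd.DataFrame(terms, columns=["term_id", "name", "namespace", "parent_ids"])
    return go_map, go_terms


# ---------------------------------------------------------------------------
# GFF3 writer


def _write_gff3(cfg: SimConfig, drafts: list[_GeneDraft], path: Path) -> None:
    lines = ["##gff-version 3"]
    for d in sorted(drafts, key=lambda d: (d.chromosome, min(iv.start for iv in d.exon_ivs))):
        span_s = min(iv.start for iv in d.exon_ivs) + 1
        span_e = max(iv.end for iv in d.exon_ivs)
        gid, tid = d.gene_id, f"{d.gene_id}.1"
        lines.append(
            f"{d.chromosome}\tcircsam_sim\tgene\t{span_s}\t{span_e}\t.\t{d.strand}\t.\tID={gid}"
        )
        lines.append(
            f"{d.chromosome}\tcircsam_sim\tmRNA\t{span_s}\t{span_e}\t.\t{d.strand}\t.\tID={tid};Parent={gid}"
        )
        for k, iv in enumerate(d.exon_ivs):
            lines.append(
                f"{d.chromosome}\tcircsam_sim\texon\t{iv.start + 1}\t{iv.end}\t.\t{d.strand}\t.\t"
                f"ID={tid}.exon{k + 1};Parent={tid}"
            )
        for kind, ivs in _cds_utrs(cfg, d):
            for iv in ivs:
                lines.append(
                    f"{d.chromosome}\tcircsam_sim\t{kind}\t{iv.start + 1}\t{iv.end}\t.\t{d.strand}\t.\t"
                    f"Parent={tid}"
                )
    path.write_text("\n".join(lines) + "\n")


def _cds_utrs(cfg: SimConfig, d: _GeneDraft):
    """CDS = spliced transcript minus a fixed-width UTR at each end."""
    total = sum(len(e) for e in d.exon_seqs)
    u = cfg.utr_length
    if total <= 3 * u:
        return [("CDS", _tx_to_genomic(d, 0, total))]
    return [
        ("five_prime_UTR", _tx_to_genomic(d, 0, u)),
        ("CDS", _tx_to_genomic(d, u, total - u)),
        ("three_prime_UTR", _tx_to_genomic(d, total - u, total)),
    ]


def _tx_to_genomic(d: _GeneDraft, ta: int, tb: int) -> list[Interval]:
    """Map a transcript-coordinate range to genomic intervals (genomic order)."""
    out = []
    cum = 0
    for e_seq, iv in zip(d.exon_seqs, d.exon_ivs):
        a, b = cum, cum + len(e_seq)
        lo, hi = max(ta, a), min(tb, b)
        if lo < hi:
            if d.strand == "+":
                out.append(Interval(iv.chromosome, iv.start + (lo - a), iv.start + (hi - a), "+"))
            else:
                out.append(Interval(iv.chromosome, iv.end - (hi - a), iv.end - (lo - a), "-"))
        cum = b
    return sorted(out, key=lambda iv: iv.start)
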