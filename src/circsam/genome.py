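"""Genome, annotation and interval primitives shared by every pipeline stage.

Internal coordinates are 0-based half-open throughout; the 1-based inclusive
convention of GFF3 and of circRNA identifiers such as ``Gm11:8912235-8915252``
is converted exactly once, at the I/O boundary.
"""

from __future__ import annotations

import io
import os
import tempfile
from dataclasses import dataclass, field

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class GenomeFormatError(ValueError):
    """Raised for malformed FASTA/GFF3 input."""


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string over the ACGTN alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, order=True)
class Interval:
    """A genomic interval, 0-based half-open, with optional strand.

    ``strand`` is '+', '-' or '.' (unstranded).
    """

    chromosome: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chromosome}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.chromosome == other.chromosome
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "Interval") -> bool:
        return (
            self.chromosome == other.chromosome
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass
class Genome:
    """Chromosome-name -> uppercase ACGTN sequence."""

    chromosomes: dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.chromosomes.items():
            if not seq:
                raise GenomeFormatError(f"chromosome {name!r} is empty")
            bad = set(seq) - VALID_ALPHABET
            if bad:
                raise GenomeFormatError(
                    f"chromosome {name!r} contains invalid symbols {sorted(bad)}"
                )

    def __contains__(self, name: str) -> bool:
        return name in self.chromosomes

    def length(self, name: str) -> int:
        return len(self.chromosomes[name])


@dataclass
class GeneModel:
    """One gene with a single mRNA isoform.

    ``exons`` are 0-based half-open intervals sorted 5'->3' in transcription
    order: ascending genomic coordinate on '+', descending on '-'.
    """

    gene_id: str
    chromosome: str
    strand: str
    exons: list[Interval]
    cds_intervals: list[Interval] = field(default_factory=list)
    utr5: list[Interval] = field(default_factory=list)
    utr3: list[Interval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        if not self.exons:
            raise GenomeFormatError(f"gene {self.gene_id} has no exons")
        genomic = sorted(self.exons, key=lambda iv: iv.start)
        for a, b in zip(genomic, genomic[1:]):
            if a.end > b.start:
                raise GenomeFormatError(
                    f"gene {self.gene_id}: overlapping exons {a} / {b}"
                )

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def span(self) -> Interval:
        starts = [iv.start for iv in self.exons]
        ends = [iv.end for iv in self.exons]
        return Interval(self.chromosome, min(starts), max(ends), self.strand)

    def exons_genomic_order(self) -> list[Interval]:
        return sorted(self.exons, key=lambda iv: iv.start)

    def introns(self) -> list[Interval]:
        """Introns in transcription order (gaps between consecutive exons)."""
        genomic = self.exons_genomic_order()
        introns = [
            Interval(self.chromosome, a.end, b.start, self.strand)
            for a, b in zip(genomic, genomic[1:])
        ]
        if self.strand == "-":
            introns.reverse()
        return introns


# ---------------------------------------------------------------------------
# FASTA


def read_genome(path: str | os.PathLike, *, allow_u: bool = False) -> Genome:
    """Load a FASTA genome; lowercase is normalized to uppercase.

    ``allow_u`` converts RNA-style U/u to T instead of rejecting the record.
    """
    chromosomes: dict[str, str] = {}
    n = 0
    for record in SeqIO.parse(os.fspath(path), "fasta"):
        n += 1
        name = record.id
        if name in chromosomes:
            raise GenomeFormatError(f"duplicate chromosome name {name!r}")
        seq = str(record.seq).upper()
        if allow_u:
            seq = seq.replace("U", "T")
        bad = set(seq) - VALID_ALPHABET
        if bad:
            raise GenomeFormatError(
                f"record {name!r} contains invalid symbols {sorted(bad)}"
            )
        chromosomes[name] = seq
    if n == 0:
        raise GenomeFormatError(f"no FASTA records found in {path}")
    return Genome(chromosomes)


def write_genome(genome: Genome, path: str | os.PathLike, width: int = 70) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in genome.chromosomes.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def read_fasta_dict(path: str | os.PathLike, *, rna_to_dna: bool = True) -> dict[str, str]:
    """Plain name->sequence FASTA reader (miRNAs, transcripts)."""
    out: dict[str, str] = {}
    for record in SeqIO.parse(os.fspath(path), "fasta"):
        seq = str(record.seq).upper()
        if rna_to_dna:
            seq = seq.replace("U", "T")
        out[record.id] = seq
    if not out:
        raise GenomeFormatError(f"no FASTA records found in {path}")
    return out


def write_fasta_dict(seqs: dict[str, str], path: str | os.PathLike, width: int = 70) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# GFF3


def read_annotation(path: str | os.PathLike) -> list[GeneModel]:
    """Parse a GFF3 file into one GeneModel per gene (first-listed mRNA).

    GFF3 coordinates (1-based inclusive) are converted to 0-based half-open.
    Orphan exons (unresolvable Parent) and genes without exons are errors.
    """
    db = gffutils.create_db(
        os.fspath(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="error",
    )
    known_tx = {f.id for f in db.features_of_type("mRNA")}
    known_genes = {f.id for f in db.features_of_type("gene")}
    for feat in db.features_of_type(("exon", "CDS", "five_prime_UTR", "three_prime_UTR")):
        parents = feat.attributes.get("Parent", [])
        if not parents or not any(p in known_tx for p in parents):
            raise GenomeFormatError(
                f"{feat.featuretype} at {feat.seqid}:{feat.start}-{feat.end} "
                "has no resolvable mRNA parent"
            )

    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene", order_by=("seqid", "start")):
        mrnas = list(db.children(gene, featuretype="mRNA", order_by="start"))
        if not mrnas:
            raise GenomeFormatError(f"gene {gene.id} has no mRNA")
        mrna = mrnas[0]  # one isoform per gene: first listed

        def _ivs(ftype: str) -> list[Interval]:
            ivs = [
                Interval(f.seqid, f.start - 1, f.end, gene.strand)
                for f in db.children(mrna, featuretype=ftype, order_by="start")
            ]
            return ivs

        exons = _ivs("exon")
        if not exons:
            raise GenomeFormatError(f"gene {gene.id} has no exons")
        if gene.strand == "-":
            exons = exons[::-1]
        genes.append(
            GeneModel(
                gene_id=gene.id,
                chromosome=gene.seqid,
                strand=gene.strand,
                exons=exons,
                cds_intervals=_ivs("CDS"),
                utr5=_ivs("five_prime_UTR"),
                utr3=_ivs("three_prime_UTR"),
            )
        )
    return genes


def extract_sequence(genome: Genome, iv: Interval) -> str:
    """Sequence of ``iv``; minus-strand intervals return the reverse complement."""
    if iv.chromosome not in genome:
        raise KeyError(f"unknown chromosome {iv.chromosome!r}")
    chrom = genome.chromosomes[iv.chromosome]
    if iv.end > len(chrom):
        raise ValueError(
            f"interval {iv.chromosome}:{iv.start}-{iv.end} exceeds "
            f"chromosome length {len(chrom)}"
        )
    seq = chrom[iv.start : iv.end]
    return reverse_complement(seq) if iv.strand == "-" else seq


# ---------------------------------------------------------------------------
# circRNA-style 1-based locus IDs


def locus_id(iv: Interval) -> str:
    """External 1-based inclusive ID, e.g. 'Gm11:8912235-8915252'."""
    return f"{iv.chromosome}:{iv.start + 1}-{iv.end}"


def parse_locus_id(circ_id: str) -> Interval:
    chrom, _, coords = circ_id.rpartition(":")
    if not chrom:
        raise ValueError(f"malformed locus id {circ_id!r}")
    start_s, _, end_s = coords.partition("-")
    return Interval(chrom, int(start_s) - 1, int(end_s))
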