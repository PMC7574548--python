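"""Genome and gene-annotation handling.

Reads the genome (FASTA) and protein-coding gene models (GFF3), extends ORFs
to transcribed spans with measured or default UTR lengths, derives intergenic
regions (IGRs) on chromosome arms, classifies IGRs by flanking-gene
orientation, and computes RPKM expression levels.

Fission yeast gene models frequently lack annotated UTRs; following the
genome-wide mean UTR lengths, ORFs without explicit UTR features are extended
by 293 bp upstream (5' UTR) and 430 bp downstream (3' UTR), strand-mirrored
and clamped to the chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
from Bio import SeqIO

from .intervals import ArmMask, GenomicInterval, complement_intervals

__all__ = [
    "GeneModel",
    "IGR",
    "read_genome",
    "read_genes",
    "derive_igrs",
    "classify_orientation",
    "classify_second_orientation",
    "compute_rpkm",
    "attach_expression",
]

UTR5_DEFAULT = 293
UTR3_DEFAULT = 430

#: attribute keywords that flag a dubious ORF (case-insensitive substring match)
DUBIOUS_KEYWORDS = ("dubious",)


@dataclass
class GeneModel:
    """A protein-coding gene: ORF plus transcribed extent.

    ``tss``/``tts`` are stored as half-open span boundaries: for a ``+`` gene
    the transcribed span is ``[tss, tts)``; for a ``-`` gene it is
    ``[tts, tss)`` (tss numerically right of tts).
    """

    gene_id: str
    orf: GenomicInterval
    tss: int
    tts: int
    rpkm: float = 0.0
    exon_length: int | None = None

    def __post_init__(self) -> None:
        if self.orf.strand == "+":
            if not (self.tss <= self.orf.start and self.tts >= self.orf.end):
                raise ValueError(f"{self.gene_id}: transcribed span must contain ORF")
        elif self.orf.strand == "-":
            if not (self.tss >= self.orf.end and self.tts <= self.orf.start):
                raise ValueError(f"{self.gene_id}: transcribed span must contain ORF")
        else:
            raise ValueError(f"{self.gene_id}: gene needs a strand")
        if self.exon_length is None:
            self.exon_length = self.orf.width

    @property
    def strand(self) -> str:
        return self.orf.strand

    @property
    def span(self) -> GenomicInterval:
        """Transcribed extent as a half-open interval (used for IGR derivation)."""
        lo, hi = sorted((self.tss, self.tts))
        return GenomicInterval(self.orf.chrom, lo, hi, self.orf.strand)


@dataclass
class IGR:
    """An intergenic region with its flanking genes and orientation classes."""

    interval: GenomicInterval
    left_gene: GeneModel | None
    right_gene: GeneModel | None
    orientation: str = "edge"
    second_orientation: str = "edge"


def read_genome(fasta_path: str | Path) -> dict[str, str]:
    """Read a FASTA genome into a chrom -> uppercase sequence map."""
    genome: dict[str, str] = {}
    for record in SeqIO.parse(str(fasta_path), "fasta"):
        if record.id in genome:
            raise ValueError(f"duplicate chromosome name {record.id!r}")
        genome[record.id] = str(record.seq).upper()
    if not genome:
        raise ValueError(f"no records in {fasta_path}")
    return genome


def _is_dubious(feature, keywords: Sequence[str]) -> bool:
    text = " ".join(
        " ".join(vals).lower() for vals in feature.attributes.values()
    )
    return any(k.lower() in text for k in keywords)


def read_genes(
    gff_path: str | Path,
    utr5_default: int = UTR5_DEFAULT,
    utr3_default: int = UTR3_DEFAULT,
    chrom_lengths: Mapping[str, int] | None = None,
    dubious_keywords: Sequence[str] = DUBIOUS_KEYWORDS,
) -> list[GeneModel]:
    """Read protein-coding gene models from GFF3 (1-based, inclusive on disk).

    Genes with explicit ``five_prime_UTR``/``three_prime_UTR`` children keep
    their annotated transcribed span; the rest get the default UTR
    extensions, clamped to ``[0, chromosome length]`` when lengths are known.
    Dubious ORFs (attribute keyword match) are excluded.
    """
    db = gffutils.create_db(
        str(gff_path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes: list[GeneModel] = []
    for g in db.features_of_type("gene"):
        if _is_dubious(g, dubious_keywords):
            continue
        if g.strand not in ("+", "-"):
            raise ValueError(f"gene {g.id}: missing strand")
        cds = list(db.children(g, featuretype="CDS"))
        if cds:
            orf_start = min(c.start for c in cds) - 1  # GFF3 -> 0-based half-open
            orf_end = max(c.end for c in cds)
            exon_length = sum(c.end - c.start + 1 for c in cds)
        else:
            orf_start, orf_end = g.start - 1, g.end
            exon_length = orf_end - orf_start
        if chrom_lengths is not None:
            length = chrom_lengths.get(g.seqid)
            if length is None:
                raise ValueError(f"gene {g.id}: unknown chromosome {g.seqid!r}")
            if orf_start < 0 or orf_end > length:
                raise ValueError(f"gene {g.id}: CDS outside chromosome")
        orf = GenomicInterval(g.seqid, orf_start, orf_end, g.strand)

        utr5 = list(db.children(g, featuretype="five_prime_UTR"))
        utr3 = list(db.children(g, featuretype="three_prime_UTR"))
        if g.strand == "+":
            tss = min(u.start for u in utr5) - 1 if utr5 else orf_start - utr5_default
            tts = max(u.end for u in utr3) if utr3 else orf_end + utr3_default
        else:
            tss = max(u.end for u in utr5) if utr5 else orf_end + utr5_default
            tts = min(u.start for u in utr3) - 1 if utr3 else orf_start - utr3_default
        if chrom_lengths is not None:
            length = chrom_lengths[g.seqid]
            tss = min(max(tss, 0), length)
            tts = min(max(tts, 0), length)
        else:
            tss, tts = max(tss, 0), max(tts, 0)
        genes.append(GeneModel(g.id, orf, tss, tts, exon_length=exon_length))
    genes.sort(key=lambda gm: (gm.orf.chrom, gm.span.start, gm.span.end))
    return genes


def _orient(left: GeneModel | None, right: GeneModel | None) -> str:
    if left is None or right is None:
        return "edge"
    if left.strand == right.strand:
        return "tandem"
    if left.strand == "-" and right.strand == "+":
        return "divergent"
    return "convergent"


def classify_orientation(igr: IGR) -> str:
    """Orientation from the flanking genes: (-,+) divergent, (+,-) convergent,
    same-strand tandem; 'edge' when a flank is missing."""
    return _orient(igr.left_gene, igr.right_gene)


def classify_second_orientation(igr: IGR, genes: Sequence[GeneModel]) -> str:
    """Same rule applied to the genes one further out on each side."""
    if igr.left_gene is None or igr.right_gene is None:
        return "edge"
    chrom_genes = sorted(
        (g for g in genes if g.orf.chrom == igr.interval.chrom),
        key=lambda g: (g.span.start, g.span.end),
    )
    try:
        li = chrom_genes.index(igr.left_gene)
        ri = chrom_genes.index(igr.right_gene)
    except ValueError:
        return "edge"
    left2 = chrom_genes[li - 1] if li >= 1 else None
    right2 = chrom_genes[ri + 1] if ri + 1 < len(chrom_genes) else None
    return _orient(left2, right2)


def derive_igrs(
    genes: Sequence[GeneModel],
    arm_mask: ArmMask,
    chrom_lengths: Mapping[str, int],
) -> list[IGR]:
    """Complement of the union of transcribed gene spans on chromosome arms.

    Zero-length gaps are dropped and overlapping genes yield no IGR between
    them. An IGR flanked by an arm edge (mask or chromosome end) on one side
    carries orientation class ``edge``.
    """
    arms = arm_mask.arms(chrom_lengths)
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.orf.chrom, []).append(g)
    igrs: list[IGR] = []
    for chrom in sorted(chrom_lengths):
        chrom_genes = sorted(
            by_chrom.get(chrom, []), key=lambda g: (g.span.start, g.span.end)
        )
        spans = [g.span for g in chrom_genes]
        for arm in arms.get(chrom, []):
            for gap in complement_intervals(spans, arm):
                left = right = None
                for g in chrom_genes:  # genes are few per arm; linear scan is fine
                    s = g.span
                    if s.end <= gap.start and s.end > arm.start:
                        if left is None or s.end > left.span.end:
                            left = g
                    if s.start >= gap.end and s.start < arm.end:
                        if right is None or s.start < right.span.start:
                            right = g
                # a flanking gene must actually touch this arm
                if left is not None and left.span.end <= arm.start:
                    left = None
                if right is not None and right.span.start >= arm.end:
                    right = None
                igr = IGR(gap, left, right)
                igr.orientation = classify_orientation(igr)
                igr.second_orientation = classify_second_orientation(igr, chrom_genes)
                igrs.append(igr)
    return igrs


def compute_rpkm(
    gene: GeneModel, mapped_read_count_on_exons: float, total_mapped_reads: float
) -> float:
    """Reads per kilobase of exon per million mapped reads."""
    if total_mapped_reads <= 0:
        raise ValueError("total_mapped_reads must be > 0")
    if not gene.exon_length or gene.exon_length <= 0:
        raise ValueError("exon length must be > 0")
    return mapped_read_count_on_exons / (
        (gene.exon_length / 1000.0) * (total_mapped_reads / 1e6)
    )


def attach_expression(
    genes: Iterable[GeneModel], table: Mapping[str, float]
) -> None:
    """Set per-gene RPKM from a gene_id -> rpkm mapping (missing genes keep 0)."""
    for g in genes:
        if g.gene_id in table:
            g.rpkm = float(table[g.gene_id])
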