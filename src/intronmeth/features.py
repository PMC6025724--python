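"""Gene models and the gene-feature partition.

A gene is partitioned into promoter, first exon, rest of exons, first
intron, rest of introns and the gene body.  "First" is meant in
transcription order, i.e. strand-aware: on the minus strand the first exon
is the genomically last one.  The promoter is a fixed-length window
immediately upstream of the annotated TSS.  All coordinates are 0-based
half-open internally; the 1-based closed convention of GFF3 is converted at
the I/O boundary.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import gffutils

from .constants import FLANK_BP, PROMOTER_LENGTH

log = logging.getLogger(__name__)

Interval = tuple[int, int]


@dataclass
class GeneModel:
    """A collapsed, gene-level transcript model.

    exons are non-overlapping (start, end) intervals sorted by genomic
    start.  ``chrom_length`` (if known) is used to clip promoter and flank
    windows at chromosome edges.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: list[Interval]
    chrom_length: Optional[int] = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be + or -, got {self.strand!r}")
        if not self.exons:
            raise ValueError(f"{self.gene_id}: gene without exons")
        self.exons = sorted((int(s), int(e)) for s, e in self.exons)
        prev_end = None
        for s, e in self.exons:
            if e <= s:
                raise ValueError(f"{self.gene_id}: empty exon [{s},{e})")
            if prev_end is not None and s < prev_end:
                raise ValueError(f"{self.gene_id}: overlapping exons")
            prev_end = e

    @property
    def tss(self) -> int:
        """Genomic coordinate of the transcription start site."""
        return self.exons[0][0] if self.strand == "+" else self.exons[-1][1]

    @property
    def utr3_end(self) -> int:
        """Genomic coordinate of the gene 3' terminus."""
        return self.exons[-1][1] if self.strand == "+" else self.exons[0][0]

    @property
    def gene_body(self) -> Interval:
        return (self.exons[0][0], self.exons[-1][1])

    @property
    def introns(self) -> list[Interval]:
        """Gaps between consecutive exons, in genomic order."""
        return [
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        ]


@dataclass
class GeneFeatureSet:
    """The feature partition of one gene.

    first_exon/rest_exons and first_intron/rest_introns tile the gene body
    exactly; the promoter lies outside it.  ``first_intron`` is None for
    single-exon genes.
    """

    gene_id: str
    chrom: str
    strand: str
    promoter: Interval
    first_exon: Interval
    rest_exons: list[Interval] = field(default_factory=list)
    first_intron: Optional[Interval] = None
    rest_introns: list[Interval] = field(default_factory=list)
    gene_body: Interval = (0, 0)

    def intervals(self, feature: str) -> list[Interval]:
        """All intervals of one feature class (possibly empty)."""
        val = getattr(self, feature)
        if val is None:
            return []
        if isinstance(val, tuple):
            return [val]
        return list(val)


FEATURE_CLASSES = (
    "promoter",
    "first_exon",
    "first_intron",
    "rest_exons",
    "rest_introns",
    "gene_body",
)


def read_gff3(path: str | os.PathLike) -> list[GeneModel]:
    """Parse a GFF3 file into one :class:`GeneModel` per gene.

    Multi-transcript genes are collapsed to the transcript with the longest
    genomic span (ties broken by smallest start).  Genes without any exon
    are skipped with a warning.  Chromosome lengths are taken from
    ``##sequence-region`` pragmas when present.
    """
    chrom_lengths: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("##sequence-region"):
                parts = line.split()
                if len(parts) >= 4:
                    chrom_lengths[parts[1]] = int(parts[3])
            elif line and not line.startswith("#"):
                break

    try:
        db = gffutils.create_db(
            str(path),
            ":memory:",
            merge_strategy="create_unique",
            keep_order=True,
        )
    except gffutils.exceptions.EmptyInputError:
        return []
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        transcripts = list(db.children(gene, featuretype=("mRNA", "transcript")))
        if transcripts:
            # longest genomic span; ties -> smallest start
            best = min(transcripts, key=lambda t: (-(t.end - t.start + 1), t.start))
            exon_parents = [best]
        else:
            exon_parents = [gene]
        exons: list[Interval] = []
        for parent in exon_parents:
            for ex in db.children(parent, featuretype="exon"):
                exons.append((ex.start - 1, ex.end))  # GFF3 1-based closed -> 0-based half-open
        if not exons:
            log.warning("gene %s has no exons; skipped", gene.id)
            continue
        genes.append(
            GeneModel(
                gene_id=gene.id,
                chrom=gene.seqid,
                strand=gene.strand,
                exons=sorted(set(exons)),
                chrom_length=chrom_lengths.get(gene.seqid),
            )
        )
    return genes


def _clip(start: int, end: int, chrom_length: Optional[int]) -> Interval:
    start = max(0, start)
    if chrom_length is not None:
        end = min(end, chrom_length)
    return (start, max(start, end))


def derive_promoter(g: GeneModel, length: int = PROMOTER_LENGTH) -> Interval:
    """Fixed-length window immediately upstream of the TSS, strand-aware."""
    if g.strand == "+":
        return _clip(g.tss - length, g.tss, g.chrom_length)
    return _clip(g.tss, g.tss + length, g.chrom_length)


def derive_features(g: GeneModel, promoter_length: int = PROMOTER_LENGTH) -> GeneFeatureSet:
    """Partition a gene into its feature classes (transcription order)."""
    introns = g.introns
    if g.strand == "+":
        first_exon = g.exons[0]
        rest_exons = g.exons[1:]
        first_intron = introns[0] if introns else None
        rest_introns = introns[1:]
    else:
        first_exon = g.exons[-1]
        rest_exons = g.exons[:-1]
        first_intron = introns[-1] if introns else None
        rest_introns = introns[:-1]
    return GeneFeatureSet(
        gene_id=g.gene_id,
        chrom=g.chrom,
        strand=g.strand,
        promoter=derive_promoter(g, promoter_length),
        first_exon=first_exon,
        rest_exons=list(rest_exons),
        first_intron=first_intron,
        rest_introns=list(rest_introns),
        gene_body=g.gene_body,
    )


def flank_window(g: GeneModel, flank: int = FLANK_BP) -> Interval:
    """Gene body extended by ``flank`` bp on both genomic sides, clipped."""
    s, e = g.gene_body
    return _clip(s - flank, e + flank, g.chrom_length)


def write_feature_bed(features: Sequence[GeneFeatureSet], path: str | os.PathLike) -> None:
    """Export all feature intervals as BED6 (name = gene_id|feature)."""
    with open(path, "w") as fh:
        for fs in features:
            for feat in FEATURE_CLASSES:
                for s, e in fs.intervals(feat):
                    fh.write(
                        f"{fs.chrom}\t{s}\t{e}\t{fs.gene_id}|{feat}\t0\t{fs.strand}\n"
                    )
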