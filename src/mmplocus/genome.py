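"""Genomic interval model, the Chr11q22.2 MMP locus, and BED-style I/O.

All coordinates are held internally in the BED convention: 0-based,
half-open ``[start, end)``.  Conversion to the 1-based inclusive coordinates
used for display happens only in :func:`to_display` / :func:`parse_region`,
so there is exactly one place an off-by-one can live.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable

__all__ = [
    "GenomicInterval",
    "GeneAnnotation",
    "ElementAnnotation",
    "LocusModel",
    "IE8",
    "overlaps",
    "read_bed",
    "write_bed",
    "to_display",
    "parse_region",
    "default_mmp_locus",
]

_STRANDS = {"+", "-", "."}
_CLUSTERS = {"5prime", "3prime", "none"}


@dataclass(frozen=True)
class GenomicInterval:
    """A strand-aware genomic interval, 0-based half-open.

    Parameters
    ----------
    chrom : str
        Chromosome name (e.g. ``"chr11"``).
    start, end : int
        0-based half-open coordinates; ``end > start >= 0``.
    strand : str
        One of ``"+"``, ``"-"``, ``"."``.  The unknown strand ``"."`` is
        treated as ``"+"`` wherever orientation matters (TSS flanks).
    name : str, optional
        Free-text label (BED column 4).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str | None = None

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must be > start, got [{self.start}, {self.end})"
            )
        if self.strand not in _STRANDS:
            raise ValueError(f"strand must be one of {_STRANDS}, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)

    def overlaps(self, other: "GenomicInterval") -> bool:
        return overlaps(self, other)

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff the two half-open intervals share at least one base."""
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


def overlap_length(a: GenomicInterval, b: GenomicInterval) -> int:
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene with its strand-resolved TSS and locus-cluster membership."""

    interval: GenomicInterval
    gene_id: str
    tss: int
    cluster_label: str = "none"

    def __post_init__(self) -> None:
        if not self.interval.contains(self.tss):
            raise ValueError(
                f"TSS {self.tss} of {self.gene_id} outside "
                f"[{self.interval.start}, {self.interval.end})"
            )
        if self.cluster_label not in _CLUSTERS:
            raise ValueError(
                f"cluster_label must be one of {_CLUSTERS}, got {self.cluster_label!r}"
            )

    def tss_window(self, flank: int) -> GenomicInterval:
        """Symmetric window ``[tss - flank, tss + flank)``, clipped at 0."""
        return GenomicInterval(
            self.interval.chrom,
            max(0, self.tss - flank),
            self.tss + flank,
            self.interval.strand,
            name=f"{self.gene_id}_tss",
        )


@dataclass(frozen=True)
class ElementAnnotation:
    """A regulatory element with its functional class."""

    interval: GenomicInterval
    kind: str  # insulator | enhancer | promoter | other

    def __post_init__(self) -> None:
        if self.kind not in {"insulator", "enhancer", "promoter", "other"}:
            raise ValueError(f"unknown element kind {self.kind!r}")


@dataclass
class LocusModel:
    """A gene cluster split in two by an insulator boundary.

    ``genes`` must be sorted by start coordinate and every gene must fall on
    exactly one side of the boundary midpoint (by its TSS).
    """

    genes: list[GeneAnnotation]
    boundary: GenomicInterval
    elements: list[ElementAnnotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        starts = [g.interval.start for g in self.genes]
        if starts != sorted(starts):
            raise ValueError("locus genes must be sorted by start coordinate")
        lo = min(g.interval.start for g in self.genes)
        hi = max(g.interval.end for g in self.genes)
        if not (lo <= self.boundary.midpoint <= hi):
            raise ValueError("boundary must lie within the locus span")
        mid = self.boundary.midpoint
        for g in self.genes:
            if g.tss == mid:
                raise ValueError(f"gene {g.gene_id} TSS sits exactly on the boundary")

    @property
    def chrom(self) -> str:
        return self.boundary.chrom

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom,
            min(g.interval.start for g in self.genes),
            max(g.interval.end for g in self.genes),
            name="locus",
        )

    def side_of(self, gene: GeneAnnotation) -> str:
        """Side of the boundary midpoint the gene's TSS falls on.

        Lower coordinates are the 5' side of the locus.
        """
        return "5prime" if gene.tss < self.boundary.midpoint else "3prime"

    def genes_on(self, side: str) -> list[GeneAnnotation]:
        if side not in {"5prime", "3prime"}:
            raise ValueError("side must be '5prime' or '3prime'")
        return [g for g in self.genes if g.cluster_label == side]

    def gene(self, gene_id: str) -> GeneAnnotation:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)


# The IE8 insulator anchor, stored BED-style (0-based half-open).
IE8 = GenomicInterval("chr11", 102_732_800, 102_733_900, "+", "IE8")

# Approximate hg38 gene spans for the Chr11q22.2 cluster (start, end, tss,
# strand).  Positions are rounded to the kb; only their order and rough
# spacing matter for the synthetic analyses.
_MMP_LOCUS_TABLE: list[tuple[str, int, int, int, str]] = [
    ("TMEM123", 102_267_000, 102_298_000, 102_298_000 - 1, "-"),
    ("BIRC3", 102_317_000, 102_339_000, 102_317_000, "+"),
    ("MMP7", 102_520_000, 102_531_000, 102_531_000 - 1, "-"),
    ("MMP20", 102_575_000, 102_623_000, 102_623_000 - 1, "-"),
    ("MMP27", 102_690_000, 102_710_000, 102_710_000 - 1, "-"),
    ("MMP8", 102_711_000, 102_724_000, 102_724_000 - 1, "-"),
    ("MMP10", 102_770_000, 102_780_000, 102_780_000 - 1, "-"),
    ("MMP1", 102_789_000, 102_798_000, 102_798_000 - 1, "-"),
    ("MMP3", 102_835_000, 102_843_000, 102_843_000 - 1, "-"),
    ("MMP12", 102_862_000, 102_875_000, 102_875_000 - 1, "-"),
    ("MMP13", 102_913_000, 102_926_000, 102_926_000 - 1, "-"),
]

MMP_GENES_5PRIME = ["MMP7", "MMP8", "MMP20", "MMP27"]
MMP_GENES_3PRIME = ["MMP1", "MMP3", "MMP10", "MMP12", "MMP13"]
NEIGHBOR_GENES_5PRIME = ["TMEM123", "BIRC3"]


def default_mmp_locus(include_neighbors: bool = False) -> LocusModel:
    """The nine-MMP Chr11q22.2 locus partitioned at the IE8 insulator.

    Parameters
    ----------
    include_neighbors : bool
        When True, the non-MMP neighbors TMEM123 and BIRC3 join the 5'
        cluster (the wider coexpression-cluster membership); by default the
        signature uses MMP genes only.
    """
    five = set(MMP_GENES_5PRIME)
    if include_neighbors:
        five |= set(NEIGHBOR_GENES_5PRIME)
    three = set(MMP_GENES_3PRIME)
    genes = []
    for gene_id, start, end, tss, strand in _MMP_LOCUS_TABLE:
        if gene_id in five:
            label = "5prime"
        elif gene_id in three:
            label = "3prime"
        else:
            label = "none"
        genes.append(
            GeneAnnotation(
                GenomicInterval("chr11", start, end, strand, gene_id),
                gene_id,
                tss,
                label,
            )
        )
    return LocusModel(genes=genes, boundary=IE8)


class BedParseError(ValueError):
    """A malformed BED line; the message names the offending line number."""


def read_bed(path) -> list[GenomicInterval]:
    """Read a 3-6 column BED file into intervals, preserving input order."""
    out: list[GenomicInterval] = []
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(
                    f"{path}: line {lineno}: expected >= 3 tab-separated fields"
                )
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            strand = fields[5] if len(fields) > 5 else "."
            try:
                out.append(GenomicInterval(chrom, start, end, strand, name))
            except ValueError as exc:
                raise BedParseError(f"{path}: line {lineno}: {exc}") from exc
    return out


def write_bed(intervals: Iterable[GenomicInterval], path) -> None:
    """Write BED6 (LF line endings).  Round-trips :func:`read_bed` output."""
    with open(path, "wt", encoding="utf-8", newline="\n") as fh:
        for iv in intervals:
            name = iv.name if iv.name is not None else "."
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


def to_display(iv: GenomicInterval) -> str:
    """Render 1-based inclusive, the convention used in prose and figures."""
    return f"{iv.chrom}:{iv.start + 1:,}-{iv.end:,}"


_REGION_RE = re.compile(r"^([\w.]+):([\d,]+)\s*[-−–]\s*([\d,]+)$")


def parse_region(text: str) -> GenomicInterval:
    """Parse ``chrom:start-end`` given in 1-based inclusive coordinates."""
    m = _REGION_RE.match(text.strip())
    if not m:
        raise ValueError(f"cannot parse region {text!r}; expected chrom:start-end")
    chrom = m.group(1)
    start = int(m.group(2).replace(",", "")) - 1
    end = int(m.group(3).replace(",", ""))
    return GenomicInterval(chrom, start, end)
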