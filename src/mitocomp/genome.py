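"""Circular-genome data model and coordinate accounting.

Coordinates are 1-based inclusive throughout, matching the convention of
mitogenome annotation tables.  A feature whose ``end`` is smaller than its
``start`` wraps through the origin of a circular genome.

The census/partition logic reconciles an annotation table against the genome
length: the spans of the 36 genes, plus the intergenic gaps, minus the gene
overlaps, must tile the circle exactly.  Non-coding regions (NCR features)
are carried in tables for fidelity to published annotations but are treated
as intergenic intervals, never as members of the gene ring.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

from .codes import CANONICAL_GENES, GENE_CLASSES, GeneticCode, INVERTEBRATE_MITO, revcomp

_VALID_RESIDUES = frozenset("ACGTN")


class CoordinateError(ValueError):
    """Raised for coordinates outside the genome or illegal wrap requests."""


@dataclass(frozen=True)
class CircularGenome:
    """A (by default circular) nucleotide sequence."""

    id: str
    residues: str
    topology: str = "circular"

    def __post_init__(self):
        object.__setattr__(self, "residues", self.residues.upper())
        if not self.residues:
            raise ValueError("genome must be non-empty")
        bad = set(self.residues) - _VALID_RESIDUES
        if bad:
            raise ValueError(f"invalid residues: {sorted(bad)}")
        if self.topology not in ("circular", "linear"):
            raise ValueError(f"unknown topology {self.topology!r}")

    @property
    def length(self) -> int:
        return len(self.residues)

    @property
    def is_circular(self) -> bool:
        return self.topology == "circular"

    def subsequence(self, start: int, end: int) -> str:
        """Residues from ``start`` to ``end`` (1-based inclusive), 5'->3'.

        ``end < start`` wraps through the origin on circular genomes.
        """
        L = self.length
        if not (1 <= start <= L and 1 <= end <= L):
            raise CoordinateError(f"coordinates ({start}, {end}) outside [1, {L}]")
        if end >= start:
            return self.residues[start - 1:end]
        if not self.is_circular:
            raise CoordinateError("wrapping span requested on a linear genome")
        return self.residues[start - 1:] + self.residues[:end]

    def rotate(self, new_origin: int) -> "CircularGenome":
        """Return the same circle with position ``new_origin`` as position 1."""
        if not self.is_circular:
            raise CoordinateError("cannot rotate a linear genome")
        if not 1 <= new_origin <= self.length:
            raise CoordinateError(f"origin {new_origin} outside genome")
        r = self.residues
        return replace(self, residues=r[new_origin - 1:] + r[:new_origin - 1])


@dataclass(frozen=True)
class GeneFeature:
    """One annotated feature with 1-based inclusive coordinates."""

    name: str
    klass: str
    start: int
    end: int
    strand: str = "+"
    start_codon: Optional[str] = None
    stop_codon: Optional[str] = None
    anticodon: Optional[str] = None

    def __post_init__(self):
        if self.klass not in GENE_CLASSES:
            raise ValueError(f"unknown feature class {self.klass!r}")
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if self.start < 1 or self.end < 1:
            raise CoordinateError(f"{self.name}: coordinates must be >= 1")
        if self.stop_codon is not None and self.stop_codon not in ("TAA", "TAG", "T", "TA"):
            raise ValueError(f"{self.name}: stop codon {self.stop_codon!r} not in TAA/TAG/T/TA")

    @property
    def wraps(self) -> bool:
        return self.end < self.start

    def length(self, genome_length: Optional[int] = None) -> int:
        return feature_length(self, genome_length)

    def stop_length(self) -> int:
        """Length in bp of the termination codon (complete or incomplete)."""
        if self.klass != "PCG":
            return 0
        if self.stop_codon is not None:
            return len(self.stop_codon)
        # infer from reading-frame remainder: 0 -> complete stop, 1 -> T, 2 -> TA
        rem = (self.end - self.start + 1) % 3 if not self.wraps else None
        if rem is None:
            raise ValueError(f"{self.name}: wrapping PCG needs genome length to infer stop")
        return 3 if rem == 0 else rem

    def sequence(self, genome: CircularGenome) -> str:
        seq = genome.subsequence(self.start, self.end)
        return revcomp(seq) if self.strand == "-" else seq


def feature_length(f: GeneFeature, genome_length: Optional[int] = None) -> int:
    """Span length in bp; wrapping features need the genome length."""
    if not f.wraps:
        return f.end - f.start + 1
    if genome_length is None:
        raise CoordinateError(f"{f.name}: wrapping feature needs genome length")
    if f.start > genome_length or f.end > genome_length:
        raise CoordinateError(f"{f.name}: coordinates outside [1, {genome_length}]")
    return (genome_length - f.start + 1) + f.end


def subsequence(genome: CircularGenome, start: int, end: int) -> str:
    return genome.subsequence(start, end)


@dataclass
class FeatureTable:
    """Ordered annotation of one genome (genes plus optional NCR intervals)."""

    genome_id: str
    features: list = field(default_factory=list)

    def __post_init__(self):
        self.features = sorted(self.features, key=lambda f: (f.start, f.end))

    def __iter__(self):
        return iter(self.features)

    def __len__(self):
        return len(self.features)

    def by_name(self, name: str) -> GeneFeature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)

    def of_class(self, klass: str) -> list:
        return [f for f in self.features if f.klass == klass]

    @property
    def pcgs(self) -> list:
        return self.of_class("PCG")

    @property
    def trnas(self) -> list:
        return self.of_class("tRNA")

    @property
    def rrnas(self) -> list:
        return self.of_class("rRNA")

    @property
    def ncrs(self) -> list:
        return self.of_class("NCR")

    def gene_ring(self) -> list:
        """Features participating in the circular gene order (NCRs excluded)."""
        return [f for f in self.features if f.klass != "NCR"]

    def is_complete(self) -> bool:
        names = [f.name for f in self.gene_ring()]
        return len(names) == 36 and set(names) == CANONICAL_GENES

    def require_complete(self):
        if not self.is_complete():
            names = [f.name for f in self.gene_ring()]
            missing = sorted(CANONICAL_GENES - set(names))
            extra = sorted(set(names) - CANONICAL_GENES)
            dup = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(
                f"{self.genome_id}: incomplete 36-gene table "
                f"(missing={missing}, unexpected={extra}, duplicated={dup})"
            )


@dataclass(frozen=True)
class GapOrOverlap:
    """Signed junction between consecutive ring genes.

    Positive = intergenic gap (bp), negative = overlap, zero = abutting.
    """

    left_gene: str
    right_gene: str
    length: int


def gap_overlap_census(table: FeatureTable, genome_length: int) -> list:
    """One signed entry per consecutive gene pair around the circle.

    NCR features are excluded from the ring; their spans show up inside the
    flanking positive gap.  The junction between the last and the first gene
    (through the origin) is included.
    """
    ring = table.gene_ring()
    if not ring:
        return []
    seen = {}
    for f in ring:
        if (f.start, f.end) in seen:
            raise ValueError(f"duplicate coordinates for {seen[(f.start, f.end)]} and {f.name}")
        seen[(f.start, f.end)] = f.name
    entries = []
    for left, right in zip(ring, ring[1:]):
        left_end = left.end if not left.wraps else left.end + genome_length
        entries.append(GapOrOverlap(left.name, right.name, right.start - left_end - 1))
    last, first = ring[-1], ring[0]
    last_end = last.end if not last.wraps else last.end + genome_length
    entries.append(GapOrOverlap(last.name, first.name, first.start + genome_length - last_end - 1))
    return entries


def intergenic_intervals(table: FeatureTable, genome_length: int) -> list:
    """(left_gene, right_gene, start, end, length) for every positive gap.

    Coordinates are 1-based inclusive on the genome; a gap crossing the
    origin is reported with ``end < start``.
    """
    ring = table.gene_ring()
    out = []
    for entry in gap_overlap_census(table, genome_length):
        if entry.length <= 0:
            continue
        left = next(f for f in ring if f.name == entry.left_gene)
        s = left.end % genome_length + 1
        e = (left.end + entry.length - 1) % genome_length + 1
        out.append((entry.left_gene, entry.right_gene, s, e, entry.length))
    return out


@dataclass
class PartitionReport:
    """Per-class length accounting and the circle-tiling reconciliation."""

    genome_id: str
    genome_length: int
    pcg_span_total: int
    pcg_coding_total: int          # termination codons excluded
    stop_total: int
    rrna_total: int
    trna_total: int
    ncr_feature_total: int         # NCR-class features only
    intergenic_total: int          # all positive gaps (includes NCR spans)
    overlap_total: int             # absolute bp of all negative junctions
    gap_count: int
    overlap_count: int
    reconciles: bool
    diagnostic: Optional[str] = None

    @property
    def total_codons(self) -> int:
        return self.pcg_coding_total // 3


def partition_report(
    table: FeatureTable,
    genome: Optional[CircularGenome] = None,
    code: GeneticCode = INVERTEBRATE_MITO,
    genome_length: Optional[int] = None,
) -> PartitionReport:
    """Reconcile a complete 36-gene table against the genome length.

    The identity checked is:  sum(ring spans) + sum(gaps) - sum(overlaps)
    = genome length.  A failure is reported in ``diagnostic``, not raised.
    """
    table.require_complete()
    if genome_length is None:
        if genome is None:
            raise ValueError("need a genome or an explicit genome_length")
        genome_length = genome.length
    L = genome_length
    out_of_range = [f.name for f in table.features if f.start > L or f.end > L]
    pcg_span = sum(feature_length(f, L) for f in table.pcgs)
    stops = sum(f.stop_length() for f in table.pcgs)
    rrna = sum(feature_length(f, L) for f in table.rrnas)
    trna = sum(feature_length(f, L) for f in table.trnas)
    ncr = sum(feature_length(f, L) for f in table.ncrs)
    census = gap_overlap_census(table, L)
    gaps = [e.length for e in census if e.length > 0]
    overlaps = [-e.length for e in census if e.length < 0]
    span_total = pcg_span + rrna + trna
    tiled = span_total + sum(gaps) - sum(overlaps)
    ok = tiled == L and not out_of_range
    if out_of_range:
        diagnostic = f"features outside [1, {L}]: {out_of_range}"
    elif tiled != L:
        diagnostic = (f"spans ({span_total}) + gaps ({sum(gaps)}) - overlaps "
                      f"({sum(overlaps)}) = {tiled} != genome length {L}")
    else:
        diagnostic = None
    return PartitionReport(
        genome_id=table.genome_id,
        genome_length=L,
        pcg_span_total=pcg_span,
        pcg_coding_total=pcg_span - stops,
        stop_total=stops,
        rrna_total=rrna,
        trna_total=trna,
        ncr_feature_total=ncr,
        intergenic_total=sum(gaps),
        overlap_total=sum(overlaps),
        gap_count=len(gaps),
        overlap_count=len(overlaps),
        reconciles=ok,
        diagnostic=diagnostic,
    )


def rotate_table(table: FeatureTable, offset: int, genome_length: int) -> FeatureTable:
    """Shift all coordinates by ``offset`` bp around the circle (for tests of
    rotation invariance)."""
    def shift(x):
        return (x - 1 + offset) % genome_length + 1

    feats = [replace(f, start=shift(f.start), end=shift(f.end)) for f in table.features]
    return FeatureTable(table.genome_id, feats)
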