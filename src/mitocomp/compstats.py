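"""Nucleotide composition and codon usage statistics.

The key accounting convention: termination codons (complete TAA/TAG, or the
incomplete T/TA forms completed by polyadenylation) are excluded from the
protein-coding partition and from all codon counts.  Under this convention
the concatenated coding partition length is exactly three times the codon
total, and the per-codon-position partitions each have length equal to the
codon total.  An ``include_stops`` switch exists for other conventions.

Percentages are computed over non-N residues and rounded half-up: one
decimal for composition, two for codon usage, matching how such tables are
conventionally printed.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from .codes import ALL_CODONS, GeneticCode, INVERTEBRATE_MITO, round_half_up
from .genome import CircularGenome, FeatureTable


@dataclass(frozen=True)
class CompositionProfile:
    """Base composition of one partition (percent over non-N residues)."""

    partition: str
    length: int
    counts: dict = field(repr=False)

    @classmethod
    def from_sequence(cls, partition: str, seq: str) -> "CompositionProfile":
        if not seq:
            raise ValueError(f"{partition}: empty sequence")
        c = Counter(seq.upper())
        counts = {b: c.get(b, 0) for b in "ACGT"}
        return cls(partition=partition, length=len(seq), counts=counts)

    @property
    def denominator(self) -> int:
        return sum(self.counts.values())       # non-N residues

    def percent(self, base: str) -> float:
        """Unrounded percentage of one base."""
        return 100.0 * self.counts[base.upper()] / self.denominator

    @property
    def at_percent(self) -> float:
        return self.percent("A") + self.percent("T")

    def rounded(self, ndigits: int = 1) -> dict:
        out = {b: round_half_up(self.percent(b), ndigits) for b in "ACGT"}
        out["AT"] = round_half_up(self.at_percent, ndigits)
        return out


def base_composition(seq: str, partition: str = "sequence") -> CompositionProfile:
    return CompositionProfile.from_sequence(partition, seq)


def _pcg_coding_sequences(genome: CircularGenome, table: FeatureTable,
                          include_stops: bool = False) -> list:
    """(gene, coding sequence) per PCG, stop codons stripped unless asked."""
    out = []
    for f in table.pcgs:
        seq = f.sequence(genome)
        if not include_stops:
            seq = seq[:len(seq) - f.stop_length()]
        out.append((f.name, seq))
    return out


def partitioned_composition(
    genome: CircularGenome,
    table: FeatureTable,
    code: GeneticCode = INVERTEBRATE_MITO,
    include_stops: bool = False,
) -> list:
    """Composition of every standard partition of a complete mitogenome.

    Partitions: entire sequence; concatenated PCG coding sequence (stops
    excluded by default); its 1st/2nd/3rd codon positions; concatenated
    rRNA; concatenated tRNA; concatenated NCR features.  Overlapping bases
    are counted once per feature (each gene contributes its full span).
    """
    profiles = [CompositionProfile.from_sequence("Entire sequence", genome.residues)]
    per_gene = [seq for _, seq in _pcg_coding_sequences(genome, table, include_stops)]
    coding = "".join(per_gene)
    if len(coding) % 3 and not include_stops:
        raise ValueError("concatenated coding length not divisible by 3 after stop exclusion")
    profiles.append(CompositionProfile.from_sequence("Protein coding sequence", coding))
    for k, label in enumerate(("1st", "2nd", "3rd")):
        # codon positions are taken per gene so that incomplete stop codons
        # (include_stops=True) cannot shift downstream genes out of frame
        profiles.append(CompositionProfile.from_sequence(
            label, "".join(seq[k::3] for seq in per_gene)))
    rrna = "".join(f.sequence(genome) for f in table.rrnas)
    trna = "".join(f.sequence(genome) for f in table.trnas)
    profiles.append(CompositionProfile.from_sequence("Ribosomal RNA gene sequence", rrna))
    profiles.append(CompositionProfile.from_sequence("Transfer RNA gene sequence", trna))
    ncr = "".join(f.sequence(genome) for f in table.ncrs)
    if ncr:
        profiles.append(CompositionProfile.from_sequence("Non coding region", ncr))
    return profiles


@dataclass(frozen=True)
class CodonUsageTable:
    """Per-codon counts over the 12 PCGs, termination codons excluded."""

    counts: dict = field(repr=False)
    code: GeneticCode = INVERTEBRATE_MITO

    def __post_init__(self):
        unknown = set(self.counts) - set(ALL_CODONS)
        if unknown:
            raise ValueError(f"unknown codons: {sorted(unknown)}")

    @classmethod
    def from_counts(cls, counts: dict, code: GeneticCode = INVERTEBRATE_MITO):
        full = {c: int(counts.get(c, 0)) for c in ALL_CODONS}
        return cls(counts=full, code=code)

    @property
    def total_codons(self) -> int:
        return sum(self.counts.values())

    def count(self, codon: str) -> int:
        return self.counts[codon.upper()]

    def percent(self, codon: str, ndigits: Optional[int] = 2) -> float:
        """Percent of total codons; round half-up at ``ndigits`` (None = raw)."""
        raw = 100.0 * self.counts[codon.upper()] / self.total_codons
        return raw if ndigits is None else round_half_up(raw, ndigits)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"codon": c, "aa": self.code.amino_acid(c),
             "count": self.counts[c], "percent": self.percent(c)}
            for c in ALL_CODONS
        ]
        return pd.DataFrame(rows)


def codon_usage(
    genome: CircularGenome,
    table: FeatureTable,
    code: GeneticCode = INVERTEBRATE_MITO,
    include_stops: bool = False,
) -> CodonUsageTable:
    """Codon counts over all annotated PCGs (stop codons excluded by default)."""
    if len(table.pcgs) != 12:
        raise ValueError(f"{table.genome_id}: expected 12 PCGs, found {len(table.pcgs)}")
    counts = Counter()
    for gene, seq in _pcg_coding_sequences(genome, table, include_stops):
        if len(seq) % 3:
            raise ValueError(f"{gene}: coding length {len(seq)} not divisible by 3")
        counts.update(seq[i:i + 3] for i in range(0, len(seq), 3))
    return CodonUsageTable.from_counts(counts, code)


def top_codon_summary(usage: CodonUsageTable, k: int = 3, ndigits: int = 1) -> tuple:
    """The ``k`` most frequent codons and their combined percentage.

    Ties break by count then alphabetically; the combined percentage is the
    sum of unrounded frequencies, rounded half-up to ``ndigits`` decimals.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    ranked = sorted(ALL_CODONS, key=lambda c: (-usage.counts[c], c))[:k]
    combined = sum(usage.percent(c, ndigits=None) for c in ranked)
    return ranked, round_half_up(combined, ndigits)
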