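"""Protein-coding gene verification and ORF scanning.

Mitochondrial PCGs of chromadorean nematodes frequently begin with
non-canonical start codons (ATT, ATA, TTG, TTA) and may end in incomplete
termination codons -- a bare ``T`` or ``TA`` at the gene boundary that is
completed to UAA by post-transcriptional polyadenylation.  The stop kind is
therefore dictated by the reading-frame remainder of the annotated span:
remainder 0 requires a complete stop in the last triplet, remainder 1 a
terminal ``T``, remainder 2 a terminal ``TA``.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Optional

from .codes import GeneticCode, INVERTEBRATE_MITO, STOP_SENTINEL
from .genome import CircularGenome, FeatureTable, GeneFeature, gap_overlap_census

#: start codons accepted by the ORF scanner: the non-canonical set observed
#: in nematode mitogenomes plus canonical ATG and GTG.  Overridable.
DEFAULT_START_CODONS = frozenset({"ATT", "ATA", "ATG", "TTG", "TTA", "GTG"})


@dataclass(frozen=True)
class CodonInference:
    """Inferred start/stop codons of one annotated PCG."""

    gene: str
    start_codon: str
    stop_codon: str               # TAA, TAG, T, or TA
    stop_kind: str                # "complete" or "incomplete"
    internal_stops: tuple = ()
    violations: tuple = ()

    @property
    def ok(self) -> bool:
        return not self.violations


def infer_codons(
    f: GeneFeature,
    genome: CircularGenome,
    code: GeneticCode = INVERTEBRATE_MITO,
) -> CodonInference:
    """Read the start and (possibly incomplete) stop codon off the sequence.

    Any internal stop codon and any inconsistency between the reading-frame
    remainder and the terminal bases is recorded as a violation.
    """
    if f.klass != "PCG":
        raise ValueError(f"{f.name}: infer_codons requires a PCG feature")
    seq = f.sequence(genome)
    violations = []
    start_codon = seq[:3]
    rem = len(seq) % 3
    if rem == 0:
        stop = seq[-3:]
        kind = "complete"
        if stop not in code.stop_codons:
            violations.append(f"last triplet {stop} is not a stop codon")
        coding = seq[:-3]
    elif rem == 1:
        stop = seq[-1:]
        kind = "incomplete"
        if stop != "T":
            violations.append(f"trailing base {stop} is not T (incomplete stop)")
        coding = seq[:-1]
    else:
        stop = seq[-2:]
        kind = "incomplete"
        if stop != "TA":
            violations.append(f"trailing bases {stop} are not TA (incomplete stop)")
        coding = seq[:-2]
    internal = tuple(
        i // 3 for i in range(0, len(coding), 3)
        if code.amino_acid(coding[i:i + 3]) == STOP_SENTINEL
    )
    if internal:
        violations.append(f"{len(internal)} internal stop codon(s) at codon(s) {internal[:5]}")
    if f.start_codon and f.start_codon != start_codon:
        violations.append(f"annotated start {f.start_codon} != observed {start_codon}")
    if f.stop_codon and f.stop_codon != stop:
        violations.append(f"annotated stop {f.stop_codon} != observed {stop}")
    return CodonInference(f.name, start_codon, stop, kind, internal, tuple(violations))


def start_codon_histogram(
    table: FeatureTable,
    genome: CircularGenome,
    code: GeneticCode = INVERTEBRATE_MITO,
) -> Counter:
    """Counts of observed start triplets over the 12 annotated PCGs."""
    pcgs = table.pcgs
    if len(pcgs) != 12:
        raise ValueError(f"{table.genome_id}: expected 12 PCGs, found {len(pcgs)}")
    return Counter(infer_codons(f, genome, code).start_codon for f in pcgs)


def verify_table(
    table: FeatureTable,
    genome: CircularGenome,
    code: GeneticCode = INVERTEBRATE_MITO,
) -> list:
    """Per-PCG verification report (one CodonInference per gene), with the
    signed distance to the next ring feature attached."""
    census = {e.left_gene: e.length for e in gap_overlap_census(table, genome.length)}
    out = []
    for f in table.pcgs:
        inf = infer_codons(f, genome, code)
        out.append((inf, census.get(f.name)))
    return out


@dataclass(frozen=True)
class OrfCandidate:
    """A maximal open reading frame found by the scanner."""

    start: int                    # 1-based on the scanned strand
    end: int                      # 1-based inclusive, includes the stop bases
    frame: int                    # 0-2 relative to scan origin
    start_codon: str
    stop_kind: str                # TAA, TAG, T, TA, or "open"
    aa_length: int


def scan_orfs(
    genome: CircularGenome,
    code: GeneticCode = INVERTEBRATE_MITO,
    min_aa: int = 50,
    start_codons: frozenset = DEFAULT_START_CODONS,
) -> list:
    """Maximal reading frames on the annotated (+) strand.

    Each frame is walked codon by codon; an ORF opens at the first start-set
    codon after the previous stop and closes at the next complete stop codon,
    or at the sequence end with an incomplete ``T``/``TA`` stop when the
    trailing bases permit.  Candidates shorter than ``min_aa`` residues are
    dropped.  Sorted by start position.
    """
    if min_aa < 1:
        raise ValueError("min_aa must be >= 1")
    seq = genome.residues
    n = len(seq)
    out = []
    for frame in range(3):
        orf_start = None
        start_codon = None
        i = frame
        while i + 3 <= n:
            codon = seq[i:i + 3]
            if code.is_stop(codon) and orf_start is not None:
                aa_len = (i - orf_start) // 3
                if aa_len >= min_aa:
                    out.append(OrfCandidate(orf_start + 1, i + 3, frame,
                                            start_codon, codon, aa_len))
                orf_start = None
            elif orf_start is None and codon in start_codons:
                orf_start = i
                start_codon = codon
            i += 3
        if orf_start is not None:
            # sequence end: open frame, possibly closeable by an incomplete stop
            tail = seq[i:]
            if tail == "T" or tail == "TA":
                aa_len = (i - orf_start) // 3
                if aa_len >= min_aa:
                    out.append(OrfCandidate(orf_start + 1, n, frame,
                                            start_codon, tail, aa_len))
            else:
                aa_len = (i - orf_start) // 3
                if aa_len >= min_aa:
                    out.append(OrfCandidate(orf_start + 1, i, frame,
                                            start_codon, "open", aa_len))
    return sorted(out, key=lambda c: (c.start, c.end))
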