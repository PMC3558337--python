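"""Codon-alignment preparation for phylogenetic analysis.

The pipeline follows the standard practice for mitochondrial protein-coding
genes: translate each gene under the invertebrate mitochondrial code, align
the proteins, back-translate the gapped proteins onto their source codons
(each residue column becomes its codon, each gap a ``---``), concatenate the
per-gene codon alignments into a supermatrix with a partition table, and
optionally strip third codon positions.

The built-in aligner is intentionally simple: pairwise Needleman-Wunsch
with affine gaps (Gotoh), extended to multiple sequences by center-star
progressive merging, fully deterministic.  It exists so the pipeline and its
tests need no external aligner; externally produced protein alignments in
FASTA are treated identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Optional, Sequence

from .codes import GeneticCode, INVERTEBRATE_MITO, STOP_SENTINEL
from .genome import CircularGenome, GeneFeature

GAP = "-"


def translate_pcg(f: GeneFeature, genome: CircularGenome,
                  code: GeneticCode = INVERTEBRATE_MITO) -> str:
    """Amino-acid sequence of a PCG with the termination codon removed.

    Incomplete stop codons (T/TA) contribute no residue.  An internal stop
    is an error.
    """
    seq = f.sequence(genome)
    coding = seq[:len(seq) - f.stop_length()]
    if len(coding) % 3:
        raise ValueError(f"{f.name}: coding length {len(coding)} not divisible by 3")
    aa = code.translate(coding)
    if STOP_SENTINEL in aa:
        raise ValueError(f"{f.name}: internal stop codon at residue {aa.index(STOP_SENTINEL) + 1}")
    return aa


def strip_stop(cds: str, code: GeneticCode = INVERTEBRATE_MITO) -> str:
    """Remove a trailing complete or incomplete termination codon, if present."""
    rem = len(cds) % 3
    if rem == 0 and len(cds) >= 3 and code.is_stop(cds[-3:]):
        return cds[:-3]
    if rem == 1 and cds.endswith("T"):
        return cds[:-1]
    if rem == 2 and cds.endswith("TA"):
        return cds[:-2]
    if rem:
        raise ValueError(f"CDS length {len(cds)} not divisible by 3 and no incomplete stop found")
    return cds


@dataclass(frozen=True)
class AlignParams:
    match: int = 2
    mismatch: int = -1
    gap_open: int = -3      # charged once per gap run, plus extend per base
    gap_extend: int = -1


DEFAULT_ALIGN = AlignParams()

_NEG = float("-inf")


def needleman_wunsch(a: str, b: str, params: AlignParams = DEFAULT_ALIGN) -> tuple:
    """Global pairwise alignment with affine gaps; returns (row_a, row_b, score).

    Deterministic traceback (diagonal preferred, then gap-in-b, then
    gap-in-a).
    """
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    n, m = len(a), len(b)
    go, ge = params.gap_open, params.gap_extend

    def s(x, y):
        return params.match if x == y else params.mismatch

    # states: 0=M (diagonal), 1=X (gap in b: a char over gap), 2=Y (gap in a)
    M = [[_NEG] * (m + 1) for _ in range(n + 1)]
    X = [[_NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[_NEG] * (m + 1) for _ in range(n + 1)]
    ptr = {}
    M[0][0] = 0
    for i in range(1, n + 1):
        X[i][0] = go + ge * i
        ptr[(1, i, 0)] = 1 if i > 1 else 0
    for j in range(1, m + 1):
        Y[0][j] = go + ge * j
        ptr[(2, 0, j)] = 2 if j > 1 else 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            cands = (M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            k = max(range(3), key=lambda t: (cands[t], -t))
            M[i][j] = cands[k] + s(a[i - 1], b[j - 1])
            ptr[(0, i, j)] = k
            cands = (M[i - 1][j] + go + ge, X[i - 1][j] + ge, Y[i - 1][j] + go + ge)
            k = max(range(3), key=lambda t: (cands[t], -t))
            X[i][j] = cands[k]
            ptr[(1, i, j)] = k
            cands = (M[i][j - 1] + go + ge, X[i][j - 1] + go + ge, Y[i][j - 1] + ge)
            k = max(range(3), key=lambda t: (cands[t], -t))
            Y[i][j] = cands[k]
            ptr[(2, i, j)] = k

    finals = (M[n][m], X[n][m], Y[n][m])
    state = max(range(3), key=lambda t: (finals[t], -t))
    score = finals[state]
    ra, rb = [], []
    i, j = n, m
    while i > 0 or j > 0:
        prev = ptr[(state, i, j)]
        if state == 0:
            ra.append(a[i - 1]); rb.append(b[j - 1]); i -= 1; j -= 1
        elif state == 1:
            ra.append(a[i - 1]); rb.append(GAP); i -= 1
        else:
            ra.append(GAP); rb.append(b[j - 1]); j -= 1
        state = prev
    return "".join(reversed(ra)), "".join(reversed(rb)), score


@dataclass(frozen=True)
class ProteinAlignment:
    """Equal-length gapped amino-acid rows, one per taxon."""

    taxa: tuple
    rows: tuple
    gene: str = ""

    def __post_init__(self):
        if len(self.taxa) != len(self.rows):
            raise ValueError("taxa/rows length mismatch")
        widths = {len(r) for r in self.rows}
        if len(widths) > 1:
            raise ValueError(f"rows have unequal lengths {sorted(widths)}")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    def row(self, taxon: str) -> str:
        return self.rows[self.taxa.index(taxon)]

    def degapped(self, taxon: str) -> str:
        return self.row(taxon).replace(GAP, "")


def _merge_center(master_center: str, new_center: str) -> tuple:
    """Column maps injecting two gapped copies of the same sequence into
    their union gap pattern."""
    out_master, out_new = [], []
    i = j = 0
    while i < len(master_center) or j < len(new_center):
        ci = master_center[i] if i < len(master_center) else None
        cj = new_center[j] if j < len(new_center) else None
        if ci is not None and cj is not None and ci != GAP and cj != GAP:
            out_master.append(i); out_new.append(j); i += 1; j += 1
        elif ci == GAP:
            out_master.append(i); out_new.append(None); i += 1
        else:  # cj == GAP or master exhausted
            out_master.append(None); out_new.append(j); j += 1
    return out_master, out_new


def align_proteins(seqs: Dict[str, str], gene: str = "",
                   params: AlignParams = DEFAULT_ALIGN) -> ProteinAlignment:
    """Center-star progressive multiple alignment (deterministic).

    The center is the sequence with the greatest summed pairwise score to
    the others (ties to the earliest taxon); every other sequence is aligned
    to the center pairwise and merged under "once a gap, always a gap".
    """
    taxa = tuple(seqs)
    if any(not s for s in seqs.values()):
        raise ValueError("cannot align an empty sequence")
    if len(taxa) < 2:
        raise ValueError("need at least two sequences")
    plain = [seqs[t] for t in taxa]
    k = len(taxa)
    totals = [0] * k
    for i in range(k):
        for j in range(i + 1, k):
            sc = needleman_wunsch(plain[i], plain[j], params)[2]
            totals[i] += sc
            totals[j] += sc
    center = max(range(k), key=lambda i: (totals[i], -i))

    center_aligned = plain[center]
    rows = {taxa[center]: plain[center]}
    for i in range(k):
        if i == center:
            continue
        new_center, new_row, _ = needleman_wunsch(plain[center], plain[i], params)
        map_master, map_new = _merge_center(center_aligned, new_center)
        width = len(map_master)

        def inject(row, colmap):
            return "".join(row[c] if c is not None else GAP for c in colmap)

        for t in list(rows):
            rows[t] = inject(rows[t], map_master)
        rows[taxa[i]] = inject(new_row, map_new)
        center_aligned = inject(center_aligned, map_master)
        assert all(len(r) == width for r in rows.values())
    return ProteinAlignment(taxa=taxa, rows=tuple(rows[t] for t in taxa), gene=gene)


@dataclass(frozen=True)
class CodonAlignment:
    """Equal-length gapped nucleotide rows; 3 columns per protein column."""

    taxa: tuple
    rows: tuple
    gene: str = ""

    def __post_init__(self):
        widths = {len(r) for r in self.rows}
        if len(widths) > 1:
            raise ValueError(f"rows have unequal lengths {sorted(widths)}")
        if self.n_columns % 3:
            raise ValueError(f"column count {self.n_columns} not divisible by 3")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    def row(self, taxon: str) -> str:
        return self.rows[self.taxa.index(taxon)]

    def degapped(self, taxon: str) -> str:
        return self.row(taxon).replace(GAP, "")


def backtranslate(pa: ProteinAlignment, cds_by_taxon: Dict[str, str],
                  code: GeneticCode = INVERTEBRATE_MITO) -> CodonAlignment:
    """Map a gapped protein alignment onto its coding sequences.

    Each residue column becomes its source codon; each gap becomes ``---``.
    The degapped protein rows must equal the translations of the (stop-
    stripped) coding sequences.
    """
    rows = []
    for taxon in pa.taxa:
        if taxon not in cds_by_taxon:
            raise KeyError(f"no CDS for taxon {taxon!r}")
        cds = strip_stop(cds_by_taxon[taxon].upper(), code)
        aa = code.translate(cds)
        expected = pa.degapped(taxon)
        if aa != expected:
            raise ValueError(
                f"{taxon}: CDS translation does not match alignment row "
                f"({aa[:20]}... vs {expected[:20]}...)"
            )
        codons = [cds[i:i + 3] for i in range(0, len(cds), 3)]
        it = iter(codons)
        rows.append("".join(GAP * 3 if ch == GAP else next(it) for ch in pa.row(taxon)))
    return CodonAlignment(taxa=pa.taxa, rows=tuple(rows), gene=pa.gene)


#: canonical gene concatenation order (alphanumeric)
CANONICAL_CONCAT_ORDER = (
    "atp6", "cob", "cox1", "cox2", "cox3",
    "nad1", "nad2", "nad3", "nad4", "nad4L", "nad5", "nad6",
)


@dataclass(frozen=True)
class Supermatrix:
    """Concatenated alignment with a per-gene partition table.

    Partitions are (gene, start_col, end_col), 1-based inclusive, tiling the
    matrix without overlap.
    """

    taxa: tuple
    rows: tuple
    partitions: tuple

    def __post_init__(self):
        widths = {len(r) for r in self.rows}
        if len(widths) > 1:
            raise ValueError("rows have unequal lengths")
        expect = 1
        for gene, s, e in self.partitions:
            if s != expect or e < s:
                raise ValueError(f"partitions do not tile: {gene} spans {s}-{e}, expected start {expect}")
            expect = e + 1
        if self.partitions and expect != self.n_columns + 1:
            raise ValueError("partitions do not cover the matrix")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    def row(self, taxon: str) -> str:
        return self.rows[self.taxa.index(taxon)]


def concatenate(alignments: Sequence[CodonAlignment],
                order: Optional[Sequence[str]] = None,
                fill_missing: bool = False) -> Supermatrix:
    """Concatenate per-gene codon alignments into a supermatrix.

    Genes are ordered canonically (alphanumeric) unless ``order`` is given.
    Taxon sets must match exactly unless ``fill_missing`` allows all-gap rows.
    """
    by_gene = {a.gene: a for a in alignments}
    if len(by_gene) != len(alignments):
        raise ValueError("duplicate gene names among alignments")
    genes = list(order) if order is not None else sorted(by_gene)
    taxa = tuple(dict.fromkeys(t for g in genes for t in by_gene[g].taxa))
    parts = []
    chunks = {t: [] for t in taxa}
    col = 1
    for gene in genes:
        aln = by_gene[gene]
        missing = set(taxa) - set(aln.taxa)
        if missing and not fill_missing:
            raise ValueError(f"{gene}: missing taxa {sorted(missing)} (set fill_missing to pad)")
        for t in taxa:
            chunks[t].append(aln.row(t) if t in aln.taxa else GAP * aln.n_columns)
        parts.append((gene, col, col + aln.n_columns - 1))
        col += aln.n_columns
    rows = tuple("".join(chunks[t]) for t in taxa)
    return Supermatrix(taxa=taxa, rows=rows, partitions=tuple(parts))


def exclude_third_positions(sm: Supermatrix) -> Supermatrix:
    """Drop the third position of every codon (per partition)."""
    keep_cols = []
    parts = []
    col = 1
    for gene, s, e in sm.partitions:
        width = e - s + 1
        if width % 3:
            raise ValueError(f"{gene}: partition width {width} not divisible by 3")
        cols = [c for c in range(s, e + 1) if (c - s) % 3 != 2]
        keep_cols.extend(cols)
        parts.append((gene, col, col + len(cols) - 1))
        col += len(cols)
    idx = [c - 1 for c in keep_cols]
    rows = tuple("".join(r[i] for i in idx) for r in sm.rows)
    return Supermatrix(taxa=sm.taxa, rows=rows, partitions=tuple(parts))


def write_fasta_alignment(aln, path):
    lines = []
    for t, r in zip(aln.taxa, aln.rows):
        lines.append(f">{t}")
        lines.append(r)
    Path(path).write_text("\n".join(lines) + "\n")


def read_fasta_alignment(path, gene: str = "", protein: bool = True):
    from Bio import SeqIO
    taxa, rows = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        taxa.append(rec.id)
        rows.append(str(rec.seq).upper())
    cls = ProteinAlignment if protein else CodonAlignment
    return cls(taxa=tuple(taxa), rows=tuple(rows), gene=gene)


def write_phylip_relaxed(sm: Supermatrix, path):
    lines = [f" {len(sm.taxa)} {sm.n_columns}"]
    for t, r in zip(sm.taxa, sm.rows):
        lines.append(f"{t}  {r}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_nexus(sm: Supermatrix, path, datatype: str = "dna"):
    lines = [
        "#NEXUS",
        "begin data;",
        f"  dimensions ntax={len(sm.taxa)} nchar={sm.n_columns};",
        f"  format datatype={datatype} missing=? gap=-;",
        "  matrix",
    ]
    for t, r in zip(sm.taxa, sm.rows):
        lines.append(f"    {t}  {r}")
    lines += ["  ;", "end;", "", "begin sets;"]
    for gene, s, e in sm.partitions:
        lines.append(f"  charset {gene} = {s}-{e};")
    lines += ["end;"]
    Path(path).write_text("\n".join(lines) + "\n")


def write_raxml_partitions(sm: Supermatrix, path, datatype: str = "DNA"):
    lines = [f"{datatype}, {gene} = {s}-{e}" for gene, s, e in sm.partitions]
    Path(path).write_text("\n".join(lines) + "\n")
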