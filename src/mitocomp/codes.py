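"""Genetic codes, gene vocabulary, and small numeric helpers.

The default genetic code is NCBI translation table 5 (invertebrate
mitochondrial), under which AGA/AGG encode serine and TGA encodes
tryptophan.  Codes are table-driven: any NCBI table id can be loaded, and a
custom codon map can be supplied for idiosyncratic mitochondrial codes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

from Bio.Data import CodonTable

NUCLEOTIDES = "ACGT"
STOP_SENTINEL = "*"

#: 12 mitochondrial protein-coding genes of chromadorean nematodes (atp8 absent).
PCG_GENES = (
    "atp6", "cob", "cox1", "cox2", "cox3",
    "nad1", "nad2", "nad3", "nad4", "nad4L", "nad5", "nad6",
)

#: 22 tRNA genes; leucine and serine isoacceptors disambiguated by anticodon.
TRNA_GENES = (
    "trnA", "trnC", "trnD", "trnE", "trnF", "trnG", "trnH", "trnI", "trnK",
    "trnL1", "trnL2", "trnM", "trnN", "trnP", "trnQ", "trnR",
    "trnS1", "trnS2", "trnT", "trnV", "trnW", "trnY",
)

RRNA_GENES = ("rrnS", "rrnL")

#: the 36-gene canonical complement of a chromadorean mitogenome
CANONICAL_GENES = frozenset(PCG_GENES) | frozenset(TRNA_GENES) | frozenset(RRNA_GENES)

GENE_CLASSES = ("PCG", "tRNA", "rRNA", "NCR")

#: Conventional anticodons (DNA alphabet, 5'->3') for each tRNA gene under the
#: invertebrate mitochondrial code.  The isoacceptor labels follow anticodon
#: usage: L1 = trnL-uag (CUN leucine), L2 = trnL-uaa (UUR leucine),
#: S1 = trnS-ucu (AGN serine), S2 = trnS-uga (UCN serine).
ANTICODONS = {
    "trnA": "TGC", "trnR": "TCG", "trnN": "GTT", "trnD": "GTC",
    "trnC": "GCA", "trnQ": "TTG", "trnE": "TTC", "trnG": "TCC",
    "trnH": "GTG", "trnI": "GAT", "trnK": "TTT", "trnL1": "TAG",
    "trnL2": "TAA", "trnM": "CAT", "trnF": "GAA", "trnP": "TGG",
    "trnS1": "TCT", "trnS2": "TGA", "trnT": "TGT", "trnW": "TCA",
    "trnY": "GTA", "trnV": "TAC",
}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Round with ties away from zero, matching hand-tabulated percentages."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


ALL_CODONS = tuple("".join(c) for c in itertools.product(NUCLEOTIDES, repeat=3))


@dataclass(frozen=True)
class GeneticCode:
    """A 64-entry codon table with start and stop codon sets.

    Stop codons map to the sentinel ``*`` in :attr:`forward`.
    """

    table_id: int
    forward: dict = field(repr=False)
    start_codons: frozenset
    stop_codons: frozenset

    def __post_init__(self):
        if len(self.forward) != 64:
            raise ValueError(f"codon map has {len(self.forward)} entries, expected 64")

    @classmethod
    def from_ncbi_id(cls, table_id: int = 5) -> "GeneticCode":
        tab = CodonTable.unambiguous_dna_by_id[table_id]
        forward = dict(tab.forward_table)
        for stop in tab.stop_codons:
            forward[stop] = STOP_SENTINEL
        return cls(
            table_id=table_id,
            forward=forward,
            start_codons=frozenset(tab.start_codons),
            stop_codons=frozenset(tab.stop_codons),
        )

    def amino_acid(self, codon: str) -> str:
        """One-letter amino acid, ``*`` for stops, ``X`` for ambiguous codons."""
        return self.forward.get(codon.upper(), "X")

    def is_stop(self, codon: str) -> bool:
        return codon.upper() in self.stop_codons

    def translate(self, seq: str) -> str:
        if len(seq) % 3:
            raise ValueError(f"sequence length {len(seq)} not divisible by 3")
        s = seq.upper()
        return "".join(self.amino_acid(s[i:i + 3]) for i in range(0, len(s), 3))

    def codons_for(self, aa: str) -> tuple:
        return tuple(c for c in ALL_CODONS if self.forward[c] == aa)


INVERTEBRATE_MITO = GeneticCode.from_ncbi_id(5)


def trna_label_for_anticodon(anticodon: str, code: GeneticCode = INVERTEBRATE_MITO) -> str:
    """Gene label implied by an anticodon (read 5'->3', DNA or RNA alphabet).

    The decoded codon is the reverse complement of the anticodon; leucine and
    serine are disambiguated to L1/L2 and S1/S2 by codon family.
    """
    ac = anticodon.upper().replace("U", "T")
    codon = revcomp(ac)
    aa = code.amino_acid(codon)
    if aa == STOP_SENTINEL:
        raise ValueError(f"anticodon {anticodon} decodes to a stop codon ({codon})")
    if aa == "L":
        return "trnL1" if codon.startswith("CT") else "trnL2"
    if aa == "S":
        return "trnS1" if codon.startswith("AG") else "trnS2"
    return f"trn{aa}"
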