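"""Secondary-structure folding of nematode mitochondrial tRNAs.

Most nematode mitochondrial tRNAs deviate from the canonical cloverleaf:
the T-arm and variable loop are replaced by a single unpaired "TV
replacement" loop.  The two serine tRNAs show the mirror-image economy --
they lack the DHU arm but keep a T-arm stem-loop.  The folder searches
exhaustively over all arm placements compatible with a structural model
(sequences are <= 75 nt, so brute force is instantaneous), scores each
placement by paired-base count with a penalty per mismatch, and returns the
best placement under a per-stem mismatch budget.  There is no thermodynamic
energy model; this mirrors how such structures are accepted by eye.

Model geometry (TV variant, 5'->3'):
    acceptor stem 5' (7) | spacer | DHU stem 5' (4) | DHU loop | DHU stem 3'
    | spacer | anticodon stem 5' (5) | anticodon loop (7, anticodon central)
    | anticodon stem 3' | TV replacement loop | acceptor stem 3' (7)

Serine variant:
    acceptor 5' (7) | spacer | DHU-replacement loop | anticodon arm as above
    | spacer | T stem 5' (3-5) | T loop (3-8) | T stem 3' | acceptor 3' (7)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .codes import GeneticCode, INVERTEBRATE_MITO, trna_label_for_anticodon

VARIANT_TV = "TV-loop"
VARIANT_SERINE = "T-arm-serine"

#: valid pairs: Watson-Crick plus G.U wobble, at full weight
_PAIRS = frozenset({("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")})


def can_pair(a: str, b: str) -> bool:
    return (a, b) in _PAIRS


@dataclass(frozen=True)
class TrnaModel:
    """Length ranges and pairing rules for the fold search."""

    acceptor_stem: int = 7
    dhu_stem: int = 4
    dhu_loop_range: tuple = (4, 9)
    anticodon_stem: int = 5
    anticodon_loop: int = 7            # anticodon = central 3 nt
    tv_loop_range: tuple = (4, 12)
    t_stem_range: tuple = (3, 5)       # serine variant
    t_loop_range: tuple = (3, 8)       # serine variant
    spacer1_range: tuple = (0, 2)      # between acceptor 5' and next arm
    spacer2_range: tuple = (0, 1)      # between arms
    max_mismatch_per_stem: int = 1
    min_length: int = 45
    max_length: int = 75


DEFAULT_MODEL = TrnaModel()


@dataclass(frozen=True)
class TrnaStructure:
    """One scored arm placement.

    ``arms`` maps region name to a half-open 0-based (start, end) extent;
    ``pairs`` lists paired position indices (5' partner first).
    """

    variant: str
    arms: dict = field(repr=False)
    pairs: tuple
    anticodon: str
    mismatches: int
    score: int

    def dot_bracket(self, length: int) -> str:
        s = ["."] * length
        for i, j in self.pairs:
            s[i], s[j] = "(", ")"
        return "".join(s)


def _range(lo_hi):
    return range(lo_hi[0], lo_hi[1] + 1)


def _tv_placements(L: int, m: TrnaModel):
    base = 2 * m.acceptor_stem + 2 * m.dhu_stem + 2 * m.anticodon_stem + m.anticodon_loop
    for s1 in _range(m.spacer1_range):
        for dl in _range(m.dhu_loop_range):
            for s2 in _range(m.spacer2_range):
                tv = L - (base + s1 + dl + s2)
                if not (m.tv_loop_range[0] <= tv <= m.tv_loop_range[1]):
                    continue
                p = m.acceptor_stem
                arms = {"acceptor5": (0, p)}
                p += s1
                arms["dhu5"] = (p, p + m.dhu_stem); p += m.dhu_stem
                arms["dhu_loop"] = (p, p + dl); p += dl
                arms["dhu3"] = (p, p + m.dhu_stem); p += m.dhu_stem
                p += s2
                arms["ac5"] = (p, p + m.anticodon_stem); p += m.anticodon_stem
                arms["ac_loop"] = (p, p + m.anticodon_loop); p += m.anticodon_loop
                arms["ac3"] = (p, p + m.anticodon_stem); p += m.anticodon_stem
                arms["tv_loop"] = (p, p + tv); p += tv
                arms["acceptor3"] = (p, p + m.acceptor_stem)
                yield VARIANT_TV, arms, (tv, s1, dl, s2, 0)


def _serine_placements(L: int, m: TrnaModel):
    for s1 in _range(m.spacer1_range):
        for drep in _range(m.dhu_loop_range):
            for s2 in _range(m.spacer2_range):
                for ts in _range(m.t_stem_range):
                    tl = L - (2 * m.acceptor_stem + 2 * m.anticodon_stem
                              + m.anticodon_loop + s1 + drep + s2 + 2 * ts)
                    if not (m.t_loop_range[0] <= tl <= m.t_loop_range[1]):
                        continue
                    p = m.acceptor_stem
                    arms = {"acceptor5": (0, p)}
                    p += s1
                    arms["dhu_replacement"] = (p, p + drep); p += drep
                    arms["ac5"] = (p, p + m.anticodon_stem); p += m.anticodon_stem
                    arms["ac_loop"] = (p, p + m.anticodon_loop); p += m.anticodon_loop
                    arms["ac3"] = (p, p + m.anticodon_stem); p += m.anticodon_stem
                    p += s2
                    arms["t5"] = (p, p + ts); p += ts
                    arms["t_loop"] = (p, p + tl); p += tl
                    arms["t3"] = (p, p + ts); p += ts
                    arms["acceptor3"] = (p, p + m.acceptor_stem)
                    yield VARIANT_SERINE, arms, (tl, s1, drep, s2, ts)


def _stem_pairs(arms: dict) -> dict:
    """Map stem name -> list of (i, j) paired indices (antiparallel)."""
    stems = {}
    for five, three in (("acceptor5", "acceptor3"), ("dhu5", "dhu3"),
                        ("ac5", "ac3"), ("t5", "t3")):
        if five in arms:
            (a, b), (c, d) = arms[five], arms[three]
            n = b - a
            stems[five[:-1]] = [(a + k, d - 1 - k) for k in range(n)]
    return stems


def placement_pairs(arms: dict) -> tuple:
    return tuple(p for pl in _stem_pairs(arms).values() for p in pl)


def fold(seq: str, model: TrnaModel = DEFAULT_MODEL) -> Optional[TrnaStructure]:
    """Best-scoring arm placement, or None if no placement satisfies the
    per-stem mismatch budget.

    Deterministic tie-break: highest score, then fewest mismatches, then the
    TV variant before the serine variant, then the smallest trailing loop,
    then the leftmost (smallest-spacer, smallest-loop) placement.
    """
    seq = seq.upper().replace("U", "T")
    L = len(seq)
    if not (model.min_length <= L <= model.max_length):
        raise ValueError(f"sequence length {L} outside [{model.min_length}, {model.max_length}]")
    if set(seq) - set("ACGTN"):
        raise ValueError(f"non-nucleotide characters: {sorted(set(seq) - set('ACGTN'))}")

    best = None
    best_key = None
    candidates = list(_tv_placements(L, model)) + list(_serine_placements(L, model))
    for rank, (variant, arms, params) in enumerate(candidates):
        stems = _stem_pairs(arms)
        total_match = 0
        total_mm = 0
        feasible = True
        for pair_list in stems.values():
            mm = sum(0 if can_pair(seq[i], seq[j]) else 1 for i, j in pair_list)
            if mm > model.max_mismatch_per_stem:
                feasible = False
                break
            total_mm += mm
            total_match += len(pair_list) - mm
        if not feasible:
            continue
        score = total_match - total_mm
        variant_rank = 0 if variant == VARIANT_TV else 1
        key = (-score, total_mm, variant_rank) + params
        if best_key is None or key < best_key:
            a, b = arms["ac_loop"]
            mid = a + (b - a) // 2
            anticodon = seq[mid - 1:mid + 2]
            best = TrnaStructure(variant, arms, placement_pairs(arms),
                                 anticodon, total_mm, score)
            best_key = key
    return best


def classify(structure: TrnaStructure, code: GeneticCode = INVERTEBRATE_MITO) -> str:
    """Gene label implied by the folded anticodon (L1/L2/S1/S2 disambiguated)."""
    return trna_label_for_anticodon(structure.anticodon, code)


@dataclass
class TrnaReportRow:
    name: str
    length: int
    folded: bool
    variant: Optional[str] = None
    anticodon: Optional[str] = None
    inferred_label: Optional[str] = None
    label_agrees: Optional[bool] = None
    mismatches: Optional[int] = None


@dataclass
class TrnaValidation:
    rows: list
    length_range: tuple              # (min, max) over the 22 spans

    @property
    def n_folded(self) -> int:
        return sum(r.folded for r in self.rows)

    @property
    def variants(self):
        from collections import Counter
        return Counter(r.variant for r in self.rows if r.folded)


def validate_trna_set(table, genome, model: TrnaModel = DEFAULT_MODEL,
                      code: GeneticCode = INVERTEBRATE_MITO) -> TrnaValidation:
    """Fold every annotated tRNA and check anticodon/label agreement."""
    rows = []
    lengths = []
    for f in table.trnas:
        seq = f.sequence(genome)
        lengths.append(len(seq))
        row = TrnaReportRow(name=f.name, length=len(seq), folded=False)
        try:
            st = fold(seq, model)
        except ValueError:
            st = None
        if st is not None:
            row.folded = True
            row.variant = st.variant
            row.anticodon = st.anticodon
            row.mismatches = st.mismatches
            try:
                row.inferred_label = classify(st, code)
                row.label_agrees = row.inferred_label == f.name
            except ValueError:
                row.label_agrees = False
        rows.append(row)
    return TrnaValidation(rows=rows, length_range=(min(lengths), max(lengths)) if lengths else (0, 0))
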