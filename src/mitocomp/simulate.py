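"""Synthetic mitogenome generation with known ground truth.

A :class:`GenomeSpec` fixes everything the analysis modules measure: the
gene layout (coordinates, start/stop codons, overlaps), a 64-entry codon
distribution for drawing protein-coding sequence, per-class A+T targets for
rRNA/NCR background, a tRNA structural model, and tandem-repeat plans for
non-coding regions.  Generation is deterministic given the seed.

Layout templates transcribed from the two published annotation tables ship
with the package (``GenomeSpec.from_template``); their codon distributions
are the published per-codon counts, so synthetic genomes reproduce the
published marginal statistics up to sampling noise while the layout numbers
(spans, gaps, overlaps, codon totals) are reproduced exactly.

Overlap realization: features are generated downstream-first, so a
downstream feature's bases take precedence in shared positions, and the
upstream gene's codons are sampled conditioned on them.  The hard base
requirements of every planned start/stop codon are checked for mutual
consistency up front; an infeasible plan fails loudly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Optional, Sequence

import numpy as np

from .codes import ALL_CODONS, ANTICODONS, GeneticCode, INVERTEBRATE_MITO
from .genome import CircularGenome, FeatureTable, GeneFeature, feature_length
from .io import load_codon_usage_counts, load_template_table, TEMPLATE_LENGTHS
from .gene_order import GeneOrder
from . import trna as trna_mod
from .trna import (DEFAULT_MODEL, TrnaModel, VARIANT_SERINE, VARIANT_TV,
                   _serine_placements, _stem_pairs, _tv_placements, fold)


class SpecError(ValueError):
    """An infeasible generative specification (e.g. contradictory overlaps)."""


@dataclass(frozen=True)
class RepeatPlan:
    """A planted tandem array: ``copies`` x ``unit_length`` with
    ``mismatches`` substitutions placed in the first copy."""

    unit_length: int
    copies: int
    mismatches: int = 0

    @property
    def span(self) -> int:
        return self.unit_length * self.copies


@dataclass
class GenomeSpec:
    """Generative specification of one synthetic mitogenome."""

    genome_id: str
    length: int
    features: list
    codon_distribution: dict                 # 64 codons -> frequency, stops 0
    at_targets: dict = field(default_factory=lambda: {"rRNA": 0.80, "NCR": 0.90, "tRNA": 0.80})
    trna_model: TrnaModel = DEFAULT_MODEL
    repeat_plans: dict = field(default_factory=dict)   # NCR feature name -> [RepeatPlan]
    anticodons: dict = field(default_factory=lambda: dict(ANTICODONS))
    seed: int = 0

    def __post_init__(self):
        probs = np.array([self.codon_distribution.get(c, 0.0) for c in ALL_CODONS])
        if probs.sum() <= 0:
            raise SpecError("codon distribution sums to zero")
        self.codon_distribution = {
            c: float(p / probs.sum()) for c, p in zip(ALL_CODONS, probs)
        }

    def to_yaml(self, path):
        """Serialize the spec (layout, distribution, targets, plans, seed)."""
        import dataclasses
        import yaml

        doc = {
            "genome_id": self.genome_id,
            "length": self.length,
            "features": [dataclasses.asdict(f) for f in self.features],
            "codon_distribution": {c: p for c, p in self.codon_distribution.items() if p > 0},
            "at_targets": dict(self.at_targets),
            "trna_model": {k: list(v) if isinstance(v, tuple) else v
                           for k, v in dataclasses.asdict(self.trna_model).items()},
            "repeat_plans": {name: [dataclasses.asdict(p) for p in plans]
                             for name, plans in self.repeat_plans.items()},
            "anticodons": dict(self.anticodons),
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "GenomeSpec":
        import yaml
        from .trna import TrnaModel as TM

        with open(path) as fh:
            doc = yaml.safe_load(fh)
        model_kwargs = {k: tuple(v) if isinstance(v, list) else v
                        for k, v in doc.get("trna_model", {}).items()}
        return cls(
            genome_id=doc["genome_id"],
            length=doc["length"],
            features=[GeneFeature(**f) for f in doc["features"]],
            codon_distribution=doc["codon_distribution"],
            at_targets=doc.get("at_targets", {}),
            trna_model=TM(**model_kwargs) if model_kwargs else DEFAULT_MODEL,
            repeat_plans={name: [RepeatPlan(**p) for p in plans]
                          for name, plans in doc.get("repeat_plans", {}).items()},
            anticodons=doc.get("anticodons", dict(ANTICODONS)),
            seed=doc.get("seed", 0),
        )

    @classmethod
    def random(cls, seed: int = 0, genome_id: Optional[str] = None,
               overlap_prob: float = 0.25, ncr_repeats: bool = True) -> "GenomeSpec":
        """A randomized but feasible complete 36-gene layout.

        Gene lengths, start/stop codons, intergenic gaps, single-base
        overlaps and one repeat-bearing NCR are drawn at random within the
        ranges typical of chromadorean mitogenomes; the codon distribution
        is Dirichlet-random over the 60 sense codons.  Useful for property
        tests that need many independent valid genomes.
        """
        from .codes import PCG_GENES, RRNA_GENES, TRNA_GENES

        rng = np.random.default_rng(seed)
        genes = list(PCG_GENES) + list(TRNA_GENES) + list(RRNA_GENES)
        rng.shuffle(genes)
        feats = []
        pos = 1
        prev_overlappable = False      # previous gene ends in TAA (complete stop)
        for i, name in enumerate(genes):
            overlap = 0
            if i and prev_overlappable and rng.random() < overlap_prob:
                overlap = 1
            else:
                pos += int(rng.integers(0, 25))
            start = pos - overlap
            if name in PCG_GENES:
                n_codons = int(rng.integers(70, 400))
                stop = str(rng.choice(["TAA", "TAG", "T", "TA"]))
                start_codon = str(rng.choice(["ATT", "ATA"])) if overlap \
                    else str(rng.choice(["ATT", "ATA", "ATG", "TTG"]))
                span = 3 * n_codons + len(stop)
                feats.append(GeneFeature(name, "PCG", start, start + span - 1,
                                         "+", start_codon, stop))
                prev_overlappable = stop == "TAA"
            elif name in TRNA_GENES:
                span = int(rng.integers(52, 61))
                feats.append(GeneFeature(name, "tRNA", start, start + span - 1, "+"))
                prev_overlappable = False
            else:
                span = int(rng.integers(600, 1001))
                feats.append(GeneFeature(name, "rRNA", start, start + span - 1, "+"))
                prev_overlappable = False
            pos = start + span
        plans = {}
        if ncr_repeats:
            unit = int(rng.integers(20, 80))
            copies = int(rng.integers(2, 5))
            ncr_len = unit * copies + int(rng.integers(50, 200))
            pos += int(rng.integers(0, 10))
            feats.append(GeneFeature("NCR", "NCR", pos, pos + ncr_len - 1, "+"))
            plans["NCR"] = [RepeatPlan(unit, copies, 0)]
            pos += ncr_len
        length = pos - 1 + int(rng.integers(0, 20))   # trailing gap to cox-start
        sense = [c for c in ALL_CODONS if c not in ("TAA", "TAG")]
        alpha = rng.gamma(1.0, 1.0, size=len(sense)) + 0.05
        dist = dict(zip(sense, alpha / alpha.sum()))
        return cls(
            genome_id=genome_id or f"synthetic-{seed}",
            length=length,
            features=feats,
            codon_distribution=dist,
            at_targets={"rRNA": 0.75, "NCR": 0.85, "tRNA": 0.75},
            repeat_plans=plans,
            seed=seed,
        )

    @classmethod
    def from_template(cls, species: str, seed: int = 0,
                      code: GeneticCode = INVERTEBRATE_MITO) -> "GenomeSpec":
        """Spec replicating a packaged annotation template.

        ``species`` is ``bxylophilus`` or ``pvulnus``.  Codon distribution =
        the published per-codon counts; A+T targets = the published
        partition compositions; repeat plans = the published repeat arrays.
        """
        table = load_template_table(species)
        counts = load_codon_usage_counts()
        col = {"bxylophilus": "bx_count", "pvulnus": "pv_count"}[species]
        dist = dict(zip(counts["codon"], counts[col].astype(float)))
        at = {
            "bxylophilus": {"rRNA": 0.853, "NCR": 0.987, "tRNA": 0.847},
            "pvulnus": {"rRNA": 0.694, "NCR": 0.729, "tRNA": 0.772},
        }[species]
        plans = {
            "bxylophilus": {"NCR": [RepeatPlan(147, 4, 0), RepeatPlan(101, 4, 0),
                                    RepeatPlan(56, 3, 1)]},
            "pvulnus": {"NCR1": [RepeatPlan(494, 3, 2)]},
        }[species]
        return cls(
            genome_id=species,
            length=TEMPLATE_LENGTHS[species],
            features=list(table.features),
            codon_distribution=dist,
            at_targets=at,
            repeat_plans=plans,
            seed=seed,
        )


def _positions(f: GeneFeature, L: int) -> list:
    """Absolute 0-based genome positions covered by a feature, 5'->3'."""
    if not f.wraps:
        return list(range(f.start - 1, f.end))
    return list(range(f.start - 1, L)) + list(range(0, f.end))


def _at_background(rng, n, at_fraction):
    """i.i.d. background with the A+T target split evenly within AT and GC."""
    p = [at_fraction / 2, (1 - at_fraction) / 2, (1 - at_fraction) / 2, at_fraction / 2]
    return rng.choice(list("ACGT"), size=n, p=p)


def _register(fixed: dict, pos: int, base: str, who: str):
    if pos in fixed and fixed[pos] != base:
        raise SpecError(f"conflicting base requirement at position {pos + 1}: "
                        f"{fixed[pos]} vs {base} ({who})")
    fixed[pos] = base


def _hard_constraints(spec: GenomeSpec) -> dict:
    """Absolute base requirements implied by planned start/stop codons."""
    fixed = {}
    L = spec.length
    for f in spec.features:
        if f.klass != "PCG":
            continue
        pos = _positions(f, L)
        if f.start_codon:
            for off, b in enumerate(f.start_codon):
                _register(fixed, pos[off], b, f"{f.name} start")
        if f.stop_codon:
            for off, b in enumerate(reversed(f.stop_codon)):
                _register(fixed, pos[-1 - off], b, f"{f.name} stop")
        rem = feature_length(f, L) % 3
        want = {0: 3, 1: 1, 2: 2}[rem]
        if f.stop_codon and len(f.stop_codon) != want:
            raise SpecError(f"{f.name}: stop {f.stop_codon} inconsistent with span "
                            f"length remainder {rem}")
    return fixed


def _sample_codon(rng, dist: dict, pattern: str) -> str:
    """Draw a codon from ``dist`` conditioned on fixed bases ('.' = free)."""
    allowed = [c for c in ALL_CODONS
               if dist[c] > 0 and all(p == "." or p == b for p, b in zip(pattern, c))]
    if not allowed:
        raise SpecError(f"no codon with positive frequency matches pattern {pattern}")
    probs = np.array([dist[c] for c in allowed])
    return allowed[rng.choice(len(allowed), p=probs / probs.sum())]


def _gen_pcg(f: GeneFeature, spec: GenomeSpec, fixed: dict, rng):
    L = spec.length
    pos = _positions(f, L)
    stop_len = f.stop_length()
    n_codons = (len(pos) - stop_len) // 3
    if f.start_codon is None or f.stop_codon is None:
        raise SpecError(f"{f.name}: planned PCGs need explicit start and stop codons")
    for k in range(n_codons):
        p3 = pos[3 * k:3 * k + 3]
        if k == 0:
            codon = f.start_codon
            if any(fixed.get(p, b) != b for p, b in zip(p3, codon)):
                raise SpecError(f"{f.name}: start codon conflicts with shared bases")
        else:
            pattern = "".join(fixed.get(p, ".") for p in p3)
            codon = _sample_codon(rng, spec.codon_distribution, pattern)
        for p, b in zip(p3, codon):
            _register(fixed, p, b, f.name)
    for p, b in zip(pos[-stop_len:], f.stop_codon):
        _register(fixed, p, b, f"{f.name} stop")


def generate_trna(label: str, model: TrnaModel = DEFAULT_MODEL,
                  rng=None, length: Optional[int] = None,
                  anticodon: Optional[str] = None,
                  fixed_bases: Optional[dict] = None,
                  at_fraction: float = 0.80,
                  max_tries: int = 200) -> tuple:
    """Generate a tRNA sequence that folds into its planted structure.

    Serine labels (trnS1/trnS2) use the DHU-less T-arm variant; all others
    the TV-replacement-loop variant.  ``fixed_bases`` maps 0-based offsets
    within the sequence to required bases (overlap constraints).  The draw is
    accepted only when :func:`~mitocomp.trna.fold` returns exactly the
    planted placement, so the generator/folder round trip holds by
    construction.  Returns (sequence, TrnaStructure).
    """
    if rng is None:
        rng = np.random.default_rng(0)
    if anticodon is None:
        anticodon = ANTICODONS[label]
    fixed_bases = fixed_bases or {}
    serine = label in ("trnS1", "trnS2")
    if length is None:
        length = 55
    placements = list((_serine_placements if serine else _tv_placements)(length, model))
    if not placements:
        raise SpecError(f"{label}: no {('serine' if serine else 'TV')} placement of length {length}")

    pair_choices = ["AT", "TA", "GC", "CG", "GT", "TG"]
    pair_probs = np.array([.3, .3, .12, .12, .08, .08])

    for attempt in range(max_tries):
        variant, arms, _ = placements[rng.choice(len(placements))]
        seq = [None] * length
        for off, b in fixed_bases.items():
            seq[off] = b
        # anticodon occupies the centre of the anticodon loop
        a, b = arms["ac_loop"]
        mid = a + (b - a) // 2
        ok = True
        for off, base in zip(range(mid - 1, mid + 2), anticodon):
            if seq[off] is not None and seq[off] != base:
                ok = False
                break
            seq[off] = base
        if not ok:
            continue
        for i, j in (p for pl in _stem_pairs(arms).values() for p in pl):
            bi, bj = seq[i], seq[j]
            if bi is not None and bj is not None:
                continue                      # may or may not pair; fold will judge
            if bi is not None:
                seq[j] = {"A": "T", "T": "A", "G": "C", "C": "G", "N": "N"}[bi]
            elif bj is not None:
                seq[i] = {"A": "T", "T": "A", "G": "C", "C": "G", "N": "N"}[bj]
            else:
                pick = pair_choices[rng.choice(len(pair_choices), p=pair_probs)]
                seq[i], seq[j] = pick[0], pick[1]
        free = [k for k, v in enumerate(seq) if v is None]
        if free:
            bg = _at_background(rng, len(free), at_fraction)
            for k, b2 in zip(free, bg):
                seq[k] = b2
        s = "".join(seq)
        st = fold(s, model)
        if st is None:
            continue
        if st.variant == (VARIANT_SERINE if serine else VARIANT_TV) \
                and st.arms == arms and st.anticodon == anticodon:
            return s, st
    raise SpecError(f"{label}: no accepted draw in {max_tries} tries "
                    f"(length {length}, {len(fixed_bases)} fixed bases)")


def _gen_trna_feature(f: GeneFeature, spec: GenomeSpec, fixed: dict, rng):
    L = spec.length
    pos = _positions(f, L)
    local_fixed = {k: fixed[p] for k, p in enumerate(pos) if p in fixed}
    anticodon = f.anticodon or spec.anticodons[f.name]
    seq, _ = generate_trna(f.name, spec.trna_model, rng, length=len(pos),
                           anticodon=anticodon, fixed_bases=local_fixed,
                           at_fraction=spec.at_targets.get("tRNA", 0.80))
    for p, b in zip(pos, seq):
        _register(fixed, p, b, f.name)


def _plant_repeats(region_len: int, plans: Sequence[RepeatPlan], rng,
                   at_fraction: float) -> tuple:
    """Sequence of a non-coding region with planted head-to-tail arrays.

    Repeat families are placed contiguously from the 5' end of the region;
    the remainder is i.i.d. background.  Returns (sequence, truth list of
    (offset, unit, copies, mismatches))."""
    total = sum(p.span for p in plans)
    if total > region_len:
        raise SpecError(f"repeat plans ({total} bp) exceed region ({region_len} bp)")
    chunks = []
    truth = []
    offset = 0
    for plan in plans:
        unit = "".join(_at_background(rng, plan.unit_length, at_fraction))
        copies = [list(unit) for _ in range(plan.copies)]
        sites = rng.choice(plan.unit_length, size=plan.mismatches, replace=False)
        for site in sites:
            old = copies[0][site]
            alt = [b for b in "ACGT" if b != old]
            copies[0][site] = alt[rng.choice(3)]
        array = "".join("".join(c) for c in copies)
        chunks.append(array)
        truth.append({"offset": offset, "unit_length": plan.unit_length,
                      "copies": plan.copies, "mismatches": plan.mismatches,
                      "unit": unit})
        offset += plan.span
    rest = region_len - total
    chunks.append("".join(_at_background(rng, rest, at_fraction)))
    return "".join(chunks), truth


def generate_genome(spec: GenomeSpec, seed: Optional[int] = None) -> tuple:
    """Realize a spec into (CircularGenome, FeatureTable, truth dict).

    Deterministic given the seed (``spec.seed`` unless overridden).
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    L = spec.length
    fixed = _hard_constraints(spec)
    truth = {"repeats": {}, "anticodons": {}, "codon_distribution": dict(spec.codon_distribution)}

    ordered = sorted(spec.features, key=lambda f: f.start, reverse=True)
    ncr_at = spec.at_targets.get("NCR", 0.90)
    for f in ordered:
        if f.klass == "PCG":
            _gen_pcg(f, spec, fixed, rng)
        elif f.klass == "tRNA":
            _gen_trna_feature(f, spec, fixed, rng)
            truth["anticodons"][f.name] = f.anticodon or spec.anticodons[f.name]
        elif f.klass == "rRNA":
            pos = _positions(f, L)
            bg = _at_background(rng, len(pos), spec.at_targets.get("rRNA", 0.80))
            for p, b in zip(pos, bg):
                if p not in fixed:
                    fixed[p] = b
        else:  # NCR
            pos = _positions(f, L)
            plans = spec.repeat_plans.get(f.name, [])
            seq, planted = _plant_repeats(len(pos), plans, rng, ncr_at)
            conflicts = [p for p in pos if p in fixed]
            if conflicts and plans:
                raise SpecError(f"{f.name}: NCR with repeat plans overlaps other features")
            for p, b in zip(pos, seq):
                if p not in fixed:
                    fixed[p] = b
            truth["repeats"][f.name] = planted

    # intergenic positions not covered by any feature: NCR-like background
    free = [p for p in range(L) if p not in fixed]
    bg = _at_background(rng, len(free), ncr_at)
    for p, b in zip(free, bg):
        fixed[p] = b

    residues = "".join(fixed[p] for p in range(L))
    genome = CircularGenome(id=spec.genome_id, residues=residues)
    table = FeatureTable(spec.genome_id, [replace(f) for f in spec.features])
    return genome, table, truth


def perturb_gene_order(order: GeneOrder, n_moves: int, seed: int = 0) -> tuple:
    """Apply ``n_moves`` single-gene translocations at seeded random positions.

    Each move takes a gene out of the circle and reinserts it between two
    genes that were not adjacent to it, so one move always breaks exactly
    three adjacencies.  Returns (new order, list of moved gene names).
    """
    if n_moves < 0:
        raise ValueError("n_moves must be >= 0")
    rng = np.random.default_rng(seed)
    genes = list(order.genes)
    moves = []
    for _ in range(n_moves):
        n = len(genes)
        for _try in range(1000):
            gi = int(rng.choice(n))
            gene = genes[gi]
            rest = genes[:gi] + genes[gi + 1:]
            ins = int(rng.choice(len(rest) + 1))
            # veto re-creating the old neighborhood (no-op moves)
            new = rest[:ins] + [gene] + rest[ins:]
            m = len(new)
            ni = new.index(gene)
            old_pred, old_succ = genes[(gi - 1) % n], genes[(gi + 1) % n]
            new_pred, new_succ = new[(ni - 1) % m], new[(ni + 1) % m]
            if (new_pred, new_succ) != (old_pred, old_succ):
                genes = new
                moves.append(gene)
                break
        else:
            raise RuntimeError("could not find a valid translocation")
    return GeneOrder(order.genome_id + f"+{n_moves}mv", tuple(genes)), moves
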