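"""Circular gene-order comparison: adjacencies, breakpoints, NJ tree.

Mitochondrial gene orders are circular permutations of the 36-gene
complement.  Because all genes are co-oriented in these genomes,
adjacencies are directed gene pairs; the breakpoint distance between two
orders is the number of adjacencies of one that the other lacks.  A
neighbor-joining tree over a breakpoint-distance matrix gives a coarse
rearrangement-based clustering.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .genome import FeatureTable


@dataclass(frozen=True)
class GeneOrder:
    """A circular gene order (NCRs excluded), optionally anchored."""

    genome_id: str
    genes: tuple

    def __post_init__(self):
        if len(set(self.genes)) != len(self.genes):
            dup = sorted({g for g in self.genes if self.genes.count(g) > 1})
            raise ValueError(f"{self.genome_id}: duplicated genes {dup}")

    def __len__(self):
        return len(self.genes)

    @classmethod
    def from_table(cls, table: FeatureTable, anchor: Optional[str] = "cox1") -> "GeneOrder":
        ring = table.gene_ring()
        genes = tuple(f.name for f in sorted(ring, key=lambda f: f.start))
        order = cls(table.genome_id, genes)
        return order.anchored(anchor) if anchor else order

    def anchored(self, anchor: str = "cox1") -> "GeneOrder":
        """Pure rotation so that ``anchor`` comes first."""
        if anchor not in self.genes:
            raise ValueError(f"{self.genome_id}: anchor {anchor!r} not in order")
        i = self.genes.index(anchor)
        return GeneOrder(self.genome_id, self.genes[i:] + self.genes[:i])

    def rotated(self, k: int) -> "GeneOrder":
        k %= len(self.genes)
        return GeneOrder(self.genome_id, self.genes[k:] + self.genes[:k])

    def adjacency_set(self) -> frozenset:
        """Directed neighbor pairs around the circle (|set| = gene count)."""
        n = len(self.genes)
        return frozenset((self.genes[i], self.genes[(i + 1) % n]) for i in range(n))

    def neighbors(self, gene: str) -> tuple:
        i = self.genes.index(gene)
        n = len(self.genes)
        return self.genes[(i - 1) % n], self.genes[(i + 1) % n]


def order_from_table(table: FeatureTable, anchor: Optional[str] = "cox1") -> GeneOrder:
    return GeneOrder.from_table(table, anchor)


def _check_universe(orders: Sequence[GeneOrder]):
    universe = set(orders[0].genes)
    for o in orders[1:]:
        if set(o.genes) != universe:
            raise ValueError(
                f"gene universes differ: {o.genome_id} vs {orders[0].genome_id}"
            )


def shared_adjacencies(*orders: GeneOrder) -> frozenset:
    """Directed adjacencies common to all input orders."""
    if len(orders) < 2:
        raise ValueError("need at least two orders")
    _check_universe(orders)
    shared = orders[0].adjacency_set()
    for o in orders[1:]:
        shared &= o.adjacency_set()
    return shared


def breakpoint_distance(a: GeneOrder, b: GeneOrder) -> int:
    """Number of adjacencies of one circular order absent from the other.

    Symmetric, non-negative, zero iff the circular orders are identical.
    """
    return len(a) - len(shared_adjacencies(a, b))


def translocation_report(a: GeneOrder, b: GeneOrder) -> dict:
    """Genes whose (predecessor, successor) context differs between orders.

    Maps gene -> ((pred_a, succ_a), (pred_b, succ_b)).
    """
    _check_universe((a, b))
    out = {}
    for gene in a.genes:
        ctx_a, ctx_b = a.neighbors(gene), b.neighbors(gene)
        if ctx_a != ctx_b:
            out[gene] = (ctx_a, ctx_b)
    return out


def nj_tree(distance: np.ndarray, labels: Sequence[str]) -> str:
    """Neighbor-joining tree in Newick, with deterministic tie-breaking.

    Requires a symmetric zero-diagonal matrix over >= 3 taxa.  Ties in the
    Q criterion break on the lexicographically smallest (label_i, label_j)
    pair; negative branch lengths are clamped to zero.
    """
    d = np.asarray(distance, dtype=float)
    n = d.shape[0]
    if d.shape != (n, n) or n != len(labels):
        raise ValueError("distance matrix shape does not match labels")
    if n < 3:
        raise ValueError("need at least 3 taxa")
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0.0):
        raise ValueError("distance matrix must have a zero diagonal")

    # active nodes: (sort_label, newick_subtree)
    nodes = [(lab, lab) for lab in labels]
    d = d.copy()

    def fmt(x: float) -> str:
        return f"{max(x, 0.0):.6g}"

    while len(nodes) > 2:
        m = len(nodes)
        r = d.sum(axis=1)
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * d[i, j] - r[i] - r[j]
                pair = tuple(sorted((nodes[i][0], nodes[j][0])))
                key = (q, pair)
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        li = d[i, j] / 2 + (r[i] - r[j]) / (2 * (m - 2))
        lj = d[i, j] - li
        sub = f"({nodes[i][1]}:{fmt(li)},{nodes[j][1]}:{fmt(lj)})"
        new_label = min(nodes[i][0], nodes[j][0])
        dn = np.zeros(m - 1)
        keep = [k for k in range(m) if k not in (i, j)]
        for a, k in enumerate(keep):
            dn[a] = (d[i, k] + d[j, k] - d[i, j]) / 2
        d2 = np.zeros((m - 1, m - 1))
        for a, ka in enumerate(keep):
            for b, kb in enumerate(keep):
                d2[a, b] = d[ka, kb]
        d2[-1, :-1] = dn[:len(keep)]
        d2[:-1, -1] = dn[:len(keep)]
        nodes = [nodes[k] for k in keep] + [(new_label, sub)]
        d = d2

    (la, sa), (lb, sb) = nodes
    half = d[0, 1] / 2
    return f"({sa}:{fmt(half)},{sb}:{fmt(half)});"
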