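"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own algorithms: alignment scores are
found by enumerating every possible alignment, and tandem arrays by direct
window comparison.
"""

from functools import lru_cache


def exhaustive_alignment_score(a: str, b: str, match, mismatch, gap_open, gap_extend):
    """Maximum global alignment score by enumerating all alignments.

    An alignment is a sequence of columns (pair, insert, delete); every
    maximal gap run in either row costs ``gap_open + k * gap_extend``.
    Feasible only for short sequences (say <= 8 residues).
    """

    best = [float("-inf")]

    def step(i, j, score, state):
        # state: 0 = last column was a pair, 1 = gap in b open, 2 = gap in a open
        if i == len(a) and j == len(b):
            best[0] = max(best[0], score)
            return
        if i < len(a) and j < len(b):
            s = match if a[i] == b[j] else mismatch
            step(i + 1, j + 1, score + s, 0)
        if i < len(a):
            open_cost = gap_extend if state == 1 else gap_open + gap_extend
            step(i + 1, j, score + open_cost, 1)
        if j < len(b):
            open_cost = gap_extend if state == 2 else gap_open + gap_extend
            step(i, j + 1, score + open_cost, 2)

    step(0, 0, 0, 0)
    return best[0]


def exact_tandem_arrays(seq: str, min_unit: int, min_copies: int):
    """All maximal perfect (0-mismatch) tandem arrays, by direct comparison."""
    L = len(seq)
    found = []
    for p in range(min_unit, L // min_copies + 1):
        for s in range(0, L - min_copies * p + 1):
            unit = seq[s:s + p]
            c = 1
            while s + (c + 1) * p <= L and seq[s + c * p:s + (c + 1) * p] == unit:
                c += 1
            if c >= min_copies:
                # maximality: not a continuation of the same phase
                if s >= p and seq[s - p:s] == unit:
                    continue
                found.append((s, p, c))
    return found


def random_additive_matrix(rng, n=5):
    """A random exactly-additive n-taxon tree metric.

    Built by random agglomeration with positive integer branch lengths.
    """
    import numpy as np

    D = np.zeros((n, n))
    nodes = [{i: 0.0} for i in range(n)]   # leaf -> distance to cluster root
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        da, db = nodes[i], nodes[j]
        la, lb = float(rng.integers(1, 9)), float(rng.integers(1, 9))
        for k, v in da.items():
            for k2, v2 in db.items():
                D[k, k2] = D[k2, k] = v + la + v2 + lb
        merged = {k: v + la for k, v in da.items()}
        merged.update({k: v + lb for k, v in db.items()})
        nodes = [nodes[k] for k in range(len(nodes)) if k not in (i, j)] + [merged]
    return D
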