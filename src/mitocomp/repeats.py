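"""Tandem-repeat discovery in non-coding regions.

Mitochondrial control regions frequently carry head-to-tail tandem arrays
(unit lengths from tens to hundreds of bp, a handful of copies, near-perfect
identity).  The detector slides every candidate period over the region,
extends runs greedily against a running consensus, and reports maximal
arrays.  Mismatches are counted against the final column-majority consensus,
not against the first copy, so a single deviant first copy is charged its
own mismatches.  The O(L x P) scan is perfectly adequate at mitogenome
scale (L <= ~25 kb).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .codes import revcomp
from .compstats import base_composition
from .genome import CircularGenome, FeatureTable, intergenic_intervals

_BASE_ORDER = "ACGT"
_BASE_CODES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class TandemRepeat:
    """A maximal tandem array within the queried region (1-based start)."""

    start: int
    unit_length: int
    copies: int
    consensus: str
    total_mismatches: int
    per_copy_mismatches: tuple

    @property
    def span(self) -> int:
        return self.copies * self.unit_length

    @property
    def end(self) -> int:
        return self.start + self.span - 1


def _extend_run(arr: np.ndarray, s: int, p: int, max_mm: int):
    """Greedy left-to-right extension of a period-``p`` run starting at ``s``.

    The next window is accepted while its Hamming distance to the running
    column-majority consensus stays within ``max_mm``.  Returns
    (copies, consensus string, per-copy mismatch tuple) with mismatches
    recounted against the final consensus, or None if fewer than two copies.
    """
    L = len(arr)
    counts = np.zeros((4, p), dtype=np.int32)
    windows = [arr[s:s + p]]
    counts += (windows[0] == _BASE_CODES[:, None])
    consensus = windows[0].copy()
    nxt = s + p
    while nxt + p <= L:
        w = arr[nxt:nxt + p]
        if int(np.count_nonzero(w != consensus)) > max_mm:
            break
        windows.append(w)
        counts += (w == _BASE_CODES[:, None])
        # argmax ties resolve to the first (A < C < G < T) row
        consensus = _BASE_CODES[np.argmax(counts, axis=0)]
        nxt += p
    if len(windows) < 2:
        return None
    final = _BASE_CODES[np.argmax(counts, axis=0)]
    per_copy = tuple(int(np.count_nonzero(w != final)) for w in windows)
    return windows, final.tobytes().decode(), per_copy


def find_tandem_repeats(
    seq: str,
    min_unit: int = 20,
    max_unit: Optional[int] = None,
    min_copies: int = 2,
    max_mismatch_per_copy: int = 1,
) -> list:
    """Maximal tandem arrays with period in [min_unit, max_unit].

    For every period, runs are extended greedily left to right from every
    start whose adjacent-window Hamming distance permits two copies (a safe
    prefilter by the triangle inequality).  Reported mismatches are counted
    against the final whole-array consensus, so a single deviant first copy
    is charged its own mismatches.  Overlapping reports are reduced to the
    maximal ones: longest array span wins, then fewest mismatches, then
    smaller unit, then leftmost.  Output is ordered by start, then
    descending unit length.
    """
    seq = seq.upper()
    L = len(seq)
    if min_unit < 2:
        raise ValueError("min_unit must be >= 2")
    if max_unit is None:
        max_unit = L // max(min_copies, 2)
    if max_unit < min_unit:
        raise ValueError(f"degenerate unit range [{min_unit}, {max_unit}]")
    if min_copies < 2:
        raise ValueError("min_copies must be >= 2")

    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    candidates = []
    for p in range(min_unit, min(max_unit, L // 2) + 1):
        diff = (arr[p:] != arr[:-p]).astype(np.int32)
        cum = np.concatenate(([0], np.cumsum(diff)))
        # Hamming distance between windows [s, s+p) and [s+p, s+2p)
        adjacent = cum[p:L - p + 1] - cum[:L - 2 * p + 1]
        for s in np.nonzero(adjacent <= 2 * max_mismatch_per_copy)[0]:
            run = _extend_run(arr, int(s), p, max_mismatch_per_copy)
            if run is None:
                continue
            windows, consensus, per_copy = run
            if len(windows) < min_copies:
                continue
            if any(mm > max_mismatch_per_copy for mm in per_copy):
                continue
            candidates.append(TandemRepeat(
                start=int(s) + 1, unit_length=p, copies=len(windows),
                consensus=consensus, total_mismatches=sum(per_copy),
                per_copy_mismatches=per_copy,
            ))

    # suppress overlapping/contained reports in favor of the maximal one
    candidates.sort(key=lambda r: (-r.span, r.total_mismatches, r.unit_length, r.start))
    accepted = []
    for cand in candidates:
        if all(cand.end < a.start or cand.start > a.end for a in accepted):
            accepted.append(cand)
    accepted.sort(key=lambda r: (r.start, -r.unit_length))
    return accepted


@dataclass(frozen=True)
class NcrRepeatSummary:
    """Repeat families and composition of one non-coding interval."""

    left_gene: str
    right_gene: str
    start: int
    end: int
    length: int
    at_percent: float
    repeats: tuple


def ncr_report(
    genome: CircularGenome,
    table: FeatureTable,
    min_unit: int = 20,
    max_unit: Optional[int] = None,
    min_copies: int = 2,
    max_mismatch_per_copy: int = 1,
    floor: int = 100,
) -> list:
    """Run the repeat detector over every non-coding interval >= ``floor`` bp.

    Non-coding intervals are the positive gaps of the gene-ring census
    (NCR-class features fall inside these gaps by construction).
    """
    out = []
    for left, right, s, e, length in intergenic_intervals(table, genome.length):
        if length < floor:
            continue
        seq = genome.subsequence(s, e)
        reps = find_tandem_repeats(seq, min_unit=min_unit, max_unit=max_unit,
                                   min_copies=min_copies,
                                   max_mismatch_per_copy=max_mismatch_per_copy)
        at = base_composition(seq).at_percent
        out.append(NcrRepeatSummary(left, right, s, e, length, at, tuple(reps)))
    return out
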