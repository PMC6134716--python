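"""Bounded, length-aware pairwise verification.

Candidate pairs surviving the segment filter are verified by computing
their distance only if it does not exceed the threshold tau.  Two modes
exist:

* **edit-distance mode** — ``bounded_edit_distance`` runs a banded
  Levenshtein DP restricted to the diagonals any <=tau-edit alignment can
  visit, with early termination once every active cell exceeds tau.
* **scoring-function mode** — ``bounded_score_distance`` runs a banded
  three-state affine-gap (Gotoh) DP and counts the number of difference
  columns (mismatches + gapped columns) of an optimal-score alignment.
  Among co-optimal alignments the minimum difference count is reported,
  computed by a lexicographic (max score, then min differences) recurrence;
  this makes the count deterministic and symmetric without a traceback.

A gap of length g costs ``gap_open + g * gap_extend`` (the opening gap
column is also charged the extension penalty).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

__all__ = [
    "ScoringFunction",
    "Outcome",
    "DistanceOutcome",
    "bounded_edit_distance",
    "bounded_score_distance",
]

_INF = float("inf")


class Outcome(Enum):
    WITHIN = "within"
    EXCEEDS = "exceeds"


@dataclass(frozen=True)
class DistanceOutcome:
    """Result of a bounded distance computation.

    ``value`` is the exact distance (number of differences) when
    ``kind == WITHIN`` and ``None`` otherwise.
    """

    kind: Outcome
    value: int | None = None

    @property
    def within(self) -> bool:
        return self.kind is Outcome.WITHIN


EXCEEDS = DistanceOutcome(Outcome.EXCEEDS)


@dataclass(frozen=True)
class ScoringFunction:
    """Affine scoring function delta: reward and penalties are magnitudes.

    Defaults follow Swarm's conventional parameters (match +5, mismatch 4,
    gap opening 12, gap extension 4).
    """

    match_reward: int = 5
    mismatch_penalty: int = 4
    gap_open_penalty: int = 12
    gap_extend_penalty: int = 4

    def __post_init__(self) -> None:
        if self.gap_extend_penalty < 1:
            raise ValueError("gap_extend_penalty must be >= 1")
        for name in ("match_reward", "mismatch_penalty", "gap_open_penalty"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def _band(delta: int, tau: int) -> tuple[int, int]:
    # Admissible diagonals c = j - i: reaching diagonal c and ending on
    # diagonal delta requires at least |c| + |c - delta| gap columns.
    slack = (tau - abs(delta)) // 2
    return min(0, delta) - slack, max(0, delta) + slack


def bounded_edit_distance(r: str, s: str, tau: int) -> DistanceOutcome:
    """Exact edit distance d_e(r, s) if <= tau, else EXCEEDS.

    Only the diagonals admissible for a <=tau-edit alignment given the
    length difference are computed, and the DP stops early once no active
    cell can stay within tau.
    """
    if tau < 0:
        raise ValueError("tau must be >= 0")
    n, m = len(r), len(s)
    delta = m - n
    if abs(delta) > tau:
        return EXCEEDS
    if r == s:
        return DistanceOutcome(Outcome.WITHIN, 0)
    lo, hi = _band(delta, tau)
    width = hi - lo + 1
    # row[c - lo] = D[i][i + c]; band is relative to the current row i.
    row = [_INF] * width
    for c in range(lo, hi + 1):
        if 0 <= c <= m:
            row[c - lo] = c  # D[0][j] = j
    for i in range(1, n + 1):
        new = [_INF] * width
        best = _INF
        for c in range(lo, hi + 1):
            j = i + c
            if j < 0 or j > m:
                continue
            if j == 0:
                val = i
            else:
                val = _INF
                diag = row[c - lo]
                if diag is not _INF:
                    val = diag + (r[i - 1] != s[j - 1])
                if c - lo - 1 >= 0 and new[c - lo - 1] + 1 < val:
                    val = new[c - lo - 1] + 1  # deletion (consume r)
                if c - lo + 1 < width and row[c - lo + 1] + 1 < val:
                    val = row[c - lo + 1] + 1  # insertion (consume s)
            new[c - lo] = val
            if val < best:
                best = val
        if best > tau:
            return EXCEEDS
        row = new
    d = row[delta - lo]
    if d <= tau:
        return DistanceOutcome(Outcome.WITHIN, int(d))
    return EXCEEDS


_NEG = (-_INF, -_INF)  # unreachable (score, -differences) state


def bounded_score_distance(
    r: str, s: str, tau: int, delta: ScoringFunction | None = None
) -> DistanceOutcome:
    """Difference count of an optimal affine-gap alignment, bounded by tau.

    Runs Gotoh's three-state recurrence inside the band of diagonals that
    any alignment with <= tau difference columns can visit.  Cells hold
    (score, -differences) pairs compared lexicographically, so a plain max
    prefers the higher score and, on ties, the fewer differences.  Returns
    WITHIN with the difference count when it is <= tau, else EXCEEDS.
    """
    if tau < 0:
        raise ValueError("tau must be >= 0")
    if delta is None:
        delta = ScoringFunction()
    n, m = len(r), len(s)
    dl = m - n
    if abs(dl) > tau:
        return EXCEEDS
    if r == s:
        return DistanceOutcome(Outcome.WITHIN, 0)
    lo, hi = _band(dl, tau)
    width = hi - lo + 1
    ma, mi = delta.match_reward, -delta.mismatch_penalty
    go = -(delta.gap_open_penalty + delta.gap_extend_penalty)
    ge = -delta.gap_extend_penalty

    # Three banded rows of (score, -diffs): M ends in a substitution column,
    # V in a gap-in-s column (consumes r), H in a gap-in-r column.
    M = [_NEG] * width
    V = [_NEG] * width
    H = [_NEG] * width
    if lo <= 0 <= hi:
        M[-lo] = (0.0, 0.0)
    for c in range(max(lo, 1), hi + 1):
        H[c - lo] = (go + ge * (c - 1), float(-c))  # row 0: gap of length j
    for i in range(1, n + 1):
        nM = [_NEG] * width
        nV = [_NEG] * width
        nH = [_NEG] * width
        for c in range(lo, hi + 1):
            j = i + c
            if j < 0 or j > m:
                continue
            w = c - lo
            if j == 0:
                nV[w] = (go + ge * (i - 1), float(-i))
                continue
            # substitution column from (i-1, j-1): same diagonal, prev row
            best = max(M[w], V[w], H[w])
            if best[0] != -_INF:
                if r[i - 1] == s[j - 1]:
                    nM[w] = (best[0] + ma, best[1])
                else:
                    nM[w] = (best[0] + mi, best[1] - 1)
            # gap in s (consume r[i-1]) from (i-1, j): diagonal c+1, prev row
            if w + 1 < width:
                op = max(M[w + 1], H[w + 1])
                ext = V[w + 1]
                cand = max((op[0] + go, op[1] - 1), (ext[0] + ge, ext[1] - 1))
                if cand[0] != -_INF:
                    nV[w] = cand
            # gap in r (consume s[j-1]) from (i, j-1): diagonal c-1, this row
            if w - 1 >= 0:
                op = max(nM[w - 1], nV[w - 1])
                ext = nH[w - 1]
                cand = max((op[0] + go, op[1] - 1), (ext[0] + ge, ext[1] - 1))
                if cand[0] != -_INF:
                    nH[w] = cand
        M, V, H = nM, nV, nH
        # Early termination: every active cell already needs more than tau
        # differences, even before paying for the remaining length gap.
        if i < n:
            alive = False
            for w in range(width):
                future = abs(dl - (w + lo))
                for row in (M, V, H):
                    sc, nd = row[w]
                    if sc != -_INF and -nd + future <= tau:
                        alive = True
                        break
                if alive:
                    break
            if not alive:
                return EXCEEDS
    w = dl - lo
    best = max(M[w], V[w], H[w])
    if best[0] == -_INF or -best[1] > tau:
        return EXCEEDS
    return DistanceOutcome(Outcome.WITHIN, int(-best[1]))
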