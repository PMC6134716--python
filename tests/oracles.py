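"""Independent reference implementations used only to check the package.

These deliberately avoid the package's banded/filtered code paths: edit
distances come from edlib (full alignment, no band reuse), the affine
scoring reference is an unbanded bottom-up DP, tiny instances are checked
by literal enumeration of alignment paths, and the clustering oracle is a
direct transcription of the iterative strategy over a precomputed
distance matrix without any segment filter.
"""

from __future__ import annotations

from collections import OrderedDict
from dataclasses import dataclass

import edlib

from ampliswarm.io import Amplicon
from ampliswarm.pooling import priority_key
from ampliswarm.verify import ScoringFunction

NEG_INF = float("-inf")


def full_edit_distance(r: str, s: str) -> int:
    """Unbounded edit distance via edlib global alignment."""
    return edlib.align(r, s, task="distance")["editDistance"]


def bounded_oracle(r: str, s: str, tau: int) -> int | None:
    """Edit distance if <= tau else None, via edlib's own bound."""
    d = edlib.align(r, s, task="distance", k=tau)["editDistance"]
    return None if d == -1 else d


def ref_score_distance(
    r: str, s: str, delta: ScoringFunction
) -> tuple[float, int]:
    """(optimal score, min differences among optimal alignments), unbanded.

    Bottom-up three-matrix affine-gap DP over the full table; cells hold
    (score, -differences) and are combined with lexicographic max.  A gap
    of length g costs open + g*extend.
    """
    n, m = len(r), len(s)
    ma, mi = delta.match_reward, -delta.mismatch_penalty
    go = -(delta.gap_open_penalty + delta.gap_extend_penalty)
    ge = -delta.gap_extend_penalty
    dead = (NEG_INF, NEG_INF)
    M = [[dead] * (m + 1) for _ in range(n + 1)]
    V = [[dead] * (m + 1) for _ in range(n + 1)]
    H = [[dead] * (m + 1) for _ in range(n + 1)]
    M[0][0] = (0.0, 0.0)
    for i in range(1, n + 1):
        V[i][0] = (go + ge * (i - 1), float(-i))
    for j in range(1, m + 1):
        H[0][j] = (go + ge * (j - 1), float(-j))
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            best = max(M[i - 1][j - 1], V[i - 1][j - 1], H[i - 1][j - 1])
            if best[0] > NEG_INF:
                if r[i - 1] == s[j - 1]:
                    M[i][j] = (best[0] + ma, best[1])
                else:
                    M[i][j] = (best[0] + mi, best[1] - 1)
            op = max(M[i - 1][j], H[i - 1][j])
            ext = V[i - 1][j]
            cand = max((op[0] + go, op[1] - 1), (ext[0] + ge, ext[1] - 1))
            if cand[0] > NEG_INF:
                V[i][j] = cand
            op = max(M[i][j - 1], V[i][j - 1])
            ext = H[i][j - 1]
            cand = max((op[0] + go, op[1] - 1), (ext[0] + ge, ext[1] - 1))
            if cand[0] > NEG_INF:
                H[i][j] = cand
    score, negd = max(M[n][m], V[n][m], H[n][m])
    return score, int(-negd)


def enumerate_alignments(r: str, s: str, delta: ScoringFunction) -> tuple[float, int]:
    """Literal enumeration of every alignment path (tiny strings only).

    Walks all monotone paths through the edit graph, scoring affine gaps
    by tracking the previous column type.  Returns the optimal score and
    the minimum difference count among optimal-score alignments.
    """
    ma, mi = delta.match_reward, -delta.mismatch_penalty
    go = -(delta.gap_open_penalty + delta.gap_extend_penalty)
    ge = -delta.gap_extend_penalty
    best: list[tuple[float, int]] = []

    def walk(i: int, j: int, prev: str, score: float, diffs: int) -> None:
        if i == len(r) and j == len(s):
            best.append((score, diffs))
            return
        if i < len(r) and j < len(s):
            if r[i] == s[j]:
                walk(i + 1, j + 1, "m", score + ma, diffs)
            else:
                walk(i + 1, j + 1, "m", score + mi, diffs + 1)
        if i < len(r):
            cost = ge if prev == "v" else go
            walk(i + 1, j, "v", score + cost, diffs + 1)
        if j < len(s):
            cost = ge if prev == "h" else go
            walk(i, j + 1, "h", score + cost, diffs + 1)

    walk(0, 0, "m", 0.0, 0)
    top = max(sc for sc, _ in best)
    return top, min(df for sc, df in best if sc == top)


@dataclass
class OracleMember:
    id: str
    parent: str | None
    distance: int
    generation: int


def brute_force_cluster(
    amplicons: list[Amplicon],
    t: int,
    breaking: bool = True,
    distances: dict[frozenset[str], int] | None = None,
) -> list[list[OracleMember]]:
    """Literal iterative clustering without any filtering.

    Uses a precomputed all-pairs distance map (pairs within t only;
    computed with edlib when not supplied) and replays the strategy: most
    abundant unassigned amplicon seeds an OTU, generations grow breadth
    first with subseeds in priority order, first claim wins, breaking
    excludes partners more abundant than the subseed.
    """
    if distances is None:
        distances = {}
        for i, a in enumerate(amplicons):
            for b in amplicons[i + 1 :]:
                d = bounded_oracle(a.sequence, b.sequence, t)
                if d is not None:
                    distances[frozenset((a.id, b.id))] = d
    order = sorted(amplicons, key=priority_key)
    unswarmed: "OrderedDict[str, Amplicon]" = OrderedDict((a.id, a) for a in order)
    otus: list[list[OracleMember]] = []
    while unswarmed:
        seed_id, seed = next(iter(unswarmed.items()))
        del unswarmed[seed_id]
        members = [OracleMember(seed_id, None, 0, 0)]
        frontier = [seed]
        gen = 0
        while frontier and unswarmed:
            gen += 1
            frontier.sort(key=priority_key)
            nxt: list[Amplicon] = []
            for sub in frontier:
                partners = []
                for b in unswarmed.values():
                    d = distances.get(frozenset((sub.id, b.id)))
                    if d is None or d > t:
                        continue
                    if breaking and b.abundance > sub.abundance:
                        continue
                    partners.append((b, d))
                partners.sort(key=lambda bd: priority_key(bd[0]))
                for b, d in partners:
                    del unswarmed[b.id]
                    members.append(OracleMember(b.id, sub.id, d, gen))
                    nxt.append(b)
            frontier = nxt
        otus.append(members)
    return otus
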