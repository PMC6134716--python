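"""Pigeonhole segment filter for finding similar amplicons.

To find all amplicons within edit distance tau of a query without
comparing it to the whole pool, every indexed amplicon of length l is cut
into ``tau + k`` contiguous segments of near-equal length.  If two
sequences are within distance tau, at most tau segments can be touched by
edits, so at least k segments of one occur *exactly* in the other
(generalised pigeonhole).  Inverted indices I_(l,i) map (length, segment
index, segment string) to amplicon identifiers; a query sequence S probes
them with a small set of substrings chosen by multimatch-aware selection
(for k=1, the tight Pass-Join windows; for k>1 a conservative +-tau
window, favouring completeness).  Survivors can be re-checked with the
roles of query and candidate swapped (bidirectional filter) before the
expensive verification step.

Amplicons shorter than tau + k cannot be partitioned and are kept in a
side list: they bypass the filter and are verified directly against every
length-compatible query.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .io import Amplicon

__all__ = [
    "Partition",
    "SegmentIndexSet",
    "partition_positions",
    "build_indices",
    "select_substrings",
    "candidates",
    "bidirectional_check",
]


@dataclass(frozen=True)
class Partition:
    """Even partition of a sequence of length l into n contiguous segments.

    Segment lengths differ by at most one; the longer segments are placed
    last, so index and query sides agree on the layout.
    """

    segments: tuple[tuple[int, int], ...]  # (start, length), 0-based

    def __len__(self) -> int:
        return len(self.segments)


def partition_positions(l: int, n: int) -> Partition:
    """Partition positions for a sequence of length ``l`` into ``n`` segments."""
    if n < 1:
        raise ValueError("segment count must be >= 1")
    if l < n:
        raise ValueError(f"cannot partition length {l} into {n} non-empty segments")
    base, rem = divmod(l, n)
    segs = []
    start = 0
    for i in range(n):
        length = base + (1 if i >= n - rem else 0)
        segs.append((start, length))
        start += length
    return Partition(tuple(segs))


def select_substrings(
    s_len: int, l: int, i: int, p_i: int, l_i: int, tau: int, k: int = 1
) -> range:
    """Admissible start positions in S of substrings probing segment i.

    ``l`` is the indexed length, ``i`` the 1-based segment index, ``p_i``
    and ``l_i`` the segment's start and length in the partition of ``l``.
    For k=1 the tight multimatch-aware window is used: if d_e(S, R) <= tau
    for some R of length l, the i-th segment of R occurs in S at one of
    the returned starts.  For k>1 the window is relaxed to +-tau around
    the segment (shifted by the length difference), which is conservative
    but complete.
    """
    d = s_len - l
    if k == 1:
        low = max(0, p_i - (i - 1), p_i + d - (tau + 1 - i))
        high = min(s_len - l_i, p_i + (i - 1), p_i + d + (tau + 1 - i))
    else:
        low = max(0, p_i + min(0, d) - tau)
        high = min(s_len - l_i, p_i + max(0, d) + tau)
    return range(low, high + 1)


@dataclass
class SegmentIndexSet:
    """Inverted indices I_(l,i) over the t+k segments of indexed amplicons.

    ``indices[(l, i)]`` maps the segment string to the set of identifiers
    of length-l amplicons carrying it as their i-th segment (1-based).
    Amplicons too short to partition are kept in ``short`` for direct
    verification.
    """

    tau: int
    k: int
    indices: dict[tuple[int, int], dict[str, list[str]]] = field(default_factory=dict)
    short: list[Amplicon] = field(default_factory=list)
    lengths: set[int] = field(default_factory=set)

    @property
    def n_segments(self) -> int:
        return self.tau + self.k

    def add(self, amplicon: Amplicon) -> None:
        l = len(amplicon.sequence)
        n = self.n_segments
        if l < n:
            self.short.append(amplicon)
            return
        self.lengths.add(l)
        part = _partition_cached(l, n)
        for i, (start, length) in enumerate(part.segments, start=1):
            bucket = self.indices.setdefault((l, i), {})
            seg = amplicon.sequence[start : start + length]
            bucket.setdefault(seg, []).append(amplicon.id)


_PARTITION_CACHE: dict[tuple[int, int], Partition] = {}


def _partition_cached(l: int, n: int) -> Partition:
    key = (l, n)
    part = _PARTITION_CACHE.get(key)
    if part is None:
        part = _PARTITION_CACHE[key] = partition_positions(l, n)
    return part


def build_indices(amplicons: Iterable[Amplicon], tau: int, k: int) -> SegmentIndexSet:
    """Index all amplicons at once (they arrive in abundance order, not by length)."""
    if tau < 1 or k < 1:
        raise ValueError("tau and k must be >= 1")
    idx = SegmentIndexSet(tau=tau, k=k)
    for a in amplicons:
        idx.add(a)
    return idx


def candidates(query: Amplicon, idx: SegmentIndexSet, tau: int | None = None) -> set[str]:
    """Identifiers of indexed amplicons that may be within tau of the query.

    Complete: every indexed amplicon within distance tau of the query is
    returned (long amplicons via >= k segment matches, short ones via the
    side list).  Self-matches are excluded.
    """
    if tau is None:
        tau = idx.tau
    s = query.sequence
    s_len = len(s)
    k = idx.k
    n = idx.n_segments
    hits: dict[str, set[int]] = {}
    for l in idx.lengths:
        if abs(s_len - l) > tau:
            continue
        part = _partition_cached(l, n)
        for i, (p_i, l_i) in enumerate(part.segments, start=1):
            bucket = idx.indices.get((l, i))
            if not bucket:
                continue
            window = select_substrings(s_len, l, i, p_i, l_i, tau, k)
            seen: str | None = None
            for w in window:
                sub = s[w : w + l_i]
                if sub == seen:
                    continue
                seen = sub
                ids = bucket.get(sub)
                if ids:
                    for ident in ids:
                        hits.setdefault(ident, set()).add(i)
    out = {ident for ident, segs in hits.items() if len(segs) >= k}
    for a in idx.short:
        if abs(s_len - len(a.sequence)) <= tau:
            out.add(a.id)
    out.discard(query.id)
    return out


def bidirectional_check(query: Amplicon, cand: Amplicon, tau: int, k: int) -> bool:
    """Second filtering stage with the roles of query and candidate swapped.

    Partitions the query into tau+k segments and requires at least k of
    them to occur in the candidate within their admissible windows.  Never
    rejects a pair with true distance <= tau; pairs too short to partition
    pass unconditionally.
    """
    s = query.sequence
    c = cand.sequence
    n = tau + k
    if len(s) < n:
        return True
    if abs(len(s) - len(c)) > tau:
        return False
    part = _partition_cached(len(s), n)
    matched = 0
    for i, (p_i, l_i) in enumerate(part.segments, start=1):
        seg = s[p_i : p_i + l_i]
        for w in select_substrings(len(c), len(s), i, p_i, l_i, tau, k):
            if c[w : w + l_i] == seg:
                matched += 1
                break
        if matched >= k:
            return True
    return False
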