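"""Processing order and length-based pooling of amplicons.

Amplicons are processed most-abundant first (the seed of each new cluster
is the most abundant unassigned amplicon).  Because any alignment of two
sequences whose lengths differ by g contains at least g gap columns, the
distance between them is at least g in both modes; splitting the input
wherever consecutive observed lengths differ by more than the clustering
threshold t therefore yields pools that cannot share similar amplicons
and can be clustered independently.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .io import Amplicon

__all__ = ["AmpliconPool", "sort_amplicons", "build_pools", "priority_key"]


def priority_key(a: Amplicon) -> tuple[int, str, int]:
    """Sort key: abundance descending, then id ascending, then input order."""
    return (-a.abundance, a.id, a.input_rank)


def sort_amplicons(amplicons: Sequence[Amplicon]) -> list[Amplicon]:
    """Stable processing order: by abundance desc, ties by id then input rank."""
    return sorted(amplicons, key=priority_key)


@dataclass
class AmpliconPool:
    """A set of amplicons whose lengths permit mutual similarity at threshold t."""

    members: list[Amplicon]
    length_range: tuple[int, int]

    def __len__(self) -> int:
        return len(self.members)


def build_pools(amplicons: Sequence[Amplicon], t: int) -> list[AmpliconPool]:
    """Split sorted amplicons into pools along length gaps larger than t.

    ``amplicons`` must already be in processing order (``sort_amplicons``);
    each pool preserves that order.  Pools are returned by ascending length.
    """
    if t < 1:
        raise ValueError("t must be >= 1")
    if not amplicons:
        return []
    lengths = sorted({len(a.sequence) for a in amplicons})
    # maximal runs of observed lengths with consecutive gaps <= t
    pool_of_length: dict[int, int] = {}
    runs: list[tuple[int, int]] = []
    run_start = lengths[0]
    prev = lengths[0]
    for l in lengths[1:]:
        if l - prev > t:
            runs.append((run_start, prev))
            run_start = l
        prev = l
    runs.append((run_start, prev))
    for pool_idx, (lo, hi) in enumerate(runs):
        for l in lengths:
            if lo <= l <= hi:
                pool_of_length[l] = pool_idx
    buckets: list[list[Amplicon]] = [[] for _ in runs]
    for a in amplicons:
        buckets[pool_of_length[len(a.sequence)]].append(a)
    return [
        AmpliconPool(members=bucket, length_range=run)
        for bucket, run in zip(buckets, runs)
    ]
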