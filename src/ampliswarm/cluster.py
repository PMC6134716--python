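"""Iterative OTU formation from abundance-ranked seeds.

An OTU is grown from a seed by repeatedly attaching, generation by
generation, every still-unassigned amplicon within the local threshold t
of some current-generation member (a *subseed*).  With the breaking rule
enabled (the default) a link is only allowed when the subseed's abundance
is at least the partner's, so abundances decrease monotonically outward
from the seed and distinct centres of abundance end up in separate OTUs.

The resulting cluster is a rooted acyclic member graph: each member
records its parent, the verified distance of the link, and its generation
(0 for the seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .io import Amplicon
from .pooling import AmpliconPool, priority_key
from .segment_filter import SegmentIndexSet, bidirectional_check, build_indices, candidates
from .verify import (
    DistanceOutcome,
    ScoringFunction,
    bounded_edit_distance,
    bounded_score_distance,
)

__all__ = ["ClusteringConfig", "OtuMember", "Otu", "find_partners", "cluster_pool"]


@dataclass(frozen=True)
class ClusteringConfig:
    """All knobs of the clustering pipeline.

    t is the local clustering threshold; mode selects plain edit distance
    ("edit") or difference counting under an affine scoring function
    ("score"); k is the number of extra segments of the pigeonhole filter
    (t+k segments, >= k matches required).  The fastidious step grafts
    light OTUs (total abundance < boundary b) onto heavy ones through
    links of distance <= t_f; t_f defaults to 2*t and must be >= t+1.
    """

    t: int = 1
    mode: str = "edit"
    delta: ScoringFunction = field(default_factory=ScoringFunction)
    breaking: bool = True
    k: int = 2
    fastidious: bool = False
    t_f: int | None = None
    boundary: int = 3

    def __post_init__(self) -> None:
        if self.t < 1:
            raise ValueError("t must be >= 1")
        if self.mode not in ("edit", "score"):
            raise ValueError("mode must be 'edit' or 'score'")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.boundary < 1:
            raise ValueError("boundary must be >= 1")
        if self.fastidious and self.fastidious_threshold < self.t + 1:
            raise ValueError("fastidious threshold must be >= t + 1")

    @property
    def fastidious_threshold(self) -> int:
        return 2 * self.t if self.t_f is None else self.t_f

    def distance(self, r: str, s: str, tau: int) -> DistanceOutcome:
        if self.mode == "edit":
            return bounded_edit_distance(r, s, tau)
        return bounded_score_distance(r, s, tau, self.delta)


@dataclass
class OtuMember:
    """One amplicon inside an OTU with its link back towards the seed."""

    amplicon: Amplicon
    parent: Amplicon | None  # None for the seed
    distance: int  # verified distance to the parent (0 for the seed)
    generation: int  # 0 for the seed
    grafted: bool = False  # True only for the light amplicon of a grafting link


@dataclass
class Otu:
    """Rooted acyclic member graph of one cluster."""

    seed: Amplicon
    members: list[OtuMember]

    @property
    def weight(self) -> int:
        return sum(m.amplicon.abundance for m in self.members)

    @property
    def amplicons(self) -> list[Amplicon]:
        return [m.amplicon for m in self.members]

    def max_generation(self) -> int:
        return max(m.generation for m in self.members)

    def radius(self) -> int:
        """Maximum cumulative link distance from the seed to any member."""
        cum: dict[str, int] = {self.seed.id: 0}
        radius = 0
        for m in self.members[1:]:
            d = cum[m.parent.id] + m.distance
            cum[m.amplicon.id] = d
            radius = max(radius, d)
        return radius


def find_partners(
    a: Amplicon,
    unswarmed: dict[str, Amplicon],
    idx: SegmentIndexSet,
    cfg: ClusteringConfig,
    tau: int | None = None,
    bidirectional: bool = True,
    breaking: bool | None = None,
) -> list[tuple[Amplicon, int]]:
    """Unassigned partners of ``a`` within the threshold, in priority order.

    Candidates come from the segment filter, pass the optional
    bidirectional re-check and are verified with the bounded distance of
    the configured mode.  With breaking enabled, partners more abundant
    than ``a`` are excluded.  Returns (partner, verified distance) pairs.
    """
    if tau is None:
        tau = cfg.t
    if breaking is None:
        breaking = cfg.breaking
    found: list[tuple[Amplicon, int]] = []
    cand_ids = candidates(a, idx, tau)
    cands = [unswarmed[i] for i in cand_ids if i in unswarmed]
    cands.sort(key=priority_key)
    for b in cands:
        if breaking and b.abundance > a.abundance:
            continue
        if bidirectional and not bidirectional_check(a, b, tau, cfg.k):
            continue
        outcome = cfg.distance(a.sequence, b.sequence, tau)
        if outcome.within:
            found.append((b, outcome.value))
    return found


def cluster_pool(
    pool: AmpliconPool,
    cfg: ClusteringConfig,
    idx: SegmentIndexSet | None = None,
) -> list[Otu]:
    """Cluster one pool into OTUs by iterative breadth-first exploration.

    The pool must be in processing order.  Each OTU starts from the
    highest-priority unassigned amplicon; subseeds of one generation are
    explored in priority order, each claiming its partners for the next
    generation (first claim wins).  OTUs are returned in seed order.
    """
    if idx is None:
        idx = build_indices(pool.members, cfg.t, cfg.k)
    unswarmed: dict[str, Amplicon] = {a.id: a for a in pool.members}
    otus: list[Otu] = []
    for seed in pool.members:
        if seed.id not in unswarmed:
            continue
        del unswarmed[seed.id]
        members = [OtuMember(seed, None, 0, 0)]
        frontier = [seed]
        generation = 0
        while frontier and unswarmed:
            generation += 1
            frontier.sort(key=priority_key)  # subseeds explored in priority order
            next_frontier: list[Amplicon] = []
            for subseed in frontier:
                for partner, dist in find_partners(subseed, unswarmed, idx, cfg):
                    del unswarmed[partner.id]
                    members.append(OtuMember(partner, subseed, dist, generation))
                    next_frontier.append(partner)
            frontier = next_frontier
        otus.append(Otu(seed=seed, members=members))
    return otus
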