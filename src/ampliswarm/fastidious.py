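"""Fastidious refinement: grafting light OTUs onto heavy ones.

Low-abundance clusters are often satellites of an abundant cluster that
the local threshold t could not reach.  The fastidious step postulates a
*virtual linking amplicon* between the two: if an amplicon h of a heavy
OTU (weight >= boundary b) and an amplicon l of a light OTU (weight < b)
are within the fastidious threshold t_f (default 2*t, i.e. one virtual
intermediate at distance t from each side), the whole light OTU is moved
into the heavy one.  The virtual amplicon itself is never materialised.

Only the amplicons of light OTUs are indexed; heavy amplicons query that
index.  Each light amplicon keeps only its most abundant heavy partner,
links are applied in decreasing (heavy, light) abundance order, and a
light OTU is grafted at most once.
"""

from __future__ import annotations

from dataclasses import dataclass

from .cluster import ClusteringConfig, Otu, OtuMember
from .io import Amplicon
from .segment_filter import bidirectional_check, build_indices, candidates

__all__ = [
    "GraftingLink",
    "split_light_heavy",
    "enumerate_grafting_links",
    "sort_links",
    "apply_grafts",
    "refine",
]


@dataclass(frozen=True)
class GraftingLink:
    """A qualifying (heavy amplicon, light amplicon) pair within t_f."""

    heavy: Amplicon
    light: Amplicon
    distance: int


def split_light_heavy(otus: list[Otu], b: int) -> tuple[list[Otu], list[Otu]]:
    """Partition OTUs into (light, heavy) by total abundance vs boundary b."""
    if b < 1:
        raise ValueError("boundary must be >= 1")
    light = [o for o in otus if o.weight < b]
    heavy = [o for o in otus if o.weight >= b]
    return light, heavy


def enumerate_grafting_links(
    heavy_amplicons: list[Amplicon],
    light_otus: list[Otu],
    cfg: ClusteringConfig,
) -> list[GraftingLink]:
    """All grafting links, reduced to one (max-abundance) heavy per light amplicon.

    Light-OTU amplicons are indexed at t_f; heavy amplicons query the
    index and surviving pairs are verified in the configured mode.  Ties
    between equally abundant heavy partners go to the lexicographically
    smaller heavy id.
    """
    t_f = cfg.fastidious_threshold
    light_amps = {a.id: a for o in light_otus for a in o.amplicons}
    idx = build_indices(light_amps.values(), t_f, cfg.k)
    best: dict[str, GraftingLink] = {}
    for h in heavy_amplicons:
        for lid in candidates(h, idx, t_f):
            l = light_amps[lid]
            if not bidirectional_check(h, l, t_f, cfg.k):
                continue
            outcome = cfg.distance(h.sequence, l.sequence, t_f)
            if not outcome.within:
                continue
            link = GraftingLink(heavy=h, light=l, distance=outcome.value)
            cur = best.get(lid)
            if (
                cur is None
                or link.heavy.abundance > cur.heavy.abundance
                or (
                    link.heavy.abundance == cur.heavy.abundance
                    and link.heavy.id < cur.heavy.id
                )
            ):
                best[lid] = link
    return list(best.values())


def sort_links(links: list[GraftingLink]) -> list[GraftingLink]:
    """Order links by heavy abundance desc, light abundance desc, then ids."""
    return sorted(
        links,
        key=lambda g: (
            -g.heavy.abundance,
            -g.light.abundance,
            g.heavy.id,
            g.light.id,
        ),
    )


def apply_grafts(
    links: list[GraftingLink], otus: list[Otu]
) -> tuple[list[Otu], list[GraftingLink]]:
    """Merge light OTUs into heavy ones along valid links.

    Links must already be sorted; a link is valid iff its light OTU has
    not been grafted yet.  On a valid link (h, l) the light OTU is
    re-rooted at l (its internal links are preserved, reoriented towards
    l) and appended to h's OTU: l becomes a child of h at the link
    distance, one generation below h.  Returns the surviving OTUs (in
    their original order) and the applied links.
    """
    otu_of: dict[str, int] = {}
    for i, otu in enumerate(otus):
        for a in otu.amplicons:
            otu_of[a.id] = i
    grafted: set[int] = set()
    applied: list[GraftingLink] = []
    extra_members: dict[int, list[OtuMember]] = {}
    for link in links:
        li = otu_of[link.light.id]
        if li in grafted:
            continue
        grafted.add(li)
        applied.append(link)
        hi = otu_of[link.heavy.id]
        heavy_otu = otus[hi]
        gen_h = next(
            m.generation for m in heavy_otu.members if m.amplicon.id == link.heavy.id
        )
        rerooted = _reroot(otus[li], link.light, link.heavy, link.distance, gen_h + 1)
        extra_members.setdefault(hi, []).extend(rerooted)
    result: list[Otu] = []
    for i, otu in enumerate(otus):
        if i in grafted:
            continue
        if i in extra_members:
            otu = Otu(seed=otu.seed, members=otu.members + extra_members[i])
        result.append(otu)
    return result, applied


def _reroot(
    light: Otu,
    new_root: Amplicon,
    graft_parent: Amplicon,
    graft_distance: int,
    base_generation: int,
) -> list[OtuMember]:
    """Reorient a light OTU's member tree so that ``new_root`` is its root."""
    adjacency: dict[str, list[tuple[Amplicon, int]]] = {
        m.amplicon.id: [] for m in light.members
    }
    for m in light.members:
        if m.parent is not None:
            adjacency[m.parent.id].append((m.amplicon, m.distance))
            adjacency[m.amplicon.id].append((m.parent, m.distance))
    out = [OtuMember(new_root, graft_parent, graft_distance, base_generation, True)]
    visited = {new_root.id}
    frontier = [(new_root, base_generation)]
    while frontier:
        next_frontier: list[tuple[Amplicon, int]] = []
        for node, gen in frontier:
            for child, dist in adjacency[node.id]:
                if child.id in visited:
                    continue
                visited.add(child.id)
                out.append(OtuMember(child, node, dist, gen + 1))
                next_frontier.append((child, gen + 1))
        frontier = next_frontier
    return out


def refine(otus: list[Otu], cfg: ClusteringConfig) -> tuple[list[Otu], list[GraftingLink]]:
    """Run the full fastidious step over the OTUs of all pools."""
    light, heavy = split_light_heavy(otus, cfg.boundary)
    if not light or not heavy:
        return otus, []
    heavy_amps = [a for o in heavy for a in o.amplicons]
    links = sort_links(enumerate_grafting_links(heavy_amps, light, cfg))
    return apply_grafts(links, otus)
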