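"""End-to-end clustering pipeline.

Three phases: preprocessing (ordering and length-based pooling), per-pool
iterative clustering, and the optional fastidious refinement across all
pools.  The high-level entry point is :func:`run_clustering`.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Sequence

from .cluster import ClusteringConfig, Otu, cluster_pool
from .fastidious import GraftingLink, refine
from .io import Amplicon
from .pooling import build_pools, priority_key, sort_amplicons

__all__ = ["ClusteringResult", "RunReport", "run_clustering"]


@dataclass
class RunReport:
    """Per-phase summary of one pipeline run."""

    pool_sizes: list[int] = field(default_factory=list)
    pool_otu_counts: list[int] = field(default_factory=list)
    otus_before_grafting: int = 0
    otus_after_grafting: int = 0
    grafted_otus: int = 0
    phase_seconds: dict[str, float] = field(default_factory=dict)


@dataclass
class ClusteringResult:
    """Final partition of all amplicons into OTUs plus applied grafting links."""

    otus: list[Otu]
    grafts: list[GraftingLink]
    config: ClusteringConfig
    report: RunReport

    @property
    def partition(self) -> list[list[str]]:
        return [[m.amplicon.id for m in otu.members] for otu in self.otus]


def run_clustering(
    amplicons: Sequence[Amplicon], cfg: ClusteringConfig
) -> ClusteringResult:
    """Cluster amplicons: sort, pool, cluster each pool, optionally refine.

    OTUs are returned in global seed-selection order (the priority order
    of their seeds), independent of pooling.
    """
    report = RunReport()
    t0 = time.perf_counter()
    ordered = sort_amplicons(amplicons)
    pools = build_pools(ordered, cfg.t)
    report.pool_sizes = [len(p) for p in pools]
    report.phase_seconds["preprocessing"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    otus: list[Otu] = []
    for pool in pools:
        pool_otus = cluster_pool(pool, cfg)
        report.pool_otu_counts.append(len(pool_otus))
        otus.extend(pool_otus)
    otus.sort(key=lambda o: priority_key(o.seed))
    report.otus_before_grafting = len(otus)
    report.phase_seconds["clustering"] = time.perf_counter() - t0

    grafts: list[GraftingLink] = []
    if cfg.fastidious:
        t0 = time.perf_counter()
        otus, grafts = refine(otus, cfg)
        report.phase_seconds["fastidious"] = time.perf_counter() - t0
    report.otus_after_grafting = len(otus)
    report.grafted_otus = len(grafts)
    return ClusteringResult(otus=otus, grafts=grafts, config=cfg, report=report)
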