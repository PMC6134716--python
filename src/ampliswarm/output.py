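"""The five Swarm-compatible output writers.

All writers take the final :class:`~ampliswarm.pipeline.ClusteringResult`
(post-refinement if the fastidious step ran) and a header dialect for
re-attaching abundance annotations.  Formats:

1. membership — one line per OTU, space-separated member labels in
   attachment order, seed first;
2. statistics — per OTU: unique amplicons, total abundance, seed id, seed
   abundance, number of singleton members, maximum generation, radius
   (maximum cumulative link distance from the seed);
3. seeds FASTA — seed sequence per OTU, annotated with the OTU's total
   abundance;
4. uclust-like table — S/H/C records; H records report the percent
   identity of the member/parent verification, 100*(alen - d)/alen with
   alen the longer of the two lengths;
5. internal structures — one line per link: parent id, child id,
   distance, 1-based OTU number, child generation; grafting links carry a
   trailing ``G`` flag.
"""

from __future__ import annotations

from pathlib import Path
from typing import TextIO

from .io import AbundanceDialect
from .pipeline import ClusteringResult

__all__ = [
    "write_membership",
    "write_statistics",
    "write_seeds_fasta",
    "write_uclust",
    "write_internal_structures",
    "write_outputs",
]


def write_membership(
    result: ClusteringResult, fh: TextIO, dialect: AbundanceDialect
) -> None:
    for otu in result.otus:
        fh.write(
            " ".join(
                dialect.label(m.amplicon.id, m.amplicon.abundance)
                for m in otu.members
            )
            + "\n"
        )


def write_statistics(
    result: ClusteringResult, fh: TextIO, dialect: AbundanceDialect
) -> None:
    for otu in result.otus:
        singletons = sum(1 for m in otu.members if m.amplicon.abundance == 1)
        fh.write(
            f"{len(otu.members)}\t{otu.weight}\t{otu.seed.id}\t"
            f"{otu.seed.abundance}\t{singletons}\t{otu.max_generation()}\t"
            f"{otu.radius()}\n"
        )


def write_seeds_fasta(
    result: ClusteringResult, fh: TextIO, dialect: AbundanceDialect
) -> None:
    for otu in result.otus:
        fh.write(f">{dialect.label(otu.seed.id, otu.weight)}\n{otu.seed.sequence}\n")


def write_uclust(
    result: ClusteringResult, fh: TextIO, dialect: AbundanceDialect
) -> None:
    for number, otu in enumerate(result.otus):
        seed_label = dialect.label(otu.seed.id, otu.seed.abundance)
        fh.write(
            f"S\t{number}\t{len(otu.seed.sequence)}\t*\t*\t*\t*\t*\t{seed_label}\t*\n"
        )
        for m in otu.members[1:]:
            alen = max(len(m.amplicon.sequence), len(m.parent.sequence))
            pid = 100.0 * (alen - m.distance) / alen
            member_label = dialect.label(m.amplicon.id, m.amplicon.abundance)
            parent_label = dialect.label(m.parent.id, m.parent.abundance)
            fh.write(
                f"H\t{number}\t{len(m.amplicon.sequence)}\t{pid:.1f}\t+\t0\t0\t*\t"
                f"{member_label}\t{parent_label}\n"
            )
        fh.write(
            f"C\t{number}\t{len(otu.members)}\t*\t*\t*\t*\t*\t{seed_label}\t*\n"
        )


def write_internal_structures(
    result: ClusteringResult, fh: TextIO, dialect: AbundanceDialect
) -> None:
    for number, otu in enumerate(result.otus, start=1):
        for m in otu.members[1:]:
            line = (
                f"{m.parent.id}\t{m.amplicon.id}\t{m.distance}\t"
                f"{number}\t{m.generation}"
            )
            if m.grafted:
                line += "\tG"
            fh.write(line + "\n")


_WRITERS = {
    "membership": write_membership,
    "statistics": write_statistics,
    "seeds": write_seeds_fasta,
    "uclust": write_uclust,
    "internal": write_internal_structures,
}


def write_outputs(
    result: ClusteringResult,
    requests: dict[str, str | Path],
    dialect: AbundanceDialect | None = None,
) -> None:
    """Write the requested output types, ``requests`` mapping kind to path.

    Kinds: membership, statistics, seeds, uclust, internal.  Requesting
    nothing is an error.
    """
    if dialect is None:
        dialect = AbundanceDialect()
    if not requests:
        raise ValueError(
            "no output requested; choose at least one of " + ", ".join(_WRITERS)
        )
    unknown = set(requests) - set(_WRITERS)
    if unknown:
        raise ValueError(f"unknown output type(s): {sorted(unknown)}")
    for kind, path in requests.items():
        with open(path, "w") as fh:
            _WRITERS[kind](result, fh, dialect)
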