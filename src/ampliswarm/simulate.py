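"""Synthetic mock communities with ground truth.

Mock communities are the standard middle ground between simulated and
natural amplicon data: a set of known species whose reads are sequenced
together.  This generator emulates that design for testing and
benchmarking the clustering pipeline: species centroid sequences drawn
over {A,C,G,T} with a minimum pairwise edit distance, per-species read
counts drawn from a log-normal distribution (few abundant and many rare
species, as fitted from soil communities), and reads derived from their
centroid by random substitutions and indels.  Identical reads are
dereplicated into unique amplicons with summed abundance, and every
unique amplicon keeps its true species label.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .io import AbundanceDialect, Amplicon
from .verify import bounded_edit_distance

__all__ = ["MockCommunity", "generate_community", "write_community"]

_BASES = "ACGT"


@dataclass
class MockCommunity:
    """Species centroids, dereplicated reads and their true labels."""

    species: list[tuple[str, str, int]]  # (label, centroid sequence, total reads)
    amplicons: list[Amplicon]  # unique reads with summed abundance
    labels: dict[str, str]  # amplicon id -> species label
    rng_seed: int

    @property
    def true_partition(self) -> list[list[str]]:
        by_label: dict[str, list[str]] = {}
        for a in self.amplicons:
            by_label.setdefault(self.labels[a.id], []).append(a.id)
        return [by_label[lab] for lab in sorted(by_label)]


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=length))


def _mutate(
    rng: np.random.Generator,
    sequence: str,
    mutation_rate: float,
    indel_fraction: float,
    max_mutations: int | None,
) -> str:
    n_mut = int(rng.binomial(len(sequence), mutation_rate))
    if max_mutations is not None:
        n_mut = min(n_mut, max_mutations)
    seq = list(sequence)
    for _ in range(n_mut):
        pos = int(rng.integers(0, len(seq))) if seq else 0
        if rng.random() < indel_fraction and len(seq) > 1:
            if rng.random() < 0.5:
                seq.insert(pos, _BASES[rng.integers(0, 4)])
            else:
                del seq[pos]
        else:
            old = seq[pos]
            choices = [b for b in _BASES if b != old]
            seq[pos] = choices[rng.integers(0, 3)]
    return "".join(seq)


def generate_community(
    n_species: int = 50,
    mean_log_reads: float = 4.0,
    sigma_log_reads: float = 1.5,
    mutation_rate: float = 0.005,
    indel_fraction: float = 0.1,
    length: int = 250,
    min_separation: int = 20,
    max_mutations: int | None = None,
    rng_seed: int = 0,
) -> MockCommunity:
    """Generate a reproducible mock community.

    Parameters
    ----------
    n_species:
        Number of species centroids.
    mean_log_reads, sigma_log_reads:
        Log-normal parameters of the per-species read count (at least one
        read per species); the default skew yields a few abundant and
        many rare species.
    mutation_rate:
        Per-base probability of an edit in each read (substitution or
        indel), emulating amplification and sequencing errors.
    indel_fraction:
        Proportion of edits that are indels (split evenly between
        insertions and deletions) rather than substitutions.
    length:
        Centroid length in bases.
    min_separation:
        Minimum pairwise edit distance between centroids; drawing is
        retried a bounded number of times before aborting.
    max_mutations:
        Optional hard cap on the number of edits per read.
    rng_seed:
        Seed of the single random generator; the output is a pure
        function of the arguments.
    """
    if n_species < 1:
        raise ValueError("n_species must be >= 1")
    if not (0.0 <= mutation_rate <= 1.0 and 0.0 <= indel_fraction <= 1.0):
        raise ValueError("probabilities must lie in [0, 1]")
    rng = np.random.default_rng(rng_seed)
    centroids: list[str] = []
    attempts = 0
    while len(centroids) < n_species:
        attempts += 1
        if attempts > 200 * n_species:
            raise RuntimeError(
                f"could not draw {n_species} centroids with pairwise "
                f"edit distance >= {min_separation}"
            )
        cand = _random_sequence(rng, length)
        if all(
            not bounded_edit_distance(cand, c, min_separation - 1).within
            for c in centroids
        ):
            centroids.append(cand)
    read_counts = np.maximum(
        1, np.rint(rng.lognormal(mean_log_reads, sigma_log_reads, n_species))
    ).astype(int)

    species: list[tuple[str, str, int]] = []
    seq_abundance: dict[str, int] = {}
    seq_labels: dict[str, dict[str, int]] = {}
    for si in range(n_species):
        label = f"species{si + 1:03d}"
        centroid = centroids[si]
        total = int(read_counts[si])
        species.append((label, centroid, total))
        for _ in range(total):
            read = _mutate(rng, centroid, mutation_rate, indel_fraction, max_mutations)
            seq_abundance[read] = seq_abundance.get(read, 0) + 1
            counts = seq_labels.setdefault(read, {})
            counts[label] = counts.get(label, 0) + 1

    amplicons: list[Amplicon] = []
    labels: dict[str, str] = {}
    for rank, (seq, abundance) in enumerate(seq_abundance.items()):
        ident = f"a{rank + 1:06d}"
        amplicons.append(Amplicon(ident, seq, abundance, rank))
        counts = seq_labels[seq]
        labels[ident] = min(counts, key=lambda lab: (-counts[lab], lab))
    return MockCommunity(species, amplicons, labels, rng_seed)


def write_community(
    community: MockCommunity,
    fasta_path: str | Path,
    truth_path: str | Path | None = None,
    dialect: AbundanceDialect | None = None,
) -> None:
    """Write the community FASTA (abundance-annotated) and ground-truth TSV."""
    if dialect is None:
        dialect = AbundanceDialect()
    with open(fasta_path, "w") as fh:
        for a in community.amplicons:
            fh.write(f">{dialect.label(a.id, a.abundance)}\n{a.sequence}\n")
    if truth_path is not None:
        with open(truth_path, "w") as fh:
            for a in community.amplicons:
                fh.write(f"{a.id}\t{community.labels[a.id]}\n")
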