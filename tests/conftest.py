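from __future__ import annotations

import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from ampliswarm.cluster import Otu
from ampliswarm.io import Amplicon


def make_amplicons(spec: list[tuple[str, str, int]]) -> list[Amplicon]:
    """Build amplicons from (id, sequence, abundance) triples in input order."""
    return [Amplicon(i, s, a, rank) for rank, (i, s, a) in enumerate(spec)]


def otu_tuples(otu: Otu) -> list[tuple[str, str | None, int, int]]:
    """Comparable (id, parent id, distance, generation) view of an OTU."""
    return [
        (m.amplicon.id, m.parent.id if m.parent else None, m.distance, m.generation)
        for m in otu.members
    ]


@pytest.fixture
def small_pool():
    """Five amplicons forming two OTUs at t=1 with breaking enabled."""
    return make_amplicons(
        [
            ("A", "AAAA", 10),
            ("B", "AAAT", 5),
            ("C", "AATT", 3),
            ("D", "GGGG", 8),
            ("E", "GGGC", 2),
        ]
    )
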