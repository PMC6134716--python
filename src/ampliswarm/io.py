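"""Reading and preparing abundance-annotated amplicon FASTA files.

Amplicon clustering tools in the Swarm family expect dereplicated input:
every record is a unique sequence whose header carries the number of reads
it represents, either as a trailing ``label_N`` (configurable separator) or
as a USEARCH-style ``;size=N`` annotation.  This module parses both
dialects, applies length/alphabet filtering and (re-)dereplication, and
provides the label formatting used by all output writers.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

__all__ = [
    "Amplicon",
    "AbundanceDialect",
    "FastaError",
    "parse_fasta",
    "filter_amplicons",
    "dereplicate",
]

DNA_ALPHABET = frozenset("ACGT")

_USEARCH_SIZE_RE = re.compile(r";size=(-?\d+);?\s*$")


class FastaError(ValueError):
    """Raised for malformed FASTA input or abundance annotations."""


@dataclass(frozen=True)
class AbundanceDialect:
    """How read abundances are encoded in FASTA headers.

    ``kind`` is ``"separator"`` (trailing ``<sep><int>``, Swarm's default
    with ``sep="_"``) or ``"usearch"`` (``;size=<int>`` anywhere at the end
    of the header, optionally followed by ``;``).
    """

    kind: str = "separator"
    separator: str = "_"

    def __post_init__(self) -> None:
        if self.kind not in ("separator", "usearch"):
            raise ValueError(f"unknown abundance dialect {self.kind!r}")
        if self.kind == "separator" and len(self.separator) != 1:
            raise ValueError("separator must be a single character")

    def split(self, header: str) -> tuple[str, int | None]:
        """Split a header into (identifier, abundance or None)."""
        if self.kind == "usearch":
            m = _USEARCH_SIZE_RE.search(header)
            if m is None:
                return header, None
            return header[: m.start()], int(m.group(1))
        head, sep, tail = header.rpartition(self.separator)
        if sep and re.fullmatch(r"-?\d+", tail) and head:
            return head, int(tail)
        return header, None

    def label(self, identifier: str, abundance: int) -> str:
        """Re-attach an abundance annotation to an identifier."""
        if self.kind == "usearch":
            return f"{identifier};size={abundance}"
        return f"{identifier}{self.separator}{abundance}"


@dataclass(frozen=True)
class Amplicon:
    """A dereplicated sequence with its read count.

    Attributes
    ----------
    id:
        Header up to (excluding) the abundance annotation.
    sequence:
        Upper-case nucleotide sequence.
    abundance:
        Number of reads represented by this amplicon (>= 1).
    input_rank:
        0-based order of first appearance in the input.
    """

    id: str
    sequence: str
    abundance: int
    input_rank: int = 0

    def __post_init__(self) -> None:
        if self.abundance < 1:
            raise ValueError(
                f"amplicon {self.id!r}: abundance must be >= 1, got {self.abundance}"
            )
        if not self.sequence:
            raise ValueError(f"amplicon {self.id!r}: empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)


def parse_fasta(
    path: str | Path,
    dialect: AbundanceDialect | None = None,
    strict: bool = True,
) -> list[Amplicon]:
    """Read an abundance-annotated FASTA file into a list of amplicons.

    Multi-line sequences are concatenated and upper-cased; ``input_rank``
    follows file order.  In strict mode (the default) a record without a
    parseable positive integer abundance aborts with an error naming the
    record; non-strict mode defaults missing annotations to abundance 1.
    """
    if dialect is None:
        dialect = AbundanceDialect()
    amplicons: list[Amplicon] = []
    for rank, record in enumerate(SeqIO.parse(str(path), "fasta")):
        header = record.description or record.id
        identifier, abundance = dialect.split(header)
        if abundance is None:
            if strict:
                raise FastaError(
                    f"record {header!r}: missing abundance annotation "
                    f"(dialect {dialect.kind!r})"
                )
            abundance = 1
        elif abundance < 1:
            raise FastaError(
                f"record {header!r}: abundance must be a positive integer, "
                f"got {abundance}"
            )
        sequence = str(record.seq).upper()
        if not sequence:
            raise FastaError(f"record {header!r}: empty sequence")
        amplicons.append(Amplicon(identifier, sequence, abundance, rank))
    return amplicons


def filter_amplicons(
    amplicons: Sequence[Amplicon],
    min_len: int = 1,
    max_len: int | None = None,
    alphabet: Iterable[str] = DNA_ALPHABET,
) -> list[Amplicon]:
    """Keep amplicons within the length bounds and over the alphabet.

    Reads containing ambiguous bases (e.g. IUPAC ``N``) are removed by the
    default alphabet.  Relative order is preserved; an empty result is
    allowed.
    """
    allowed = frozenset(alphabet)
    if not allowed:
        raise ValueError("alphabet must be non-empty")
    if max_len is not None and min_len > max_len:
        raise ValueError("min_len must be <= max_len")
    kept = []
    for a in amplicons:
        n = len(a.sequence)
        if n < min_len or (max_len is not None and n > max_len):
            continue
        if not allowed.issuperset(a.sequence):
            continue
        kept.append(a)
    return kept


def dereplicate(amplicons: Sequence[Amplicon]) -> list[Amplicon]:
    """Merge amplicons with identical sequences, summing abundances.

    The representative (id and input_rank) of each merged group is the
    member with the highest abundance, ties broken by smallest input_rank.
    Output order follows the first appearance of each distinct sequence.
    """
    groups: dict[str, list[Amplicon]] = {}
    for a in amplicons:
        groups.setdefault(a.sequence, []).append(a)
    merged = []
    for members in groups.values():  # dict preserves first-appearance order
        rep = max(members, key=lambda a: (a.abundance, -a.input_rank))
        merged.append(replace(rep, abundance=sum(a.abundance for a in members)))
    return merged
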