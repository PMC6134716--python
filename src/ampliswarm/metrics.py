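"""Pair-counting quality metrics for clusterings against a ground truth.

Recall measures the proportion of amplicon pairs from the same species
that end up in the same OTU; precision the proportion of co-clustered
pairs that share a species; the adjusted Rand index (Hubert-Arabie)
summarises both, correcting for chance agreement.

Metrics are computed over unique amplicons, unweighted by abundance; an
abundance-weighted variant (each amplicon counted with multiplicity equal
to its read count) is available behind ``weights``.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

__all__ = ["pair_counting_metrics", "adjusted_rand"]


def _contingency(
    predicted: Sequence[Iterable[str]],
    truth: Mapping[str, str],
    weights: Mapping[str, int] | None = None,
) -> tuple[dict[tuple[int, str], int], dict[int, int], dict[str, int], int]:
    cells: dict[tuple[int, str], int] = {}
    row: dict[int, int] = {}
    col: dict[str, int] = {}
    total = 0
    seen: set[str] = set()
    for ci, cluster in enumerate(predicted):
        for ident in cluster:
            if ident not in truth:
                raise KeyError(f"amplicon {ident!r} has no ground-truth label")
            if ident in seen:
                raise ValueError(f"amplicon {ident!r} appears in several clusters")
            seen.add(ident)
            w = 1 if weights is None else weights[ident]
            label = truth[ident]
            cells[(ci, label)] = cells.get((ci, label), 0) + w
            row[ci] = row.get(ci, 0) + w
            col[label] = col.get(label, 0) + w
            total += w
    missing = set(truth) - seen
    if missing:
        raise ValueError(f"{len(missing)} labelled amplicons missing from the clustering")
    return cells, row, col, total


def _c2(n: int) -> int:
    return n * (n - 1) // 2


def pair_counting_metrics(
    predicted: Sequence[Iterable[str]],
    truth: Mapping[str, str],
    weights: Mapping[str, int] | None = None,
) -> tuple[float, float]:
    """(precision, recall) over unordered amplicon pairs.

    TP are pairs both co-clustered and co-labelled; precision divides by
    the co-clustered pairs, recall by the co-labelled pairs.  An empty
    denominator yields 1.0 (nothing asserted, nothing wrong).
    """
    cells, row, col, _ = _contingency(predicted, truth, weights)
    tp = sum(_c2(n) for n in cells.values())
    co_clustered = sum(_c2(n) for n in row.values())
    co_labelled = sum(_c2(n) for n in col.values())
    precision = tp / co_clustered if co_clustered else 1.0
    recall = tp / co_labelled if co_labelled else 1.0
    return precision, recall


def adjusted_rand(
    predicted: Sequence[Iterable[str]],
    truth: Mapping[str, str],
    weights: Mapping[str, int] | None = None,
) -> float:
    """Hubert-Arabie adjusted Rand index between clustering and labels.

    1.0 for identical partitions, ~0 for chance-level agreement.  The
    degenerate case with zero denominator (e.g. both partitions all
    singletons) returns 1.0.
    """
    cells, row, col, total = _contingency(predicted, truth, weights)
    index = sum(_c2(n) for n in cells.values())
    sum_row = sum(_c2(n) for n in row.values())
    sum_col = sum(_c2(n) for n in col.values())
    pairs = _c2(total)
    expected = sum_row * sum_col / pairs if pairs else 0.0
    maximum = (sum_row + sum_col) / 2
    if maximum == expected:
        return 1.0
    return (index - expected) / (maximum - expected)
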