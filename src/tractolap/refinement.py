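"""Merging per-example candidate segmentations into one final tract.

Each example tract yields a candidate set of target streamlines with per-pair
selection costs. The union of the candidates is ranked by (1) frequency — how
many examples selected the streamline, descending; (2) accumulated selection
cost, ascending (a cheaper match is a more reliable one); (3) target index,
ascending, for total determinism. The final segmentation keeps the top k-hat
streamlines, where k-hat is the median of the per-example segmentation sizes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import Tract, Tractogram

logger = logging.getLogger(__name__)

__all__ = [
    "ExampleSegmentation",
    "RankedCandidates",
    "SegmentationResult",
    "rank_candidates",
    "median_size",
    "merge_examples",
]


@dataclass(frozen=True)
class ExampleSegmentation:
    """One example's candidate segmentation: selected target indices and the
    MAM cost at which each was selected. A target index selected more than
    once within one example (possible only for the greedy NN mode) appears
    once, with the costs of all its selections summed."""

    indices: tuple[int, ...]
    costs: tuple[float, ...]

    def __post_init__(self):
        if len(self.indices) != len(self.costs):
            raise ValueError("indices and costs must have equal length")
        if len(set(self.indices)) != len(self.indices):
            raise ValueError("indices must be unique; sum duplicate costs first")

    @classmethod
    def from_pairs(cls, pairs: dict[int, int], per_pair_cost: dict[int, float]):
        """Build from a row->column mapping with per-row costs, merging rows
        that selected the same column."""
        acc: dict[int, float] = {}
        for row, col in pairs.items():
            acc[col] = acc.get(col, 0.0) + float(per_pair_cost[row])
        idx = tuple(sorted(acc))
        return cls(indices=idx, costs=tuple(acc[i] for i in idx))

    def __len__(self) -> int:
        return len(self.indices)


@dataclass(frozen=True)
class RankedCandidates:
    """Total ordering of the union of candidate target streamlines."""

    indices: np.ndarray  # target streamline index, in rank order
    frequency: np.ndarray  # examples that selected it
    total_selection_cost: np.ndarray  # summed selection cost, mm

    def __len__(self) -> int:
        return len(self.indices)


@dataclass
class SegmentationResult:
    """Final merged segmentation and the evidence behind it."""

    tract: Tract
    k_hat: int
    ranking: RankedCandidates
    per_example_sizes: list[int]


def rank_candidates(per_example: list[ExampleSegmentation]) -> RankedCandidates:
    """Rank the union of per-example candidates.

    Ordering: frequency descending, then total selection cost ascending, then
    target index ascending. Invariant to the order of the examples.
    """
    if len(per_example) < 1:
        raise ValueError("need at least one example segmentation")
    freq: dict[int, int] = {}
    cost: dict[int, float] = {}
    for seg in per_example:
        for idx, c in zip(seg.indices, seg.costs):
            freq[idx] = freq.get(idx, 0) + 1
            cost[idx] = cost.get(idx, 0.0) + float(c)
    idx = np.array(sorted(freq), dtype=np.intp)
    f = np.array([freq[i] for i in idx])
    tc = np.array([cost[i] for i in idx])
    order = np.lexsort((idx, tc, -f))  # primary key last in lexsort
    return RankedCandidates(
        indices=idx[order], frequency=f[order], total_selection_cost=tc[order]
    )


def median_size(per_example_sizes) -> int:
    """Integer median of the per-example segmentation sizes.

    Odd N: the middle order statistic. Even N: floor of the mean of the two
    middle order statistics (an integer size is required).
    """
    sizes = sorted(int(s) for s in per_example_sizes)
    if not sizes:
        raise ValueError("per_example_sizes is empty")
    if any(s <= 0 for s in sizes):
        raise ValueError("sizes must be positive")
    n = len(sizes)
    if n % 2:
        return sizes[n // 2]
    return (sizes[n // 2 - 1] + sizes[n // 2]) // 2


def merge_examples(
    per_example: list[ExampleSegmentation],
    target: Tractogram,
    label: str = "",
) -> SegmentationResult:
    """Merge per-example segmentations into the final tract.

    The final tract is the top k-hat of the ranking, with k-hat the median of
    the per-example sizes; if k-hat exceeds the union size the whole union is
    taken (with a warning).
    """
    ranking = rank_candidates(per_example)
    sizes = [len(seg) for seg in per_example]
    k_hat = median_size(sizes)
    if k_hat > len(ranking):
        logger.warning(
            "median size %d exceeds candidate union of %d; taking the union",
            k_hat,
            len(ranking),
        )
    chosen = ranking.indices[: min(k_hat, len(ranking))]
    tract = Tract(parent=target, indices=tuple(int(i) for i in chosen), label=label)
    return SegmentationResult(
        tract=tract, k_hat=k_hat, ranking=ranking, per_example_sizes=sizes
    )


def ranking_table(ranking: RankedCandidates, k_hat: int) -> str:
    """Tab-separated export: index, frequency, total_selection_cost, rank,
    selected(0/1)."""
    lines = ["index\tfrequency\ttotal_selection_cost\trank\tselected"]
    for rank, (i, f, c) in enumerate(
        zip(ranking.indices, ranking.frequency, ranking.total_selection_cost)
    ):
        sel = 1 if rank < k_hat else 0
        lines.append(f"{int(i)}\t{int(f)}\t{float(c):.6f}\t{rank}\t{sel}")
    return "\n".join(lines) + "\n"
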