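"""Streamline correspondence between an example tract and a target tractogram.

Two strategies are provided. The nearest-neighbor baseline maps each example
streamline independently to its closest target streamline in embedding space
(greedy, duplicates allowed). The assignment strategy instead solves a
rectangular linear assignment problem (RLAP): minimize the total MAM cost of a
one-to-one matching between the k example streamlines and k of the M target
streamlines. The one-to-one constraint is what lets the matching follow a
systematic residual displacement between subjects that defeats the greedy rule.

The cost matrix is sparsified before solving: candidate columns are the union
of each example streamline's nearest neighbors in embedding space, and exact
MAM distances are computed only for (row, union-column) pairs.

The solver is a rectangular Jonker–Volgenant shortest-augmenting-path
implementation with an exact-optimality contract, plus a lexicographic
refinement pass so that among cost-tied optima the returned assignment is the
one whose (row, column) pair list is lexicographically smallest.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import Tract, Tractogram, mam_distance_matrix
from .embedding import (
    DissimilarityEmbedding,
    NeighborIndex,
    PrototypeSet,
    embed,
    knn_query,
    sff_select_prototypes,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ReducedCostMatrix",
    "Assignment",
    "nn_correspondence",
    "build_reduced_cost_matrix",
    "solve_rlap",
    "segment_from_single_example",
]

UNAVAILABLE = np.inf


@dataclass
class ReducedCostMatrix:
    """Sparsified cost matrix: rows are example streamlines, columns the
    candidate target streamlines (the neighbor union). Entries are MAM
    distances in mm; unavailable pairs are +inf."""

    row_ids: np.ndarray
    col_ids: np.ndarray
    costs: np.ndarray

    def __post_init__(self):
        self.row_ids = np.asarray(self.row_ids, dtype=np.intp)
        self.col_ids = np.asarray(self.col_ids, dtype=np.intp)
        self.costs = np.asarray(self.costs, dtype=np.float64)
        k, m = self.costs.shape
        if k != self.row_ids.size or m != self.col_ids.size:
            raise ValueError("costs shape inconsistent with row/col ids")
        if len(set(self.col_ids.tolist())) != m:
            raise ValueError("col_ids must be distinct")
        if k > m:
            raise ValueError(f"infeasible: {k} rows but only {m} columns")
        finite = np.isfinite(self.costs)
        if np.any(self.costs[finite] < 0):
            raise ValueError("costs must be non-negative")
        starved = np.where(~finite.any(axis=1))[0]
        if starved.size:
            raise ValueError(
                f"rows with no available column: {self.row_ids[starved].tolist()}"
            )

    @property
    def k(self) -> int:
        return self.costs.shape[0]


@dataclass
class Assignment:
    """One-to-one correspondence: row id -> column id with per-pair MAM cost."""

    pairs: dict[int, int]
    per_pair_cost: dict[int, float]
    total_cost: float

    def __post_init__(self):
        cols = list(self.pairs.values())
        if len(set(cols)) != len(cols):
            raise ValueError("assignment is not injective")

    @property
    def selected_columns(self) -> list[int]:
        return sorted(set(self.pairs.values()))


def nn_correspondence(
    t_A: Tract | list,
    index: NeighborIndex,
    emb_A: DissimilarityEmbedding,
    target: Tractogram,
    mam_rerank: int = 0,
):
    """Greedy nearest-neighbor correspondence (the NN_DR_MAM baseline).

    Each example streamline maps to the target streamline nearest in embedding
    space; duplicates are allowed (no one-to-one constraint). The recorded
    per-pair cost is the exact MAM distance of the matched pair.

    ``mam_rerank > 0`` optionally re-ranks that many embedding-space candidates
    by exact MAM before picking the closest (off by default: the plain
    procedure takes the k-d tree's top hit directly).
    """
    streamlines = t_A.streamlines if isinstance(t_A, Tract) else list(t_A)
    if len(streamlines) == 0:
        raise ValueError("example tract is empty")
    if mam_rerank > 0:
        kq = min(mam_rerank, index.n)
        cand_idx, _ = knn_query(index, emb_A.vectors, kq)
        matched = np.empty(len(streamlines), dtype=np.intp)
        costs = np.empty(len(streamlines))
        for i, s in enumerate(streamlines):
            d = mam_distance_matrix([s], target.subset(cand_idx[i]))[0]
            j = int(np.argmin(d))
            matched[i] = cand_idx[i][j]
            costs[i] = d[j]
    else:
        cand_idx, _ = knn_query(index, emb_A.vectors, 1)
        matched = cand_idx[:, 0]
        costs = np.array(
            [
                mam_distance_matrix([s], [target[j]])[0, 0]
                for s, j in zip(streamlines, matched)
            ]
        )
    pairs = {int(i): int(j) for i, j in enumerate(matched)}
    per_cost = {int(i): float(c) for i, c in enumerate(costs)}
    return pairs, per_cost


def build_reduced_cost_matrix(
    t_A: Tract | list,
    target: Tractogram,
    emb_A: DissimilarityEmbedding,
    index: NeighborIndex,
    n_neighbors: int = 500,
) -> ReducedCostMatrix:
    """Sparsify the full k x M cost matrix to the neighbor union.

    Candidate columns are the union, over example streamlines, of their
    ``n_neighbors`` nearest target streamlines in embedding space; exact MAM
    distances are then computed for every (row, union-column) pair.
    ``n_neighbors`` greater than M is clamped with a warning.
    """
    streamlines = t_A.streamlines if isinstance(t_A, Tract) else list(t_A)
    k = len(streamlines)
    if k == 0:
        raise ValueError("example tract is empty")
    if n_neighbors < 1:
        raise ValueError("n_neighbors must be >= 1")
    M = index.n
    if n_neighbors > M:
        logger.warning("n_neighbors=%d exceeds M=%d; clamped", n_neighbors, M)
        n_neighbors = M
    cand_idx, _ = knn_query(index, emb_A.vectors, n_neighbors)
    col_ids = np.unique(cand_idx)
    if col_ids.size < k:
        raise ValueError(
            f"neighbor union has {col_ids.size} columns < {k} rows; "
            "increase n_neighbors"
        )
    costs = mam_distance_matrix(streamlines, target.subset(col_ids))
    return ReducedCostMatrix(
        row_ids=np.arange(k), col_ids=col_ids, costs=costs
    )


def _jv_min_cost(cost: np.ndarray):
    """Rectangular Jonker–Volgenant via successive shortest augmenting paths.

    ``cost`` is a dense (k, m) matrix with +inf for unavailable pairs, k <= m.
    Returns (col4row, total). Exact; raises on infeasibility.
    """
    nr, nc = cost.shape
    u = np.zeros(nr)
    v = np.zeros(nc)
    col4row = np.full(nr, -1, dtype=np.intp)
    row4col = np.full(nc, -1, dtype=np.intp)
    path = np.full(nc, -1, dtype=np.intp)

    for cur_row in range(nr):
        min_val = 0.0
        i = cur_row
        scanned_rows = np.zeros(nr, dtype=bool)
        scanned_cols = np.zeros(nc, dtype=bool)
        shortest = np.full(nc, np.inf)
        sink = -1
        while sink == -1:  # Dijkstra over alternating paths

            scanned_rows[i] = True
            r = min_val + cost[i] - u[i] - v
            better = ~scanned_cols & (r < shortest)
            shortest[better] = r[better]
            path[better] = i
            masked = np.where(scanned_cols, np.inf, shortest)
            j = int(np.argmin(masked))
            min_val = masked[j]
            if not np.isfinite(min_val):
                raise ValueError(
                    f"assignment infeasible: row {cur_row} cannot be matched"
                )
            scanned_cols[j] = True
            if row4col[j] == -1:
                sink = j
            else:
                i = int(row4col[j])
        # dual update
        u[cur_row] += min_val
        other = scanned_rows.copy()
        other[cur_row] = False
        if other.any():
            rows = np.where(other)[0]
            u[rows] += min_val - shortest[col4row[rows]]
        sc = np.where(scanned_cols)[0]
        v[sc] -= min_val - shortest[sc]
        # augment along the alternating path
        j = sink
        while True:
            i = int(path[j])
            row4col[j] = i
            col4row[i], j = j, col4row[i]
            if i == cur_row:
                break

    total = float(cost[np.arange(nr), col4row].sum())
    return col4row, total, u, v


def _lex_refine(
    cost: np.ndarray,
    col4row: np.ndarray,
    total: float,
    u: np.ndarray,
    v: np.ndarray,
) -> np.ndarray:
    """Among cost-tied optima pick the lexicographically smallest pair list.

    The duals returned by the shortest-augmenting-path solve are optimal LP
    duals (unmatched columns retain v = 0), so by complementary slackness every
    optimal assignment uses only dual-tight edges. Sequentially, for each row
    in order, commit the smallest tight column that still allows completing the
    remaining rows at the optimal total; the incumbent column always does, so
    rows whose incumbent is already the smallest tight candidate cost nothing.
    """
    nr, nc = cost.shape
    tol = 1e-9 * max(1.0, abs(total))
    reduced = cost - u[:, None] - v[None, :]
    remaining_cols = np.ones(nc, dtype=bool)
    result = np.array(col4row, dtype=np.intp)
    target = total
    for i in range(nr):
        sub_rows = np.arange(i + 1, nr)
        tight = np.where(remaining_cols & (reduced[i] <= tol))[0]
        for c in tight:
            if c == result[i]:
                break  # incumbent: already optimal, nothing smaller worked
            rem = remaining_cols.copy()
            rem[c] = False
            rem_ids = np.where(rem)[0]
            if sub_rows.size:
                sub = cost[np.ix_(sub_rows, rem_ids)]
                lb = cost[i, c] + sub.min(axis=1).sum()
                if not np.isfinite(lb) or lb > target + tol:
                    continue
                try:
                    sub_assign, sub_total, _, _ = _jv_min_cost(sub)
                except ValueError:
                    continue
                if cost[i, c] + sub_total <= target + tol:
                    result[i] = c
                    result[sub_rows] = rem_ids[sub_assign]
                    break
            elif cost[i, c] <= target + tol:
                result[i] = c
                break
        remaining_cols[result[i]] = False
        target -= cost[i, result[i]]
    return result


def solve_rlap(C: ReducedCostMatrix) -> Assignment:
    """Exact minimum-total-cost one-to-one assignment of rows to columns.

    Among equal-cost optima the assignment minimal in lexicographic
    (row_id, col_id) order of its pair list is returned, so the result is a
    pure function of the cost matrix.
    """
    cost = C.costs
    col4row, total, u, v = _jv_min_cost(cost)
    col4row = _lex_refine(cost, col4row, total, u, v)
    per_cost = cost[np.arange(C.k), col4row]
    pairs = {
        int(C.row_ids[i]): int(C.col_ids[col4row[i]]) for i in range(C.k)
    }
    per_pair = {int(C.row_ids[i]): float(per_cost[i]) for i in range(C.k)}
    return Assignment(
        pairs=pairs, per_pair_cost=per_pair, total_cost=float(per_cost.sum())
    )


def segment_from_single_example(
    t_A: Tract | list,
    target: Tractogram,
    mode: str = "lap",
    n_neighbors: int = 500,
    n_prototypes: int = 40,
    seed: int = 0,
    subset_factor: int = 25,
    mam_rerank: int = 0,
    prototypes: PrototypeSet | None = None,
    target_embedding: DissimilarityEmbedding | None = None,
    index: NeighborIndex | None = None,
):
    """Segment the target's homolog of one example tract.

    Composes prototype selection (from the target), embedding, cost-matrix
    sparsification and the RLAP solve (``mode="lap"``), or the greedy
    embedding-space baseline (``mode="nn"``). Precomputed prototypes /
    embedding / index may be passed to amortize work across examples.

    Returns ``(indices, per_pair_cost_by_row, total_cost)`` where ``indices``
    is the sorted set of selected target streamline indices (duplicates
    removed in NN mode, so its size may be below the example size there).
    """
    if mode not in ("lap", "nn"):
        raise ValueError(f"mode must be 'lap' or 'nn', got {mode!r}")
    if prototypes is None:
        p = min(n_prototypes, len(target))
        prototypes = sff_select_prototypes(
            target, p, subset_factor=subset_factor, seed=seed
        )
    if target_embedding is None:
        target_embedding = embed(target, prototypes)
    if index is None:
        index = NeighborIndex(target_embedding)
    emb_A = embed(t_A, prototypes)
    if mode == "nn":
        pairs, per_cost = nn_correspondence(
            t_A, index, emb_A, target, mam_rerank=mam_rerank
        )
        total = float(sum(per_cost.values()))
    else:
        C = build_reduced_cost_matrix(
            t_A, target, emb_A, index, n_neighbors=n_neighbors
        )
        assignment = solve_rlap(C)
        pairs, per_cost = assignment.pairs, assignment.per_pair_cost
        total = assignment.total_cost
    indices = tuple(sorted(set(pairs.values())))
    return pairs, per_cost, total, indices
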