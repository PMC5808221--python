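"""Dissimilarity-representation embedding of streamlines.

Each streamline is represented by its vector of MAM distances to a small fixed
set of prototype streamlines, giving a Euclidean embedding of an arbitrary
tractogram in R^p. Prototypes are chosen with the Subset Farthest First (SFF)
heuristic: farthest-first traversal restricted to a random subset of the
tractogram, which is what keeps selection at seconds scale on large data.
Nearest-neighbor queries in the embedding run on a k-d tree and are exact: the
results are identical to exhaustive Euclidean search, with ties broken by
ascending index.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .core import Streamline, Tract, Tractogram, mam_distance_matrix

logger = logging.getLogger(__name__)

__all__ = [
    "PrototypeSet",
    "DissimilarityEmbedding",
    "NeighborIndex",
    "sff_select_prototypes",
    "embed",
    "knn_query",
]


@dataclass(frozen=True)
class PrototypeSet:
    """Ordered prototype streamlines: indices into the source tractogram plus
    copies of the polylines themselves, so a second subject's streamlines can
    be embedded against the same prototypes."""

    indices: tuple[int, ...]
    streamlines: tuple[Streamline, ...]

    def __post_init__(self):
        if len(set(self.indices)) != len(self.indices):
            raise ValueError("prototype indices must be distinct")
        if len(self.indices) != len(self.streamlines):
            raise ValueError("indices and streamlines length mismatch")

    @property
    def p(self) -> int:
        return len(self.indices)


@dataclass(frozen=True)
class DissimilarityEmbedding:
    """M x p matrix of streamline-to-prototype MAM distances (mm)."""

    vectors: np.ndarray
    prototypes: PrototypeSet

    def __post_init__(self):
        v = np.asarray(self.vectors, dtype=np.float64)
        if v.ndim != 2 or v.shape[1] != self.prototypes.p:
            raise ValueError(
                f"vectors must be (M, {self.prototypes.p}), got {v.shape}"
            )
        object.__setattr__(self, "vectors", v)

    @property
    def n(self) -> int:
        return self.vectors.shape[0]


def sff_select_prototypes(
    T: Tractogram,
    p: int,
    subset_factor: int = 25,
    seed: int = 0,
) -> PrototypeSet:
    """Select ``p`` prototypes from ``T`` with Subset Farthest First.

    A uniform random subset of size ``min(M, subset_factor * p)`` is drawn with
    the seeded generator; the first prototype is a random subset member and each
    subsequent one is the subset member with maximal minimum MAM distance to
    those already selected. Ties break by ascending streamline index. Fully
    deterministic given ``seed``.
    """
    M = len(T)
    if not 1 <= p <= M:
        raise ValueError(f"p must be in [1, {M}], got {p}")
    if subset_factor < 1:
        raise ValueError("subset_factor must be >= 1")
    rng = np.random.default_rng(seed)
    n_sub = min(M, subset_factor * p)
    subset = np.sort(rng.choice(M, size=n_sub, replace=False))
    sub_streamlines = T.subset(subset)

    first = int(rng.integers(n_sub))
    selected = [first]
    # min distance of every subset member to the selected set, updated greedily
    min_d = mam_distance_matrix(sub_streamlines, [sub_streamlines[first]])[:, 0]
    while len(selected) < p:
        min_d[selected] = -np.inf  # never re-select
        nxt = int(np.argmax(min_d))  # ties -> lowest subset position = lowest index
        selected.append(nxt)
        d_new = mam_distance_matrix(sub_streamlines, [sub_streamlines[nxt]])[:, 0]
        np.minimum(min_d, d_new, out=min_d)

    idx = tuple(int(subset[i]) for i in selected)
    return PrototypeSet(
        indices=idx, streamlines=tuple(T[i].copy() for i in idx)
    )


def embed(collection, prototypes: PrototypeSet) -> DissimilarityEmbedding:
    """Embed a Tractogram, Tract or list of streamlines against ``prototypes``.

    Entry (i, j) of the result is the MAM distance between streamline i of the
    collection and prototype j; prototypes may come from a different subject's
    tractogram (cross-subject embeddings share prototypes).
    """
    if isinstance(collection, Tractogram):
        streamlines = collection.streamlines
    elif isinstance(collection, Tract):
        streamlines = collection.streamlines
    else:
        streamlines = list(collection)
    if len(streamlines) == 0:
        raise ValueError("cannot embed an empty streamline collection")
    vectors = mam_distance_matrix(streamlines, list(prototypes.streamlines))
    return DissimilarityEmbedding(vectors=vectors, prototypes=prototypes)


class NeighborIndex:
    """Exact k-nearest-neighbor index over the rows of an embedding.

    Backed by a k-d tree; query results are identical to exhaustive Euclidean
    search, with distance ties ordered by ascending row index.
    """

    def __init__(self, embedding: DissimilarityEmbedding):
        self.embedding = embedding
        self._tree = cKDTree(embedding.vectors)

    @property
    def n(self) -> int:
        return self.embedding.n

    def query(self, query_vectors: np.ndarray, k: int):
        return knn_query(self, query_vectors, k)


def knn_query(index: NeighborIndex, query_vectors, k: int):
    """k nearest indexed rows for each query vector.

    Returns ``(indices, distances)`` arrays of shape (n_queries, k), sorted by
    ascending Euclidean distance with ties broken by ascending index. ``k``
    must not exceed the indexed size (callers clamp explicitly).
    """
    q = np.atleast_2d(np.asarray(query_vectors, dtype=np.float64))
    if q.shape[1] != index.embedding.prototypes.p:
        raise ValueError(
            f"query dimensionality {q.shape[1]} != embedding p "
            f"{index.embedding.prototypes.p}"
        )
    if not 1 <= k <= index.n:
        raise ValueError(f"k must be in [1, {index.n}], got {k}")
    dist, idx = index._tree.query(q, k=k)
    dist = np.atleast_2d(dist).reshape(q.shape[0], k)
    idx = np.atleast_2d(idx).reshape(q.shape[0], k)
    # cKDTree sorts by distance; enforce ascending-index order within ties
    order = np.lexsort((idx, dist), axis=1)
    rows = np.arange(q.shape[0])[:, None]
    return idx[rows, order], dist[rows, order]
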