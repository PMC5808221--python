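"""Streamline and tractogram data model, inter-streamline distances, resampling.

A streamline is an ordered 3-D polyline in world millimetres (RAS+). Streamlines
within one tractogram may have different numbers of points; the MAM distance is
defined directly on the raw polylines, so no resampling is applied anywhere in
the correspondence pipeline. Resampling exists only for voxelization and for
building fixtures.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

logger = logging.getLogger(__name__)

__all__ = [
    "Streamline",
    "Tractogram",
    "Tract",
    "SpatialReference",
    "as_streamline",
    "point_to_streamline_distance",
    "mam_distance",
    "mam_distance_matrix",
    "resample_streamline",
    "streamline_length",
]

#: A streamline is simply an (n, 3) float64 array of world-mm coordinates.
Streamline = np.ndarray


def as_streamline(points) -> Streamline:
    """Validate and coerce ``points`` to an (n, 3) float64 array with n >= 2.

    Raises ``ValueError`` on wrong shape, fewer than two points, or non-finite
    coordinates.
    """
    pts = np.asarray(points, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError(f"streamline must be an (n, 3) array, got shape {pts.shape}")
    if pts.shape[0] < 2:
        raise ValueError(f"streamline needs at least 2 points, got {pts.shape[0]}")
    if not np.all(np.isfinite(pts)):
        raise ValueError("streamline contains non-finite coordinates")
    return pts


def streamline_length(s: Streamline) -> float:
    """Total arc length (mm) of the polyline."""
    return float(np.linalg.norm(np.diff(s, axis=0), axis=1).sum())


def _is_degenerate(pts: np.ndarray) -> bool:
    """True for streamlines that carry no geometry: <2 points, non-finite
    coordinates, or all points identical (zero length)."""
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 2:
        return True
    if not np.all(np.isfinite(pts)):
        return True
    return bool(np.allclose(pts, pts[0]))


@dataclass(frozen=True)
class SpatialReference:
    """Voxel grid: a 4x4 voxel-to-world affine plus grid shape.

    Voxel indices map to world mm through ``affine``; ``voxel_size`` is derived
    from the column norms of the linear part.
    """

    affine: np.ndarray
    shape: tuple[int, int, int]

    def __post_init__(self):
        aff = np.asarray(self.affine, dtype=np.float64)
        if aff.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(aff[:3, :3])) < 1e-12:
            raise ValueError("affine is not invertible")
        shp = tuple(int(v) for v in self.shape)
        if len(shp) != 3 or any(v < 1 for v in shp):
            raise ValueError("shape must be 3 positive integers")
        object.__setattr__(self, "affine", aff)
        object.__setattr__(self, "shape", shp)

    @property
    def voxel_size(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def inverse_affine(self) -> np.ndarray:
        return np.linalg.inv(self.affine)


class Tractogram:
    """Indexed collection of streamlines with an optional spatial reference.

    Indices 0..M-1 are stable identifiers for the lifetime of the object.
    Degenerate streamlines (fewer than two points, non-finite coordinates, or
    zero length) are dropped at construction with a logged count; real
    tractograms routinely contain a few.
    """

    def __init__(self, streamlines, reference: SpatialReference | None = None):
        kept: list[np.ndarray] = []
        dropped = 0
        for pts in streamlines:
            arr = np.asarray(pts, dtype=np.float64)
            if _is_degenerate(arr):
                dropped += 1
                continue
            kept.append(arr)
        if dropped:
            logger.warning("dropped %d degenerate streamline(s)", dropped)
        if not kept:
            raise ValueError("tractogram must contain at least one valid streamline")
        self.streamlines: list[Streamline] = kept
        self.reference = reference
        self.n_dropped = dropped

    def __len__(self) -> int:
        return len(self.streamlines)

    def __getitem__(self, i: int) -> Streamline:
        return self.streamlines[i]

    def subset(self, indices) -> list[Streamline]:
        return [self.streamlines[i] for i in indices]


@dataclass
class Tract:
    """A labelled subset of a tractogram's streamline indices."""

    parent: Tractogram
    indices: tuple[int, ...]
    label: str = ""

    def __post_init__(self):
        idx = tuple(int(i) for i in self.indices)
        if len(set(idx)) != len(idx):
            raise ValueError("tract indices must be unique")
        m = len(self.parent)
        if idx and (min(idx) < 0 or max(idx) >= m):
            raise ValueError(f"tract indices out of range for tractogram of size {m}")
        self.indices = idx

    def __len__(self) -> int:
        return len(self.indices)

    @property
    def streamlines(self) -> list[Streamline]:
        return self.parent.subset(self.indices)


def point_to_streamline_distance(x, s: Streamline) -> float:
    """Distance (mm) from point ``x`` to the nearest vertex of streamline ``s``.

    This is the inner term of the MAM distance: the minimum over the polyline's
    points of the Euclidean distance, not a point-to-segment distance.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.shape != (3,) or not np.all(np.isfinite(x)):
        raise ValueError("x must be a finite 3-vector")
    s = as_streamline(s)
    return float(np.min(np.linalg.norm(s - x, axis=1)))


def mam_distance(s_a: Streamline, s_b: Streamline) -> float:
    """Symmetric minimum average mean (MAM) distance between two streamlines.

    d(a, b) = (D(a, b) + D(b, a)) / 2 where D(a, b) is the mean, over points of
    a, of the distance to the closest point of b. Symmetric, non-negative, zero
    when the point sets coincide, and invariant to reversing either polyline.
    It is not a metric (the triangle inequality can fail).
    """
    a = as_streamline(s_a)
    b = as_streamline(s_b)
    d = cdist(a, b)
    return float(0.5 * (d.min(axis=1).mean() + d.min(axis=0).mean()))


def mam_distance_matrix(set_a, set_b) -> np.ndarray:
    """Pairwise MAM distances between two streamline collections.

    Returns an ``(len(set_a), len(set_b))`` array. When every streamline in a
    collection has the same point count the computation is vectorised in one
    einsum block; ragged collections fall back to a per-pair loop.
    """
    A = [as_streamline(s) for s in set_a]
    B = [as_streamline(s) for s in set_b]
    if not A or not B:
        raise ValueError("both collections must be non-empty")

    na = {s.shape[0] for s in A}
    nb = {s.shape[0] for s in B}
    if len(na) == 1 and len(nb) == 1:
        Pa = np.stack(A)  # (ka, n, 3)
        Pb = np.stack(B)  # (kb, m, 3)
        # squared distances (ka, kb, n, m) via |x|^2 + |y|^2 - 2 x.y
        sq_a = np.einsum("and,and->an", Pa, Pa)
        sq_b = np.einsum("bmd,bmd->bm", Pb, Pb)
        cross = np.einsum("and,bmd->abnm", Pa, Pb)
        d2 = sq_a[:, None, :, None] + sq_b[None, :, None, :] - 2.0 * cross
        np.maximum(d2, 0.0, out=d2)
        d = np.sqrt(d2)
        return 0.5 * (d.min(axis=3).mean(axis=2) + d.min(axis=2).mean(axis=2))

    out = np.empty((len(A), len(B)))
    for i, a in enumerate(A):
        for j, b in enumerate(B):
            out[i, j] = mam_distance(a, b)
    return out


def resample_streamline(s: Streamline, step: float) -> Streamline:
    """Resample a polyline so consecutive points are at most ``step`` mm apart.

    The returned points lie on the original polyline, keep every original
    vertex (so total arc length is preserved exactly) and include both
    endpoints. Extra points are inserted at uniform arc-length spacing.
    """
    s = as_streamline(s)
    if not np.isfinite(step) or step <= 0:
        raise ValueError(f"step must be positive, got {step}")
    seg = np.linalg.norm(np.diff(s, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    if total == 0.0:
        return s[:2].copy()
    n_div = int(np.ceil(total / step))
    grid = np.linspace(0.0, total, n_div + 1)
    # merge the uniform grid with the original vertex arc-length positions
    t = np.unique(np.concatenate([grid, cum]))
    out = np.empty((t.size, 3))
    for d in range(3):
        out[:, d] = np.interp(t, cum, s[:, d])
    return out
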