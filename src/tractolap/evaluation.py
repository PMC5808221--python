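"""Voxel-level evaluation: tract voxelization, Dice overlap, and ROC/AUC over
the streamline-ranking threshold.

A tract is converted to a binary mask on a reference grid by marking every
voxel crossed by a streamline; "crossed" is approximated by resampling each
streamline at half the smallest voxel size and rounding each point to the
nearest voxel center after the world-to-voxel affine.

The ROC analysis sweeps the segmentation threshold over the ranking: at
threshold tau the positives are the voxels of the top-tau ranked streamlines.
The voxel universe for the confusion counts is the union of the voxels of all
ranked streamlines and of the ground truth — not the whole grid, where the
overwhelming number of empty voxels would pin the false-positive rate near
zero and saturate every AUC at ~1. Absolute AUC values therefore depend on
this universe choice and are comparable only within it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import SpatialReference, Tract, resample_streamline
from .refinement import RankedCandidates

logger = logging.getLogger(__name__)

__all__ = ["VoxelMask", "RocResult", "voxelize", "dsc", "roc_analysis"]


@dataclass(frozen=True)
class VoxelMask:
    """Set of occupied voxel indices on a reference grid."""

    grid: SpatialReference
    voxels: frozenset

    def __len__(self) -> int:
        return len(self.voxels)

    def to_array(self) -> np.ndarray:
        arr = np.zeros(self.grid.shape, dtype=np.uint8)
        if self.voxels:
            ijk = np.array(sorted(self.voxels))
            arr[ijk[:, 0], ijk[:, 1], ijk[:, 2]] = 1
        return arr


def _streamline_voxels(s, grid: SpatialReference, step: float) -> set:
    pts = resample_streamline(s, step)
    inv = grid.inverse_affine
    vox = pts @ inv[:3, :3].T + inv[:3, 3]
    ijk = np.floor(vox + 0.5).astype(np.intp)  # nearest voxel center, half-up
    shape = np.asarray(grid.shape)
    inside = np.all((ijk >= 0) & (ijk < shape), axis=1)
    n_out = int((~inside).sum())
    return set(map(tuple, ijk[inside])), n_out


def voxelize(
    t,
    grid: SpatialReference,
    step_fraction: float = 0.5,
) -> VoxelMask:
    """Binary mask of the voxels crossed by the streamlines of ``t``.

    ``t`` may be a Tract or any iterable of streamlines; an empty collection
    gives an empty mask. Streamlines are resampled at
    ``step_fraction * min(voxel_size)`` before voxel assignment; points falling
    outside the grid are dropped (counted in a warning).
    """
    if step_fraction <= 0:
        raise ValueError("step_fraction must be positive")
    streamlines = t.streamlines if isinstance(t, Tract) else list(t)
    step = step_fraction * float(np.min(grid.voxel_size))
    voxels: set = set()
    dropped = 0
    for s in streamlines:
        vs, n_out = _streamline_voxels(s, grid, step)
        voxels |= vs
        dropped += n_out
    if dropped:
        logger.warning("%d resampled point(s) fell outside the grid", dropped)
    return VoxelMask(grid=grid, voxels=frozenset(voxels))


def dsc(a: VoxelMask, b: VoxelMask) -> float:
    """Dice similarity coefficient 2|A∩B| / (|A| + |B|) of two masks.

    Both masks must share a grid. Two empty masks have no defined overlap and
    raise rather than returning a misleading 0 or 1.
    """
    if a.grid.shape != b.grid.shape or not np.allclose(a.grid.affine, b.grid.affine):
        raise ValueError("masks are on different grids")
    if not a.voxels and not b.voxels:
        raise ValueError("DSC undefined: both masks are empty")
    return 2.0 * len(a.voxels & b.voxels) / (len(a.voxels) + len(b.voxels))


@dataclass(frozen=True)
class RocResult:
    """ROC curve over the ranking threshold plus its trapezoidal AUC."""

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float


def roc_analysis(
    ranking: RankedCandidates,
    target,
    gt: Tract,
    grid: SpatialReference,
    step_fraction: float = 0.5,
) -> RocResult:
    """ROC/AUC of a streamline ranking against a ground-truth tract.

    For each threshold tau = 0..len(ranking), the positive mask is the union
    of the voxels of the top-tau ranked streamlines; TP/FP/TN/FN are counted
    against the ground-truth voxels within the universe formed by all ranked
    streamlines' voxels united with the ground truth. The AUC is the trapezoid
    area under the (FPR, TPR) polyline closed with the (0,0) and (1,1)
    endpoints.
    """
    if len(ranking) < 1:
        raise ValueError("ranking is empty")
    if len(gt) < 1:
        raise ValueError("ground-truth tract is empty")
    gt_vox = voxelize(gt, grid, step_fraction).voxels
    if not gt_vox:
        raise ValueError("ground truth voxelizes to an empty mask")

    step = step_fraction * float(np.min(grid.voxel_size))
    per_streamline = []
    for idx in ranking.indices:
        vs, _ = _streamline_voxels(target[int(idx)], grid, step)
        per_streamline.append(vs)
    all_ranked = set().union(*per_streamline)
    universe = all_ranked | gt_vox
    n_pos = len(gt_vox)
    n_neg = len(universe) - n_pos

    thresholds = np.arange(len(ranking) + 1)
    tpr = np.empty(len(thresholds))
    fpr = np.empty(len(thresholds))
    pos: set = set()
    for tau in thresholds:
        if tau > 0:
            pos |= per_streamline[tau - 1]
        tp = len(pos & gt_vox)
        fp = len(pos) - tp
        tpr[tau] = tp / n_pos
        fpr[tau] = fp / n_neg if n_neg else 0.0

    xs = np.concatenate([[0.0], fpr, [1.0]])
    ys = np.concatenate([[0.0], tpr, [1.0]])
    auc = float(np.trapezoid(ys, xs))
    return RocResult(thresholds=thresholds, tpr=tpr, fpr=fpr, auc=auc)


def roc_table(result: RocResult) -> str:
    """Tab-separated export: threshold, tpr, fpr (one row per threshold)."""
    lines = ["threshold\ttpr\tfpr"]
    for t, tp, fp in zip(result.thresholds, result.tpr, result.fpr):
        lines.append(f"{int(t)}\t{tp:.6f}\t{fp:.6f}")
    return "\n".join(lines) + "\n"
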