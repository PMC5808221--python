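"""Streamline and image file I/O.

Streamlines are read from and written to TRK or TCK (dialect chosen by
extension) through ``nibabel.streamlines``. The single internal convention is
world RAS+ millimetres: TRK stores data in a voxel-based frame with a header
affine, and nibabel applies the header's affine-to-rasmm on load, so
everything in memory is world mm regardless of dialect. Binary masks and
reference grids use NIfTI.
"""

from __future__ import annotations

import logging
import os

import nibabel as nib
import numpy as np
from nibabel.streamlines.tck import TckFile
from nibabel.streamlines.trk import TrkFile

from .core import SpatialReference, Tract, Tractogram
from .evaluation import VoxelMask

logger = logging.getLogger(__name__)

__all__ = [
    "read_streamlines",
    "write_streamlines",
    "read_reference",
    "write_mask",
]

_DIALECTS = {".trk": TrkFile, ".tck": TckFile}


def _dialect(path: str):
    ext = os.path.splitext(str(path))[1].lower()
    if ext not in _DIALECTS:
        raise ValueError(
            f"unsupported streamline format {ext!r}; expected .trk or .tck"
        )
    return _DIALECTS[ext]


def read_streamlines(path) -> Tractogram:
    """Load a TRK/TCK file as a Tractogram in world RAS+ mm.

    Degenerate streamlines are dropped with a logged count. TRK headers carry
    a voxel grid, which becomes the tractogram's spatial reference; TCK files
    have none.
    """
    cls = _dialect(path)
    try:
        tf = cls.load(str(path))
    except Exception as exc:  # nibabel raises several header error types
        raise ValueError(f"cannot read streamline file {path}: {exc}") from exc
    streamlines = [np.asarray(s, dtype=np.float64) for s in tf.tractogram.streamlines]
    if not streamlines:
        raise ValueError(f"{path} contains no streamlines")
    reference = None
    if cls is TrkFile:
        hdr = tf.header
        reference = SpatialReference(
            affine=np.asarray(hdr["voxel_to_rasmm"], dtype=np.float64),
            shape=tuple(int(v) for v in hdr["dimensions"]),
        )
    return Tractogram(streamlines, reference=reference)


def write_streamlines(obj, path, reference: SpatialReference | None = None) -> None:
    """Write a Tractogram or Tract to TRK/TCK.

    Coordinates are written as world mm (``affine_to_rasmm`` is identity); for
    TRK a header grid is taken from ``reference``, the object's own reference,
    or an identity fallback.
    """
    cls = _dialect(path)
    if isinstance(obj, Tract):
        streamlines = obj.streamlines
        reference = reference or obj.parent.reference
    elif isinstance(obj, Tractogram):
        streamlines = obj.streamlines
        reference = reference or obj.reference
    else:
        streamlines = list(obj)
    if not streamlines:
        raise ValueError("refusing to write an empty streamline collection")
    tractogram = nib.streamlines.Tractogram(
        [np.asarray(s, dtype=np.float32) for s in streamlines],
        affine_to_rasmm=np.eye(4),
    )
    header = {}
    if cls is TrkFile and reference is not None:
        header = {
            "voxel_to_rasmm": reference.affine.astype(np.float32),
            "dimensions": np.asarray(reference.shape, dtype=np.int16),
            "voxel_sizes": reference.voxel_size.astype(np.float32),
            "voxel_order": "".join(nib.aff2axcodes(reference.affine)),
        }
    cls(tractogram, header=header or None).save(str(path))


def read_reference(path) -> SpatialReference:
    """Spatial reference (affine + shape) from a NIfTI header."""
    img = nib.load(str(path))
    return SpatialReference(
        affine=np.asarray(img.affine, dtype=np.float64),
        shape=tuple(int(v) for v in img.shape[:3]),
    )


def write_mask(mask: VoxelMask, path) -> None:
    """Write a voxel mask as uint8 NIfTI on its grid."""
    img = nib.Nifti1Image(mask.to_array(), affine=mask.grid.affine)
    nib.save(img, str(path))
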