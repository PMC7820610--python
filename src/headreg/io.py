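"""Reading and writing volumes in NIfTI, MetaImage, and NRRD formats.

SimpleITK handles the on-disk formats; this module converts between its
(z, y, x) array convention and the package's (x, y, z) :class:`Volume`.
Header spacing and origin are honored bit-exact on round trip.  Direction
matrices other than identity are not supported (the pipeline assumes
axis-aligned grids).
"""

from __future__ import annotations

import os

import numpy as np
import SimpleITK as sitk

from .volume import Modality, Volume

_FORMAT_EXT = {
    "NIfTI": (".nii", ".nii.gz"),
    "MetaImage": (".mha", ".mhd"),
    "NRRD": (".nrrd",),
}


def _check_format(path: str, format: str | None) -> None:
    if format is None:
        return
    if format not in _FORMAT_EXT:
        raise ValueError(f"unknown format {format!r}; expected one of {sorted(_FORMAT_EXT)}")
    if not str(path).endswith(_FORMAT_EXT[format]):
        raise ValueError(f"path {path!r} does not match format {format}")


def read_volume(path: str, format: str | None = None, modality: Modality = Modality.UNKNOWN) -> Volume:
    """Read a 3D scalar volume from disk.

    Raises ``FileNotFoundError`` for a missing file and ``ValueError`` for
    non-3D / vector images or non-positive header spacing.
    """
    _check_format(path, format)
    if not os.path.exists(path):
        raise FileNotFoundError(f"no such volume file: {path}")
    img = sitk.ReadImage(str(path))
    if img.GetDimension() != 3:
        raise ValueError(f"expected a 3D volume, got dimension {img.GetDimension()}")
    if img.GetNumberOfComponentsPerPixel() != 1:
        raise ValueError("vector-valued volumes are not supported")
    spacing = img.GetSpacing()
    if any(s <= 0 for s in spacing):
        raise ValueError(f"non-positive spacing in header: {spacing}")
    direction = np.asarray(img.GetDirection()).reshape(3, 3)
    if not np.allclose(direction, np.eye(3), atol=1e-6):
        raise ValueError("only identity direction matrices are supported")
    arr = sitk.GetArrayFromImage(img)  # (z, y, x)
    return Volume(
        voxels=np.ascontiguousarray(arr.transpose(2, 1, 0)),
        spacing=tuple(spacing),
        modality=modality,
        origin=tuple(img.GetOrigin()),
    )


def write_volume(v: Volume, path: str, format: str | None = None) -> None:
    """Write a volume to disk; the format follows the file extension."""
    _check_format(path, format)
    parent = os.path.dirname(os.path.abspath(str(path)))
    if not os.path.isdir(parent) or not os.access(parent, os.W_OK):
        raise PermissionError(f"cannot write to {path}")
    img = sitk.GetImageFromArray(np.ascontiguousarray(v.voxels.transpose(2, 1, 0)))
    img.SetSpacing(tuple(float(s) for s in v.spacing))
    img.SetOrigin(tuple(float(o) for o in v.origin))
    sitk.WriteImage(img, str(path))
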