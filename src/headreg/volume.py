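"""3D scalar volumes with physical spacing metadata.

A :class:`Volume` is the unit of data every pipeline stage consumes and
produces: a 3D grid of intensities plus the voxel spacing (mm), the physical
coordinate of the first voxel center (origin), and a modality tag.

Coordinate convention
---------------------
Voxel indices are 0-based and the world coordinate of voxel ``(i, j, k)`` is
``origin + (i, j, k) * spacing`` (voxel-center convention).  Axis order of the
``voxels`` array is ``(x, y, z)``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage


class Modality(enum.Enum):
    MRI = "MRI"
    CT = "CT"
    UNKNOWN = "UNKNOWN"


@dataclass
class Volume:
    """A 3D scalar image with spacing metadata.

    Parameters
    ----------
    voxels : ndarray, shape (nx, ny, nz)
        Finite intensities, stored as float64 regardless of on-disk type.
    spacing : tuple of float
        (sx, sy, sz) millimetres per voxel, each strictly positive.
    modality : Modality
        MRI, CT, or UNKNOWN.
    origin : tuple of float
        World coordinates (mm) of the center of voxel (0, 0, 0).
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    modality: Modality = Modality.UNKNOWN
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 3:
            raise ValueError(f"expected a 3D volume, got ndim={self.voxels.ndim}")
        if any(n < 2 for n in self.voxels.shape):
            raise ValueError(f"grid dimensions must be >= 2, got {self.voxels.shape}")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("volume contains non-finite intensities")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 strictly positive values, got {self.spacing}")
        if isinstance(self.modality, str):
            self.modality = Modality(self.modality)

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def extent(self) -> np.ndarray:
        """Physical extent (mm) along each axis: dims * spacing."""
        return np.asarray(self.dims) * np.asarray(self.spacing)

    @property
    def physical_center(self) -> np.ndarray:
        """World coordinates of the grid center (mm)."""
        return np.asarray(self.origin) + (np.asarray(self.dims) - 1) / 2.0 * np.asarray(self.spacing)

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        """Map (N, 3) voxel indices to world coordinates."""
        return np.asarray(self.origin) + np.asarray(idx, dtype=float) * np.asarray(self.spacing)

    def world_to_index(self, pts: np.ndarray) -> np.ndarray:
        """Map (N, 3) world coordinates to fractional voxel indices."""
        return (np.asarray(pts, dtype=float) - np.asarray(self.origin)) / np.asarray(self.spacing)

    def with_voxels(self, voxels: np.ndarray) -> "Volume":
        """A copy sharing geometry but with new intensities."""
        return replace(self, voxels=np.asarray(voxels, dtype=np.float64))

    def copy(self) -> "Volume":
        return replace(self, voxels=self.voxels.copy())


_INTERP_ORDER = {"trilinear": 1, "nearest": 0}


def sample_at_indices(
    v: Volume, idx: np.ndarray, interp: str = "trilinear", mode: str = "constant", cval: float = 0.0
) -> np.ndarray:
    """Sample a volume at fractional voxel indices.

    ``idx`` has shape (N, 3); returns N intensities.  ``mode='constant'``
    fills out-of-grid samples with ``cval``; ``mode='nearest'`` clamps to the
    border, which keeps constant fields exactly constant under resampling.
    """
    if interp not in _INTERP_ORDER:
        raise ValueError(f"unknown interpolation {interp!r}")
    coords = np.asarray(idx, dtype=float).T.copy()  # (3, N) for map_coordinates
    # snap coordinates a rounding error outside the grid back onto the border
    tol = 1e-6
    for ax in range(3):
        n = v.voxels.shape[ax] - 1
        c = coords[ax]
        inside = (c >= -tol) & (c <= n + tol)
        coords[ax] = np.where(inside, np.clip(c, 0.0, n), c)
    return ndimage.map_coordinates(
        v.voxels, coords, order=_INTERP_ORDER[interp], mode=mode, cval=cval, prefilter=False
    )


def resample_isotropic(v: Volume, interp: str = "trilinear") -> Volume:
    """Resample to the smallest input spacing along all axes.

    Output spacing is (s, s, s) with s = min(input spacing); the physical
    extent is preserved within one voxel per axis.  Already-isotropic volumes
    are returned unchanged (same grid, same voxels).
    """
    s = min(v.spacing)
    if all(abs(sp - s) < 1e-12 for sp in v.spacing):
        return v.copy()
    new_dims = tuple(max(2, int(round(e / s))) for e in v.extent)
    return _resize(v, new_dims, (s, s, s), interp)


def resize_to_grid(v: Volume, dims: tuple[int, int, int], interp: str = "trilinear") -> Volume:
    """Resize to an exact grid, rescaling spacing to preserve physical extent."""
    dims = tuple(int(d) for d in dims)
    if len(dims) != 3 or any(d < 2 for d in dims):
        raise ValueError(f"target dims must be 3 values >= 2, got {dims}")
    if dims == v.dims:
        return v.copy()
    new_spacing = tuple(e / d for e, d in zip(v.extent, dims))
    return _resize(v, dims, new_spacing, interp)


def _resize(v: Volume, dims: tuple[int, int, int], new_spacing, interp: str) -> Volume:
    # Voxel-edge alignment: sample position i maps to old fractional index
    # (i + 0.5) * ratio - 0.5, the standard image-resize convention.
    ratios = [ns / os for ns, os in zip(new_spacing, v.spacing)]
    axes = [
        (np.arange(d) + 0.5) * r - 0.5 for d, r in zip(dims, ratios)
    ]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    idx = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)
    vals = sample_at_indices(v, idx, interp=interp, mode="nearest")
    new_origin = tuple(
        o + 0.5 * (ns - os) for o, ns, os in zip(v.origin, new_spacing, v.spacing)
    )
    return Volume(
        voxels=vals.reshape(dims),
        spacing=tuple(float(s) for s in new_spacing),
        modality=v.modality,
        origin=new_origin,
    )
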