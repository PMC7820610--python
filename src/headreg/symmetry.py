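"""Symmetry-frame estimation for roughly ellipsoidal head images.

The head in a medical volume is approximately ellipsoidal, so its pose can
be estimated cheaply: extract the foreground point cloud (Otsu two-level
thresholding, lowest class discarded as background), run PCA on the voxel
center coordinates, and reorient the image so its principal axes lie along
the grid axes with the centroid at the grid center.  The resulting rigid
map is the building block of ground-truth generation (T_Fix and T_Mov).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .transforms import RigidTransform, apply_transform
from .volume import Volume, resample_isotropic


@dataclass(frozen=True)
class PointCloud:
    """N x 3 physical coordinates (mm) of foreground voxel centers."""

    points: np.ndarray

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=np.float64)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValueError(f"expected an (N, 3) array, got {pts.shape}")
        if pts.shape[0] < 4:
            raise ValueError("need at least 4 points for a 3D principal-axis fit")
        object.__setattr__(self, "points", pts)


@dataclass(frozen=True)
class SymmetryFrame:
    """Centroid plus ordered orthonormal principal axes of the head cloud.

    ``axes`` rows are the principal directions in descending explained
    variance, right-handed (det = +1); ``variances`` are the corresponding
    covariance eigenvalues.
    """

    centroid: np.ndarray
    axes: np.ndarray
    variances: np.ndarray

    def __post_init__(self) -> None:
        A = np.asarray(self.axes, dtype=float)
        if not np.allclose(A.T @ A, np.eye(3), atol=1e-9):
            raise ValueError("axes are not orthonormal within 1e-9")
        if abs(np.linalg.det(A) - 1.0) > 1e-9:
            raise ValueError("axes must be right-handed (det = +1)")
        var = np.asarray(self.variances, dtype=float)
        if np.any(var < 0) or np.any(np.diff(var) > 1e-12):
            raise ValueError("variances must be non-negative and descending")
        object.__setattr__(self, "centroid", np.asarray(self.centroid, dtype=float))
        object.__setattr__(self, "axes", A)
        object.__setattr__(self, "variances", var)


def otsu_two_level(histogram: np.ndarray) -> tuple[int, int]:
    """Two-level Otsu thresholds of an intensity histogram.

    Returns the bin-index pair ``(thr1, thr2)``, ``thr1 < thr2``, maximizing
    the between-class variance of the induced three classes
    ``bins <= thr1``, ``thr1 < bins <= thr2``, ``bins > thr2``.  Ties break
    toward the lexicographically smallest pair.  Implemented with prefix
    sums over all candidate pairs.
    """
    h = np.asarray(histogram, dtype=np.float64)
    if h.ndim != 1 or h.size < 3:
        raise ValueError("histogram must be 1D with at least 3 bins")
    if np.any(h < 0):
        raise ValueError("histogram counts must be non-negative")
    if np.count_nonzero(h) < 3:
        raise ValueError("need at least 3 occupied bins for two thresholds")
    n = h.size
    levels = np.arange(n, dtype=np.float64)
    w = np.concatenate([[0.0], np.cumsum(h)])          # w[i] = sum of h[:i]
    m = np.concatenate([[0.0], np.cumsum(h * levels)])  # first moments

    def cls(lo: np.ndarray, hi: np.ndarray):
        """Weight and mean-sum of bins [lo, hi) for broadcastable index arrays."""
        return w[hi] - w[lo], m[hi] - m[lo]

    t1 = np.arange(0, n - 2)[:, None]   # class 1 = [0, t1], class 2 = (t1, t2]
    t2 = np.arange(1, n - 1)[None, :]
    valid = t2 > t1
    w1, m1 = cls(np.zeros_like(t1), t1 + 1)
    w2, m2 = cls(np.broadcast_to(t1 + 1, (t1.size, t2.size)), np.broadcast_to(t2 + 1, (t1.size, t2.size)))
    w3 = w[-1] - w1 - w2
    m3 = m[-1] - m1 - m2
    mu = m[-1] / w[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_b = (
            np.where(w1 > 0, w1 * (m1 / np.where(w1 > 0, w1, 1) - mu) ** 2, 0.0)
            + np.where(w2 > 0, w2 * (m2 / np.where(w2 > 0, w2, 1) - mu) ** 2, 0.0)
            + np.where(w3 > 0, w3 * (m3 / np.where(w3 > 0, w3, 1) - mu) ** 2, 0.0)
        )
    sigma_b = np.where(valid, sigma_b, -np.inf)
    # argmax scans row-major, so on exact ties the smallest (t1, t2) wins
    i, j = np.unravel_index(np.argmax(sigma_b), sigma_b.shape)
    return int(t1[i, 0]), int(t2[0, j])


def intensity_thresholds(v: Volume, bins: int = 256) -> tuple[float, float]:
    """Otsu two-level thresholds in intensity units (256 uniform bins)."""
    lo, hi = float(v.voxels.min()), float(v.voxels.max())
    if hi <= lo:
        raise ValueError("constant volume has no foreground")
    hist, edges = np.histogram(v.voxels, bins=bins, range=(lo, hi))
    t1, t2 = otsu_two_level(hist)
    return float(edges[t1 + 1]), float(edges[t2 + 1])


def extract_head_points(v: Volume) -> PointCloud:
    """Foreground voxel centers (mm): intensities above the lower Otsu threshold.

    The lowest of the three Otsu classes is discarded as background; skull
    and soft tissue (middle and top classes) both belong to the head.
    """
    thr1, _ = intensity_thresholds(v)
    mask = v.voxels > thr1
    if not mask.any():
        raise ValueError("empty foreground after thresholding")
    idx = np.argwhere(mask)
    return PointCloud(v.index_to_world(idx))


def principal_axes(pc: PointCloud) -> SymmetryFrame:
    """PCA frame of a point cloud.

    Eigenvectors of the covariance in descending eigenvalue order; each
    axis's sign is fixed so its largest-magnitude component is positive,
    then the third axis is reset to the cross product of the first two to
    restore right-handedness.
    """
    pts = pc.points
    centroid = pts.mean(axis=0)
    cov = np.cov(pts - centroid, rowvar=False)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    if evals[-1] <= 1e-12 * max(evals[0], 1.0):
        raise ValueError("degenerate point cloud: covariance rank < 3")
    axes = evecs[:, order].T  # rows = principal directions
    for i in range(3):
        k = np.argmax(np.abs(axes[i]))
        if axes[i, k] < 0:
            axes[i] = -axes[i]
    axes[2] = np.cross(axes[0], axes[1])
    return SymmetryFrame(centroid=centroid, axes=axes, variances=evals)


def symmetry_transform(frame: SymmetryFrame, v: Volume) -> RigidTransform:
    """Rigid map taking the image into its symmetry pose.

    Principal axes go onto the grid axes and the centroid onto the grid's
    physical center: ``x -> A (x - centroid) + center``.  Applied to the
    point cloud this yields a centered, covariance-diagonal cloud.
    """
    A = frame.axes
    c = v.physical_center
    return RigidTransform.from_rotation_translation(A, c - A @ frame.centroid)


def align_to_symmetry(v: Volume, interp: str = "trilinear") -> tuple[Volume, RigidTransform]:
    """Resample isotropically, estimate the symmetry frame, and reorient.

    Returns the aligned volume and the symmetry transform T_sym for later
    composition into the full ground-truth map.
    """
    iso = resample_isotropic(v, interp=interp)
    frame = principal_axes(extract_head_points(iso))
    T_sym = symmetry_transform(frame, iso)
    return apply_transform(iso, T_sym, interp=interp), T_sym
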