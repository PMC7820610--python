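"""Rigid-body transform algebra.

A :class:`RigidTransform` is a 4x4 homogeneous map ``[[R, t], [0, 1]]`` acting
on world coordinates (mm).  Its 6-parameter encoding,
:class:`RegistrationParams`, carries three Euler angles in degrees (intrinsic
Z-Y-X order) and three translations in voxels of a reference grid; the
rotation is applied about the physical center of that grid.  The prediction
target of the learning stage is exactly this 6-vector.

Transforms map moving-image coordinates onto fixed-image coordinates; a
volume is resampled under a transform by pulling through its inverse
(inverse warping), so ``apply_transform(moving, T)`` lives on the moving
grid but shows the content registered onto the fixed pose.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volume import Volume, sample_at_indices

_RTOL = 1e-9


@dataclass(frozen=True)
class RigidTransform:
    """4x4 homogeneous rigid map: rotation R (det +1) plus translation t (mm)."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=np.float64)
        if m.shape != (4, 4):
            raise ValueError(f"expected a 4x4 matrix, got {m.shape}")
        R = m[:3, :3]
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise ValueError("rotation block is not orthonormal within 1e-9")
        if abs(np.linalg.det(R) - 1.0) > 1e-9:
            raise ValueError("rotation block must have determinant +1")
        m[3] = (0.0, 0.0, 0.0, 1.0)
        object.__setattr__(self, "matrix", m)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(4))

    @classmethod
    def from_rotation_translation(cls, R: np.ndarray, t: np.ndarray) -> "RigidTransform":
        m = np.eye(4)
        m[:3, :3] = R
        m[:3, 3] = t
        return cls(m)

    @property
    def rotation(self) -> np.ndarray:
        return self.matrix[:3, :3]

    @property
    def translation(self) -> np.ndarray:
        return self.matrix[:3, 3]

    def apply_points(self, pts: np.ndarray) -> np.ndarray:
        """Map (N, 3) world points through the transform."""
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        return pts @ self.rotation.T + self.translation


@dataclass(frozen=True)
class RegistrationParams:
    """Six registration parameters: Euler angles (deg) + translations (voxels).

    Angles follow the intrinsic Z-Y-X convention (R = Rz @ Ry @ Rx) and live
    in [-180, 180); translations are expressed in voxels of the reference
    grid and converted to mm via its spacing.
    """

    rx: float = 0.0
    ry: float = 0.0
    rz: float = 0.0
    tx: float = 0.0
    ty: float = 0.0
    tz: float = 0.0

    def __post_init__(self) -> None:
        vals = self.as_array()
        if not np.all(np.isfinite(vals)):
            raise ValueError("registration parameters must be finite")
        for name in ("rx", "ry", "rz"):
            a = getattr(self, name)
            if not (-180.0 <= a < 180.0):
                object.__setattr__(self, name, float((a + 180.0) % 360.0 - 180.0))

    def as_array(self) -> np.ndarray:
        return np.array([self.rx, self.ry, self.rz, self.tx, self.ty, self.tz], dtype=float)

    @classmethod
    def from_array(cls, a) -> "RegistrationParams":
        a = np.asarray(a, dtype=float)
        if a.shape != (6,):
            raise ValueError(f"expected 6 parameters, got shape {a.shape}")
        return cls(*a)


def _euler_zyx_matrix(rx: float, ry: float, rz: float) -> np.ndarray:
    """Rotation matrix for intrinsic Z-Y-X Euler angles in degrees."""
    ax, ay, az = np.deg2rad([rx, ry, rz])
    cx, sx = np.cos(ax), np.sin(ax)
    cy, sy = np.cos(ay), np.sin(ay)
    cz, sz = np.cos(az), np.sin(az)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return Rz @ Ry @ Rx


def params_to_transform(p: RegistrationParams, v: Volume) -> RigidTransform:
    """Build the rigid map encoded by six parameters on a reference grid.

    Rotation is about the grid's physical center; translations convert
    voxels -> mm through the grid spacing.
    """
    R = _euler_zyx_matrix(p.rx, p.ry, p.rz)
    c = v.physical_center
    t_mm = np.array([p.tx, p.ty, p.tz]) * np.asarray(v.spacing)
    # x -> R (x - c) + c + t
    return RigidTransform.from_rotation_translation(R, c - R @ c + t_mm)


def transform_to_params(T: RigidTransform, v: Volume) -> RegistrationParams:
    """Invert the parameterization: recover Euler angles and voxel translations.

    At gimbal lock (|ry| = 90 deg) the decomposition fixes rz = 0; the
    returned parameters always regenerate the same matrix.
    """
    R = T.rotation
    sy = -R[2, 0]
    sy = np.clip(sy, -1.0, 1.0)
    ry = np.arcsin(sy)
    if abs(abs(sy) - 1.0) < 1e-10:
        # gimbal lock: only rx -/+ rz is determined; fix rz = 0.
        # At ry = +90: R[0,1] = sin(rx-rz), R[1,1] = cos(rx-rz);
        # at ry = -90: R[0,1] = -sin(rx+rz), R[1,1] = cos(rx+rz).
        rz = 0.0
        rx = float(np.arctan2(np.sign(sy) * R[0, 1], R[1, 1]))
    else:
        rx = np.arctan2(R[2, 1], R[2, 2])
        rz = np.arctan2(R[1, 0], R[0, 0])
    c = v.physical_center
    t_mm = T.apply_points(c)[0] - c
    t_vox = t_mm / np.asarray(v.spacing)
    return RegistrationParams(
        float(np.rad2deg(rx)), float(np.rad2deg(ry)), float(np.rad2deg(rz)),
        float(t_vox[0]), float(t_vox[1]), float(t_vox[2]),
    )


def compose(T1: RigidTransform, T2: RigidTransform) -> RigidTransform:
    """(T1 o T2)(x) = T1(T2(x))."""
    return RigidTransform(T1.matrix @ T2.matrix)


def invert(T: RigidTransform) -> RigidTransform:
    R = T.rotation
    return RigidTransform.from_rotation_translation(R.T, -R.T @ T.translation)


def compose_ground_truth(
    T_fix: RigidTransform, T_reg: RigidTransform, T_mov: RigidTransform
) -> RigidTransform:
    """Full ground-truth map T_fix^-1 o T_reg o T_mov.

    T_mov takes the original moving image to its symmetry pose, T_reg
    registers the symmetry-aligned pair, and T_fix^-1 carries the result
    back from the fixed image's symmetry pose into its original frame.
    """
    return compose(invert(T_fix), compose(T_reg, T_mov))


def apply_transform(v: Volume, T: RigidTransform, interp: str = "trilinear") -> Volume:
    """Resample a volume under a rigid transform (inverse warping).

    The output lives on ``v``'s grid: ``out(x) = v(T^-1 x)`` with fill value
    0 outside the input grid.
    """
    Ti = invert(T)
    dims = v.dims
    gx, gy, gz = np.meshgrid(*(np.arange(d) for d in dims), indexing="ij")
    idx = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)
    world = v.index_to_world(idx)
    src_idx = v.world_to_index(Ti.apply_points(world))
    vals = sample_at_indices(v, src_idx, interp=interp, mode="constant", cval=0.0)
    return v.with_voxels(vals.reshape(dims))


def rotation_angle_deg(T: RigidTransform) -> float:
    """Geodesic rotation magnitude of the transform, in degrees."""
    tr = np.trace(T.rotation)
    return float(np.rad2deg(np.arccos(np.clip((tr - 1.0) / 2.0, -1.0, 1.0))))


def save_transform(T: RigidTransform, path: str) -> None:
    """Serialize as a plain-text 4x4 matrix."""
    np.savetxt(path, T.matrix, fmt="%.17g", header="rigid 4x4 (row-major)")


def load_transform(path: str) -> RigidTransform:
    return RigidTransform(np.loadtxt(path))


def save_params(p: RegistrationParams, path: str) -> None:
    """ITK-style parameter text form: 6 values plus a convention tag."""
    with open(path, "w") as fh:
        fh.write("# convention: euler-zyx-deg, translation-voxels\n")
        fh.write(" ".join(f"{x:.17g}" for x in p.as_array()) + "\n")


def load_params(path: str) -> RegistrationParams:
    with open(path) as fh:
        lines = [ln for ln in fh if not ln.startswith("#")]
    return RegistrationParams.from_array(np.fromstring(lines[0], sep=" "))
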