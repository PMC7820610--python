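"""Co-registered two-modality digital head phantoms.

Every stage of the registration framework is testable without external data
through these phantoms: an ellipsoidal "head" (the symmetry assumption the
ground-truth stage relies on) with a bony shell and off-center internal
structures that break rotational symmetry about the long axis, rendered
under two injective tissue->intensity maps so the pair is genuinely
multi-modal (bone bright in the CT-like map, dim in the MRI-like map), plus
additive Gaussian noise.

Geometry is evaluated analytically in world coordinates, so a phantom can
be posed exactly (no resampling error) via ``PhantomSpec.pose``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .transforms import (
    RegistrationParams,
    RigidTransform,
    _euler_zyx_matrix,
    apply_transform,
    invert,
    params_to_transform,
    transform_to_params,
)
from .volume import Modality, Volume

#: tissue -> intensity for the two modality renderings (unit intensity scale).
#: Orderings differ on purpose: bone is the brightest CT-like tissue but
#: nearly the darkest MRI-like one, so the voxelwise intensity relation
#: between modalities is non-monotone.
MRI_MAP = {"background": 0.0, "bone": 0.15, "soft": 0.70, "csf": 0.95, "lesion": 0.45}
CT_MAP = {"background": 0.0, "bone": 1.00, "soft": 0.30, "csf": 0.22, "lesion": 0.38}


@dataclass(frozen=True)
class Structure:
    """An internal ellipsoidal structure in head-local coordinates (mm)."""

    tissue: str
    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]


def _default_structures() -> tuple[Structure, ...]:
    # Off-center structures break the ellipsoid's rotational symmetry about
    # its long axis, making rigid recovery well-posed for the network stage.
    return (
        Structure("csf", (5.0, 2.5, 0.8), (4.5, 3.0, 1.8)),
        Structure("lesion", (-7.0, -4.0, -0.8), (3.0, 2.2, 1.5)),
    )


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and rendering parameters of a synthetic head.

    ``semi_axes`` (a, b, c) are the outer head semi-axes in mm with
    a > b > c (long axis along x in head-local coordinates); the bony shell
    occupies the outer ``shell_fraction`` of the ellipsoid radius.  ``pose``
    rotates/translates the head analytically within the grid.
    """

    dims: tuple[int, int, int] = (64, 64, 16)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    semi_axes: tuple[float, float, float] = (22.0, 16.0, 5.2)
    shell_fraction: float = 0.85
    structures: tuple[Structure, ...] = field(default_factory=_default_structures)
    mri_map: dict = field(default_factory=lambda: dict(MRI_MAP))
    ct_map: dict = field(default_factory=lambda: dict(CT_MAP))
    noise_sd: tuple[float, float] = (0.02, 0.02)  # (MRI-like, CT-like)
    background_level: float = 0.0
    pose: RegistrationParams = field(default_factory=RegistrationParams)

    def __post_init__(self) -> None:
        a, b, c = self.semi_axes
        if not (a > b > c > 0):
            raise ValueError(f"semi-axes must satisfy a > b > c > 0, got {self.semi_axes}")
        if any(sd < 0 for sd in self.noise_sd):
            raise ValueError("noise sd must be non-negative")
        for m in (self.mri_map, self.ct_map):
            vals = list(m.values())
            if len(set(vals)) != len(vals):
                raise ValueError("modality intensity map must be injective")


def _label_grid(spec: PhantomSpec) -> tuple[np.ndarray, list[str]]:
    """Tissue labels on the grid, with the head posed per ``spec.pose``."""
    dims = spec.dims
    ref = Volume(np.zeros(dims), spacing=spec.spacing)
    gx, gy, gz = np.meshgrid(*(np.arange(d) for d in dims), indexing="ij")
    world = ref.index_to_world(np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1))
    # head-local coordinates: undo the pose about the grid center
    T_pose = params_to_transform(spec.pose, ref)
    local = invert(T_pose).apply_points(world) - ref.physical_center

    a, b, c = spec.semi_axes
    r2 = (local[:, 0] / a) ** 2 + (local[:, 1] / b) ** 2 + (local[:, 2] / c) ** 2
    labels = np.zeros(local.shape[0], dtype=np.int8)
    names = ["background", "soft", "bone"] + [s.tissue for s in spec.structures]
    labels[r2 <= 1.0] = 2  # bone shell
    labels[r2 <= spec.shell_fraction**2] = 1  # soft interior
    for si, s in enumerate(spec.structures):
        cx, cy, cz = s.center
        sa, sb, sc = s.semi_axes
        inside = (
            ((local[:, 0] - cx) / sa) ** 2
            + ((local[:, 1] - cy) / sb) ** 2
            + ((local[:, 2] - cz) / sc) ** 2
        ) <= 1.0
        if not inside.any():
            raise ValueError(f"structure {s.tissue!r} lies outside the grid")
        labels[inside & (labels == 1)] = 3 + si  # structures live in soft tissue
    return labels.reshape(dims), names


def _render(labels: np.ndarray, names, intensity_map: dict, background: float) -> np.ndarray:
    out = np.full(labels.shape, background + intensity_map["background"], dtype=np.float64)
    for li, name in enumerate(names):
        if li == 0:
            continue
        out[labels == li] = intensity_map[name]
    return out


def generate_head_phantom(spec: PhantomSpec, seed: int = 0) -> tuple[Volume, Volume]:
    """Render one co-registered (MRI-like, CT-like) phantom pair.

    The two volumes share identical geometry (voxel-aligned, coincident
    tissue boundaries); only the intensity maps and noise realizations
    differ.  Deterministic given ``seed``.
    """
    labels, names = _label_grid(spec)
    rng = np.random.default_rng(seed)
    mri = _render(labels, names, spec.mri_map, spec.background_level)
    ct = _render(labels, names, spec.ct_map, spec.background_level)
    if spec.noise_sd[0] > 0:
        mri = mri + rng.normal(0.0, spec.noise_sd[0], size=mri.shape)
    if spec.noise_sd[1] > 0:
        ct = ct + rng.normal(0.0, spec.noise_sd[1], size=ct.shape)
    mri_v = Volume(mri, spacing=spec.spacing, modality=Modality.MRI)
    ct_v = Volume(ct, spacing=spec.spacing, modality=Modality.CT)
    return mri_v, ct_v


def make_pair(
    spec: PhantomSpec, p: RegistrationParams, seed: int = 0
) -> tuple[Volume, Volume, RegistrationParams]:
    """A (fixed, moving, truth) phantom registration pair.

    The fixed image is the MRI-like rendering; the moving image is the
    CT-like rendering displaced by ``p``; ``truth`` is the inverse mapping
    that registers the moving image back onto the fixed one.
    """
    mri, ct = generate_head_phantom(spec, seed=seed)
    T_p = params_to_transform(p, ct)
    moving = apply_transform(ct, T_p)
    truth = transform_to_params(invert(T_p), ct)
    return mri, moving, truth


@dataclass
class PairRecord:
    """One labelled registration pair of a dataset."""

    subject_id: int
    fixed: Volume
    moving: Volume
    truth: RegistrationParams
    split: str  # "train" | "test"
    synthetic: bool = False

    @property
    def pair_id(self) -> str:
        kind = "syn" if self.synthetic else "orig"
        return f"s{self.subject_id:03d}-{kind}"


@dataclass
class RegistrationDataset:
    """A list of labelled pairs with a train/test split."""

    records: list[PairRecord]

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def subset(self, split: str) -> list[PairRecord]:
        return [r for r in self.records if r.split == split]


def default_spec_sampler(rng: np.random.Generator) -> PhantomSpec:
    """Per-subject anatomy variation: jittered semi-axes, structures, pose."""
    base = PhantomSpec()
    a, b, c = base.semi_axes
    jit = lambda x, f=0.08: float(x * (1.0 + rng.uniform(-f, f)))
    semi = (jit(a), jit(b), jit(c))
    if not semi[0] > semi[1] > semi[2]:
        semi = (a, b, c)
    structures = tuple(
        replace(
            s,
            center=tuple(cc + rng.uniform(-1.0, 1.0) for cc in s.center),
            semi_axes=tuple(jit(ax, 0.1) for ax in s.semi_axes),
        )
        for s in base.structures
    )
    pose = RegistrationParams(
        rx=float(rng.uniform(-2, 2)), ry=float(rng.uniform(-2, 2)), rz=float(rng.uniform(-2, 2)),
        tx=float(rng.uniform(-1, 1)), ty=float(rng.uniform(-1, 1)), tz=float(rng.uniform(-0.5, 0.5)),
    )
    return replace(base, semi_axes=semi, structures=structures, pose=pose)


def write_manifest(dataset: RegistrationDataset, out_dir: str) -> str:
    """Write NIfTI volumes plus a tab-separated manifest describing them.

    Columns: pair id, modality, split, the six truth parameters of the pair
    (the transform that registers its moving image onto its fixed one), and
    the volume path.  Returns the manifest path.
    """
    import os

    from .io import write_volume

    os.makedirs(out_dir, exist_ok=True)
    rows = ["id\tmodality\tsplit\trx\try\trz\ttx\tty\ttz\tpath"]
    for i, rec in enumerate(dataset):
        for vol, modality in ((rec.fixed, "MRI"), (rec.moving, "CT")):
            path = os.path.join(out_dir, f"{rec.pair_id}-{i:04d}_{modality.lower()}.nii")
            write_volume(vol, path)
            t = rec.truth.as_array()
            rows.append(
                f"{rec.pair_id}-{i:04d}\t{modality}\t{rec.split}\t"
                + "\t".join(f"{x:.17g}" for x in t)
                + f"\t{path}"
            )
    manifest_path = os.path.join(out_dir, "manifest.tsv")
    with open(manifest_path, "w") as fh:
        fh.write("\n".join(rows) + "\n")
    return manifest_path


def load_manifest_dataset(manifest_path: str) -> RegistrationDataset:
    """Rebuild a dataset from a manifest written by :func:`write_manifest`."""
    from .io import read_volume

    groups: dict[str, dict] = {}
    with open(manifest_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            cells = dict(zip(header, line.rstrip("\n").split("\t")))
            g = groups.setdefault(cells["id"], {"split": cells["split"]})
            g[cells["modality"]] = cells["path"]
            g["truth"] = RegistrationParams(
                *(float(cells[k]) for k in ("rx", "ry", "rz", "tx", "ty", "tz"))
            )
    records = []
    for i, (pid, g) in enumerate(sorted(groups.items())):
        if "MRI" not in g or "CT" not in g:
            raise ValueError(f"manifest entry {pid!r} is missing a modality")
        records.append(
            PairRecord(
                subject_id=i,
                fixed=read_volume(g["MRI"], modality=Modality.MRI),
                moving=read_volume(g["CT"], modality=Modality.CT),
                truth=g["truth"],
                split=g["split"],
                synthetic="syn" in pid,
            )
        )
    return RegistrationDataset(records)


def generate_dataset(
    n_subjects: int,
    spec_sampler=default_spec_sampler,
    seed: int = 0,
    train_fraction: float = 0.6,
) -> RegistrationDataset:
    """Generate co-registered subject pairs with a 60/40 train/test split.

    Original pairs are co-registered (truth = identity); synthetic displaced
    pairs come from :func:`headreg.augmentation.augment_dataset`.
    Reproducible by seed, including split membership.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects for a train/test split")
    rng = np.random.default_rng(seed)
    n_train = int(round(train_fraction * n_subjects))
    n_train = min(max(n_train, 1), n_subjects - 1)
    order = rng.permutation(n_subjects)
    split_of = {int(s): ("train" if i < n_train else "test") for i, s in enumerate(order)}
    records = []
    for sid in range(n_subjects):
        spec = spec_sampler(rng)
        mri, ct = generate_head_phantom(spec, seed=int(rng.integers(0, 2**31 - 1)))
        records.append(
            PairRecord(
                subject_id=sid,
                fixed=mri,
                moving=ct,
                truth=RegistrationParams(),
                split=split_of[sid],
            )
        )
    return RegistrationDataset(records)
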