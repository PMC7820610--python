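"""Synthetic rigid augmentation of registration pairs.

Registration datasets are scarce, so each co-registered pair is multiplied
by applying random rigid displacements to the moving image: one rotation by
an angle uniform in [-15, 15] degrees about a uniformly random unit axis,
plus per-axis translations uniform in [-5, 5] voxels.  Every synthetic pair
inherits its parent's train/test membership so no information leaks across
the split.  The sweep over the number of synthetic images per original
(4, 9, ..., 124) selects how much augmentation is worth doing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .phantom import PairRecord, RegistrationDataset
from .transforms import (
    RegistrationParams,
    apply_transform,
    compose,
    invert,
    params_to_transform,
    transform_to_params,
)

DEFAULT_COUNTS = tuple(range(4, 125, 5))  # 4, 9, ..., 124 (25 entries)


@dataclass(frozen=True)
class AugmentationConfig:
    angle_range: tuple[float, float] = (-15.0, 15.0)  # degrees
    translation_range: tuple[float, float] = (-5.0, 5.0)  # voxels
    counts: tuple[int, ...] = DEFAULT_COUNTS
    seed: int = 0

    def __post_init__(self) -> None:
        for rng_ in (self.angle_range, self.translation_range):
            if abs(rng_[0] + rng_[1]) > 1e-12 or rng_[1] < 0:
                raise ValueError(f"range must be symmetric about 0, got {rng_}")
        if any(b <= a for a, b in zip(self.counts, self.counts[1:])):
            raise ValueError("counts must be strictly increasing")


def sample_rigid_params(cfg: AugmentationConfig, rng: np.random.Generator) -> RegistrationParams:
    """One random rigid displacement.

    A single rotation about a uniformly random unit axis by an angle uniform
    in the configured range, converted to the Euler parameterization, plus
    independent per-axis translations uniform in the translation range.
    """
    axis = rng.standard_normal(3)
    axis /= np.linalg.norm(axis)
    angle = rng.uniform(*cfg.angle_range)
    rz, ry, rx = Rotation.from_rotvec(np.deg2rad(angle) * axis).as_euler("ZYX", degrees=True)
    t = rng.uniform(*cfg.translation_range, size=3)
    return RegistrationParams(float(rx), float(ry), float(rz), *(float(x) for x in t))


def augment_record(
    record: PairRecord, p: RegistrationParams
) -> PairRecord:
    """One synthetic child of a pair: moving displaced by ``p``, truth updated."""
    T_p = params_to_transform(p, record.moving)
    moving = apply_transform(record.moving, T_p)
    # the child is registered by undoing p first, then applying the parent truth
    T_parent = params_to_transform(record.truth, record.moving)
    truth = transform_to_params(compose(T_parent, invert(T_p)), record.moving)
    return PairRecord(
        subject_id=record.subject_id,
        fixed=record.fixed,
        moving=moving,
        truth=truth,
        split=record.split,
        synthetic=True,
    )


def augment_dataset(
    dataset: RegistrationDataset,
    n_per_image: int,
    cfg: AugmentationConfig | None = None,
    rng: np.random.Generator | None = None,
    keep_originals: bool = True,
) -> RegistrationDataset:
    """Multiply every pair by ``n_per_image`` synthetic displaced copies.

    Parents are never mutated; each child inherits its parent's split, so
    the total is ``n_original * (1 + n_per_image)`` when originals are kept.
    """
    if n_per_image < 1:
        raise ValueError("n_per_image must be >= 1")
    cfg = cfg or AugmentationConfig()
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    out: list[PairRecord] = []
    for rec in dataset:
        if keep_originals:
            out.append(rec)
        for _ in range(n_per_image):
            out.append(augment_record(rec, sample_rigid_params(cfg, rng)))
    return RegistrationDataset(out)


def sweep_synthetic_count(
    dataset: RegistrationDataset,
    counts,
    train_and_score,
    cfg: AugmentationConfig | None = None,
    tolerance: float = 0.01,
    seed: int = 0,
):
    """Score a train-and-evaluate callback at each augmentation count.

    ``train_and_score(augmented_dataset, n)`` must return a goodness score
    (e.g. held-out R^2) for a model trained on the augmented dataset; every
    count is scored on the same held-out originals.  Returns
    ``(curve, elbow)`` where ``curve`` is a list of (n, score) and ``elbow``
    is the smallest n whose score is within ``tolerance`` of the plateau
    (the maximum score over the sweep).
    """
    counts = list(counts)
    if not counts:
        raise ValueError("counts must be non-empty")
    cfg = cfg or AugmentationConfig()
    curve = []
    for i, n in enumerate(counts):
        rng = np.random.default_rng(np.random.SeedSequence([seed, i]))
        aug = augment_dataset(dataset, n, cfg, rng=rng)
        curve.append((n, float(train_and_score(aug, n))))
    plateau = max(s for _, s in curve)
    elbow = next(n for n, s in curve if s >= plateau - tolerance)
    return curve, elbow
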