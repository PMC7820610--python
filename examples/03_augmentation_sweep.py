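"""Rigid augmentation and the synthetic-count selection sweep.

Each co-registered pair is multiplied by random rigid displacements
(rotation up to 15 degrees about a random axis, translations up to 5
voxels).  The sweep trains/scores a model per augmentation count and picks
the elbow — the smallest count within tolerance of the plateau.  Here the
scoring callback is a cheap stand-in (a saturating function of the count)
so the example runs in seconds; the pipeline uses held-out R^2.
"""

import dataclasses as dc

import numpy as np

from headreg import (
    AugmentationConfig,
    PhantomSpec,
    augment_dataset,
    generate_dataset,
    sample_rigid_params,
    sweep_synthetic_count,
)

small = lambda rng: dc.replace(PhantomSpec(), dims=(16, 16, 8), semi_axes=(5.5, 4.0, 2.2), structures=())
dataset = generate_dataset(4, spec_sampler=small, seed=0)

cfg = AugmentationConfig(seed=1)
p = sample_rigid_params(cfg, np.random.default_rng(1))
print(f"one sampled displacement: {p.as_array().round(2)} (deg / voxels)")

augmented = augment_dataset(dataset, n_per_image=9, cfg=cfg)
print(f"{len(dataset)} originals -> {len(augmented)} pairs after 9 synthetic copies each")

counts = [4, 9, 14, 19, 24]
curve, elbow = sweep_synthetic_count(
    dataset, counts, lambda ds, n: 1.0 - np.exp(-n / 6.0), cfg=cfg
)
for n, score in curve:
    print(f"  n = {n:3d}  score = {score:.3f}")
print(f"elbow choice: n = {elbow} (smallest count within 0.01 of the plateau)")
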