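"""Automatic modality identification and pair ordering.

The registration CNN backbone with a softmax head learns to tell MRI-like
from CT-like volumes; order_pair then presents any input pair to the
registration stage as (fixed = MRI, moving = CT), making the pipeline fully
automatic.  A same-modality pair is refused with an explicit ambiguity
error instead of a silent wrong ordering.
"""

from headreg import (
    AmbiguousModalityError,
    AugmentationConfig,
    DCNNConfig,
    Modality,
    augment_dataset,
    build_classifier,
    classify_modality,
    generate_dataset,
    order_pair,
    train_classifier,
)

dataset = generate_dataset(8, seed=0)
augmented = augment_dataset(dataset, 4, AugmentationConfig(seed=1))
volumes, labels = [], []
for rec in augmented.subset("train"):
    volumes += [rec.fixed, rec.moving]
    labels += [Modality.MRI, Modality.CT]

clf = build_classifier(DCNNConfig(seed=1))
clf, _ = train_classifier(clf, volumes, labels, clf.cfg)

rec = dataset.subset("test")[0]
for vol, name in ((rec.fixed, "MRI-like"), (rec.moving, "CT-like")):
    pred = classify_modality(clf, vol)
    print(f"{name:8s} -> {pred.label.value}  P(MRI)={pred.probabilities[0]:.3f}")

fixed, moving = order_pair(clf, rec.moving, rec.fixed)  # deliberately swapped
print(f"order_pair returned fixed={fixed.modality.value}, moving={moving.modality.value}")

try:
    order_pair(clf, rec.moving, rec.moving.copy())
except AmbiguousModalityError as exc:
    print(f"same-modality pair rejected: {exc}")
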