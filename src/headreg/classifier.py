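"""Modality identification (MRI vs CT) to automate fixed/moving ordering.

The classifier reuses the registration backbone with the regression head
replaced by a 2-class softmax trained with cross-entropy; the training
strategy (optimizer, schedule, validation split) is unchanged.  A correctly
ordered pair has the MRI volume as the fixed image and the CT volume as the
moving image.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .network import (
    DCNNConfig,
    SequentialModel,
    build_dcnn,
    softmax,
    train_model,
    volume_to_input,
)
from .volume import Modality, Volume

#: class index convention: 0 = MRI, 1 = CT
CLASS_LABELS = (Modality.MRI, Modality.CT)


@dataclass(frozen=True)
class ModalityPrediction:
    label: Modality
    probabilities: tuple[float, float]  # (P(MRI), P(CT))

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, float)
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("probabilities must be non-negative and sum to 1")


class AmbiguousModalityError(ValueError):
    """Raised when a pair cannot be ordered (same predicted modality)."""

    def __init__(self, msg: str, prediction_a: ModalityPrediction, prediction_b: ModalityPrediction):
        super().__init__(msg)
        self.prediction_a = prediction_a
        self.prediction_b = prediction_b


def build_classifier(cfg: DCNNConfig | None = None) -> SequentialModel:
    """Same backbone as the regression network, softmax head over 2 classes."""
    cfg = replace(cfg or DCNNConfig(), n_outputs=2)
    return build_dcnn(cfg)


def train_classifier(model: SequentialModel, volumes, labels, cfg: DCNNConfig | None = None):
    """Train on labelled single volumes with the shared SGDM strategy.

    ``labels`` may be Modality values or 0/1 integers (0 = MRI, 1 = CT);
    at least one example of each class is required.
    """
    cfg = cfg or model.cfg
    y = np.array(
        [l if isinstance(l, (int, np.integer)) else CLASS_LABELS.index(l) for l in labels],
        dtype=int,
    )
    if len(set(y.tolist())) < 2:
        raise ValueError("training set must contain both modalities")
    inputs = np.concatenate([volume_to_input(v, cfg) for v in volumes], axis=0)
    history = train_model(model, inputs, y, cfg, loss="cross_entropy")
    return model, history


def classify_modality(model: SequentialModel, v: Volume) -> ModalityPrediction:
    """Deterministic modality prediction; exact ties break toward MRI."""
    logits = model.forward(volume_to_input(v, model.cfg), train=False)
    probs = softmax(logits)[0]
    label = CLASS_LABELS[0] if probs[0] >= probs[1] else CLASS_LABELS[1]
    return ModalityPrediction(label=label, probabilities=(float(probs[0]), float(probs[1])))


def order_pair(
    model: SequentialModel, a: Volume, b: Volume, min_confidence: float = 0.6
) -> tuple[Volume, Volume]:
    """Return (fixed = MRI, moving = CT) regardless of input order.

    Raises :class:`AmbiguousModalityError` when both volumes get the same
    label or either prediction falls below the confidence floor.
    """
    pa, pb = classify_modality(model, a), classify_modality(model, b)
    if pa.label == pb.label:
        raise AmbiguousModalityError(
            f"both volumes classified as {pa.label.value}; cannot order the pair", pa, pb
        )
    if max(pa.probabilities) < min_confidence or max(pb.probabilities) < min_confidence:
        raise AmbiguousModalityError(
            f"prediction confidence below {min_confidence}; refusing to order the pair", pa, pb
        )
    return (a, b) if pa.label is Modality.MRI else (b, a)
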