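"""End-to-end orchestration of the registration framework.

``run_pipeline`` chains every stage on synthetic phantom data: dataset
generation, rigid augmentation, ground-truth generation spot checks,
modality-classifier training, DCNN feature training, ANN regression on
concatenated pair features, and metric evaluation on held-out pairs.  A
single global seed propagates deterministically to every stage, and the
returned manifest records configs, seeds, and per-stage metrics.

``run_registration_service`` is the inference path for a trained model
set: classify-and-order the input pair, predict the registration, apply
it, and (optionally) score against a ground truth.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np

from .ann import ANNConfig, train_ann
from .augmentation import AugmentationConfig, augment_dataset
from .classifier import build_classifier, classify_modality, order_pair, train_classifier
from .groundtruth import OptimizerConfig, generate_ground_truth
from .metrics import evaluate_registration
from .network import (
    DCNNConfig,
    build_dcnn,
    concat_pair_features,
    dataset_to_arrays,
    extract_features,
    predict_params,
    r_squared,
    train_dcnn,
)
from .phantom import RegistrationDataset, generate_dataset
from .transforms import (
    RegistrationParams,
    apply_transform,
    params_to_transform,
    rotation_angle_deg,
    transform_to_params,
)
from .volume import Modality, Volume


@dataclass(frozen=True)
class PipelineConfig:
    n_subjects: int = 10
    n_per_image: int = 9
    n_ground_truth_checks: int = 2
    seed: int = 0
    out_dir: str | None = None
    scale: str = "desk"  # "desk" | "full"
    augmentation: AugmentationConfig = field(default_factory=AugmentationConfig)
    optimizer: OptimizerConfig = field(default_factory=OptimizerConfig)
    dcnn: DCNNConfig | None = None
    ann: ANNConfig = field(default_factory=ANNConfig)

    def __post_init__(self) -> None:
        if self.scale not in ("desk", "full"):
            raise ValueError(f"unknown scale preset {self.scale!r}")

    def dcnn_config(self) -> DCNNConfig:
        if self.dcnn is not None:
            return self.dcnn
        if self.scale == "full":
            return DCNNConfig.full_preset(seed=self.seed)
        return DCNNConfig(seed=self.seed)


def _pair_features(dcnn, records):
    feats, targets = [], []
    for rec in records:
        f = concat_pair_features(extract_features(dcnn, rec.fixed), extract_features(dcnn, rec.moving))
        feats.append(f)
        targets.append(rec.truth.as_array())
    return np.stack(feats), np.stack(targets)


def run_pipeline(cfg: PipelineConfig | None = None) -> dict:
    """Execute all stages in order on synthetic data; returns the manifest."""
    cfg = cfg or PipelineConfig()
    manifest: dict = {"seed": cfg.seed, "scale": cfg.scale, "stages": {}}

    # 1. phantom dataset (originals are co-registered)
    dataset = generate_dataset(cfg.n_subjects, seed=cfg.seed)
    manifest["stages"]["phantom"] = {
        "n_subjects": cfg.n_subjects,
        "n_train": len(dataset.subset("train")),
        "n_test": len(dataset.subset("test")),
    }

    # 2. rigid augmentation, split-preserving
    aug_cfg = dataclasses.replace(cfg.augmentation, seed=cfg.seed + 1)
    augmented = augment_dataset(dataset, cfg.n_per_image, aug_cfg)
    manifest["stages"]["augmentation"] = {
        "n_per_image": cfg.n_per_image,
        "n_pairs": len(augmented),
    }

    # 3. ground-truth generation spot checks on displaced train pairs
    opt_cfg = dataclasses.replace(cfg.optimizer, seed=cfg.seed + 2)
    checks = []
    synth_train = [r for r in augmented.subset("train") if r.synthetic]
    for rec in synth_train[: cfg.n_ground_truth_checks]:
        T_comp, report = generate_ground_truth(rec.fixed, rec.moving, opt_cfg)
        T_truth = params_to_transform(rec.truth, rec.moving)
        from .transforms import compose, invert  # local to avoid cycle noise

        T_err = compose(invert(T_truth), T_comp)
        err_params = transform_to_params(T_err, rec.moving)
        checks.append(
            {
                "pair": rec.pair_id,
                "rotation_error_deg": rotation_angle_deg(T_err),
                "translation_error_vox": float(
                    np.linalg.norm(err_params.as_array()[3:])
                ),
                "mi_before": report["mi_before"],
                "mi_after": report["mi_after"],
            }
        )
    manifest["stages"]["ground_truth"] = {"checks": checks}

    # 4. modality classifier, trained on the augmented train split
    net_cfg = cfg.dcnn_config()
    clf_volumes, clf_labels = [], []
    for rec in augmented.subset("train"):
        clf_volumes += [rec.fixed, rec.moving]
        clf_labels += [Modality.MRI, Modality.CT]
    clf = build_classifier(net_cfg)
    clf, clf_history = train_classifier(clf, clf_volumes, clf_labels, clf.cfg)
    correct = total = 0
    for rec in dataset.subset("test"):
        correct += classify_modality(clf, rec.fixed).label is Modality.MRI
        correct += classify_modality(clf, rec.moving).label is Modality.CT
        total += 2
    manifest["stages"]["classifier"] = {
        "train_loss": clf_history["train_loss"][-1],
        "test_accuracy": correct / max(total, 1),
    }

    # 5. DCNN regression training
    dcnn = build_dcnn(net_cfg)
    dcnn, dcnn_history = train_dcnn(dcnn, augmented, net_cfg)
    manifest["stages"]["dcnn"] = {
        "train_loss": dcnn_history["train_loss"][-1],
        "val_loss": dcnn_history["val_loss"][-1],
    }

    # 6. ANN regression on concatenated pair features
    feats, targets = _pair_features(dcnn, augmented.subset("train"))
    ann = train_ann(feats, targets, cfg.ann)
    manifest["stages"]["ann"] = {"trainer": cfg.ann.trainer}

    # 7. evaluation on held-out pairs
    test_records = augmented.subset("test")
    reports, preds, truths = [], [], []
    for rec in test_records:
        f = concat_pair_features(extract_features(dcnn, rec.fixed), extract_features(dcnn, rec.moving))
        p = RegistrationParams.from_array(ann.predict(f))
        preds.append(p.as_array())
        truths.append(rec.truth.as_array())
        registered = apply_transform(rec.moving, params_to_transform(p, rec.moving))
        truth_reg = apply_transform(rec.moving, params_to_transform(rec.truth, rec.moving))
        reports.append(evaluate_registration(rec.fixed, registered, truth_reg).as_dict())
    eval_stage: dict = {"reports": reports}
    if len(test_records) >= 2:
        pooled, per_param = r_squared(np.stack(preds), np.stack(truths))
        eval_stage["ann_pooled_r2"] = pooled
        eval_stage["ann_per_param_r2"] = per_param.tolist()
    manifest["stages"]["evaluation"] = eval_stage

    if cfg.out_dir:
        os.makedirs(cfg.out_dir, exist_ok=True)
        from .persist import save_ann, save_dcnn

        save_dcnn(dcnn, os.path.join(cfg.out_dir, "dcnn.npz"))
        save_dcnn(clf, os.path.join(cfg.out_dir, "classifier.npz"))
        save_ann(ann, os.path.join(cfg.out_dir, "ann.npz"))
        with open(os.path.join(cfg.out_dir, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2, default=float)
    manifest["_models"] = {"dcnn": dcnn, "classifier": clf, "ann": ann}
    return manifest


def run_registration_service(
    fixed: Volume,
    moving: Volume,
    dcnn,
    classifier,
    ann,
    ground_truth: RegistrationParams | None = None,
    min_confidence: float = 0.6,
) -> dict:
    """Fully automated registration of one input pair.

    The modality classifier orders the inputs (fixed = MRI, moving = CT);
    order-ambiguity errors from the classifier surface verbatim.
    """
    fixed, moving = order_pair(classifier, fixed, moving, min_confidence=min_confidence)
    f = concat_pair_features(extract_features(dcnn, fixed), extract_features(dcnn, moving))
    params = RegistrationParams.from_array(ann.predict(f))
    registered = apply_transform(moving, params_to_transform(params, moving))
    result = {"params": params, "registered": registered, "fixed": fixed, "moving": moving}
    if ground_truth is not None:
        truth_reg = apply_transform(moving, params_to_transform(ground_truth, moving))
        result["metrics"] = evaluate_registration(fixed, registered, truth_reg).as_dict()
    return result
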