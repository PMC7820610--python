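"""Desk-scale evaluation benchmarks for the registration framework.

Each benchmark regenerates its synthetic study data from a seed, runs the
relevant stage end to end, and reports summary numbers.  Problem sizes are
chosen for single-CPU desk-scale runs: 64 x 64 x 16 phantoms, 20 ground-truth
pairs, ~200 training pairs for the learning stage.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .ann import ANNConfig, train_ann
from .augmentation import AugmentationConfig, augment_dataset, sample_rigid_params
from .classifier import build_classifier, classify_modality, train_classifier
from .groundtruth import OptimizerConfig, compare_symmetry_benefit, generate_ground_truth
from .metrics import binarize_for_overlap, overlap_metrics
from .network import (
    DCNNConfig,
    build_dcnn,
    concat_pair_features,
    extract_features,
    predict_params,
    r_squared,
    train_dcnn,
)
from .phantom import default_spec_sampler, generate_dataset, make_pair
from .transforms import (
    RegistrationParams,
    apply_transform,
    compose,
    invert,
    params_to_transform,
    rotation_angle_deg,
    transform_to_params,
)


def _sub_seed(seed: int, *tags: int) -> int:
    return int(np.random.SeedSequence([seed, *tags]).generate_state(1)[0] % (2**31 - 1))


def ground_truth_benchmark(seed: int = 0, n_pairs: int = 20) -> dict:
    """Parameter recovery of the symmetry-assisted ground-truth generator.

    Random phantoms displaced by rotations up to 15 degrees and translations
    up to 5 voxels; reports the median rotation error (degrees) and median
    translation error (voxels) of the recovered transform.
    """
    rng = np.random.default_rng(_sub_seed(seed, 1))
    aug_cfg = AugmentationConfig()
    rot_errs, tr_errs = [], []
    for i in range(n_pairs):
        spec = default_spec_sampler(rng)
        p = sample_rigid_params(aug_cfg, rng)
        fixed, moving, truth = make_pair(spec, p, seed=_sub_seed(seed, 2, i))
        T_comp, _ = generate_ground_truth(fixed, moving, OptimizerConfig(seed=_sub_seed(seed, 3, i)))
        T_err = compose(invert(params_to_transform(truth, moving)), T_comp)
        rot_errs.append(rotation_angle_deg(T_err))
        tr_errs.append(float(np.linalg.norm(transform_to_params(T_err, moving).as_array()[3:])))
    return {
        "median_rotation_error_deg": float(np.median(rot_errs)),
        "median_translation_error_vox": float(np.median(tr_errs)),
        "rotation_errors": rot_errs,
        "translation_errors": tr_errs,
        "n_pairs": n_pairs,
    }


def symmetry_benefit_benchmark(seed: int = 0, n_pairs: int = 4, angle_range=(30.0, 45.0)) -> dict:
    """Symmetry-aligned vs plain MI optimization on large-rotation pairs."""
    rng = np.random.default_rng(_sub_seed(seed, 4))
    pairs = []
    for i in range(n_pairs):
        spec = default_spec_sampler(rng)
        angle = float(rng.uniform(*angle_range)) * (1.0 if rng.random() < 0.5 else -1.0)
        p = RegistrationParams(
            rz=angle, tx=float(rng.uniform(-3, 3)), ty=float(rng.uniform(-3, 3))
        )
        fixed, moving, _ = make_pair(spec, p, seed=_sub_seed(seed, 5, i))
        pairs.append((fixed, moving))
    result = compare_symmetry_benefit(pairs, OptimizerConfig(seed=_sub_seed(seed, 6)))
    result["n_pairs"] = n_pairs
    return result


def learning_benchmark(
    seed: int = 0,
    n_subjects: int = 20,
    n_per_image: int = 16,
    n_eval: int = 20,
    ann_epochs: int = 30,
) -> dict:
    """Train the DCNN + ANN registration stack and score held-out pairs.

    Reports the fraction of held-out pairs whose foreground DSC improves
    over the unregistered baseline, plus pooled R^2 of the ANN-on-features
    regressor and of the end-to-end DCNN on the same pairs.
    """
    dataset = generate_dataset(n_subjects, seed=_sub_seed(seed, 7))
    aug = augment_dataset(dataset, n_per_image, AugmentationConfig(seed=_sub_seed(seed, 8)))
    net_cfg = DCNNConfig(seed=_sub_seed(seed, 9))
    model = build_dcnn(net_cfg)
    model, history = train_dcnn(model, aug, net_cfg)

    def feats_of(records):
        F, T = [], []
        for r in records:
            F.append(
                concat_pair_features(
                    extract_features(model, r.fixed), extract_features(model, r.moving)
                )
            )
            T.append(r.truth.as_array())
        return np.stack(F), np.stack(T)

    train_records = aug.subset("train")
    eval_records = [r for r in aug.subset("test") if r.synthetic][:n_eval]
    F_train, T_train = feats_of(train_records)
    F_eval, T_eval = feats_of(eval_records)
    ann = train_ann(
        F_train, T_train, ANNConfig(seed=_sub_seed(seed, 10), max_epochs=ann_epochs)
    )
    pred_ann = ann.predict(F_eval)
    ann_r2, _ = r_squared(pred_ann, T_eval)
    pred_dcnn = np.stack([predict_params(model, r.moving).as_array() for r in eval_records])
    dcnn_r2, _ = r_squared(pred_dcnn, T_eval)

    improved = 0
    for rec, p in zip(eval_records, pred_ann):
        T = params_to_transform(RegistrationParams.from_array(p), rec.moving)
        registered = apply_transform(rec.moving, T)
        mask_fixed = binarize_for_overlap(rec.fixed)
        dsc_before = overlap_metrics(mask_fixed, binarize_for_overlap(rec.moving))[0]
        dsc_after = overlap_metrics(mask_fixed, binarize_for_overlap(registered))[0]
        improved += int(dsc_after > dsc_before)
    return {
        "improved_fraction": improved / max(len(eval_records), 1),
        "n_eval": len(eval_records),
        "n_train": len(train_records),
        "ann_pooled_r2": float(ann_r2),
        "dcnn_pooled_r2": float(dcnn_r2),
        "final_train_loss": history["train_loss"][-1],
        "models": {"dcnn": model, "ann": ann},
    }


def classifier_benchmark(seed: int = 0, n_subjects: int = 16, n_per_image: int = 4) -> dict:
    """Held-out modality-classification accuracy on phantom volumes.

    Trained on the rigid-augmented train split (every displaced copy keeps
    its parent's modality label) and scored on held-out subjects.
    """
    dataset = generate_dataset(n_subjects, seed=_sub_seed(seed, 11))
    aug = augment_dataset(dataset, n_per_image, AugmentationConfig(seed=_sub_seed(seed, 13)))
    cfg = DCNNConfig(seed=_sub_seed(seed, 12))
    clf = build_classifier(cfg)
    volumes, labels = [], []
    for rec in aug.subset("train"):
        volumes += [rec.fixed, rec.moving]
        labels += [0, 1]
    clf, _ = train_classifier(clf, volumes, labels, clf.cfg)
    correct = total = 0
    for rec in aug.subset("test"):
        correct += int(classify_modality(clf, rec.fixed).label.value == "MRI")
        correct += int(classify_modality(clf, rec.moving).label.value == "CT")
        total += 2
    return {"accuracy": correct / max(total, 1), "n_test_volumes": total, "model": clf}
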