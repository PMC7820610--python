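"""Train the CNN feature extractor + ANN regressor and register a pair.

A small end-to-end run: phantom dataset, rigid augmentation, CNN trained to
regress the six registration parameters, 128 features per image tapped at
the global average pool, concatenated pair features fed to a
Bayesian-regularized ANN, and the prediction applied and scored.  Expect a
couple of minutes on one CPU; enlarge the dataset for better accuracy.
"""

import numpy as np

from headreg import (
    ANNConfig,
    AugmentationConfig,
    DCNNConfig,
    RegistrationParams,
    apply_transform,
    augment_dataset,
    build_dcnn,
    concat_pair_features,
    evaluate_registration,
    extract_features,
    generate_dataset,
    params_to_transform,
    train_ann,
    train_dcnn,
)

dataset = generate_dataset(8, seed=2)
augmented = augment_dataset(dataset, 6, AugmentationConfig(seed=3))
print(f"{len(augmented.subset('train'))} training pairs, {len(augmented.subset('test'))} test pairs")

cfg = DCNNConfig(seed=4)
dcnn = build_dcnn(cfg)
dcnn, history = train_dcnn(dcnn, augmented, cfg)
print(f"CNN final train loss (half-MSE): {history['train_loss'][-1]:.3f}")

feats, targets = [], []
for rec in augmented.subset("train"):
    f = concat_pair_features(extract_features(dcnn, rec.fixed), extract_features(dcnn, rec.moving))
    feats.append(f)
    targets.append(rec.truth.as_array())
ann = train_ann(np.stack(feats), np.stack(targets), ANNConfig(seed=5, max_epochs=25))

rec = [r for r in augmented.subset("test") if r.synthetic][0]
f = concat_pair_features(extract_features(dcnn, rec.fixed), extract_features(dcnn, rec.moving))
pred = RegistrationParams.from_array(ann.predict(f))
registered = apply_transform(rec.moving, params_to_transform(pred, rec.moving))
truth_reg = apply_transform(rec.moving, params_to_transform(rec.truth, rec.moving))
report = evaluate_registration(rec.fixed, registered, truth_reg)

print(f"truth params     : {rec.truth.as_array().round(2)}")
print(f"predicted params : {pred.as_array().round(2)}")
print(f"overlap with ground-truth registration: DSC {report.dsc:.3f}, SSIM {report.ssim:.3f}")
# DSC near 1 means the predicted transform lands the moving image on the
# same pose the ground-truth transform does.
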