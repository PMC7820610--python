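"""Symmetry-assisted ground-truth registration of a displaced pair.

A CT-like moving image is displaced by a known rigid transform; the
ground-truth generator re-estimates that transform without ever seeing it:
both images are PCA-aligned into their symmetry poses, the aligned pair is
registered by 1+1 evolutionary maximization of mutual information, and the
stage transforms are composed as T_fix^-1 * T_reg * T_mov.
"""

import numpy as np

from headreg import (
    OptimizerConfig,
    PhantomSpec,
    RegistrationParams,
    compose,
    generate_ground_truth,
    invert,
    make_pair,
    params_to_transform,
    transform_to_params,
)
from headreg.transforms import rotation_angle_deg

displacement = RegistrationParams(rx=6.0, ry=-4.0, rz=10.0, tx=3.0, ty=-2.0, tz=1.0)
fixed, moving, truth = make_pair(PhantomSpec(), displacement, seed=11)

T_comp, report = generate_ground_truth(fixed, moving, OptimizerConfig(seed=0))

T_err = compose(invert(params_to_transform(truth, moving)), T_comp)
err_params = transform_to_params(T_err, moving)

print(f"applied displacement : {displacement.as_array().round(2)}")
print(f"recovered (composed) : {transform_to_params(T_comp, moving).as_array().round(2)}")
print(f"rotation error       : {rotation_angle_deg(T_err):.2f} degrees")
print(f"translation error    : {np.linalg.norm(err_params.as_array()[3:]):.2f} voxels")
print(f"mutual information   : {report['mi_before']:.3f} -> {report['mi_after']:.3f}")
# Sub-degree / sub-voxel recovery: the PCA pre-alignment removes most of the
# displacement and the MI optimizer refines the residual.
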