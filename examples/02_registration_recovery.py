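"""Recovering a known deformation of the tensor phantom.

Warps the synthetic tensor brain by a known affine, registers it back
under the deviatoric metric, and prints the mean displacement error
before and after — the basic sanity check of the registration engine.
"""

import numpy as np

from tensorxfer import RegistrationConfig, register_tensor
from tensorxfer.registration import (
    AffineTransform,
    ComposedTransform,
    PiecewiseAffineTransform,
    _target_domain,
    apply_transform_tensor,
    mean_displacement_error,
)
from tensorxfer.synthetic import PhantomSpec, make_template

template = make_template(PhantomSpec(seed=0))
lo, hi = _target_domain(template)

angle = np.deg2rad(7.0)
rot = np.array([[np.cos(angle), -np.sin(angle), 0],
                [np.sin(angle), np.cos(angle), 0], [0, 0, 1.0]])
truth = PiecewiseAffineTransform((1, 1, 1), lo, hi, a=(rot * 1.04)[None],
                                 t=np.array([[3.0, -4.0, 2.0]]))
subject = apply_transform_tensor(template, truth, template)

result = register_tensor(subject, template, RegistrationConfig.affine_only())
identity = AffineTransform.identity()
before = mean_displacement_error(truth, identity, template,
                                 mask=template.mask)
after = mean_displacement_error(ComposedTransform(truth, result.transform),
                                identity, template, mask=template.mask)
print(f"true deformation magnitude : {before:.2f} voxels")
print(f"residual after registration: {after:.2f} voxels")
print(f"objective: {result.objective_trajectory[0]:.3e} -> "
      f"{result.objective_trajectory[-1]:.3e} "
      f"({len(result.objective_trajectory)} accepted steps)")
# A residual well under half a voxel means the estimated pull-back map
# composed with the true warp is close to the identity.
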