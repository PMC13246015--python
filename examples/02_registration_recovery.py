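"""Recover a known interval deformation by intensity-based registration.

Registers the restaging image onto the baseline image (intensities only —
no segmentations), then propagates the baseline tumor mask through the
recovered field and compares the implied volume change with the ground
truth built into the pair.
"""

import numpy as np

from regresponse import StudyConfig, mask_volume, register, warp_mask
from regresponse.synthetic import make_interval_deformation, make_phantom

config = StudyConfig(seed=1)
pre_image, pancreas, tumor = make_phantom(config, seed_key=(1, 0, 1))
true_field, post_image, pancreas_post, tumor_post = make_interval_deformation(
    pre_image, pancreas, tumor, rho=0.7, config=config, seed_key=(1, 0, 3)
)

field = register(fixed=post_image, moving=pre_image)  # fixed = restaging scan

v_pre = mask_volume(tumor)
pct_true = (mask_volume(tumor_post) / v_pre - 1) * 100
pct_reg = (mask_volume(warp_mask(tumor, field)) / v_pre - 1) * 100

sp = np.asarray(pre_image.spacing).reshape(3, 1, 1, 1)
err = np.sqrt((((field.displacement - true_field.displacement) / sp) ** 2).sum(axis=0))
mean_err = err[pancreas_post.voxels.astype(bool)].mean()

print(f"true   percent volume change: {pct_true:+6.1f} %")
print(f"recovered (registration):     {pct_reg:+6.1f} %")
print(f"mean displacement error over the pancreas: {mean_err:.2f} voxels")
# The registration-assisted volume change should track the truth within a
# few percentage points, with sub-voxel mean displacement error.
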