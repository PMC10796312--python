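"""Preprocess one phantom and build its augmented copies.

Shows the acquisition-to-network path for a single subject: anisotropic
native volume -> 1.5 mm isotropic resample -> 60 mm nodule-centred crop
(40^3 voxels) -> [0,1] normalisation -> 61 augmented copies under the
minority-class plan (20 translations, 21 rotations, 20 noisy copies).
"""

import numpy as np

from petnodule import (AugmentationPlan, PhantomSpec, apply_minmax,
                       augment_subject, crop_cube, fit_minmax,
                       generate_phantom, resample_isotropic)

spec = PhantomSpec(seed=7)
vol, ann = generate_phantom(spec, "malignant", np.random.default_rng(7))
print(f"native grid {vol.shape} at spacing {vol.spacing_mm} mm")

iso = resample_isotropic(vol, spec.voxel_mm)
print(f"isotropic grid {iso.shape} at {iso.spacing_mm[0]} mm")

tensor = crop_cube(iso, ann.center_mm, side_mm=60.0)
print(f"network input {tensor.values.shape} "
      f"(nodule of {ann.diameter_mm:.1f} mm centred at voxel 20)")

stats = fit_minmax([tensor])
normed = apply_minmax(tensor, stats)
print(f"normalised range [{normed.values.min():.2f}, "
      f"{normed.values.max():.2f}]")

plan = AugmentationPlan(seed=1)
copies, records = augment_subject(normed.values, "minority", plan,
                                  np.random.default_rng(1),
                                  return_records=True)
kinds = [r["transform"] for r in records]
print(f"{len(copies)} augmented copies: "
      f"{kinds.count('translate')} translations, "
      f"{kinds.count('rotate')} rotations, {kinds.count('noise')} noisy")
# Each augmented example carries exactly one transform; at the default
# factors one minority-class original becomes 62 training images in total.
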