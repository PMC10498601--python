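"""Generate the synthetic abdomen and recover its structures by HU window.

Builds the small noise-free phantom, segments muscle (180-230 HU), vessels
(window derived by sampling the contrast-filled trunk, emulating an aortic
reference sample) and umbilicus, and prints Dice overlap against the exact
ground truth — 1.0 means the segmentation reproduced the truth voxel for
voxel.
"""

import voxflap as vf

vol, truth = vf.make_phantom(vf.PhantomSpec.small())
print(f"phantom: {vol.shape} voxels at {vol.spacing} mm")

mean, vessel_params = vf.sample_reference_range(vol, (32, 20, 16), roi_radius=2.0)
print(f"reference sample mean {mean:.1f} HU -> vessel window "
      f"[{vessel_params.hu_lo:.1f}, {vessel_params.hu_hi:.1f}]")

for name, params, target in (
    ("muscle", vf.SegmentationParams(180, 230), truth.muscle),
    ("vessels", vessel_params, truth.vessels),
    ("umbilicus", vf.SegmentationParams(50, 90), truth.umbilicus),
):
    mask = vf.threshold_segment(vol, params, name=name)
    print(f"{name:9s} {mask.count():6d} voxels, Dice vs truth = "
          f"{vf.dice(mask, target):.3f}")
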