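"""Stamp the 1 cm measured grid onto the muscle and read off perforators.

The grid is two orthogonal families of planes with a linear 1 mm-falloff
halo at full strength — 2 mm wide bands every 10 mm, centered on the
umbilicus. It writes a material channel only: the muscle's shape channel is
bit-identical before and after (checked by hash). Perforator exit points are
then reported as anchor-relative grid cells and cm offsets.
"""

import voxflap as vf

vol, truth = vf.make_phantom(vf.PhantomSpec.small())
spec = vf.GridSpec.from_volume(vol, voxel_size=1.0)
muscle = vf.from_mask(truth.muscle, spec)
muscle.declare_material("grid")

anchor = tuple(truth.umbilicus.centroid())
plane_spec = vf.PlaneArraySpec(spacing=10.0, falloff=1.0, strength=1.0, anchor=anchor)

before = muscle.shape_hash()
overlay = vf.apply_grid_overlay(muscle, plane_spec, material="grid")
print(f"anchor (umbilicus centroid): ({anchor[0]:.1f}, {anchor[1]:.1f}, {anchor[2]:.1f}) mm")
print(f"shape channel unchanged: {overlay.shape_hash() == before}")
print(f"grid material volume: {vf.measure_volume(overlay, 'material:grid'):.1f} mm^3")

for i, cell in enumerate(vf.map_perforators_to_grid(truth.exit_points, plane_spec)):
    print(f"perforator {i}: cell {cell.cell}, offsets {cell.offsets_cm} cm "
          f"from the umbilicus")
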