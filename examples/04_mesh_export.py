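"""Extract watertight meshes, check printability, write STL + manifest.

Builds a grid-banded muscle, splits it into the band part and the remainder
at the material threshold, verifies every mesh is closed/manifold/positively
oriented, and writes binary STLs plus the JSON print manifest with the
default material mixtures (clear muscle, 80/20 cyan/clear grid).
"""

import os
import tempfile

import voxflap as vf

vol, truth = vf.make_phantom(vf.PhantomSpec.small())
spec = vf.GridSpec.from_volume(vol, voxel_size=1.0)
muscle = vf.from_mask(truth.muscle, spec)
muscle.declare_material("grid")
anchor = tuple(truth.umbilicus.centroid())
banded = vf.apply_grid_overlay(muscle, vf.PlaneArraySpec(anchor=anchor))

grid_mesh, rest_mesh = vf.split_by_material(banded, "grid", threshold=0.5)
out_dir = tempfile.mkdtemp(prefix="voxflap_")
parts = []
for name, mesh in (("grid_bands", grid_mesh), ("muscle_remainder", rest_mesh)):
    report = vf.check_watertight(mesh)
    print(f"{name:16s} {len(mesh.faces):6d} faces, volume {report.signed_volume:9.1f} mm^3, "
          f"watertight={report.passed}")
    vf.write_stl(mesh, os.path.join(out_dir, f"{name}.stl"))
    parts.append(vf.make_part(name, mesh))

manifest = vf.PrintManifest(parts=parts, provenance={"example": "04"})
vf.write_manifest(manifest, os.path.join(out_dir, "manifest.json"))
for p in manifest.parts:
    print(f"{p.name}: mixture {p.mixture}, opacity {p.opacity}, finish {p.finish}")
print(f"wrote STLs + manifest to {out_dir}")
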