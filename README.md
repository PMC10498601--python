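# voxflap

Hybrid voxel/mesh modeling for multi-material 3D-printed DIEP-flap
presurgical planning models.

## The problem

A DIEP (Deep Inferior Epigastric Perforator) free-flap breast reconstruction
hinges on locating the perforator vessels that pierce the rectus abdominis
muscle. Patient-specific 3D prints from CT angiography help, but composing
them is awkward in pure surface-mesh tools: boolean operations between a
muscle mesh and dozens of thin vessel meshes are computationally prohibitive
and prone to non-manifold output. `voxflap` takes the hybrid route: anatomy
is segmented from CT by Hounsfield window, composited on a regular voxel
grid where booleans are per-voxel arithmetic, annotated with a measured
reference grid through a material (color) channel that cannot alter the
geometry, and only then converted back to watertight STL meshes for polyjet
multi-material printing.

## The model

A compositing grid carries a **shape channel** `s(v) ∈ [0,1]` (occupancy)
and named **material channels** `m_i(v) ∈ [0,1]` with `Σ m_i ≤ 1`. A layer
stack is folded bottom-up:

- `subtract`: `s ← max(0, s − ℓ)` — carve vessel/umbilicus voids,
- `add`: `s ← min(1, s + ℓ)` — add support struts,
- `material_add`: `m ← min(1, m + w·ℓ)` (or supersede, `max`) where
  `ℓ > 0` and `s > 0` — color edits that leave `s` bit-identical.

The measured grid is two orthogonal families of planes (spacing 10 mm,
anchored on the umbilicus) radiating a linear halo
`h(d) = strength · max(0, 1 − d/falloff)`; with full strength and a 1 mm
falloff each band is exactly 2 mm wide between zero crossings. Vessel voxels
are classified **intra-muscular** where the (lumen-filled) muscle contains
them, **extra-muscular** elsewhere; the two sets partition the vessel
support. Marching cubes at the material-gradient midpoint (level 0.5)
extracts per-part surfaces, every part is verified closed, manifold and
positively oriented before STL export, and the pigment mixtures (clear
muscle, 80 % cyan / 20 % clear grid, magenta vs. magenta+cyan vessels)
travel in a JSON print manifest.

A seeded synthetic abdomen phantom — curved muscle slab in the 180–230 HU
window, a contrast-filled trunk + perforator tree in 900–1100 HU, an
umbilicus cone, fat background, optional noise — provides exact ground truth
for every stage.

## Worked example

```bash
python examples/05_full_pipeline.py
```

prints (default 128×128×96 phantom, 1 mm voxels):

```
6 parts exported to /tmp/voxflap_pipeline_...:
  muscle_remainder 108704 faces,   79426.7 mm^3, mixture {'clear': 1.0}
  grid_bands        88856 faces,   20381.0 mm^3, mixture {'cyan': 0.8, 'clear': 0.2}
  vessels_intra      1344 faces,     368.0 mm^3, mixture {'magenta': 0.5, 'cyan': 0.5}
  vessels_extra      8552 faces,    3625.8 mm^3, mixture {'magenta': 1.0}
  umbilicus           944 faces,     481.7 mm^3, mixture {'yellow': 1.0}
  struts              976 faces,     305.7 mm^3, mixture {'yellow': 1.0}
perforator grid coordinates (cells/offsets from the umbilicus):
  perforator 0: cell (0, -4), offsets (0.0, -3.4) cm
  perforator 1: cell (0, -2), offsets (0.0, -1.6) cm
  perforator 2: cell (0, 2), offsets (0.0, 2.4) cm
```

Each part is a watertight binary STL; the perforator lines read as "this
perforator exits the muscle 1.6 cm inferior to the umbilicus", i.e. the
coordinates a surgeon reads off the printed centimetre ruling. The other
examples (`examples/01`–`04`) walk through segmentation, compositing,
the grid overlay and mesh export individually.

The same pipeline runs from the shell:

```bash
voxflap pipeline --out out/            # default config + built-in phantom
voxflap phantom --out phantom/ --seed 1
voxflap segment --volume phantom/volume.nii.gz --out masks/
```

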