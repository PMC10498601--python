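"""Voxelization, layer compositing, material arithmetic, containment."""

import numpy as np
import pytest
import trimesh

import voxflap as vf
from voxflap.errors import ConfigurationError, GeometryError


# ---------------------------------------------------------------------------
# Independent point-in-mesh oracle (Moller-Trumbore along a skew ray),
# algorithmically unrelated to the production parity rasterizer.
# ---------------------------------------------------------------------------

_RAY_DIR = np.array([0.1234567, 0.7654321, 1.0])
_RAY_DIR /= np.linalg.norm(_RAY_DIR)


def _inside_oracle(mesh: trimesh.Trimesh, points: np.ndarray) -> np.ndarray:
    v0 = mesh.triangles[:, 0]
    e1 = mesh.triangles[:, 1] - v0
    e2 = mesh.triangles[:, 2] - v0
    h = np.cross(_RAY_DIR, e2)
    a = np.einsum("ij,ij->i", e1, h)
    ok = np.abs(a) > 1e-12
    inside = np.zeros(len(points), dtype=bool)
    for i, p in enumerate(points):
        s = p - v0
        u = np.einsum("ij,ij->i", s, h) / np.where(ok, a, 1.0)
        q = np.cross(s, e1)
        v = q @ _RAY_DIR / np.where(ok, a, 1.0)
        t = np.einsum("ij,ij->i", e2, q) / np.where(ok, a, 1.0)
        hits = ok & (u >= 0) & (v >= 0) & (u + v <= 1) & (t > 0)
        inside[i] = hits.sum() % 2 == 1
    return inside


# ---------------------------------------------------------------------------
# Voxelization
# ---------------------------------------------------------------------------


def test_unit_cube_voxelization_counts_interior_centers():
    cube = trimesh.creation.box(extents=(10, 10, 10))
    cube.apply_translation((5, 5, 5))
    spec = vf.GridSpec(bounds_lo=(0.5,) * 3, bounds_hi=(9.5,) * 3, voxel_size=1.0)
    grid = vf.voxelize_mesh(cube, spec)
    assert int(grid.shape.sum()) == 1000
    assert vf.measure_volume(grid) == pytest.approx(1000.0)


def test_sphere_voxelization_volume_and_oracle_agreement():
    sphere = trimesh.creation.icosphere(subdivisions=3, radius=5.0)
    spec = vf.GridSpec(bounds_lo=(-5,) * 3, bounds_hi=(5,) * 3, voxel_size=0.5)
    grid = vf.voxelize_mesh(sphere, spec)
    analytic = 4 / 3 * np.pi * 5**3
    assert vf.measure_volume(grid) == pytest.approx(analytic, rel=0.02)
    # spot-check inside/outside against the independent ray-cast oracle
    xs, ys, zs = spec.axis_centers()
    rng = np.random.default_rng(3)
    idx = np.stack([rng.integers(0, n, 300) for n in spec.dims], axis=1)
    pts = np.stack([xs[idx[:, 0]], ys[idx[:, 1]], zs[idx[:, 2]]], axis=1)
    oracle = _inside_oracle(sphere, pts)
    ours = grid.shape[idx[:, 0], idx[:, 1], idx[:, 2]] > 0.5
    assert np.array_equal(ours, oracle)


def test_voxelize_rejects_mesh_with_hole():
    cube = trimesh.creation.box(extents=(10, 10, 10))
    cube = trimesh.Trimesh(vertices=cube.vertices, faces=cube.faces[:-1], process=False)
    spec = vf.GridSpec(bounds_lo=(-5,) * 3, bounds_hi=(5,) * 3, voxel_size=1.0)
    with pytest.raises(GeometryError, match="3 open edges"):
        vf.voxelize_mesh(cube, spec)


# ---------------------------------------------------------------------------
# Mask intake
# ---------------------------------------------------------------------------


def _random_mask(shape=(10, 10, 10), p=0.3, seed=0, spacing=(1.0, 1.0, 1.0)):
    rng = np.random.default_rng(seed)
    return vf.LabelMask(
        data=(rng.random(shape) < p), spacing=spacing, origin=(0, 0, 0), name="other"
    )


def test_from_mask_identity_at_matching_resolution():
    mask = _random_mask()
    spec = vf.GridSpec.from_volume(mask, voxel_size=1.0, padding=2.0)
    grid = vf.from_mask(mask, spec)
    assert int(grid.shape.sum()) == mask.count()
    # the mask occupies the interior region offset by the padding
    np.testing.assert_array_equal(grid.shape[2:12, 2:12, 2:12], mask.data.astype(float))


def test_from_mask_refinement_maps_each_voxel_to_eight():
    mask = _random_mask(shape=(6, 6, 6))
    spec = vf.GridSpec(
        bounds_lo=(0, 0, 0), bounds_hi=(5, 5, 5), voxel_size=0.5, padding=0.25
    )
    grid = vf.from_mask(mask, spec)
    assert int(grid.shape.sum()) == 8 * mask.count()


def test_from_mask_empty_gives_empty_grid():
    mask = vf.LabelMask(
        data=np.zeros((5, 5, 5), dtype=np.uint8), spacing=(1, 1, 1), origin=(0, 0, 0)
    )
    spec = vf.GridSpec.from_volume(mask, voxel_size=1.0)
    assert vf.from_mask(mask, spec).shape.sum() == 0


# ---------------------------------------------------------------------------
# Compositing
# ---------------------------------------------------------------------------


def _grid_from(spec, arr):
    return vf.MultiChannelGrid(spec, shape=np.asarray(arr, dtype=np.float64))


def _tiny_spec(n=1):
    return vf.GridSpec(
        bounds_lo=(0, 0, 0), bounds_hi=(n - 1, n - 1, n - 1), voxel_size=1.0, padding=0.0
    )


@pytest.mark.parametrize(
    "base,top,expected", [(1, 1, 0), (1, 0, 1), (0, 1, 0), (0, 0, 0)]
)
def test_subtract_truth_table(base, top, expected):
    spec = _tiny_spec()
    stack = vf.LayerStack(
        layers=[
            vf.Layer(source=_grid_from(spec, [[[base]]]), op="replace"),
            vf.Layer(source=_grid_from(spec, [[[top]]]), op="subtract"),
        ]
    )
    out = vf.composite(stack, spec)
    assert out.shape[0, 0, 0] == expected


def _brute_force_composite(base, layers):
    """Per-voxel loop oracle for subtract/add on binary occupancy arrays."""
    out = base.astype(float).copy()
    it = np.ndindex(out.shape)
    for idx in it:
        v = out[idx]
        for op, arr in layers:
            l = 1.0 if arr[idx] > 0.5 else 0.0
            if op == "subtract":
                v = max(0.0, v - l)
            else:
                v = min(1.0, v + l)
        out[idx] = v
    return out


def test_cube_minus_sphere_matches_per_voxel_oracle():
    spec = vf.GridSpec(bounds_lo=(0.25,) * 3, bounds_hi=(9.75,) * 3, voxel_size=0.5)
    cube = trimesh.creation.box(extents=(10, 10, 10))
    cube.apply_translation((5, 5, 5))
    sphere = trimesh.creation.icosphere(subdivisions=3, radius=4.0)
    sphere.apply_translation((5, 5, 5))
    base = vf.voxelize_mesh(cube, spec)
    top = vf.voxelize_mesh(sphere, spec)
    out = vf.composite(
        vf.LayerStack(
            layers=[vf.Layer(source=base, op="replace"), vf.Layer(source=top, op="subtract")]
        ),
        spec,
    )
    oracle = _brute_force_composite(base.shape, [("subtract", top.shape)])
    np.testing.assert_array_equal(out.shape, oracle)


def test_subtraction_carves_voids_everywhere_the_vessel_sits(small_phantom):
    """After the vessel layer subtracts from the muscle base, no voxel
    occupied by the vessel grid retains muscle shape."""
    vol, truth = small_phantom
    spec = vf.GridSpec.from_volume(vol, voxel_size=1.0)
    muscle = vf.from_mask(truth.muscle, spec)
    vessels = vf.from_mask(truth.vessels, spec)
    out = vf.composite(
        vf.LayerStack(
            layers=[
                vf.Layer(source=muscle, op="replace"),
                vf.Layer(source=vessels, op="subtract"),
            ]
        ),
        spec,
    )
    assert not np.any((vessels.shape > 0.5) & (out.shape > 0))


def test_composite_is_order_sensitive():
    spec = _tiny_spec(2)
    a = np.zeros(spec.dims)
    b = np.zeros(spec.dims)
    a[0, 0, 0] = 1
    b[0, 0, 0] = 1
    b[1, 0, 0] = 1
    s_ab = vf.composite(
        vf.LayerStack(layers=[vf.Layer(_grid_from(spec, a), "replace"),
                              vf.Layer(_grid_from(spec, b), "subtract")]), spec)
    s_ba = vf.composite(
        vf.LayerStack(layers=[vf.Layer(_grid_from(spec, b), "replace"),
                              vf.Layer(_grid_from(spec, a), "subtract")]), spec)
    assert not np.array_equal(s_ab.shape, s_ba.shape)


def test_stack_must_start_with_replace_base():
    spec = _tiny_spec()
    with pytest.raises(ConfigurationError):
        vf.LayerStack(layers=[vf.Layer(source=_grid_from(spec, [[[1]]]), op="subtract")])


def test_material_add_requires_declared_material():
    spec = _tiny_spec()
    stack = vf.LayerStack(
        layers=[
            vf.Layer(source=_grid_from(spec, [[[1]]]), op="replace"),
            vf.Layer(source=np.ones(spec.dims), op="material_add", target="material:ink"),
        ],
        materials=(),  # 'ink' not declared
    )
    with pytest.raises(ConfigurationError, match="ink"):
        vf.composite(stack, spec)


# ---------------------------------------------------------------------------
# Material arithmetic
# ---------------------------------------------------------------------------


def _material_grid():
    spec = _tiny_spec(3)
    grid = vf.MultiChannelGrid(spec, shape=np.ones(spec.dims))
    grid.declare_material("a")
    grid.declare_material("b")
    return spec, grid


def test_material_add_leaves_shape_bit_identical():
    spec, grid = _material_grid()
    rng = np.random.default_rng(0)
    grid.shape = rng.random(spec.dims)
    before = grid.shape_hash()
    out = vf.material_add(grid, rng.random(spec.dims), "a", weight=0.7)
    out = vf.material_add(out, rng.random(spec.dims), "b", weight=0.4)
    assert out.shape_hash() == before


def test_material_add_supersedes_on_renormalization():
    spec, grid = _material_grid()
    grid.materials["a"][...] = 1.0
    out = vf.material_add(grid, np.ones(spec.dims), "b", weight=1.0)
    np.testing.assert_allclose(out.material("b"), 1.0)
    np.testing.assert_allclose(out.material("a"), 0.0)
    out.validate()


def test_material_add_outside_shape_is_a_noop():
    spec, grid = _material_grid()
    grid.shape[...] = 0.0
    out = vf.material_add(grid, np.ones(spec.dims), "a")
    np.testing.assert_array_equal(out.material("a"), 0.0)


def test_material_sum_never_exceeds_one():
    spec, grid = _material_grid()
    rng = np.random.default_rng(5)
    out = grid
    for name, w in (("a", 0.9), ("b", 0.8), ("a", 0.6)):
        out = vf.material_add(out, rng.random(spec.dims), name, weight=w)
    total = out.material("a") + out.material("b")
    assert total.max() <= 1.0 + 1e-6
    out.validate()


# ---------------------------------------------------------------------------
# Containment classification
# ---------------------------------------------------------------------------


def _tube_and_slab(slab_z=(8.0, 16.0)):
    spec = vf.GridSpec(bounds_lo=(0, 0, 0), bounds_hi=(23, 23, 23), voxel_size=1.0,
                       padding=0.0)
    tube = np.zeros(spec.dims)
    tube[10:13, 10:13, :] = 1.0  # vertical tube through all z
    slab = np.zeros(spec.dims)
    zs = spec.axis_centers()[2]
    zsel = (zs >= slab_z[0]) & (zs <= slab_z[1])
    slab[:, :, zsel] = 1.0
    return spec, vf.MultiChannelGrid(spec, shape=tube), vf.MultiChannelGrid(spec, shape=slab)


def test_classification_matches_point_in_slab_oracle():
    spec, tube, slab = _tube_and_slab()
    intra, extra = vf.classify_by_containment(tube, slab)
    zs = spec.axis_centers()[2]
    for idx in np.argwhere(tube.shape > 0.5):
        z = zs[idx[2]]
        expect_intra = 8.0 <= z <= 16.0
        assert bool(intra.data[tuple(idx)]) == expect_intra
        assert bool(extra.data[tuple(idx)]) == (not expect_intra)


def test_classification_partitions_vessel_support():
    spec, tube, slab = _tube_and_slab()
    intra, extra = vf.classify_by_containment(tube, slab)
    v = tube.shape > 0.5
    assert not np.any(intra.data & extra.data)
    np.testing.assert_array_equal((intra.data | extra.data).astype(bool), v)


def test_classification_degenerate_cases():
    spec, tube, slab = _tube_and_slab()
    empty = vf.MultiChannelGrid(spec)
    intra, extra = vf.classify_by_containment(tube, empty)
    assert intra.count() == 0 and extra.count() == int(tube.shape.sum())
    full = vf.MultiChannelGrid(spec, shape=np.ones(spec.dims))
    intra, extra = vf.classify_by_containment(tube, full)
    assert extra.count() == 0 and intra.count() == int(tube.shape.sum())


def test_classification_rejects_mismatched_specs():
    spec, tube, _ = _tube_and_slab()
    other_spec = vf.GridSpec(bounds_lo=(0, 0, 0), bounds_hi=(23, 23, 23), voxel_size=0.5)
    with pytest.raises(GeometryError):
        vf.classify_by_containment(tube, vf.MultiChannelGrid(other_spec))


# ---------------------------------------------------------------------------
# Volume measurement and conservation
# ---------------------------------------------------------------------------


def test_measure_volume_arithmetic():
    spec = vf.GridSpec(bounds_lo=(0, 0, 0), bounds_hi=(4.5, 4.5, 4.5), voxel_size=0.5,
                       padding=0.0)
    shape = np.zeros(spec.dims)
    shape.ravel()[:1000] = 1.0
    grid = vf.MultiChannelGrid(spec, shape=shape)
    assert vf.measure_volume(grid) == pytest.approx(125.0)
    assert vf.measure_volume(vf.MultiChannelGrid(spec)) == 0.0
    with pytest.raises(ConfigurationError):
        vf.measure_volume(grid, "material:missing")


def test_volume_conservation_identity_on_random_binary_grids():
    """V(base) = V(base - top) + V(base AND top), exactly, per seed."""
    spec = vf.GridSpec(bounds_lo=(0, 0, 0), bounds_hi=(15, 15, 15), voxel_size=1.0,
                       padding=0.0)
    rng = np.random.default_rng(11)
    for _ in range(10):
        base = (rng.random(spec.dims) < 0.5).astype(float)
        top = (rng.random(spec.dims) < 0.5).astype(float)
        diff = vf.composite(
            vf.LayerStack(layers=[vf.Layer(_grid_from(spec, base), "replace"),
                                  vf.Layer(_grid_from(spec, top), "subtract")]), spec)
        inter = base * top
        v = lambda arr: float(arr.sum()) * spec.voxel_size**3
        assert v(base) == v(diff.shape) + v(inter)
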