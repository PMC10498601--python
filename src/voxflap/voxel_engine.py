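"""Multi-channel voxel substrate and layer compositing.

This is the core of the hybrid modeling approach: anatomy is discretized onto
a regular voxel grid carrying one *shape* channel (geometric occupancy in
[0, 1]) and any number of named *material* channels (per-voxel material
fractions). Boolean-style edits — carving vessel voids out of the muscle,
adding support struts — are cheap per-voxel arithmetic instead of mesh-domain
boolean operations, and material edits (the measured grid, intra-muscular
vessel coloring) change color channels only, leaving the morphology untouched.

Layers are evaluated strictly bottom-up: layer 0 replaces the shape channel
(the base anatomy, e.g. the rectus abdominis muscle); subsequent layers
subtract from it (vessels, umbilicus), add to it (struts), or write material
channels. Boolean layers operate on occupancy binarized at 0.5.
"""

from __future__ import annotations

import hashlib
import logging
import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import trimesh

from .errors import ConfigurationError, GeometryError, UnsupportedInputError
from .volumes import LabelMask, ScalarVolume

logger = logging.getLogger("voxflap")

_EPS = 1e-6
# Deterministic sub-voxel ray offset so parity ray casting never hits mesh
# vertices/edges exactly (see voxelize_mesh).
_JITTER_SEED = 1905


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a compositing grid: isotropic voxels over a padded box.

    Voxel centers lie at ``(bounds_lo - padding) + i * voxel_size`` per axis
    (the first center sits on the padded corner), so grids built at the source
    image resolution align exactly with the image's voxel centers. Padding
    (default 2 mm) leaves empty voxels around the anatomy so isosurfaces close
    at the grid border.
    """

    bounds_lo: tuple[float, float, float]
    bounds_hi: tuple[float, float, float]
    voxel_size: float = 0.5
    padding: float = 2.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "bounds_lo", tuple(float(v) for v in self.bounds_lo))
        object.__setattr__(self, "bounds_hi", tuple(float(v) for v in self.bounds_hi))
        if self.voxel_size <= 0:
            raise ConfigurationError(f"voxel_size must be > 0, got {self.voxel_size}")
        if self.padding < 0:
            raise ConfigurationError(f"padding must be >= 0, got {self.padding}")
        for lo, hi in zip(self.bounds_lo, self.bounds_hi):
            if hi + self.padding < lo - self.padding:  # single-point bounds are fine
                raise ConfigurationError(
                    f"degenerate grid bounds after padding: [{lo}, {hi}], padding {self.padding}"
                )

    @property
    def lo(self) -> tuple[float, float, float]:
        """World coordinate of the first voxel center per axis."""
        return tuple(b - self.padding for b in self.bounds_lo)

    @property
    def dims(self) -> tuple[int, int, int]:
        return tuple(
            int(math.ceil((hi + self.padding - lo) / self.voxel_size)) + 1
            for lo, hi in zip(self.lo, self.bounds_hi)
        )

    def axis_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return tuple(
            lo + self.voxel_size * np.arange(n) for lo, n in zip(self.lo, self.dims)
        )

    def centers_broadcast(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        xs, ys, zs = self.axis_centers()
        return xs[:, None, None], ys[None, :, None], zs[None, None, :]

    @classmethod
    def from_volume(
        cls, vol: ScalarVolume | LabelMask, voxel_size: float = 0.5, padding: float = 2.0
    ) -> "GridSpec":
        lo = vol.origin
        hi = tuple(
            o + s * (n - 1) for o, s, n in zip(vol.origin, vol.spacing, vol.shape)
        )
        return cls(bounds_lo=lo, bounds_hi=hi, voxel_size=voxel_size, padding=padding)

    @classmethod
    def from_mesh(
        cls, mesh: trimesh.Trimesh, voxel_size: float = 0.5, padding: float = 2.0
    ) -> "GridSpec":
        lo, hi = mesh.bounds
        return cls(
            bounds_lo=tuple(lo), bounds_hi=tuple(hi), voxel_size=voxel_size, padding=padding
        )


class MultiChannelGrid:
    """A voxel grid with one shape channel and named material channels.

    Invariants: all channels share the spec's dimensions; shape and material
    values lie in [0, 1]; the per-voxel material sum is <= 1 (+1e-6); material
    is zero wherever shape is zero.
    """

    def __init__(
        self,
        spec: GridSpec,
        shape: np.ndarray | None = None,
        materials: Mapping[str, np.ndarray] | None = None,
    ) -> None:
        self.spec = spec
        dims = spec.dims
        if shape is None:
            shape = np.zeros(dims, dtype=np.float64)
        shape = np.asarray(shape, dtype=np.float64)
        if shape.shape != dims:
            raise GeometryError(f"shape channel dims {shape.shape} != grid dims {dims}")
        self.shape = shape
        self.materials: dict[str, np.ndarray] = {}
        for name, arr in (materials or {}).items():
            arr = np.asarray(arr, dtype=np.float64)
            if arr.shape != dims:
                raise GeometryError(
                    f"material '{name}' dims {arr.shape} != grid dims {dims}"
                )
            self.materials[name] = arr

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.spec.dims

    def declare_material(self, name: str) -> None:
        if name not in self.materials:
            self.materials[name] = np.zeros(self.dims, dtype=np.float64)

    def material(self, name: str) -> np.ndarray:
        if name not in self.materials:
            raise ConfigurationError(
                f"material '{name}' is not declared (have: {sorted(self.materials)})"
            )
        return self.materials[name]

    def copy(self) -> "MultiChannelGrid":
        return MultiChannelGrid(
            self.spec,
            shape=self.shape.copy(),
            materials={k: v.copy() for k, v in self.materials.items()},
        )

    def binarized(self, threshold: float = 0.5) -> np.ndarray:
        return self.shape > threshold

    def shape_hash(self) -> str:
        """SHA-256 of the shape channel's bytes; bit-level morphology identity."""
        return hashlib.sha256(self.shape.tobytes()).hexdigest()

    def validate(self) -> None:
        if self.shape.min() < -_EPS or self.shape.max() > 1 + _EPS:
            raise GeometryError("shape channel values outside [0, 1]")
        if self.materials:
            total = sum(self.materials.values())
            if total.max() > 1 + _EPS:
                raise GeometryError("per-voxel material sum exceeds 1")
            empty = self.shape == 0
            for name, arr in self.materials.items():
                if arr[empty].any():
                    raise GeometryError(f"material '{name}' present where shape is 0")


@dataclass
class Layer:
    """One compositing layer: a geometry source, an operation, and a target.

    ``replace``/``add``/``subtract`` act on the shape channel;
    ``material_add`` writes a material channel named by ``target``
    (``"material:<name>"``). ``weight``/``mode`` only apply to material
    writes.
    """

    source: object
    op: str = "replace"
    target: str = "shape"
    weight: float = 1.0
    mode: str = "add"

    def __post_init__(self) -> None:
        if self.op not in ("replace", "add", "subtract", "material_add"):
            raise ConfigurationError(f"unknown layer op {self.op!r}")
        if self.op == "material_add":
            if not self.target.startswith("material:"):
                raise ConfigurationError(
                    f"material_add must target 'material:<name>', got {self.target!r}"
                )
        elif self.target != "shape":
            raise ConfigurationError(
                f"op {self.op!r} must target the shape channel, got {self.target!r}"
            )


@dataclass
class LayerStack:
    """Ordered compositing layers (index 0 = base) plus declared materials."""

    layers: list[Layer]
    materials: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.layers:
            raise ConfigurationError("layer stack is empty")
        base = self.layers[0]
        if base.op != "replace" or base.target != "shape":
            raise ConfigurationError(
                "layer 0 must be the base: op 'replace' on the shape channel"
            )


# ---------------------------------------------------------------------------
# Voxelization
# ---------------------------------------------------------------------------


def voxelize_mesh(mesh: trimesh.Trimesh, spec: GridSpec) -> MultiChannelGrid:
    """Rasterize a watertight mesh: shape = 1 at voxel centers inside it.

    Inside/outside is decided by parity ray casting along +x with a fixed
    deterministic sub-voxel lateral ray offset, so rays never pass exactly
    through mesh vertices or edges.
    """
    _require_watertight(mesh)
    xs, ys, zs = spec.axis_centers()
    occ = _parity_voxelize(np.asarray(mesh.triangles, float), xs, ys, zs, spec.voxel_size)
    return MultiChannelGrid(spec, shape=occ.astype(np.float64))


def _require_watertight(mesh: trimesh.Trimesh) -> None:
    if mesh.is_watertight:
        return
    edges = np.sort(mesh.edges, axis=1)
    _, counts = np.unique(edges, axis=0, return_counts=True)
    n_open = int((counts == 1).sum())
    raise GeometryError(f"mesh is not watertight ({n_open} open edges)")


def _parity_voxelize(
    triangles: np.ndarray,
    xs: np.ndarray,
    ys: np.ndarray,
    zs: np.ndarray,
    voxel_size: float,
) -> np.ndarray:
    rng = np.random.default_rng(_JITTER_SEED)
    jy, jz = (rng.random(2) - 0.5) * 1e-3 * voxel_size
    ny, nz = len(ys), len(zs)
    cols: list[np.ndarray] = []
    xhits: list[np.ndarray] = []
    for (v0, v1, v2) in triangles:
        (x0, y0, z0), (x1, y1, z1), (x2, y2, z2) = v0, v1, v2
        det = (y1 - y0) * (z2 - z0) - (y2 - y0) * (z1 - z0)
        if abs(det) < 1e-14:
            continue  # triangle parallel to the ray direction
        ylo, yhi = min(y0, y1, y2), max(y0, y1, y2)
        zlo, zhi = min(z0, z1, z2), max(z0, z1, z2)
        j0 = int(np.searchsorted(ys, ylo - jy, side="left"))
        j1 = int(np.searchsorted(ys, yhi - jy, side="right"))
        k0 = int(np.searchsorted(zs, zlo - jz, side="left"))
        k1 = int(np.searchsorted(zs, zhi - jz, side="right"))
        if j0 >= j1 or k0 >= k1:
            continue
        py = ys[j0:j1, None] + jy - y0
        pz = zs[None, k0:k1] + jz - z0
        a = (py * (z2 - z0) - pz * (y2 - y0)) / det
        b = (pz * (y1 - y0) - py * (z1 - z0)) / det
        inside = (a >= 0) & (b >= 0) & (a + b <= 1)
        if not inside.any():
            continue
        jj, kk = np.nonzero(inside)
        x = x0 + a[inside] * (x1 - x0) + b[inside] * (x2 - x0)
        cols.append((j0 + jj) * nz + (k0 + kk))
        xhits.append(x)

    occ = np.zeros((len(xs), ny, nz), dtype=bool)
    if not cols:
        return occ
    col = np.concatenate(cols)
    xh = np.concatenate(xhits)
    order = np.lexsort((xh, col))
    col, xh = col[order], xh[order]
    starts = np.flatnonzero(np.r_[True, col[1:] != col[:-1]])
    ends = np.r_[starts[1:], len(col)]
    odd_cols = 0
    for s, e in zip(starts, ends):
        crossings = xh[s:e]
        if (e - s) % 2:
            odd_cols += 1
            crossings = crossings[: e - s - 1]
        j, k = divmod(int(col[s]), nz)
        for x_in, x_out in zip(crossings[0::2], crossings[1::2]):
            i0 = int(np.searchsorted(xs, x_in, side="left"))
            i1 = int(np.searchsorted(xs, x_out, side="left"))
            occ[i0:i1, j, k] = True
    if odd_cols:
        logger.warning("parity voxelization: %d columns had odd crossing counts", odd_cols)
    return occ


def from_mask(mask: LabelMask, spec: GridSpec) -> MultiChannelGrid:
    """Resample a binary mask onto a grid (nearest neighbour, half-open ties).

    Each grid voxel center maps to the nearest source voxel per axis using
    ``floor(x + 0.5)``, i.e. exact half-way ties resolve upward, giving
    half-open cells and a deterministic refinement (a 1 mm source voxel maps
    to exactly 8 voxels of a 0.5 mm grid).
    """
    if not mask.data.any():
        logger.warning("from_mask: mask '%s' is empty", mask.name)
    out = np.zeros(spec.dims, dtype=np.float64)
    idx = []
    valid = []
    for ax in range(3):
        centers = spec.axis_centers()[ax]
        i = np.floor((centers - mask.origin[ax]) / mask.spacing[ax] + 0.5).astype(int)
        ok = (i >= 0) & (i < mask.shape[ax])
        idx.append(np.clip(i, 0, mask.shape[ax] - 1))
        valid.append(ok)
    sub = mask.data[np.ix_(idx[0], idx[1], idx[2])].astype(np.float64)
    sub *= valid[0][:, None, None]
    sub *= valid[1][None, :, None]
    sub *= valid[2][None, None, :]
    out[...] = sub
    return MultiChannelGrid(spec, shape=out)


# ---------------------------------------------------------------------------
# Compositing
# ---------------------------------------------------------------------------


def _source_field(source: object, spec: GridSpec) -> np.ndarray:
    """Turn a layer source into a scalar field on the grid."""
    if isinstance(source, MultiChannelGrid):
        if source.spec != spec:
            raise GeometryError("layer grid spec does not match the stack's grid spec")
        return source.shape
    if isinstance(source, LabelMask):
        return from_mask(source, spec).shape
    if isinstance(source, trimesh.Trimesh):
        return voxelize_mesh(source, spec).shape
    if callable(source):  # e.g. a plane-halo field generator
        arr = np.asarray(source(spec), dtype=np.float64)
    else:
        arr = np.asarray(source, dtype=np.float64)
    if arr.shape != spec.dims:
        raise GeometryError(f"layer field dims {arr.shape} != grid dims {spec.dims}")
    return arr


def composite(stack: LayerStack, spec: GridSpec) -> MultiChannelGrid:
    """Evaluate a layer stack strictly bottom-up on the given grid.

    Boolean semantics on the shape channel (layer fields binarized at 0.5):
    ``subtract`` -> max(0, below - layer); ``add`` -> min(1, below + layer).
    ``material_add`` layers write material channels and never change shape.
    Material channels are zeroed wherever the shape channel ends up empty.
    """
    grid = MultiChannelGrid(spec)
    for name in stack.materials:
        grid.declare_material(name)
    for i, layer in enumerate(stack.layers):
        if layer.op == "material_add":
            name = layer.target.split(":", 1)[1]
            if name not in grid.materials:
                raise ConfigurationError(
                    f"layer {i}: material '{name}' is not declared in the stack"
                )
            support = _source_field(layer.source, spec)
            grid = material_add(grid, support, name, layer.weight, mode=layer.mode)
            continue
        field = (_source_field(layer.source, spec) > 0.5).astype(np.float64)
        if layer.op == "replace":
            grid.shape = field
        elif layer.op == "add":
            grid.shape = np.minimum(1.0, grid.shape + field)
        elif layer.op == "subtract":
            grid.shape = np.maximum(0.0, grid.shape - field)
        empty = grid.shape == 0
        for arr in grid.materials.values():
            arr[empty] = 0.0
    return grid


def material_add(
    grid: MultiChannelGrid,
    support: np.ndarray,
    material: str,
    weight: float = 1.0,
    mode: str = "add",
) -> MultiChannelGrid:
    """Write a material channel where ``support > 0``; morphology unaltered.

    ``mode="add"``: target = min(1, existing + weight * support) — additive
    arithmetic compositing. ``mode="max"``: target = min(1, max(existing,
    weight * support)) — supersede semantics, idempotent (used by the grid
    overlay). Competing materials are scaled down proportionally so the
    per-voxel material sum stays <= 1. The shape channel is bit-identical to
    the input.
    """
    if not 0.0 < weight <= 1.0:
        raise ConfigurationError(f"material weight must be in (0, 1], got {weight}")
    if mode not in ("add", "max"):
        raise ConfigurationError(f"unknown material_add mode {mode!r}")
    support = np.asarray(support, dtype=np.float64)
    if support.shape != grid.dims:
        raise GeometryError(f"support dims {support.shape} != grid dims {grid.dims}")
    out = grid.copy()
    target = out.material(material)
    sel = (support > 0) & (out.shape > 0)
    if not sel.any():
        return out
    contrib = weight * support[sel]
    if mode == "add":
        new = np.minimum(1.0, target[sel] + contrib)
    else:
        new = np.minimum(1.0, np.maximum(target[sel], contrib))
    target[sel] = new
    others = [arr for name, arr in out.materials.items() if name != material]
    if others:
        other_sum = sum(arr[sel] for arr in others)
        over = new + other_sum > 1.0 + _EPS
        if over.any():
            scale = np.ones_like(other_sum)
            nz = over & (other_sum > 0)
            scale[nz] = np.maximum(0.0, 1.0 - new[nz]) / other_sum[nz]
            for arr in others:
                vals = arr[sel]
                vals[nz] *= scale[nz]
                arr[sel] = vals
    return out


def classify_by_containment(
    vessels: MultiChannelGrid, muscle: MultiChannelGrid
) -> tuple[LabelMask, LabelMask]:
    """Split vessel voxels into intra-/extra-muscular by muscle containment.

    ``intra`` holds vessel voxels where the (pre-subtraction) muscle shape is
    > 0.5, ``extra`` the rest; the two masks partition the vessel support.
    """
    if vessels.spec != muscle.spec:
        raise GeometryError("vessel and muscle grids have different specs")
    v = vessels.shape > 0.5
    m = muscle.shape > 0.5
    spacing = (vessels.spec.voxel_size,) * 3
    origin = vessels.spec.lo
    intra = LabelMask(data=v & m, spacing=spacing, origin=origin, name="vessels_intra")
    extra = LabelMask(data=v & ~m, spacing=spacing, origin=origin, name="vessels_extra")
    return intra, extra


def measure_volume(grid: MultiChannelGrid, channel: str = "shape") -> float:
    """Volume (mm^3) of a channel: sum of values times the voxel volume."""
    if channel == "shape":
        arr = grid.shape
    elif channel.startswith("material:"):
        arr = grid.material(channel.split(":", 1)[1])
    else:
        raise ConfigurationError(
            f"unknown channel {channel!r}; expected 'shape' or 'material:<name>'"
        )
    return float(arr.sum()) * grid.spec.voxel_size**3
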