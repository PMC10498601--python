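"""Isosurface extraction, watertightness checks, STL export, print manifest.

Composited grids leave the voxel domain here: marching cubes extracts a
closed triangle surface per part at the midpoint of the material gradient
(level 0.5), channels are zero-padded first so surfaces cap at the grid
border, and every mesh is verified watertight before it may be written to
binary STL. Since STL carries no color, the per-part pigment mixtures,
opacities and finishes travel in a JSON print manifest alongside the STLs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field as dc_field
from typing import Mapping, Sequence

import numpy as np
import trimesh
from scipy import ndimage
from skimage import measure as sk_measure

from ._raster import segment_mask
from .errors import ConfigurationError, EmptySurfaceError, GeometryError
from .voxel_engine import GridSpec, MultiChannelGrid

logger = logging.getLogger("voxflap")


# ---------------------------------------------------------------------------
# Isosurface extraction
# ---------------------------------------------------------------------------


def _channel_array(grid: MultiChannelGrid, channel: str) -> np.ndarray:
    if channel == "shape":
        return grid.shape
    if channel.startswith("material:"):
        return grid.material(channel.split(":", 1)[1])
    raise ConfigurationError(
        f"unknown channel {channel!r}; expected 'shape' or 'material:<name>'"
    )


def extract_isosurface(
    grid: MultiChannelGrid,
    channel: str = "shape",
    level: float = 0.5,
    smooth_sigma: float = 0.5,
) -> trimesh.Trimesh:
    """Extract a watertight triangle mesh from one channel of a grid.

    The default level of 0.5 is the midpoint of the material gradient between
    absent (0) and full (1). ``smooth_sigma`` (in voxels; 0 disables) applies
    a Gaussian to the channel before extraction to soften marching-cubes
    faceting; volume-conservation checks should run with it off. The channel
    is zero-padded by one voxel so surfaces reaching the grid border are
    capped; vertices are returned in world mm.
    """
    field = _channel_array(grid, channel).astype(np.float64)
    if smooth_sigma > 0:
        field = ndimage.gaussian_filter(field, sigma=smooth_sigma)
    if not (field > level).any():
        raise EmptySurfaceError(
            f"channel {channel!r} has no values above level {level}; nothing to extract"
        )
    return _field_to_mesh(field, grid.spec, level)


def _field_to_mesh(field: np.ndarray, spec: GridSpec, level: float) -> trimesh.Trimesh:
    padded = np.pad(field, 1, mode="constant", constant_values=0.0)
    vs = spec.voxel_size
    verts, faces, _, _ = sk_measure.marching_cubes(padded, level=level, spacing=(vs, vs, vs))
    verts = verts + np.asarray(spec.lo) - vs  # padded index p <-> world lo + (p-1)*vs
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=True)
    if mesh.volume < 0:
        mesh.invert()
    if not mesh.is_watertight:
        raise GeometryError("isosurface extraction produced a non-watertight mesh")
    return mesh


def empty_mesh() -> trimesh.Trimesh:
    return trimesh.Trimesh(vertices=np.zeros((0, 3)), faces=np.zeros((0, 3), dtype=int))


def split_by_material(
    grid: MultiChannelGrid,
    material: str,
    threshold: float = 0.5,
    smooth_sigma: float = 0.0,
) -> tuple[trimesh.Trimesh, trimesh.Trimesh]:
    """Quantize shape support by a material fraction and mesh both halves.

    Voxels within the shape support whose material fraction exceeds the
    threshold are quantized to material 1, the rest to material 2; closed
    isosurfaces are extracted from both binary fields, trimmed by the shape
    channel (the material field is masked by binarized shape before
    quantization so material surfaces never extend beyond anatomy). With
    smoothing off the two meshes' shared interface coincides exactly, giving
    a watertight split whose voxelized supports partition the shape support.
    An all-material grid yields an empty second mesh.
    """
    shape_bin = grid.binarized()
    frac = _channel_array(grid, f"material:{material}") * shape_bin
    quant = (frac > threshold) & shape_bin
    rest = shape_bin & ~quant
    if not quant.any():
        raise EmptySurfaceError(
            f"material '{material}' has no support above threshold {threshold}"
        )
    mesh_mat = _binary_to_mesh(quant, grid.spec, smooth_sigma)
    mesh_rest = _binary_to_mesh(rest, grid.spec, smooth_sigma) if rest.any() else empty_mesh()
    return mesh_mat, mesh_rest


def _binary_to_mesh(
    binary: np.ndarray, spec: GridSpec, smooth_sigma: float
) -> trimesh.Trimesh:
    field = binary.astype(np.float64)
    if smooth_sigma > 0:
        field = ndimage.gaussian_filter(field, sigma=smooth_sigma)
    return _field_to_mesh(field, spec, 0.5)


# ---------------------------------------------------------------------------
# Struts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StrutSpec:
    """A support strut: a capsule between two world points (default r=1.5 mm).

    Struts prop up fragile vessels, thin muscle regions and the umbilicus in
    the printed part; placement is listed explicitly in the config.
    """

    endpoints: tuple[tuple[float, float, float], tuple[float, float, float]]
    radius: float = 1.5

    def __post_init__(self) -> None:
        a = np.asarray(self.endpoints[0], float)
        b = np.asarray(self.endpoints[1], float)
        if np.allclose(a, b):
            raise GeometryError("strut endpoints coincide (zero-length strut)")
        if self.radius <= 0:
            raise GeometryError(f"strut radius must be > 0, got {self.radius}")
        object.__setattr__(self, "endpoints", (tuple(map(float, a)), tuple(map(float, b))))


def generate_strut(spec: StrutSpec, grid_spec: GridSpec) -> MultiChannelGrid:
    """Voxelize a capsule strut (cylinder with hemispherical caps)."""
    occ = np.zeros(grid_spec.dims, dtype=bool)
    xs, ys, zs = grid_spec.axis_centers()
    segment_mask(xs, ys, zs, spec.endpoints[0], spec.endpoints[1], spec.radius, occ)
    return MultiChannelGrid(grid_spec, shape=occ.astype(np.float64))


# ---------------------------------------------------------------------------
# Watertightness
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WatertightReport:
    """Mesh printability report: a mesh passes iff it is closed, manifold,
    consistently wound and positively oriented."""

    open_edges: int
    nonmanifold_edges: int
    flipped_pairs: int
    signed_volume: float

    @property
    def passed(self) -> bool:
        return (
            self.open_edges == 0
            and self.nonmanifold_edges == 0
            and self.flipped_pairs == 0
            and self.signed_volume > 0
        )


def check_watertight(mesh: trimesh.Trimesh) -> WatertightReport:
    """Count open edges, non-manifold edges and flipped-winding pairs."""
    if len(mesh.faces) == 0:
        return WatertightReport(0, 0, 0, 0.0)
    directed = mesh.edges  # (3F, 2) in winding order
    und = np.sort(directed, axis=1)
    _, inverse, counts = np.unique(
        und, axis=0, return_inverse=True, return_counts=True
    )
    open_edges = int((counts == 1).sum())
    nonmanifold = int((counts > 2).sum())
    flipped = 0
    order = np.argsort(inverse, kind="stable")
    sorted_inv = inverse[order]
    sorted_dir = directed[order]
    starts = np.flatnonzero(np.r_[True, sorted_inv[1:] != sorted_inv[:-1]])
    ends = np.r_[starts[1:], len(sorted_inv)]
    for s, e in zip(starts, ends):
        if e - s == 2 and np.array_equal(sorted_dir[s], sorted_dir[s + 1]):
            flipped += 1  # both faces traverse the edge in the same direction
    tri = mesh.triangles
    signed_volume = float(np.einsum("ij,ij->", tri[:, 0], np.cross(tri[:, 1], tri[:, 2])) / 6.0)
    return WatertightReport(open_edges, nonmanifold, flipped, signed_volume)


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

#: Default print styles, mirroring the reference model: clear muscle so the
#: intramuscular vessel course stays visible, an 80/20 cyan/clear grid for
#: legible ruling, 100% magenta extra-muscular vessels, a half-and-half
#: magenta/cyan (purple) for intra-muscular segments, and a distinct opaque
#: color for the umbilicus and support struts.
DEFAULT_PART_STYLES: dict[str, dict] = {
    "muscle_remainder": {"mixture": {"clear": 1.0}, "opacity": "clear", "finish": "glossy"},
    "grid_bands": {"mixture": {"cyan": 0.8, "clear": 0.2}, "opacity": "opaque", "finish": "glossy"},
    "vessels_extra": {"mixture": {"magenta": 1.0}, "opacity": "opaque", "finish": "glossy"},
    "vessels_intra": {"mixture": {"magenta": 0.5, "cyan": 0.5}, "opacity": "opaque", "finish": "glossy"},
    "umbilicus": {"mixture": {"yellow": 1.0}, "opacity": "opaque", "finish": "glossy"},
    "struts": {"mixture": {"yellow": 1.0}, "opacity": "opaque", "finish": "glossy"},
}


@dataclass
class PrintPart:
    """One printable part: a watertight mesh plus its print material."""

    name: str
    mesh: trimesh.Trimesh
    mixture: dict[str, float]
    opacity: str = "opaque"
    finish: str = "glossy"
    stl_name: str | None = None

    def __post_init__(self) -> None:
        total = sum(self.mixture.values())
        if abs(total - 1.0) > 1e-6:
            raise ConfigurationError(
                f"part '{self.name}': mixture fractions sum to {total}, expected 1"
            )
        if any(not 0 <= f <= 1 for f in self.mixture.values()):
            raise ConfigurationError(f"part '{self.name}': mixture fractions outside [0, 1]")
        if self.opacity not in ("clear", "translucent", "opaque"):
            raise ConfigurationError(f"part '{self.name}': unknown opacity {self.opacity!r}")
        if self.finish not in ("glossy", "matte"):
            raise ConfigurationError(f"part '{self.name}': unknown finish {self.finish!r}")
        if self.stl_name is None:
            self.stl_name = f"{self.name}.stl"


@dataclass
class PrintManifest:
    """The machine-readable twin of the print setup: all parts + provenance."""

    parts: list[PrintPart]
    provenance: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        names = [p.name for p in self.parts]
        if len(set(names)) != len(names):
            raise ConfigurationError(f"duplicate part names in manifest: {names}")

    def part(self, name: str) -> PrintPart:
        for p in self.parts:
            if p.name == name:
                return p
        raise KeyError(name)


def make_part(name: str, mesh: trimesh.Trimesh, style: Mapping | None = None) -> PrintPart:
    """Build a PrintPart using the default style table (overridable)."""
    base = dict(DEFAULT_PART_STYLES.get(name, {"mixture": {"white": 1.0}, "opacity": "opaque", "finish": "glossy"}))
    if style:
        base.update(style)
    return PrintPart(name=name, mesh=mesh, mixture=dict(base["mixture"]),
                     opacity=base.get("opacity", "opaque"), finish=base.get("finish", "glossy"))


def write_stl(mesh: trimesh.Trimesh, path: str) -> None:
    """Write a binary little-endian STL (mm); refuses non-watertight meshes."""
    report = check_watertight(mesh)
    if not report.passed:
        raise GeometryError(
            f"refusing to export non-watertight mesh to {path}: "
            f"{report.open_edges} open edges, {report.nonmanifold_edges} non-manifold, "
            f"{report.flipped_pairs} flipped pairs, signed volume {report.signed_volume:.3f}"
        )
    mesh.export(path, file_type="stl")


def read_stl(path: str) -> trimesh.Trimesh:
    mesh = trimesh.load(path, file_type="stl", process=True)
    return mesh


def write_manifest(manifest: PrintManifest, path: str) -> None:
    """Write the print manifest as JSON (per-part STL filename + material)."""
    doc = {
        "parts": [
            {
                "name": p.name,
                "stl": p.stl_name,
                "mixture": p.mixture,
                "opacity": p.opacity,
                "finish": p.finish,
            }
            for p in manifest.parts
        ],
        "provenance": manifest.provenance,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True)
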