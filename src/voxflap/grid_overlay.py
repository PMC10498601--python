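"""Measured grid overlay: plane-halo bands stamped into a material channel.

Two orthogonal families of parallel world-space planes (default 1 cm apart,
anchored on the umbilicus) each radiate a *halo* that fades linearly with
perpendicular distance, dying out at the falloff distance (default 1 mm).
With full strength and 1 mm falloff each band is exactly 2 mm wide between
zero crossings. Composited into a material channel of the muscle grid, the
bands mark a printable centimetre ruling on the muscle surface without
altering its geometry, so perforator locations can be read off as grid
coordinates relative to the umbilicus.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ConfigurationError
from .voxel_engine import GridSpec, MultiChannelGrid, material_add

_ORTHO_TOL = 1e-6


@dataclass(frozen=True)
class PlaneArraySpec:
    """Two orthogonal families of equally spaced planes with linear halos.

    spacing : mm between adjacent plane centers within a family (default 10).
    falloff : mm at which a plane's halo reaches zero (default 1). Must be
        less than spacing/2 so neighbouring bands never merge.
    strength : peak halo value on a plane, in (0, 1] (default 1.0 = 100%).
    anchor : world point (mm) through which one plane of each family passes
        (the umbilicus centroid in the reference pipeline).
    normals : the two unit plane normals (default patient left-right and
        superior-inferior); must be orthogonal.
    """

    spacing: float = 10.0
    falloff: float = 1.0
    strength: float = 1.0
    anchor: tuple[float, float, float] = (0.0, 0.0, 0.0)
    normals: tuple[tuple[float, float, float], tuple[float, float, float]] = (
        (1.0, 0.0, 0.0),
        (0.0, 1.0, 0.0),
    )

    def __post_init__(self) -> None:
        if self.falloff <= 0:
            raise ConfigurationError(f"falloff must be > 0, got {self.falloff}")
        if not self.spacing > 2 * self.falloff:
            raise ConfigurationError(
                f"spacing ({self.spacing}) must exceed twice the falloff "
                f"({self.falloff}) or adjacent bands would merge"
            )
        if not 0.0 < self.strength <= 1.0:
            raise ConfigurationError(f"strength must be in (0, 1], got {self.strength}")
        n1 = np.asarray(self.normals[0], float)
        n2 = np.asarray(self.normals[1], float)
        for n in (n1, n2):
            if abs(np.linalg.norm(n) - 1.0) > _ORTHO_TOL:
                raise ConfigurationError(f"plane normal {n.tolist()} is not unit length")
        if abs(float(n1 @ n2)) > _ORTHO_TOL:
            raise ConfigurationError("plane normals must be orthogonal")
        object.__setattr__(self, "anchor", tuple(float(v) for v in self.anchor))
        object.__setattr__(
            self, "normals", (tuple(map(float, n1)), tuple(map(float, n2)))
        )


def _family_distance(u: np.ndarray, spacing: float) -> np.ndarray:
    """Perpendicular distance to the nearest plane of one family (planes at
    signed offsets k*spacing, k integer)."""
    return np.abs(u - spacing * np.round(u / spacing))


def halo_at(points: np.ndarray, spec: PlaneArraySpec) -> np.ndarray:
    """Halo field value at arbitrary world points, shape (..., 3) -> (...).

    field = strength * max(0, 1 - d / falloff), where d is the distance to
    the nearest plane of either family; families combine by maximum so band
    crossings never exceed the strength.
    """
    p = np.asarray(points, float) - np.asarray(spec.anchor)
    vals = []
    for n in spec.normals:
        u = p @ np.asarray(n)
        d = _family_distance(u, spec.spacing)
        vals.append(spec.strength * np.clip(1.0 - d / spec.falloff, 0.0, None))
    return np.maximum(vals[0], vals[1])


def plane_field(spec: PlaneArraySpec, grid_spec: GridSpec) -> np.ndarray:
    """Evaluate the plane-halo field at every voxel center of a grid."""
    X, Y, Z = grid_spec.centers_broadcast()
    ax, ay, az = spec.anchor
    field = None
    for n in spec.normals:
        u = (X - ax) * n[0] + (Y - ay) * n[1] + (Z - az) * n[2]
        d = _family_distance(u, spec.spacing)
        h = spec.strength * np.clip(1.0 - d / spec.falloff, 0.0, None)
        field = h if field is None else np.maximum(field, h)
    return field


def apply_grid_overlay(
    base: MultiChannelGrid, spec: PlaneArraySpec, material: str = "grid"
) -> MultiChannelGrid:
    """Stamp the grid bands into a material channel of the base grid.

    Delegates to :func:`material_add` with the plane-halo field as support and
    supersede (max) semantics, matching the way the grid layer supersedes the
    base layer's voxel color data: only voxels with base shape > 0 receive
    grid material, the operation is idempotent, and the shape channel is
    bit-identical before and after.
    """
    support = plane_field(spec, base.spec)
    return material_add(base, support, material, weight=1.0, mode="max")


@dataclass(frozen=True)
class PerforatorCell:
    """Grid-coordinate readout for one perforator exit point."""

    point: tuple[float, float, float]
    cell: tuple[int, int]
    offsets_cm: tuple[float, float]


def map_perforators_to_grid(
    points: Sequence, spec: PlaneArraySpec
) -> list[PerforatorCell]:
    """Project perforator exit points into grid cells relative to the anchor.

    Signed in-plane offsets (u, v) are the projections onto the two family
    normals; the cell index is ``floor(offset / spacing)`` (half-open
    anchor-centered cells), and offsets are also reported in cm to one
    decimal.
    """
    out = []
    anchor = np.asarray(spec.anchor)
    n1 = np.asarray(spec.normals[0])
    n2 = np.asarray(spec.normals[1])
    for p in points:
        p = np.asarray(p, float)
        u = float((p - anchor) @ n1)
        v = float((p - anchor) @ n2)
        cell = (int(np.floor(u / spec.spacing)), int(np.floor(v / spec.spacing)))
        offsets = (round(u / 10.0, 1), round(v / 10.0, 1))
        out.append(PerforatorCell(point=tuple(p), cell=cell, offsets_cm=offsets))
    return out
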