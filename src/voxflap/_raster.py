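"""Shared voxel rasterization helpers (capsules along polylines).

All functions take explicit 1-D axis-center arrays (world mm, voxel-center
convention) so they can serve both image-geometry masks and compositing grids.
"""

from __future__ import annotations

import numpy as np


def segment_mask(
    xs: np.ndarray,
    ys: np.ndarray,
    zs: np.ndarray,
    a,
    b,
    radius: float,
    out: np.ndarray,
    value: bool = True,
) -> None:
    """Paint ``value`` into ``out`` at voxel centers within ``radius`` of segment a-b.

    Equivalent to rasterizing a capsule (cylinder with hemispherical caps).
    Operates on the bounding sub-box only; ``out`` is modified in place.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    lo = np.minimum(a, b) - radius
    hi = np.maximum(a, b) + radius
    axes = (xs, ys, zs)
    sl = []
    for ax, lo_i, hi_i in zip(axes, lo, hi):
        i0 = int(np.searchsorted(ax, lo_i, side="left"))
        i1 = int(np.searchsorted(ax, hi_i, side="right"))
        if i0 >= i1:
            return
        sl.append((i0, i1))
    (x0, x1), (y0, y1), (z0, z1) = sl
    px = xs[x0:x1, None, None] - a[0]
    py = ys[None, y0:y1, None] - a[1]
    pz = zs[None, None, z0:z1] - a[2]
    d = b - a
    L2 = float(d @ d)
    if L2 > 0.0:
        t = np.clip((px * d[0] + py * d[1] + pz * d[2]) / L2, 0.0, 1.0)
    else:  # degenerate segment: a sphere
        t = 0.0
    dx = px - t * d[0]
    dy = py - t * d[1]
    dz = pz - t * d[2]
    hit = dx * dx + dy * dy + dz * dz <= radius * radius
    region = out[x0:x1, y0:y1, z0:z1]
    region[hit] = value


def polyline_mask(
    xs: np.ndarray,
    ys: np.ndarray,
    zs: np.ndarray,
    points,
    radius: float,
    out: np.ndarray,
    value: bool = True,
) -> None:
    """Paint a capsule swept along a polyline through ``points``."""
    pts = np.atleast_2d(np.asarray(points, float))
    if len(pts) == 1:
        segment_mask(xs, ys, zs, pts[0], pts[0], radius, out, value)
        return
    for a, b in zip(pts[:-1], pts[1:]):
        segment_mask(xs, ys, zs, a, b, radius, out, value)
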