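"""Shared 2D shape helpers: caliper (Feret) diameters on pixel sets.

Pixel coordinates are augmented with their four corners (±0.5) before the
convex hull so that caliper widths measure pixel extents rather than
center-to-center distances (a 1-pixel-wide line then has width 1, not 0).
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import ConvexHull

_CORNERS = np.array([[-0.5, -0.5], [-0.5, 0.5], [0.5, -0.5], [0.5, 0.5]])


def _hull_points(coords: np.ndarray) -> np.ndarray:
    """Convex hull vertices of corner-augmented pixel coordinates (N, 2)."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 2:
        raise ValueError("expected (N, 2) pixel coordinates")
    pts = (coords[:, None, :] + _CORNERS[None]).reshape(-1, 2)
    if len(pts) > 8:
        # thin out interior points cheaply before the hull
        pts = np.unique(pts, axis=0)
    if len(np.unique(pts[:, 0])) == 1 or len(np.unique(pts[:, 1])) == 1:
        # degenerate (collinear) set: hull would fail; handle directly
        return pts
    hull = ConvexHull(pts)
    return pts[hull.vertices]


def feret_diameters(coords: np.ndarray, spacing: tuple[float, float] = (1.0, 1.0)) -> tuple[float, float]:
    """Minimum and maximum caliper (Feret) diameter of a pixel set.

    Parameters
    ----------
    coords : (N, 2) array of (row, col) pixel indices.
    spacing : physical size of a pixel along (row, col).

    Returns
    -------
    (min_feret, max_feret) in physical units, by rotating calipers on the
    convex hull.
    """
    pts = _hull_points(coords) * np.asarray(spacing, dtype=float)
    if len(pts) == 1:
        return 0.0, 0.0
    # max Feret: largest pairwise distance between hull vertices
    diff = pts[:, None, :] - pts[None, :, :]
    dists = np.hypot(diff[..., 0], diff[..., 1])
    max_f = float(dists.max())
    # min Feret: over hull edges, the farthest point from the edge's line
    edges = np.roll(pts, -1, axis=0) - pts
    lengths = np.hypot(edges[:, 0], edges[:, 1])
    good = lengths > 1e-12
    if not good.any():
        return 0.0, max_f
    normals = np.stack([-edges[good, 1], edges[good, 0]], axis=1) / lengths[good, None]
    # distance of every vertex from every edge line
    proj = np.abs((pts[None, :, :] - pts[good][:, None, :]) @ normals[..., None])[..., 0]
    widths = proj.max(axis=1)
    return float(widths.min()), max_f
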