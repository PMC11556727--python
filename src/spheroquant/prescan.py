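"""Two-pass acquisition emulation, pass one: stitch low-magnification tiles,
detect spheroids in 2D and pick targets for high-magnification re-imaging.

"Width" here is the minimum Feret (caliper) diameter — the stable 2D
analogue of a disc's diameter — and roundness is the isoperimetric ratio
4πA/P² with the Crofton perimeter estimate, which converges to 1 for
digitized discs as the radius grows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import regionprops

from ._shape import feret_diameters

EIGHT_CONN = np.ones((3, 3), dtype=bool)


@dataclass
class Spheroid2DRecord:
    """One detected spheroid in a well montage (physical well coordinates)."""

    record_id: int
    centroid_um: tuple[float, float]  # (y, x)
    area_um2: float
    width_um: float                   # minimum Feret diameter
    roundness: float                  # 4πA / P², Crofton perimeter
    border_touching: bool

    def __post_init__(self):
        if self.area_um2 <= 0:
            raise ValueError("area must be positive")
        if self.roundness > 1.02:
            # discretization can push slightly above 1; more signals a bug
            raise ValueError(f"roundness {self.roundness} above tolerance")


@dataclass
class RescanTarget:
    """A position selected for high-magnification re-imaging."""

    source_record_id: int
    center_um: tuple[float, float]
    extent_um: tuple[float, float, float]  # requested (z, y, x) stack extent

    def __post_init__(self):
        if any(e <= 0 for e in self.extent_um):
            raise ValueError("requested stack extent must be positive")


def stitch_tiles(tiles: list[np.ndarray], grid: tuple[int, int],
                 overlap_px: int = 0) -> np.ndarray:
    """Place tiles row-major on a fixed lattice; later tiles win on overlap.

    No registration is attempted — tiles are assumed to come from a
    calibrated stage, so nominal offsets ``tile_size - overlap`` apply.
    """
    rows, cols = grid
    if len(tiles) != rows * cols:
        raise ValueError(f"expected {rows * cols} tiles for a {rows}x{cols} grid, "
                         f"got {len(tiles)}")
    shapes = {t.shape for t in tiles}
    if len(shapes) != 1:
        raise ValueError(f"tiles differ in shape: {sorted(shapes)}")
    th, tw = tiles[0].shape
    if overlap_px < 0 or overlap_px >= min(th, tw):
        raise ValueError("overlap must be non-negative and smaller than a tile")
    sy, sx = th - overlap_px, tw - overlap_px
    out = np.zeros((sy * (rows - 1) + th, sx * (cols - 1) + tw), dtype=tiles[0].dtype)
    for i, tile in enumerate(tiles):
        r, c = divmod(i, cols)
        out[r * sy:r * sy + th, c * sx:c * sx + tw] = tile
    return out


def detect_spheroids_2d(image: np.ndarray, pixel_size_um: float,
                        sigma_um: float = 5.0,
                        area_min_um2: float = 700.0) -> list[Spheroid2DRecord]:
    """Detect spheroids in a single-plane (or maximum-projected) montage.

    Gaussian smooth → Otsu threshold → hole fill → 8-connected components →
    area filter, then per-component morphometrics.
    """
    image = np.asarray(image)
    if image.ndim == 3:
        image = image.max(axis=0)  # prescan operates on a single plane; MIP stand-in
    if image.ndim != 2:
        raise ValueError(f"expected a 2D image, got ndim={image.ndim}")
    smoothed = ndimage.gaussian_filter(image.astype(np.float64),
                                       sigma=sigma_um / pixel_size_um)
    if smoothed.max() == smoothed.min():
        return []
    mask = smoothed > threshold_otsu(smoothed)
    mask = ndimage.binary_fill_holes(mask)
    labels = cc_label(mask, connectivity=2)
    px_area = pixel_size_um ** 2
    records: list[Spheroid2DRecord] = []
    h, w = mask.shape
    rid = 0
    for prop in regionprops(labels):
        area = prop.num_pixels * px_area
        if area < area_min_um2:
            continue
        coords = prop.coords
        width, _ = feret_diameters(coords, (pixel_size_um, pixel_size_um))
        perimeter = prop.perimeter_crofton * pixel_size_um
        roundness = min(4.0 * np.pi * area / perimeter ** 2, 1.02) if perimeter > 0 else 0.0
        minr, minc, maxr, maxc = prop.bbox
        border = minr == 0 or minc == 0 or maxr == h or maxc == w
        cy, cx = prop.centroid
        rid += 1
        records.append(Spheroid2DRecord(
            record_id=rid,
            centroid_um=((cy + 0.5) * pixel_size_um, (cx + 0.5) * pixel_size_um),
            area_um2=float(area),
            width_um=float(width),
            roundness=float(roundness),
            border_touching=bool(border),
        ))
    return records


def select_rescan_targets(records: list[Spheroid2DRecord], *,
                          area_range_um2: tuple[float, float] = (1000.0, 20000.0),
                          roundness_min: float = 0.8,
                          exclude_border: bool = True,
                          max_per_well: int = 10,
                          stack_extent_um: tuple[float, float, float] = (65.0, 90.0, 90.0),
                          ) -> list[RescanTarget]:
    """Filter detections, rank by area (largest first) and truncate."""
    lo, hi = area_range_um2
    passing = [
        r for r in records
        if lo <= r.area_um2 <= hi
        and r.roundness >= roundness_min
        and not (exclude_border and r.border_touching)
    ]
    passing.sort(key=lambda r: -r.area_um2)
    return [
        RescanTarget(source_record_id=r.record_id, center_um=r.centroid_um,
                     extent_um=stack_extent_um)
        for r in passing[:max_per_well]
    ]
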