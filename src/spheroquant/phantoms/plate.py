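"""Low-magnification well-montage phantoms.

Micropattern sites sit on a square lattice at the plate pitch; each site is
independently occupied with the given probability (occupied-site counts are
therefore binomial across seeds). Occupied sites receive a nuclei-stain disc
whose diameter is drawn from the stated normal distribution. The truth table
lists every occupied site with its center and diameter.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage

from .spec import PlatePhantomSpec

_MARGIN_SITES = 0.75  # lattice margin around the outer sites, in pitch units


def occupancy_draw(spec: PlatePhantomSpec) -> np.ndarray:
    """Boolean occupancy of each lattice site for this spec's seed."""
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 0xB5297A4D]))
    rows, cols = spec.grid_extent
    return rng.random((rows, cols)) < spec.occupancy_probability


def build_well_montage(spec: PlatePhantomSpec, *, render_image: bool = True,
                       ) -> tuple[np.ndarray | None, pd.DataFrame]:
    """Build a 2D nuclei-channel montage image plus its truth table.

    Returns ``(image, truth)``; ``image`` is a uint16 array (or None when
    ``render_image`` is False, which still draws the same occupancy and
    diameters). Truth columns: site_row, site_col, y_um, x_um, diameter_um.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 0xB5297A4D]))
    rows, cols = spec.grid_extent
    occupied = rng.random((rows, cols)) < spec.occupancy_probability
    mean_d, sd_d = spec.spheroid_diameter_um
    n_occ = int(occupied.sum())
    diameters = np.clip(rng.normal(mean_d, sd_d, size=n_occ), 5.0, None)

    pitch = spec.pattern_pitch_um
    margin = _MARGIN_SITES * pitch
    rr, cc = np.nonzero(occupied)
    y_um = margin + rr * pitch
    x_um = margin + cc * pitch
    truth = pd.DataFrame({
        "site_row": rr,
        "site_col": cc,
        "y_um": y_um,
        "x_um": x_um,
        "diameter_um": diameters,
    })

    if not render_image:
        return None, truth

    px = spec.pixel_size_um
    height = int(round(((rows - 1) * pitch + 2 * margin) / px))
    width = int(round(((cols - 1) * pitch + 2 * margin) / px))
    scene = np.zeros((height, width), dtype=np.float64)
    yy = (np.arange(height) + 0.5) * px
    xx = (np.arange(width) + 0.5) * px
    for y0, x0, d in zip(y_um, x_um, diameters):
        r = d / 2.0
        ylo, yhi = np.searchsorted(yy, [y0 - r - px, y0 + r + px])
        xlo, xhi = np.searchsorted(xx, [x0 - r - px, x0 + r + px])
        dy2 = (yy[ylo:yhi] - y0) ** 2
        dx2 = (xx[xlo:xhi] - x0) ** 2
        disc = dy2[:, None] + dx2[None, :] <= r * r
        scene[ylo:yhi, xlo:xhi][disc] = 1.0
    # mild blur + detector noise, as in the 3D renderer
    scene = ndimage.gaussian_filter(scene, sigma=1.0)
    counts = rng.poisson(scene * 200.0).astype(np.float64)
    counts += rng.normal(0.0, 2.0, size=counts.shape) + 20.0
    image = np.clip(np.rint(counts), 0, 65535).astype(np.uint16)
    return image, truth
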