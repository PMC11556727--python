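"""3D segmentation of spheroids, nuclei, cytoplasm and per-cell regions.

All thresholds default to Otsu's method (parameter-free and invariant to
intensity scaling); all distances respect voxel anisotropy (typically 1 μm z
steps against sub-micron xy sampling). Connectivity is 26 in 3D. Watersheds
are deterministic: scikit-image breaks ties by raster order (lowest linear
voxel index).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_multiotsu, threshold_otsu
from skimage.morphology import h_maxima
from skimage.segmentation import watershed

from .stack import ImageStack

log = logging.getLogger(__name__)

CONN_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class CellPartition:
    """Cells as nucleus + assigned cytoplasm; cytoplasm voxels are
    partitioned (each belongs to exactly one cell)."""

    cell_labels: np.ndarray      # nucleus ∪ assigned cytoplasm, per cell
    nuclei_labels: np.ndarray
    cytoplasm_mask: np.ndarray   # all-cell cytoplasm (excludes nuclei)
    nucleus_of: dict[int, int]   # cell id -> nucleus id (identical ids here)

    @property
    def cell_ids(self) -> np.ndarray:
        ids = np.unique(self.cell_labels)
        return ids[ids > 0]


def _smooth(volume: np.ndarray, sigma_um: float,
            voxel_size: tuple[float, float, float]) -> np.ndarray:
    if sigma_um <= 0:
        return volume.astype(np.float32)
    sigma_vox = tuple(sigma_um / v for v in voxel_size)
    return ndimage.gaussian_filter(volume.astype(np.float32), sigma=sigma_vox)


def segment_spheroid(stack: ImageStack, channel: str = "nuclei",
                     sigma_um: float = 2.0,
                     min_volume_um3: float = 1e4,
                     threshold_method: str = "otsu") -> np.ndarray:
    """Segment whole spheroids: smooth, threshold over in-stack voxels, 3D
    hole fill, drop small components, label the rest (26-connectivity).

    ``threshold_method="otsu"`` is the parameter-free default;
    ``"multiotsu3"`` takes the lowest of two three-class Otsu thresholds,
    which captures the full envelope when the stack histogram is trimodal
    (background, dim residual-stain rim, bright nuclear interior) — a
    two-class threshold then lands inside the rim and erodes the boundary.
    An effectively empty channel yields an all-zero labeling, not an error.
    """
    img = _smooth(stack.channel(channel), sigma_um, stack.voxel_size)
    if img.max() == img.min():
        return np.zeros(img.shape, dtype=np.int32)
    if threshold_method == "multiotsu3":
        thresh = threshold_multiotsu(img, classes=3)[0]
    elif threshold_method == "otsu":
        thresh = threshold_otsu(img)
    else:
        raise ValueError(f"unknown threshold method {threshold_method!r}")
    mask = img > thresh
    if not mask.any() or mask.all():
        return np.zeros(img.shape, dtype=np.int32)
    # contrast guard: on a structure-free (noise-only) stack any histogram
    # split produces a mask, but the raw-intensity contrast between the two
    # classes is then on the order of the noise itself
    raw = stack.channel(channel).astype(np.float32)
    bg = raw[~mask]
    if raw[mask].mean() - bg.mean() < 2.0 * bg.std():
        return np.zeros(img.shape, dtype=np.int32)
    mask = ndimage.binary_fill_holes(mask)
    labels, _ = ndimage.label(mask, structure=CONN_26)
    counts = np.bincount(labels.ravel())
    min_vox = min_volume_um3 / stack.voxel_volume
    small = np.flatnonzero(counts < min_vox)
    if len(small):
        labels[np.isin(labels, small)] = 0
    return _compact_labels(labels)


def _compact_labels(labels: np.ndarray) -> np.ndarray:
    """Relabel to contiguous ids 1..n, preserving raster order of first voxels."""
    ids = np.unique(labels)
    ids = ids[ids > 0]
    if len(ids) == 0:
        return labels.astype(np.int32)
    lut = np.zeros(int(labels.max()) + 1, dtype=np.int32)
    lut[ids] = np.arange(1, len(ids) + 1)
    return lut[labels]


def segment_nuclei(stack: ImageStack, spheroid_mask: np.ndarray,
                   channel: str = "nuclei", sigma_um: float = 1.0,
                   h_um: float = 1.0,
                   volume_window_um3: tuple[float, float] = (65.0, 1500.0),
                   ) -> np.ndarray:
    """Segment nuclei inside a spheroid mask.

    Smooth → Otsu within the mask → anisotropic Euclidean distance transform
    → h-maxima seeds (h in μm of distance) → seeded watershed → nuclear
    volume window filter.
    """
    if not spheroid_mask.any():
        return np.zeros(spheroid_mask.shape, dtype=np.int32)
    img = _smooth(stack.channel(channel), sigma_um, stack.voxel_size)
    inside = img[spheroid_mask]
    if inside.max() == inside.min():
        return np.zeros(spheroid_mask.shape, dtype=np.int32)
    mask = spheroid_mask & (img > threshold_otsu(inside))
    if not mask.any():
        return np.zeros(spheroid_mask.shape, dtype=np.int32)
    # the distance transform / watershed only matter inside the spheroid
    # bounding box; work on the crop and paste the labels back
    box = ndimage.find_objects(mask.astype(np.int8))[0]
    box = tuple(slice(max(s.start - 1, 0), s.stop + 1) for s in box)
    mask_c = mask[box]
    dist = ndimage.distance_transform_edt(mask_c, sampling=stack.voxel_size)
    seeds_mask = h_maxima(dist, h_um)
    seeds, _ = ndimage.label(seeds_mask, structure=CONN_26)
    labels_c = watershed(-dist, markers=seeds, mask=mask_c)
    vv = stack.voxel_volume
    counts = np.bincount(labels_c.ravel())
    lo, hi = volume_window_um3
    bad = np.flatnonzero((counts * vv < lo) | (counts * vv > hi))
    bad = bad[bad > 0]
    if len(bad):
        labels_c[np.isin(labels_c, bad)] = 0
    labels = np.zeros(spheroid_mask.shape, dtype=labels_c.dtype)
    labels[box] = labels_c
    return _compact_labels(labels)


def segment_cells(stack: ImageStack, spheroid_labels: np.ndarray,
                  nuclei_labels: np.ndarray, channel: str = "nuclei",
                  sigma_um: float = 1.0,
                  residual_fraction: float = 0.08) -> CellPartition:
    """Partition the residual-stain cytoplasm among nuclei.

    The cytoplasm mask keeps spheroid voxels whose smoothed nuclei-channel
    intensity is at least ``residual_fraction`` of the median intranuclear
    intensity, minus the nuclei themselves. Cell regions come from a seeded
    watershed on the anisotropic distance from the nearest nucleus,
    restricted to the spheroid; each cell is its nucleus plus its assigned
    cytoplasm.
    """
    spheroid_mask = spheroid_labels > 0
    nuc_mask = nuclei_labels > 0
    if not nuc_mask.any():
        empty = np.zeros(nuclei_labels.shape, dtype=np.int32)
        return CellPartition(empty, nuclei_labels, empty.astype(bool), {})
    img = _smooth(stack.channel(channel), sigma_um, stack.voxel_size)
    median_nuclear = float(np.median(img[nuc_mask]))
    cytoplasm = spheroid_mask & (img >= residual_fraction * median_nuclear) & ~nuc_mask
    region = cytoplasm | nuc_mask
    dist_from_nuc = ndimage.distance_transform_edt(~nuc_mask,
                                                   sampling=stack.voxel_size)
    cells = watershed(dist_from_nuc, markers=nuclei_labels, mask=region)
    nucleus_of = {int(i): int(i) for i in np.unique(nuclei_labels) if i > 0}
    # warn when a nucleus straddles two spheroid labels
    if spheroid_labels.max() > 1:
        for nid in nucleus_of:
            sph = spheroid_labels[nuclei_labels == nid]
            sph = sph[sph > 0]
            if len(np.unique(sph)) > 1:
                log.warning("nucleus %d spans multiple spheroids; assigned by majority", nid)
    return CellPartition(cell_labels=cells.astype(np.int32),
                         nuclei_labels=nuclei_labels,
                         cytoplasm_mask=cytoplasm,
                         nucleus_of=nucleus_of)


def gate_egfp(cells: CellPartition, stack: ImageStack, mode: str = "gating",
              channel: str = "egfp",
              background_stats: tuple[float, float] | None = None) -> np.ndarray:
    """Keep cells judged to express the EGFP marker.

    mode='parental' keeps every cell (uniform population naming, as when no
    marker line is present). mode='gating' computes per-cell mean EGFP and
    keeps cells at or above max(background mean + 3·sd, Otsu over the
    per-cell means). ``background_stats`` defaults to statistics of the EGFP
    channel outside all cells.
    """
    ids = cells.cell_ids
    if mode == "parental":
        return ids
    if mode != "gating":
        raise ValueError(f"unknown gating mode {mode!r}")
    if not stack.has_channel(channel):
        raise KeyError(f"gating requires an {channel!r} channel")
    egfp = stack.channel(channel).astype(np.float64)
    sums = ndimage.sum_labels(egfp, cells.cell_labels, index=ids)
    counts = ndimage.sum_labels(np.ones_like(egfp), cells.cell_labels, index=ids)
    means = sums / np.maximum(counts, 1)
    if background_stats is None:
        outside = egfp[cells.cell_labels == 0]
        background_stats = (float(outside.mean()), float(outside.std()))
    bg_mean, bg_sd = background_stats
    thresh = bg_mean + 3.0 * bg_sd
    if len(means) > 1 and means.max() > means.min():
        thresh = max(thresh, float(threshold_otsu(means)))
    return ids[means >= thresh]
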