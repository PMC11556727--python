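"""Volumetric, morphometric and texture features for spheroids, cells and
organelle sets.

Volume is the exact voxel count times the voxel volume. Surface area is the
triangle-mesh area of the 0.5-isosurface (marching cubes with anisotropic
spacing). Sphericity is Wadell's Ψ = π^(1/3)·(6V)^(2/3)/A, reported
unclipped (discretization can push it marginally above 1). Two width
conventions coexist deliberately: the 2D prescan reports the minimum Feret
diameter of a cross-section, while the volumetric spheroid width is the
maximum Feret diameter of the XY projection (the denominator of the
height-to-width aspect ratio).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.measure import marching_cubes, mesh_surface_area

from ._shape import feret_diameters
from .organelles import OrganelleSet
from .segment3d import CellPartition
from .stack import ImageStack


@dataclass
class SpheroidMeasure:
    """Whole-spheroid morphometrics."""

    spheroid_id: int
    volume_um3: float
    surface_area_um2: float
    sphericity: float
    n_nuclei: int
    width_um: float    # max Feret diameter of the XY projection
    height_um: float   # z extent

    def __post_init__(self):
        if self.volume_um3 <= 0 or self.surface_area_um2 <= 0:
            raise ValueError("volume and surface area must be positive")


def measure_region3d(mask: np.ndarray, voxel_size: tuple[float, float, float]) -> dict:
    """Geometry of a single 3D component.

    Returns volume (exact on the voxel grid), mesh surface area, Wadell
    sphericity, centroid (μm), z extent and the max XY Feret diameter of the
    projection. Raises on an empty mask.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("cannot measure an empty mask")
    dz, dy, dx = voxel_size
    n_vox = int(mask.sum())
    volume = n_vox * dz * dy * dx
    area = _mesh_area(mask, voxel_size)
    sphericity = math.pi ** (1.0 / 3.0) * (6.0 * volume) ** (2.0 / 3.0) / area
    zc, yc, xc = ndimage.center_of_mass(mask)
    zs = np.flatnonzero(mask.any(axis=(1, 2)))
    z_extent = (zs[-1] - zs[0] + 1) * dz
    proj = mask.any(axis=0)
    coords = np.argwhere(proj)
    _, feret_max = feret_diameters(coords, (dy, dx))
    return {
        "volume_um3": volume,
        "surface_area_um2": area,
        "sphericity": sphericity,
        "centroid_um": ((zc + 0.5) * dz, (yc + 0.5) * dy, (xc + 0.5) * dx),
        "z_extent_um": float(z_extent),
        "xy_feret_max_um": float(feret_max),
    }


def _mesh_area(mask: np.ndarray, voxel_size) -> float:
    """Marching-cubes surface area of a binary mask (0.5 level, zero-padded
    so surfaces at the array edge are closed).

    For bodies at least a few voxels across in every axis, the mask is
    mollified with a one-voxel Gaussian before meshing: the 0.5 level set of
    the smoothed indicator converges to the true surface as the voxel size
    shrinks, whereas meshing the raw staircase reproduces its ~8% area
    excess at every resolution. Bodies thinner than that (single-voxel
    puncta) are meshed directly — smoothing would erase them.
    """
    mask = np.asarray(mask, dtype=bool)
    zs, ys, xs = np.nonzero(mask)
    extents = (zs.max() - zs.min() + 1, ys.max() - ys.min() + 1,
               xs.max() - xs.min() + 1)
    padded = np.pad(mask.astype(np.float32), 2)
    if min(extents) >= 16:
        # mollification bias scales as (sigma/R)²; below ~8 voxel radius the
        # raw staircase is the smaller error
        padded = ndimage.gaussian_filter(padded, sigma=1.0)
    verts, faces, _, _ = marching_cubes(padded, level=0.5, spacing=voxel_size)
    return float(mesh_surface_area(verts, faces))


def measure_spheroid(spheroid_labels: np.ndarray, nuclei_labels: np.ndarray,
                     voxel_size: tuple[float, float, float],
                     spheroid_id: int = 1) -> SpheroidMeasure:
    """Whole-spheroid measurement: geometry plus the nucleus count.

    A nucleus belongs to the spheroid when its centroid voxel lies inside
    the spheroid label.
    """
    mask = spheroid_labels == spheroid_id
    if not mask.any():
        raise ValueError(f"spheroid label {spheroid_id} is empty")
    geom = measure_region3d(mask, voxel_size)
    n_nuclei = 0
    nuc_ids = np.unique(nuclei_labels)
    nuc_ids = nuc_ids[nuc_ids > 0]
    if len(nuc_ids):
        centroids = ndimage.center_of_mass(nuclei_labels > 0, nuclei_labels, nuc_ids)
        for c in centroids:
            idx = tuple(int(round(v)) for v in c)
            if mask[idx]:
                n_nuclei += 1
    return SpheroidMeasure(
        spheroid_id=spheroid_id,
        volume_um3=geom["volume_um3"],
        surface_area_um2=geom["surface_area_um2"],
        sphericity=geom["sphericity"],
        n_nuclei=n_nuclei,
        width_um=geom["xy_feret_max_um"],
        height_um=geom["z_extent_um"],
    )


def measure_cell_organelles(cells: CellPartition,
                            organelle_sets: list[OrganelleSet],
                            voxel_size: tuple[float, float, float],
                            stack: ImageStack | None = None,
                            pls: dict[str, np.ndarray] | None = None,
                            egfp_channel: str = "egfp",
                            spheroid_id: int = 1) -> pd.DataFrame:
    """Per-cell organelle and texture features.

    For every cell and organelle role: total fragment volume, total mesh
    surface area, fragment count and footprint area (distinct XY pixel
    columns holding at least one organelle voxel of that cell, times the
    pixel area). When a stack with an EGFP channel and PLS maps are given,
    the mean plane_bright and saddle over the cell's cytoplasm are reported,
    normalized by the cell's mean EGFP intensity (making them invariant to
    channel gain).
    """
    for oset in organelle_sets:
        if oset.labels.shape != cells.cell_labels.shape:
            raise ValueError(f"{oset.role} label volume is not aligned with the "
                             "cell partition")
    dz, dy, dx = voxel_size
    vv = dz * dy * dx
    px_area = dy * dx
    ids = cells.cell_ids
    rows = {int(c): {"cell_id": int(c), "spheroid_id": spheroid_id} for c in ids}

    for oset in organelle_sets:
        labels = oset.labels
        counts = np.bincount(labels.ravel())
        objects = ndimage.find_objects(labels)
        # per-cell totals
        vol = {int(c): 0.0 for c in ids}
        nfrag = {int(c): 0 for c in ids}
        frag_ids_of: dict[int, list[int]] = {int(c): [] for c in ids}
        for fid, cid in oset.cell_of.items():
            if cid not in vol:
                continue
            vol[cid] += counts[fid] * vv
            nfrag[cid] += 1
            frag_ids_of[cid].append(fid)
        area = {int(c): 0.0 for c in ids}
        footprint = {int(c): 0.0 for c in ids}
        for cid, fids in frag_ids_of.items():
            if not fids:
                continue
            # total surface area = sum of per-fragment mesh areas (fragments
            # split at watershed saddles are meshed individually)
            total_area = 0.0
            for f in fids:
                slc = objects[f - 1]
                if slc is None:
                    continue
                total_area += _mesh_area(labels[slc] == f, voxel_size)
            area[cid] = total_area
            # footprint from the union of the cell's fragments
            slcs = [objects[f - 1] for f in fids if objects[f - 1] is not None]
            lo = [min(s[d].start for s in slcs) for d in range(3)]
            hi = [max(s[d].stop for s in slcs) for d in range(3)]
            sub = labels[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
            sel = np.isin(sub, fids)
            footprint[cid] = float(sel.any(axis=0).sum()) * px_area
        for cid in rows:
            rows[cid][f"{oset.role}_volume_um3"] = vol.get(cid, 0.0)
            rows[cid][f"{oset.role}_surface_area_um2"] = area.get(cid, 0.0)
            rows[cid][f"{oset.role}_fragment_count"] = nfrag.get(cid, 0)
            rows[cid][f"{oset.role}_footprint_um2"] = footprint.get(cid, 0.0)

    if stack is not None and stack.has_channel(egfp_channel):
        egfp = stack.channel(egfp_channel).astype(np.float64)
        cell_sum = ndimage.sum_labels(egfp, cells.cell_labels, index=ids)
        cell_n = ndimage.sum_labels(np.ones_like(egfp), cells.cell_labels, index=ids)
        mean_egfp = cell_sum / np.maximum(cell_n, 1)
        cyto_labels = np.where(cells.cytoplasm_mask, cells.cell_labels, 0)
        for c, m in zip(ids, mean_egfp):
            rows[int(c)]["egfp_mean_intensity"] = float(m)
        if pls is not None:
            for name in ("plane_bright", "saddle"):
                tot = ndimage.sum_labels(pls[name], cyto_labels, index=ids)
                n = ndimage.sum_labels(np.ones_like(pls[name]), cyto_labels, index=ids)
                raw = tot / np.maximum(n, 1)
                for c, r, m in zip(ids, raw, mean_egfp):
                    rows[int(c)][f"texture_{name}"] = float(r / m) if m > 0 else 0.0
    return pd.DataFrame([rows[int(c)] for c in ids])
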