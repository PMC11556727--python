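"""Rasterization of spheroid phantoms: geometry sampling and ground truth.

The phantom is built in physical coordinates and voxelized onto the
anisotropic grid at the end. Nucleus centers are drawn by minimum-separation
rejection sampling inside the (shrunken) ellipsoid; cell regions are the
nearest-nucleus partition under anisotropic Euclidean distance, clipped to
the ellipsoid; organelles are placed per cell by rejection sampling against
the same partition, so placement truth and partition truth agree exactly.

Sphere centers keep their sub-voxel positions, which makes the voxelized
volume of a population of spheres an unbiased estimate of the analytic
volume (the expected number of lattice points inside a randomly placed body
equals its volume over the voxel volume).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from ..stack import ImageStack
from .spec import PhantomSpec, apply_phenotype

# scene intensities (arbitrary units, scaled by optics.photon_scale at render)
NUCLEUS_INTENSITY = 1.0
RESIDUAL_CYTOPLASM_INTENSITY = 0.2   # weak DNA-stain signal outside nuclei
ORGANELLE_INTENSITY = 1.0
DIFFUSE_ORGANELLE_INTENSITY = 0.04   # unbound antibody background inside the spheroid
EGFP_STRUCTURE_INTENSITY = 1.0
EGFP_CYTOSOL_INTENSITY = 0.5

_NON_EXPRESSING = "negative"


@dataclass
class GroundTruth:
    """True labels and per-object measurements implied by a PhantomSpec."""

    nuclei_labels: np.ndarray
    cell_labels: np.ndarray
    organelle_labels: dict[str, np.ndarray]
    per_cell_truth: pd.DataFrame
    per_spheroid_truth: dict
    fragment_cell_of: dict[str, dict[int, int]] = field(default_factory=dict)


def _voxel_centers(spec: PhantomSpec):
    nz, ny, nx = spec.stack_shape
    dz, dy, dx = spec.voxel_size
    z = (np.arange(nz) + 0.5) * dz
    y = (np.arange(ny) + 0.5) * dy
    x = (np.arange(nx) + 0.5) * dx
    return z, y, x


def _stack_center(spec: PhantomSpec) -> np.ndarray:
    nz, ny, nx = spec.stack_shape
    dz, dy, dx = spec.voxel_size
    return np.array([nz * dz / 2.0, ny * dy / 2.0, nx * dx / 2.0])


def _inside_ellipsoid(points: np.ndarray, center: np.ndarray,
                      half_axes_zyx: np.ndarray, margin: float = 0.0) -> np.ndarray:
    ax = np.maximum(half_axes_zyx - margin, 1e-6)
    q = (points - center) / ax
    return (q * q).sum(axis=-1) <= 1.0


def _uniform_in_ball(rng: np.random.Generator, n: int, radius: float) -> np.ndarray:
    v = rng.standard_normal((n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    r = radius * rng.random(n) ** (1.0 / 3.0)
    return v * r[:, None]


def _random_unit(rng: np.random.Generator, n: int = 1) -> np.ndarray:
    v = rng.standard_normal((n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def _ellipsoid_mask(spec: PhantomSpec) -> np.ndarray:
    z, y, x = _voxel_centers(spec)
    c = _stack_center(spec)
    a_xy, _, c_z = spec.spheroid_half_axes
    zz = ((z - c[0]) / c_z) ** 2
    yy = ((y - c[1]) / a_xy) ** 2
    xx = ((x - c[2]) / a_xy) ** 2
    return (zz[:, None, None] + yy[None, :, None] + xx[None, None, :]) <= 1.0


def _sample_nucleus_centers(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Minimum-separation rejection sampling of nucleus centers (physical μm).

    Nuclei are treated as slightly deformable: the hard minimum center
    separation is 1.8 nuclear radii, which keeps 120 nuclei packable inside
    the shrunken ellipsoid while preventing gross overlap.
    """
    center = _stack_center(spec)
    a_xy, _, c_z = spec.spheroid_half_axes
    half = np.array([c_z, a_xy, a_xy])
    r = spec.nucleus_radius
    min_sep = 1.8 * r
    margin = 0.95 * r
    kept: list[np.ndarray] = []
    tries = 0
    max_tries = 400_000
    while len(kept) < spec.n_cells and tries < max_tries:
        batch = 256
        tries += batch
        pts = center + (rng.random((batch, 3)) * 2.0 - 1.0) * (half - margin)
        ok = _inside_ellipsoid(pts, center, half, margin)
        for p in pts[ok]:
            if kept:
                d = np.linalg.norm(np.asarray(kept) - p, axis=1)
                if d.min() < min_sep:
                    continue
            kept.append(p)
            if len(kept) == spec.n_cells:
                break
    if len(kept) < spec.n_cells:
        raise RuntimeError(
            f"could not place {spec.n_cells} nuclei of radius {r} μm at separation "
            f"{min_sep:.2f} μm inside half axes {spec.spheroid_half_axes}; "
            "reduce n_cells or nucleus_radius"
        )
    return np.asarray(kept)


def _stamp_spheres(labels: np.ndarray, centers: np.ndarray, radii: np.ndarray,
                   ids: np.ndarray, voxel_size) -> None:
    """Write-once rasterization of spheres into an integer label volume.

    Sphere centers keep sub-voxel positions (unbiased voxelized volumes). A
    sphere whose extent straddles no voxel center — possible for sub-voxel
    puncta on the coarse z grid — is floored to the single voxel containing
    its center, so every drawn object materializes in the label truth.
    """
    dz, dy, dx = voxel_size
    nz, ny, nx = labels.shape
    step = np.array([dz, dy, dx])
    for ctr, rad, lab in zip(centers, radii, ids):
        lo = np.maximum(np.floor((ctr - rad) / step - 0.5).astype(int), 0)
        hi = np.minimum(np.ceil((ctr + rad) / step + 0.5).astype(int) + 1,
                        [nz, ny, nx])
        if np.any(lo >= hi):
            continue
        zc = (np.arange(lo[0], hi[0]) + 0.5) * dz - ctr[0]
        yc = (np.arange(lo[1], hi[1]) + 0.5) * dy - ctr[1]
        xc = (np.arange(lo[2], hi[2]) + 0.5) * dx - ctr[2]
        d2 = (zc ** 2)[:, None, None] + (yc ** 2)[None, :, None] + (xc ** 2)[None, None, :]
        sub = labels[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        hit = (d2 <= rad * rad) & (sub == 0)
        if hit.any():
            sub[hit] = lab
        else:
            idx = np.clip(np.floor(ctr / step).astype(int), 0, [nz - 1, ny - 1, nx - 1])
            if labels[idx[0], idx[1], idx[2]] == 0:
                labels[idx[0], idx[1], idx[2]] = lab


class _CellGeometry:
    """Continuous-space membership tests against the nearest-nucleus partition."""

    def __init__(self, spec: PhantomSpec, nucleus_centers: np.ndarray,
                 nucleus_radii: np.ndarray):
        self.spec = spec
        self.centers = nucleus_centers
        self.radii = nucleus_radii
        self.stack_center = _stack_center(spec)
        a_xy, _, c_z = spec.spheroid_half_axes
        self.half = np.array([c_z, a_xy, a_xy])
        # candidate points for cell `cid` can only be claimed by nearby
        # nuclei; restricting the nearest-center test to those makes the
        # rejection sampling O(neighbours) instead of O(all nuclei)
        d2 = ((nucleus_centers[:, None, :] - nucleus_centers[None, :, :]) ** 2).sum(-1)
        reach = (2.0 * float(nucleus_radii.max()) + 16.0) ** 2
        self._neighbors = [np.flatnonzero(row <= reach) for row in d2]

    def membership(self, pts: np.ndarray, cid: int, clearance: float,
                   edge_margin: float) -> np.ndarray:
        """True where a point lies in cell ``cid``'s cytoplasm.

        clearance: required distance beyond the nuclear surface;
        edge_margin: required distance inside the spheroid boundary.
        """
        ok = _inside_ellipsoid(pts, self.stack_center, self.half, edge_margin)
        nbrs = self._neighbors[cid]
        diff = pts[:, None, :] - self.centers[nbrs][None, :, :]
        d2 = (diff * diff).sum(axis=2)
        own = int(np.flatnonzero(nbrs == cid)[0])
        ok &= d2.argmin(axis=1) == own
        ok &= d2[:, own] >= (self.radii[cid] + clearance) ** 2
        return ok

    def sample_in_cytoplasm(self, cid: int, n: int, min_sep: float,
                            rng: np.random.Generator, clearance: float = 0.2,
                            edge_margin: float = 0.3) -> np.ndarray:
        """Rejection-sample ``n`` points in one cell's cytoplasm with a minimum
        pairwise separation; the separation is relaxed geometrically if the
        cell cannot accommodate it."""
        ctr = self.centers[cid]
        reach = self.radii[cid] + 7.0
        kept = np.empty((n, 3))
        n_kept = 0
        sep2 = min_sep * min_sep
        stale = 0
        batches = 0
        while n_kept < n:
            batches += 1
            if batches > 2000:
                raise RuntimeError(
                    f"cannot place {n} objects in cell {cid}'s cytoplasm")
            pts = ctr + _uniform_in_ball(rng, 512, reach)
            pts = pts[self.membership(pts, cid, clearance, edge_margin)]
            added = 0
            for p in pts:
                if n_kept and sep2 > 0:
                    d2 = ((kept[:n_kept] - p) ** 2).sum(axis=1)
                    if d2.min() < sep2:
                        continue
                kept[n_kept] = p
                n_kept += 1
                added += 1
                if n_kept == n:
                    break
            if added == 0:
                stale += 1
                if stale >= 3:
                    sep2 *= 0.64
                    stale = 0
                    if 0 < sep2 < 1e-6:
                        raise RuntimeError(
                            f"cannot place {n} objects in cell {cid}'s cytoplasm"
                        )
            else:
                stale = 0
        return kept

    def sample_juxtanuclear(self, cid: int, n: int, offsets: np.ndarray,
                            pole: np.ndarray, min_sep: float,
                            rng: np.random.Generator) -> np.ndarray:
        """Place ``n`` points hugging the nuclear surface on one side (around
        ``pole``), at per-point radial offsets from the nucleus center."""
        ctr = self.centers[cid]
        kept: list[np.ndarray] = []
        spread = 0.55
        for i in range(n):
            placed = False
            for attempt in range(60):
                d = pole + spread * (1.0 + attempt / 20.0) * rng.standard_normal(3)
                d /= np.linalg.norm(d)
                p = ctr + d * offsets[i]
                ok = self.membership(p[None], cid, clearance=-0.3 * offsets[i],
                                     edge_margin=0.2)[0]
                if not ok:
                    continue
                if kept and np.min(np.linalg.norm(np.asarray(kept) - p, axis=1)) < min_sep:
                    continue
                kept.append(p)
                placed = True
                break
            if not placed:
                # fall back to anywhere in the cytoplasm shell
                p = self.sample_in_cytoplasm(cid, 1, min_sep=0.0, rng=rng,
                                             clearance=0.0)[0]
                kept.append(p)
        return np.asarray(kept)


def _partition_cells(spec: PhantomSpec, nucleus_centers: np.ndarray,
                     ellipsoid: np.ndarray) -> np.ndarray:
    """Nearest-nucleus-center label volume under anisotropic distance."""
    dz, dy, dx = spec.voxel_size
    seeds = np.zeros(spec.stack_shape, dtype=np.int32)
    idx = np.floor(nucleus_centers / np.array([dz, dy, dx])).astype(int)
    idx = np.clip(idx, 0, np.array(spec.stack_shape) - 1)
    seeds[idx[:, 0], idx[:, 1], idx[:, 2]] = np.arange(1, len(nucleus_centers) + 1)
    _, inds = ndimage.distance_transform_edt(
        seeds == 0, sampling=spec.voxel_size, return_indices=True)
    cells = seeds[inds[0], inds[1], inds[2]]
    cells[~ellipsoid] = 0
    return cells


def _fragment_volumes(rng: np.random.Generator, total: float, k: int,
                      concentration: float = 4.0) -> np.ndarray:
    w = rng.dirichlet(np.full(k, concentration))
    return w * total


def _radius_of_volume(v: np.ndarray) -> np.ndarray:
    return np.cbrt(3.0 * np.asarray(v) / (4.0 * math.pi))


def build_spheroid_phantom(spec: PhantomSpec) -> tuple[ImageStack, GroundTruth]:
    """Build a noiseless multichannel scene and its ground truth.

    The returned scene is float32 in arbitrary intensity units; pass it
    through :func:`spheroquant.phantoms.render.render` to obtain a noisy
    16-bit stack. Identical specs (including seed) produce bit-identical
    output.
    """
    spec = apply_phenotype(spec)
    dz, dy, dx = spec.voxel_size
    a_xy, _, c_z = spec.spheroid_half_axes
    center = _stack_center(spec)
    nz, ny, nx = spec.stack_shape

    if (c_z + 1.0 > nz * dz / 2.0) or (a_xy + 1.0 > ny * dy / 2.0) or (a_xy + 1.0 > nx * dx / 2.0):
        raise ValueError(
            f"stack extent {(nz * dz, ny * dy, nx * dx)} μm too small for spheroid "
            f"half axes {spec.spheroid_half_axes} μm plus a 1 μm margin"
        )
    nuc_vol = spec.n_cells * 4.0 / 3.0 * math.pi * spec.nucleus_radius ** 3
    if nuc_vol >= 0.4 * spec.ellipsoid_volume_um3:
        raise ValueError(
            f"packing infeasible: total nuclear volume {nuc_vol:.0f} μm³ is not below "
            f"40% of the ellipsoid volume {spec.ellipsoid_volume_um3:.0f} μm³"
        )

    ss = np.random.SeedSequence([int(spec.seed), 0x5F3759DF])
    rng_nuc, rng_golgi, rng_endo, rng_lyso, rng_egfp = (
        np.random.default_rng(s) for s in ss.spawn(5))

    # --- nuclei and cell partition -------------------------------------
    centers = _sample_nucleus_centers(spec, rng_nuc)
    radii = spec.nucleus_radius * (1.0 + 0.08 * (rng_nuc.random(spec.n_cells) * 2 - 1))
    ellipsoid = _ellipsoid_mask(spec)
    nuclei_labels = np.zeros(spec.stack_shape, dtype=np.int32)
    _stamp_spheres(nuclei_labels, centers, radii,
                   np.arange(1, spec.n_cells + 1), spec.voxel_size)
    nuclei_labels[~ellipsoid] = 0
    cell_labels = _partition_cells(spec, centers, ellipsoid)
    # nucleus voxels always belong to their own cell
    nz_mask = nuclei_labels > 0
    cell_labels[nz_mask] = nuclei_labels[nz_mask]

    geom = _CellGeometry(spec, centers, radii)
    poles = _random_unit(rng_golgi, spec.n_cells)  # per-cell Golgi orientation

    organelle_labels: dict[str, np.ndarray] = {}
    fragment_cell_of: dict[str, dict[int, int]] = {}
    truth_cols: dict[str, np.ndarray] = {}

    # --- Golgi ----------------------------------------------------------
    if "golgi" in spec.channels:
        labels = np.zeros(spec.stack_shape, dtype=np.int32)
        cell_of: dict[int, int] = {}
        next_id = 1
        lo, hi = spec.golgi_model.fragment_count_range
        for cid in range(spec.n_cells):
            total = spec.golgi_model.total_volume_um3 * float(
                np.clip(1.0 + 0.06 * rng_golgi.standard_normal(), 0.75, 1.25))
            k = int(rng_golgi.integers(lo, hi + 1))
            # unlinked ribbon stacks are of comparable size: mild size spread
            vols = _fragment_volumes(rng_golgi, total, k, concentration=8.0)
            frad = _radius_of_volume(vols)
            if spec.golgi_model.placement == "juxtanuclear":
                offsets = radii[cid] + 0.8 * frad
                # fragments are "distinct" at light-microscope resolution:
                # keep gaps of ~0.8 μm so neighbouring fragments stay resolvable
                pts = geom.sample_juxtanuclear(
                    cid, k, offsets, poles[cid],
                    min_sep=float(2.0 * frad.mean() + 0.8), rng=rng_golgi)
            else:  # scattered through the cytoplasm (drug phenotypes);
                # "distinct punctate structures" — keep them resolvable
                sep = max(1.5, 2.2 * float(frad.mean()))
                pts = geom.sample_in_cytoplasm(cid, k, min_sep=sep, rng=rng_golgi,
                                               clearance=0.3)
            ids = np.arange(next_id, next_id + k)
            _stamp_spheres(labels, pts, frad, ids, spec.voxel_size)
            for fid in ids:
                cell_of[int(fid)] = cid + 1
            next_id += k
        organelle_labels["golgi"] = labels
        fragment_cell_of["golgi"] = cell_of

    # --- early endosomes -------------------------------------------------
    if "endosome" in spec.channels:
        labels = np.zeros(spec.stack_shape, dtype=np.int32)
        cell_of = {}
        next_id = 1
        n_p = spec.endosome_model.n_puncta_per_cell
        for cid in range(spec.n_cells):
            total = spec.endosome_model.total_volume_um3 * float(
                np.clip(1.0 + 0.06 * rng_endo.standard_normal(), 0.75, 1.25))
            vols = _fragment_volumes(rng_endo, total, n_p, concentration=8.0)
            frad = _radius_of_volume(vols)
            pts = geom.sample_in_cytoplasm(cid, n_p, min_sep=1.0, rng=rng_endo,
                                           clearance=0.1, edge_margin=0.2)
            ids = np.arange(next_id, next_id + n_p)
            _stamp_spheres(labels, pts, frad, ids, spec.voxel_size)
            for fid in ids:
                cell_of[int(fid)] = cid + 1
            next_id += n_p
        organelle_labels["endosome"] = labels
        fragment_cell_of["endosome"] = cell_of

    # --- lysosomes: one perinuclear cluster per cell ----------------------
    if "lysosome" in spec.channels:
        labels = np.zeros(spec.stack_shape, dtype=np.int32)
        cell_of = {}
        next_id = 1
        n_p = spec.lysosome_model.n_puncta_per_cell
        cr = spec.lysosome_model.cluster_radius_um
        for cid in range(spec.n_cells):
            total = spec.lysosome_model.total_volume_um3 * float(
                np.clip(1.0 + 0.08 * rng_lyso.standard_normal(), 0.7, 1.3))
            vols = _fragment_volumes(rng_lyso, total, n_p, concentration=6.0)
            frad = _radius_of_volume(vols)
            site_dir = -poles[cid] + 0.4 * rng_lyso.standard_normal(3)
            site_dir /= np.linalg.norm(site_dir)
            site = centers[cid] + site_dir * (radii[cid] + 0.5 * cr)
            pts = []
            for i in range(n_p):
                ok = False
                # clustered but non-overlapping: write-once stamping would
                # silently lose the overlap volume otherwise
                min_gap = 1.05 * 2.0 * float(frad[i])
                for attempt in range(60):
                    spread = cr / 2.0 * (1.0 + attempt / 30.0)
                    p = site + rng_lyso.standard_normal(3) * spread
                    if not geom.membership(p[None], cid, clearance=0.1,
                                           edge_margin=0.2)[0]:
                        continue
                    if pts and np.min(np.linalg.norm(np.asarray(pts) - p,
                                                     axis=1)) < min_gap:
                        continue
                    ok = True
                    break
                if not ok:
                    p = geom.sample_in_cytoplasm(cid, 1, min_gap, rng_lyso)[0]
                pts.append(p)
            ids = np.arange(next_id, next_id + n_p)
            _stamp_spheres(labels, np.asarray(pts), frad, ids, spec.voxel_size)
            for fid in ids:
                cell_of[int(fid)] = cid + 1
            next_id += n_p
        organelle_labels["lysosome"] = labels
        fragment_cell_of["lysosome"] = cell_of

    # --- EGFP marker channel ----------------------------------------------
    egfp_class = np.full(spec.n_cells, _NON_EXPRESSING, dtype=object)
    if spec.egfp_model != "none":
        expressing = rng_egfp.random(spec.n_cells) < spec.egfp_expressing_fraction
        egfp_class[expressing] = spec.egfp_model
        labels = np.zeros(spec.stack_shape, dtype=np.int32)
        if spec.egfp_model == "cytosolic":
            cyto = (cell_labels > 0) & (nuclei_labels == 0)
            keep = np.zeros(spec.n_cells + 1, dtype=bool)
            keep[1:][expressing] = True
            labels[cyto & keep[cell_labels]] = cell_labels[cyto & keep[cell_labels]]
        elif spec.egfp_model == "rab5a_puncta":
            for cid in np.flatnonzero(expressing):
                pts = geom.sample_in_cytoplasm(cid, 40, min_sep=1.2, rng=rng_egfp)
                frad = _radius_of_volume(np.full(40, 0.5))
                _stamp_spheres(labels, pts, frad, np.full(40, cid + 1),
                               spec.voxel_size)
        elif spec.egfp_model == "rab6a_golgi":
            if spec.phenotype == "bfa":
                _stamp_rab6a_web(labels, geom, np.flatnonzero(expressing), rng_egfp,
                                 spec)
            else:
                core_r = float(_radius_of_volume(spec.rab6a_core_volume_um3))
                for cid in np.flatnonzero(expressing):
                    p = geom.sample_juxtanuclear(
                        cid, 1, np.array([radii[cid] + 0.8 * core_r]),
                        poles[cid], min_sep=0.0, rng=rng_egfp)
                    _stamp_spheres(labels, p, np.array([core_r]),
                                   np.array([cid + 1]), spec.voxel_size)
                if spec.phenotype == "nocodazole":
                    # partial dispersal: a handful of small satellite puncta
                    for cid in np.flatnonzero(expressing):
                        pts = geom.sample_in_cytoplasm(cid, 10, min_sep=1.2,
                                                       rng=rng_egfp)
                        frad = _radius_of_volume(np.full(10, 0.3))
                        _stamp_spheres(labels, pts, frad, np.full(10, cid + 1),
                                       spec.voxel_size)
        organelle_labels["egfp"] = labels

    # --- per-cell truth table (volumes from labels: exact conservation) ----
    vv = dz * dy * dx
    truth = {"cell_id": np.arange(1, spec.n_cells + 1)}
    for chan, labels in organelle_labels.items():
        if chan == "egfp":
            continue
        counts = np.bincount(labels.ravel())
        vol = np.zeros(spec.n_cells)
        nfrag = np.zeros(spec.n_cells, dtype=int)
        for fid, cid in fragment_cell_of[chan].items():
            if fid < len(counts) and counts[fid] > 0:
                vol[cid - 1] += counts[fid] * vv
                nfrag[cid - 1] += 1
        truth[f"{chan}_volume_um3"] = vol
        truth[f"{chan}_fragment_count"] = nfrag
    if "egfp" in organelle_labels:
        lab = organelle_labels["egfp"]
        # per-cell footprint: distinct XY columns containing any of the cell's voxels
        proj = np.zeros((spec.n_cells + 1, ny, nx), dtype=bool)
        for z_plane in lab:
            yy_idx, xx_idx = np.nonzero(z_plane)
            proj[z_plane[yy_idx, xx_idx], yy_idx, xx_idx] = True
        truth["egfp_footprint_um2"] = proj[1:].sum(axis=(1, 2)) * dy * dx
        cnt = np.bincount(lab.ravel(), minlength=spec.n_cells + 1)
        truth["egfp_volume_um3"] = cnt[1:] * vv
    truth["egfp_class"] = egfp_class
    per_cell = pd.DataFrame(truth)

    per_spheroid = {
        "n_cells": spec.n_cells,
        "half_axes_um": spec.spheroid_half_axes,
        "centroid_um": tuple(center),
        "volume_um3": spec.ellipsoid_volume_um3,
    }

    # --- intensity scene ---------------------------------------------------
    channel_names = ["nuclei"] + [c for c in ("golgi", "endosome", "lysosome")
                                  if c in spec.channels]
    if spec.egfp_model != "none":
        channel_names.append("egfp")
    scene = np.zeros((len(channel_names),) + spec.stack_shape, dtype=np.float32)
    nuc_ch = scene[0]
    nuc_ch[ellipsoid] = RESIDUAL_CYTOPLASM_INTENSITY
    nuc_ch[nuclei_labels > 0] = NUCLEUS_INTENSITY
    for i, name in enumerate(channel_names[1:], start=1):
        ch = scene[i]
        if name == "egfp":
            lab = organelle_labels["egfp"]
            if spec.egfp_model == "cytosolic":
                ch[lab > 0] = EGFP_CYTOSOL_INTENSITY
            else:
                ch[lab > 0] = EGFP_STRUCTURE_INTENSITY
        else:
            ch[ellipsoid] = DIFFUSE_ORGANELLE_INTENSITY
            ch[organelle_labels[name] > 0] = ORGANELLE_INTENSITY

    stack = ImageStack(voxels=scene, voxel_size=spec.voxel_size,
                       channel_names=channel_names)
    gt = GroundTruth(
        nuclei_labels=nuclei_labels,
        cell_labels=cell_labels,
        organelle_labels=organelle_labels,
        per_cell_truth=per_cell,
        per_spheroid_truth=per_spheroid,
        fragment_cell_of=fragment_cell_of,
    )
    return stack, gt


def _stamp_rab6a_web(labels: np.ndarray, geom: _CellGeometry,
                     expressing_cells: np.ndarray, rng: np.random.Generator,
                     spec: PhantomSpec, n_tubules: int = 80) -> None:
    """Rasterize a reticular (web-like) tubule network through each cell's
    cytoplasm: chords between random cytoplasm points, densely sampled and
    dilated to roughly PSF-sized tubes."""
    dz, dy, dx = spec.voxel_size
    step = np.array([dz, dy, dx])
    shape = np.array(labels.shape)
    mask = np.zeros(labels.shape, dtype=np.int32)
    for cid in expressing_cells:
        anchors = geom.sample_in_cytoplasm(cid, 2 * n_tubules, min_sep=0.0,
                                           rng=rng, clearance=0.1)
        a = anchors[:n_tubules]
        b = anchors[n_tubules:]
        seg = b - a
        lengths = np.linalg.norm(seg, axis=1)
        pts = []
        for s0, sv, ln in zip(a, seg, lengths):
            n_samp = max(int(ln / 0.15), 2)
            t = np.linspace(0.0, 1.0, n_samp)
            pts.append(s0 + t[:, None] * sv)
        pts = np.concatenate(pts)
        ok = geom.membership(pts, cid, clearance=0.05, edge_margin=0.2)
        pts = pts[ok]
        if not len(pts):
            continue
        idx = np.floor(pts / step).astype(int)
        idx = np.clip(idx, 0, shape - 1)
        sel = mask[idx[:, 0], idx[:, 1], idx[:, 2]] == 0
        mask[idx[sel, 0], idx[sel, 1], idx[sel, 2]] = cid + 1
    # dilate in-plane so tubes are ~0.3 μm radius rather than single columns
    struct = np.zeros((1, 3, 3), dtype=bool)
    struct[0] = [[0, 1, 0], [1, 1, 1], [0, 1, 0]]
    dil = ndimage.grey_dilation(mask, footprint=struct)
    labels[:] = np.where(mask > 0, mask, dil)
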