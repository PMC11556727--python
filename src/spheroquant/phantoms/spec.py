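"""Generative parameter sets for synthetic spheroid and plate phantoms.

``PhantomSpec`` describes one micropatterned-plate spheroid as imaged at
high magnification: an ellipsoidal cell assembly (height about half the
width), 80–120 nuclei, juxtanuclear Golgi of about 125 μm³ per cell split
over 5–10 fragments, dispersed early-endosome puncta totalling about
120 μm³ per cell, perinuclearly clustered lysosomes of about 30 μm³ per
cell, an optional EGFP marker channel, and a simple widefield/confocal
forward-imaging model. ``paper_default()`` freezes this configuration so
that end-to-end recovery tests have a fixed, documented ground truth.

Drug phenotypes are expressed as spec transformations (``apply_phenotype``):
brefeldin A scatters the Golgi into ~25x more, smaller fragments and turns
the Golgi-associated EGFP-Rab6A signal into a reticular cytoplasmic web;
nocodazole fragments the Golgi more mildly (~3x).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

EGFP_MODELS = ("none", "cytosolic", "rab5a_puncta", "rab6a_golgi")
PHENOTYPES = ("control", "bfa", "nocodazole")

#: multiplier applied to the Golgi fragment-count range under brefeldin A
BFA_FRAGMENT_MULTIPLIER = 25
#: fractional Golgi volume retained under brefeldin A
BFA_VOLUME_FACTOR = 0.85
#: multiplier applied to the Golgi fragment-count range under nocodazole
NOCODAZOLE_FRAGMENT_MULTIPLIER = 3
NOCODAZOLE_VOLUME_FACTOR = 0.90


@dataclass(frozen=True)
class OrganelleModel:
    """Per-cell generative model for one organelle population."""

    total_volume_um3: float
    fragment_count_range: tuple[int, int] = (1, 1)
    n_puncta_per_cell: int = 0
    cluster_radius_um: float = 0.0
    placement: str = "juxtanuclear"  # juxtanuclear | uniform | perinuclear | scattered

    def __post_init__(self):
        lo, hi = self.fragment_count_range
        if self.total_volume_um3 <= 0:
            raise ValueError("organelle total volume must be positive")
        if lo > hi or lo < 1:
            raise ValueError(f"bad fragment count range {self.fragment_count_range}")


@dataclass(frozen=True)
class Optics:
    """Forward imaging model: anisotropic Gaussian PSF, Poisson shot noise,
    Gaussian read noise and a constant background offset (detector counts)."""

    psf_sigma_xy_um: float = 0.13
    psf_sigma_z_um: float = 0.5
    background: float = 40.0
    photon_scale: float = 300.0
    read_noise_sd: float = 3.0

    def __post_init__(self):
        if self.psf_sigma_xy_um < 0 or self.psf_sigma_z_um < 0:
            raise ValueError("PSF sigmas must be >= 0")
        if self.photon_scale < 0:
            raise ValueError("photon_scale must be >= 0")


@dataclass(frozen=True)
class PhantomSpec:
    """Full generative description of one spheroid stack. Lengths in μm."""

    voxel_size: tuple[float, float, float] = (1.0, 0.3, 0.3)
    stack_shape: tuple[int, int, int] = (44, 256, 256)
    spheroid_half_axes: tuple[float, float, float] = (35.0, 35.0, 17.5)  # (a_xy, a_xy, c_z)
    n_cells: int = 100
    nucleus_radius: float = 3.5
    golgi_model: OrganelleModel = field(default_factory=lambda: OrganelleModel(
        total_volume_um3=125.0, fragment_count_range=(5, 10), placement="juxtanuclear"))
    endosome_model: OrganelleModel = field(default_factory=lambda: OrganelleModel(
        total_volume_um3=120.0, n_puncta_per_cell=315, placement="uniform"))
    lysosome_model: OrganelleModel = field(default_factory=lambda: OrganelleModel(
        total_volume_um3=30.0, n_puncta_per_cell=20, cluster_radius_um=3.0,
        placement="perinuclear"))
    egfp_model: str = "none"
    #: fraction of cells that express the EGFP marker (stable lines: 1.0;
    #: set below 1 to emulate mixed populations for expression gating)
    egfp_expressing_fraction: float = 1.0
    #: volume of the compact Rab6A-positive core rendered at the Golgi in the
    #: untreated state (the reticular web replaces it under brefeldin A)
    rab6a_core_volume_um3: float = 2.5
    phenotype: str = "control"
    optics: Optics = field(default_factory=Optics)
    #: which organelle channels to rasterize (subset of golgi/endosome/lysosome)
    channels: tuple[str, ...] = ("golgi", "endosome", "lysosome")
    seed: int = 0

    def __post_init__(self):
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel sizes must be positive")
        if any(s < 4 for s in self.stack_shape):
            raise ValueError("stack too small")
        a, b, c = self.spheroid_half_axes
        if min(a, b, c) <= 0:
            raise ValueError("spheroid half axes must be positive")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.nucleus_radius <= 0:
            raise ValueError("nucleus radius must be positive")
        if not (0.0 <= self.egfp_expressing_fraction <= 1.0):
            raise ValueError("egfp_expressing_fraction must lie in [0, 1]")
        if self.egfp_model not in EGFP_MODELS:
            raise ValueError(f"unknown egfp_model {self.egfp_model!r}; use one of {EGFP_MODELS}")
        if self.phenotype not in PHENOTYPES:
            raise ValueError(f"unknown phenotype {self.phenotype!r}; use one of {PHENOTYPES}")
        unknown = set(self.channels) - {"golgi", "endosome", "lysosome"}
        if unknown:
            raise ValueError(f"unknown organelle channels {sorted(unknown)}")

    @property
    def ellipsoid_volume_um3(self) -> float:
        a, b, c = self.spheroid_half_axes
        return 4.0 / 3.0 * math.pi * a * b * c

    @property
    def aspect_z_over_xy(self) -> float:
        a, _, c = self.spheroid_half_axes
        return c / a


def paper_default(seed: int = 0, n_cells: int | None = None, *,
                  egfp_model: str = "none",
                  channels: tuple[str, ...] = ("golgi", "endosome", "lysosome"),
                  ) -> PhantomSpec:
    """The frozen default spheroid configuration.

    Encodes the study conditions this package emulates: 80–120 cells per
    spheroid (drawn from the seed when ``n_cells`` is None), height half the
    width, Golgi 125 μm³ per cell in 5–10 fragments, endosomes 120 μm³,
    lysosomes 30 μm³, 45 μm disc / 300 μm pitch plate geometry (see
    :mod:`spheroquant.phantoms.plate`), and 63x-class water-immersion optics
    sampled at 1 μm z steps.
    """
    if n_cells is None:
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xC311]))
        n_cells = int(rng.integers(80, 121))
    return PhantomSpec(seed=int(seed), n_cells=n_cells, egfp_model=egfp_model,
                       channels=tuple(channels))


def apply_phenotype(spec: PhantomSpec) -> PhantomSpec:
    """Fold the spec's drug phenotype into its generative models.

    control: returned unchanged. bfa: Golgi fragment range x25, total volume
    x0.85, fragments scattered through the cytoplasm; Rab6A EGFP re-rendered
    as a reticular web (handled by the scene builder via ``phenotype``);
    Rab5A unchanged. nocodazole: fragment range x3, volume x0.90, scattered.
    """
    if spec.phenotype == "control":
        return spec
    if spec.phenotype == "bfa":
        mult, vol = BFA_FRAGMENT_MULTIPLIER, BFA_VOLUME_FACTOR
    elif spec.phenotype == "nocodazole":
        mult, vol = NOCODAZOLE_FRAGMENT_MULTIPLIER, NOCODAZOLE_VOLUME_FACTOR
    else:  # pragma: no cover - guarded by PhantomSpec validation
        raise ValueError(f"unknown phenotype {spec.phenotype!r}")
    lo, hi = spec.golgi_model.fragment_count_range
    golgi = OrganelleModel(
        total_volume_um3=spec.golgi_model.total_volume_um3 * vol,
        fragment_count_range=(lo * mult, hi * mult),
        placement="scattered",
    )
    return replace(spec, golgi_model=golgi)


@dataclass(frozen=True)
class PlatePhantomSpec:
    """Generative description of a low-magnification well montage: a square
    lattice of micropattern sites, each independently occupied by a spheroid."""

    pattern_pitch_um: float = 300.0
    pattern_disc_diameter_um: float = 45.0
    grid_extent: tuple[int, int] = (16, 16)
    occupancy_probability: float = 0.7
    spheroid_diameter_um: tuple[float, float] = (70.0, 5.0)  # (mean, sd)
    pixel_size_um: float = 3.0
    seed: int = 0

    def __post_init__(self):
        if self.pattern_pitch_um <= self.pattern_disc_diameter_um:
            raise ValueError("pattern pitch must exceed the disc diameter")
        if not (0.0 <= self.occupancy_probability <= 1.0):
            raise ValueError("occupancy probability must lie in [0, 1]")
        if min(self.grid_extent) < 1:
            raise ValueError("grid extent must be at least (1, 1)")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel size must be positive")
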