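"""Shared fixtures: small, fast phantoms exercised by most unit tests.

The small spheroid (8 cells, 12 μm radius) keeps builds under a second;
tests that need the full-size study conditions build them explicitly.
"""

from __future__ import annotations

import logging

import numpy as np
import pytest

from spheroquant.config import AnalysisParams
from spheroquant.phantoms import (OrganelleModel, PhantomSpec,
                                  build_spheroid_phantom, render)

logging.getLogger("spheroquant").setLevel(logging.ERROR)


def small_spec(seed: int = 0, **overrides) -> PhantomSpec:
    kwargs = dict(
        stack_shape=(30, 96, 96),
        voxel_size=(1.0, 0.3, 0.3),
        spheroid_half_axes=(12.0, 12.0, 6.0),
        n_cells=8,
        nucleus_radius=3.0,
        golgi_model=OrganelleModel(60.0, (3, 5), placement="juxtanuclear"),
        endosome_model=OrganelleModel(16.0, n_puncta_per_cell=20,
                                      placement="uniform"),
        lysosome_model=OrganelleModel(8.0, n_puncta_per_cell=6,
                                      cluster_radius_um=2.5,
                                      placement="perinuclear"),
        seed=seed,
    )
    kwargs.update(overrides)
    return PhantomSpec(**kwargs)


def small_params() -> AnalysisParams:
    # the small spheroid (≈3600 μm³) is below the full-scale debris filter,
    # and fills so little of the stack that the trimodal threshold (meant
    # for stacks dominated by the spheroid) would split the background
    return AnalysisParams(spheroid_min_volume_um3=500.0,
                          spheroid_threshold="otsu")


@pytest.fixture(scope="session")
def small_phantom():
    """(spec, noiseless scene, ground truth) for the small test spheroid."""
    spec = small_spec(seed=1)
    scene, gt = build_spheroid_phantom(spec)
    return spec, scene, gt


@pytest.fixture(scope="session")
def small_rendered(small_phantom):
    """(spec, rendered 16-bit stack, ground truth)."""
    spec, scene, gt = small_phantom
    return spec, render(scene, spec.optics, seed=spec.seed), gt


@pytest.fixture(scope="session")
def truth_partition(small_phantom):
    """A CellPartition built from the ground-truth labels."""
    from spheroquant.segment3d import CellPartition

    spec, _, gt = small_phantom
    return CellPartition(
        cell_labels=gt.cell_labels,
        nuclei_labels=gt.nuclei_labels,
        cytoplasm_mask=(gt.cell_labels > 0) & (gt.nuclei_labels == 0),
        nucleus_of={i: i for i in range(1, spec.n_cells + 1)},
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
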