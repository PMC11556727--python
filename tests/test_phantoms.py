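"""Phantom generator: determinism, conservation, rendering moments and
plate-montage statistics."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from spheroquant.phantoms import (BFA_FRAGMENT_MULTIPLIER, Optics,
                                  OrganelleModel, PhantomSpec,
                                  PlatePhantomSpec, apply_phenotype,
                                  build_spheroid_phantom, build_well_montage,
                                  occupancy_draw, paper_default, render)
from spheroquant.stack import ImageStack

from conftest import small_spec


class TestSpecValidation:
    def test_fragment_range_must_be_ordered(self):
        with pytest.raises(ValueError):
            OrganelleModel(10.0, (5, 3))

    def test_unknown_phenotype_rejected(self):
        with pytest.raises(ValueError, match="phenotype"):
            small_spec(phenotype="golgicide")

    def test_unknown_egfp_model_rejected(self):
        with pytest.raises(ValueError, match="egfp_model"):
            small_spec(egfp_model="rab11")

    def test_plate_pitch_must_exceed_disc(self):
        with pytest.raises(ValueError):
            PlatePhantomSpec(pattern_pitch_um=40.0,
                             pattern_disc_diameter_um=45.0)

    def test_occupancy_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            PlatePhantomSpec(occupancy_probability=1.3)

    def test_paper_default_cell_count_in_stated_range(self):
        counts = {paper_default(seed=s).n_cells for s in range(30)}
        assert min(counts) >= 80 and max(counts) <= 120
        assert len(counts) > 5  # actually varies with the seed


class TestBuildSpheroidPhantom:
    def test_single_cell_forced_fragment_count(self):
        spec = small_spec(n_cells=1, golgi_model=OrganelleModel(40.0, (3, 3)),
                          channels=("golgi",))
        _, gt = build_spheroid_phantom(spec)
        assert gt.nuclei_labels.max() == 1
        assert gt.per_cell_truth["golgi_fragment_count"].tolist() == [3]
        assert len(np.unique(gt.organelle_labels["golgi"])) == 4  # 0 + 3

    def test_same_seed_bit_identical(self):
        spec = small_spec(seed=9, egfp_model="rab6a_golgi")
        scene_a, gt_a = build_spheroid_phantom(spec)
        scene_b, gt_b = build_spheroid_phantom(spec)
        np.testing.assert_array_equal(scene_a.voxels, scene_b.voxels)
        np.testing.assert_array_equal(gt_a.cell_labels, gt_b.cell_labels)
        for chan in gt_a.organelle_labels:
            np.testing.assert_array_equal(gt_a.organelle_labels[chan],
                                          gt_b.organelle_labels[chan])
        pd.testing.assert_frame_equal(gt_a.per_cell_truth, gt_b.per_cell_truth)

    def test_truth_volumes_equal_label_voxel_counts(self, small_phantom):
        """Conservation: the truth table is exactly the labelled volume."""
        spec, _, gt = small_phantom
        vv = np.prod(spec.voxel_size)
        for chan in ("golgi", "endosome", "lysosome"):
            counts = np.bincount(gt.organelle_labels[chan].ravel())
            by_cell = np.zeros(spec.n_cells)
            for fid, cid in gt.fragment_cell_of[chan].items():
                if fid < len(counts):
                    by_cell[cid - 1] += counts[fid] * vv
            np.testing.assert_allclose(
                gt.per_cell_truth[f"{chan}_volume_um3"], by_cell, atol=1e-9)

    def test_paper_default_golgi_volume_close_to_design(self):
        """Voxel-count oracle: mean per-cell Golgi volume within 10% of 125."""
        spec = paper_default(seed=4, channels=("golgi",))
        _, gt = build_spheroid_phantom(spec)
        mean_vol = gt.per_cell_truth["golgi_volume_um3"].mean()
        assert mean_vol == pytest.approx(125.0, rel=0.10)

    def test_packing_infeasible_raises_named_bound(self):
        spec = small_spec(n_cells=60)
        with pytest.raises(ValueError, match="packing infeasible"):
            build_spheroid_phantom(spec)

    def test_stack_too_small_raises(self):
        spec = small_spec(stack_shape=(10, 40, 40))
        with pytest.raises(ValueError, match="too small"):
            build_spheroid_phantom(spec)


class TestApplyPhenotype:
    def test_control_is_identity(self):
        spec = small_spec()
        assert apply_phenotype(spec) is spec

    def test_bfa_fragment_range_times_25(self):
        spec = small_spec(golgi_model=OrganelleModel(125.0, (5, 10)),
                          phenotype="bfa")
        out = apply_phenotype(spec)
        assert out.golgi_model.fragment_count_range == (125, 250)
        assert out.golgi_model.total_volume_um3 == pytest.approx(125.0 * 0.85)
        assert out.golgi_model.placement == "scattered"
        assert BFA_FRAGMENT_MULTIPLIER == 25

    def test_nocodazole_fragment_range_times_3(self):
        spec = small_spec(golgi_model=OrganelleModel(125.0, (5, 10)),
                          phenotype="nocodazole")
        out = apply_phenotype(spec)
        assert out.golgi_model.fragment_count_range == (15, 30)
        assert out.golgi_model.total_volume_um3 == pytest.approx(125.0 * 0.90)

    def test_truth_fragment_counts_ordered_across_phenotypes(self):
        """BFA > nocodazole > control in the generated ground truth."""
        base = dict(stack_shape=(32, 110, 110),
                    spheroid_half_axes=(14.0, 14.0, 7.0), n_cells=5,
                    nucleus_radius=3.0,
                    golgi_model=OrganelleModel(60.0, (5, 10)),
                    channels=("golgi",), seed=21)
        medians = {}
        for phenotype in ("control", "nocodazole", "bfa"):
            spec = PhantomSpec(phenotype=phenotype, **base)
            _, gt = build_spheroid_phantom(spec)
            medians[phenotype] = gt.per_cell_truth["golgi_fragment_count"].median()
        assert medians["bfa"] > medians["nocodazole"] > medians["control"]


class TestRender:
    def _flat_scene(self, value=0.0, shape=(8, 32, 32)):
        return ImageStack(np.full((1,) + shape, value, dtype=np.float32),
                          (1.0, 0.3, 0.3), ["nuclei"])

    def test_zero_photon_scale_gives_constant_background(self):
        optics = Optics(photon_scale=0.0, read_noise_sd=0.0, background=40.0)
        out = render(self._flat_scene(5.0), optics, seed=0)
        assert (out.voxels == 40).all()

    def test_no_psf_no_noise_is_quantized_identity(self, rng):
        scene = ImageStack(
            rng.random((1, 6, 16, 16)).astype(np.float32) * 100,
            (1.0, 0.3, 0.3), ["nuclei"])
        optics = Optics(psf_sigma_xy_um=0.0, psf_sigma_z_um=0.0,
                        background=0.0, photon_scale=1.0, read_noise_sd=0.0)
        out = render(scene, optics, seed=0, shot_noise=False)
        np.testing.assert_array_equal(out.voxels,
                                      np.rint(scene.voxels).astype(np.uint16))

    def test_poisson_gaussian_moments_on_uniform_region(self):
        """mean ≈ photon·I + bg and var ≈ photon·I + read² within 5%."""
        scene = self._flat_scene(1.0, shape=(20, 50, 50))  # 5e4 voxels
        optics = Optics(psf_sigma_xy_um=0.0, psf_sigma_z_um=0.0,
                        background=20.0, photon_scale=150.0, read_noise_sd=3.0)
        out = render(scene, optics, seed=3)
        vals = out.voxels.astype(float)
        assert vals.mean() == pytest.approx(170.0, rel=0.05)
        assert vals.var() == pytest.approx(159.0, rel=0.05)

    def test_same_seed_identical_noise(self):
        scene = self._flat_scene(1.0)
        optics = Optics()
        a = render(scene, optics, seed=5)
        b = render(scene, optics, seed=5)
        np.testing.assert_array_equal(a.voxels, b.voxels)


class TestWellMontage:
    def test_full_occupancy_7x7_gives_49_spheroids(self):
        spec = PlatePhantomSpec(grid_extent=(7, 7), occupancy_probability=1.0)
        _, truth = build_well_montage(spec, render_image=False)
        assert len(truth) == 49

    def test_truth_lattice_spacing_in_pixels(self):
        spec = PlatePhantomSpec(grid_extent=(3, 3), occupancy_probability=1.0,
                                pattern_pitch_um=300.0, pixel_size_um=3.0)
        _, truth = build_well_montage(spec, render_image=False)
        xs = np.sort(truth.query("site_row == 0")["x_um"].to_numpy())
        spacing_px = np.diff(xs) / spec.pixel_size_um
        np.testing.assert_allclose(spacing_px, 100.0)

    def test_occupied_counts_match_binomial_moments(self):
        """16x16 grid at p=0.7 over 200 seeds: mean ≈ 179.2, CV ≈ 4.1%."""
        counts = np.array([
            occupancy_draw(PlatePhantomSpec(grid_extent=(16, 16),
                                            occupancy_probability=0.7,
                                            seed=s)).sum()
            for s in range(200)])
        assert counts.mean() == pytest.approx(179.2, abs=2.0)
        cv = counts.std(ddof=1) / counts.mean()
        assert cv == pytest.approx(0.041, rel=0.25)

    def test_occupancy_counts_binomial_chi_square(self):
        """Goodness of fit of occupied-site counts to Binomial(n, p) over
        500 seeds is not rejected at alpha = 0.01."""
        n_sites, p = 64, 0.7
        counts = np.array([
            occupancy_draw(PlatePhantomSpec(grid_extent=(8, 8),
                                            occupancy_probability=p,
                                            seed=s)).sum()
            for s in range(500)])
        pmf = sps.binom.pmf(np.arange(n_sites + 1), n_sites, p)
        # pool bins so every expected count is >= 5
        order = np.arange(n_sites + 1)
        edges, acc = [], 0.0
        for k in order:
            acc += pmf[k] * 500
            if acc >= 5:
                edges.append(k)
                acc = 0.0
        edges[-1] = n_sites
        observed, expected = [], []
        lo = 0
        for hi in edges:
            sel = (counts >= lo) & (counts <= hi)
            observed.append(sel.sum())
            expected.append(pmf[lo:hi + 1].sum() * 500)
            lo = hi + 1
        expected = np.array(expected) * (500 / sum(expected))
        stat, p_value = sps.chisquare(observed, expected)
        assert p_value > 0.01

    def test_montage_truth_matches_image_and_determinism(self):
        spec = PlatePhantomSpec(grid_extent=(3, 3), occupancy_probability=0.7,
                                seed=5)
        image_a, truth_a = build_well_montage(spec)
        image_b, truth_b = build_well_montage(spec)
        np.testing.assert_array_equal(image_a, image_b)
        pd.testing.assert_frame_equal(truth_a, truth_b)
        _, truth_c = build_well_montage(spec, render_image=False)
        pd.testing.assert_frame_equal(truth_a, truth_c)
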