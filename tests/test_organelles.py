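"""Hessian eigenvalue maps, PLS texture filters and organelle segmentation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from spheroquant import organelles
from spheroquant.organelles import (HessianEigenMaps, _symmetric_eigvals_3x3,
                                    detect_spots, hessian_eigs, pls_maps,
                                    segment_large_organelle)
from spheroquant.phantoms import (Optics, OrganelleModel,
                                  build_spheroid_phantom, render)
from spheroquant.stack import ImageStack

from conftest import small_spec


def quadratic_stack(coeffs=(0.0, 3.0, -2.0), extent=6.0, step=0.25):
    """Sample f = a z² + b x² + c y² on an isotropic grid (μm units)."""
    az, ax, ay = coeffs[0], coeffs[1], coeffs[2]
    r = np.arange(-extent, extent + step / 2, step)
    z, y, x = np.meshgrid(r, r, r, indexing="ij")
    f = az * z ** 2 + ax * x ** 2 + ay * y ** 2
    f = f - f.min() + 10.0
    return ImageStack(f[None].astype(np.float32), (step, step, step), ["c"])


class TestEigenSolver:
    @given(hnp.arrays(np.float64, (20, 6),
                      elements=st.floats(-50, 50, allow_nan=False)))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_matches_lapack_on_random_symmetric_matrices(self, entries):
        a11, a22, a33, a12, a13, a23 = entries.T
        l1, l2, l3 = _symmetric_eigvals_3x3(a11, a22, a33, a12, a13, a23)
        mats = np.zeros((len(entries), 3, 3))
        mats[:, 0, 0], mats[:, 1, 1], mats[:, 2, 2] = a11, a22, a33
        mats[:, 0, 1] = mats[:, 1, 0] = a12
        mats[:, 0, 2] = mats[:, 2, 0] = a13
        mats[:, 1, 2] = mats[:, 2, 1] = a23
        ref = np.linalg.eigvalsh(mats)
        got = np.stack([l1, l2, l3], axis=1)
        np.testing.assert_allclose(got, ref, atol=1e-8 * (1 + np.abs(ref).max()))
        assert (np.diff(got, axis=1) >= -1e-9).all()


class TestHessianEigs:
    def test_quadratic_has_analytic_eigenvalues(self):
        """f = 3x² − 2y²: Hessian diag (6, −4, 0) → sorted (−4, 0, 6).

        Gaussian smoothing preserves second derivatives of quadratics, so
        the eigenvalues at the center are scale-independent.
        """
        stack = quadratic_stack()
        eigs = hessian_eigs(stack, "c", sigma_um=0.75)
        c = tuple(s // 2 for s in stack.voxels.shape[1:])
        assert eigs.lam1[c] == pytest.approx(-4.0, rel=0.05)
        assert abs(eigs.lam2[c]) < 0.2
        assert eigs.lam3[c] == pytest.approx(6.0, rel=0.05)

    def test_constant_image_zero_eigenvalues(self):
        stack = ImageStack(np.full((1, 12, 12, 12), 7.0, np.float32),
                           (0.5, 0.5, 0.5), ["c"])
        eigs = hessian_eigs(stack, "c", sigma_um=1.0)
        for lam in (eigs.lam1, eigs.lam2, eigs.lam3):
            np.testing.assert_allclose(lam, 0.0, atol=1e-6)

    def test_rotation_invariance_of_eigenvalue_sets(self, rng):
        """Rotating the volume 90° permutes axes but leaves the per-voxel
        eigenvalue set unchanged (within 1%)."""
        f = rng.random((24, 24, 24)).astype(np.float32)
        from scipy import ndimage
        f = ndimage.gaussian_filter(f, 2.0) * 100
        stack = ImageStack(f[None], (0.5, 0.5, 0.5), ["c"])
        rot = ImageStack(np.transpose(f, (0, 2, 1))[::-1].copy()[None],
                         (0.5, 0.5, 0.5), ["c"])
        e1 = hessian_eigs(stack, "c", sigma_um=1.0)
        e2 = hessian_eigs(rot, "c", sigma_um=1.0)
        sl = slice(6, 18)
        a = np.stack([e1.lam1, e1.lam2, e1.lam3])[:, sl, sl, sl]
        b = np.stack([e2.lam1, e2.lam2, e2.lam3])
        b = b[:, ::-1].transpose(0, 1, 3, 2)[:, sl, sl, sl]
        scale = np.abs(a).max()
        np.testing.assert_allclose(a, b, atol=0.01 * scale)

    def test_nonpositive_sigma_rejected(self):
        stack = quadratic_stack()
        with pytest.raises(ValueError):
            hessian_eigs(stack, "c", sigma_um=0.0)

    def test_undersampled_sigma_warns(self, caplog):
        stack = ImageStack(np.zeros((1, 8, 16, 16), np.float32),
                           (1.0, 0.3, 0.3), ["c"])
        with caplog.at_level("WARNING", logger="spheroquant.organelles"):
            hessian_eigs(stack, "c", sigma_um=0.3)
        assert any("under-sampled" in r.message for r in caplog.records)


def eig_maps(l1, l2, l3, sigma=1.0):
    return HessianEigenMaps(np.asarray(l1, float), np.asarray(l2, float),
                            np.asarray(l3, float), sigma)


class TestPLSMaps:
    def test_constant_image_all_maps_zero(self):
        stack = ImageStack(np.full((1, 10, 10, 10), 3.0, np.float32),
                           (0.5, 0.5, 0.5), ["c"])
        maps = pls_maps(hessian_eigs(stack, "c", sigma_um=1.0))
        for m in maps.values():
            np.testing.assert_allclose(m, 0.0, atol=1e-6)

    def test_saddle_on_quadratic_saddle_surface(self):
        """f = x² − y²: λ = (−2, 0, 2) so saddle = σ²·√(2·2) = 2σ²."""
        stack = quadratic_stack(coeffs=(0.0, 1.0, -1.0))
        sigma = 0.75
        maps = pls_maps(hessian_eigs(stack, "c", sigma_um=sigma))
        c = tuple(s // 2 for s in stack.voxels.shape[1:])
        assert maps["saddle"][c] == pytest.approx(2.0 * sigma ** 2, rel=0.05)
        assert maps["spot_bright"][c] == pytest.approx(0.0, abs=1e-6)

    def test_bright_sheet_is_plane_not_spot(self):
        """A Gaussian sheet has λ ≈ (−1/s², 0, 0) on its mid-plane."""
        s = 1.0
        r = np.arange(-6, 6.25, 0.25)
        z, y, x = np.meshgrid(r, r, r, indexing="ij")
        f = np.exp(-z ** 2 / (2 * s * s)) * 100
        stack = ImageStack(f[None].astype(np.float32), (0.25, 0.25, 0.25), ["c"])
        maps = pls_maps(hessian_eigs(stack, "c", sigma_um=0.4))
        c = tuple(v // 2 for v in f.shape)
        assert maps["plane_bright"][c] > 0
        assert maps["spot_bright"][c] == pytest.approx(0.0, abs=1e-6)

    def test_isotropic_blob_is_spot_not_plane(self):
        r = np.arange(-5, 5.25, 0.25)
        z, y, x = np.meshgrid(r, r, r, indexing="ij")
        f = np.exp(-(z ** 2 + y ** 2 + x ** 2) / 2.0) * 100
        stack = ImageStack(f[None].astype(np.float32), (0.25, 0.25, 0.25), ["c"])
        maps = pls_maps(hessian_eigs(stack, "c", sigma_um=0.4))
        c = tuple(v // 2 for v in f.shape)
        assert maps["spot_bright"][c] > 0
        assert maps["plane_bright"][c] == pytest.approx(0.0, abs=1e-6)

    @given(hnp.arrays(np.float64, (50, 3),
                      elements=st.floats(-30, 30, allow_nan=False)))
    @settings(max_examples=40, derandomize=True, deadline=None)
    def test_sign_guards_and_nonnegativity(self, lams):
        lams = np.sort(lams, axis=1)
        maps = pls_maps(eig_maps(lams[:, 0], lams[:, 1], lams[:, 2]))
        for m in maps.values():
            assert (m >= 0).all()
        any_nonneg = (lams >= 0).any(axis=1)
        assert (maps["spot_bright"][any_nonneg] == 0).all()
        same_sign = lams[:, 0] * lams[:, 2] > 0
        assert (maps["saddle"][same_sign] == 0).all()

    def test_offset_invariance_and_contrast_linearity(self, rng):
        """Adding a constant changes nothing; scaling contrast scales maps."""
        from scipy import ndimage
        f = ndimage.gaussian_filter(rng.random((16, 16, 16)), 1.5) * 50
        base = ImageStack(f[None].astype(np.float32), (0.5, 0.5, 0.5), ["c"])
        shifted = ImageStack((f + 111)[None].astype(np.float32),
                             (0.5, 0.5, 0.5), ["c"])
        scaled = ImageStack((f * 4)[None].astype(np.float32),
                            (0.5, 0.5, 0.5), ["c"])
        m0 = pls_maps(hessian_eigs(base, "c", 1.0))
        m1 = pls_maps(hessian_eigs(shifted, "c", 1.0))
        m4 = pls_maps(hessian_eigs(scaled, "c", 1.0))
        for key in m0:
            np.testing.assert_allclose(m1[key], m0[key], atol=1e-4)
            np.testing.assert_allclose(m4[key], 4 * m0[key], rtol=1e-4,
                                       atol=1e-4)


class TestSegmentLargeOrganelle:
    def test_empty_channel_gives_empty_set(self, small_rendered,
                                           truth_partition):
        spec, stack, _ = small_rendered
        zero = ImageStack(np.zeros_like(stack.voxels[:1]), spec.voxel_size,
                          ["golgi"])
        oset = segment_large_organelle(zero, "golgi", truth_partition)
        assert oset.labels.max() == 0 and oset.cell_of == {}

    def test_control_fragment_count_close_to_truth(self, small_rendered,
                                                   truth_partition):
        """Per-cell fragment counts within ±2 of the generated truth."""
        spec, stack, gt = small_rendered
        oset = segment_large_organelle(stack, "golgi", truth_partition,
                                       sigma_um=0.2, min_volume_um3=0.1)
        import collections
        per = collections.Counter(oset.cell_of.values())
        truth = gt.per_cell_truth.set_index("cell_id")["golgi_fragment_count"]
        diffs = [abs(per.get(c, 0) - truth[c]) for c in truth.index]
        assert np.median(diffs) <= 2

    def test_fragment_voxels_conserved_across_cells(self, small_rendered,
                                                    truth_partition):
        spec, stack, _ = small_rendered
        oset = segment_large_organelle(stack, "golgi", truth_partition,
                                       sigma_um=0.2, min_volume_um3=0.1)
        counts = np.bincount(oset.labels.ravel())
        assigned = sum(counts[f] for f in oset.cell_of)
        assert assigned == (oset.labels > 0).sum()


class TestDetectSpots:
    def test_well_separated_puncta_recovered(self):
        """Sparse puncta: at least 80% of the per-cell count is recovered."""
        spec = small_spec(seed=4, channels=("endosome",),
                          endosome_model=OrganelleModel(
                              16.0, n_puncta_per_cell=20, placement="uniform"))
        scene, gt = build_spheroid_phantom(spec)
        stack = render(scene, spec.optics, seed=spec.seed)
        from spheroquant.segment3d import CellPartition
        cells = CellPartition(gt.cell_labels, gt.nuclei_labels,
                              (gt.cell_labels > 0) & (gt.nuclei_labels == 0),
                              {i: i for i in range(1, spec.n_cells + 1)})
        oset = detect_spots(stack, "endosome", cells)
        import collections
        per = collections.Counter(oset.cell_of.values())
        counts = [per.get(c, 0) for c in range(1, spec.n_cells + 1)]
        assert np.median(counts) >= 0.8 * 20

    def test_two_puncta_separated_by_4_sigma_resolved(self):
        sigma = 0.4
        shape = (16, 40, 40)
        scene = np.zeros((1,) + shape, dtype=np.float32)
        zc, yc = 8, 20
        # sub-resolution puncta (single z plane, 3 px wide), 1.8 μm > 4σ apart
        for xc in (17, 23):
            scene[0, zc, yc - 1:yc + 2, xc - 1:xc + 2] = 1.0
        stack = render(ImageStack(scene, (1.0, 0.3, 0.3), ["c"]),
                       Optics(), seed=0)
        from spheroquant.segment3d import CellPartition
        # a central cell region with background margin around it (the
        # margin calibrates the noise floor, as in a real stack)
        cells_arr = np.zeros(shape, dtype=np.int32)
        cells_arr[2:-2, 6:-6, 6:-6] = 1
        cells = CellPartition(cells_arr, np.zeros(shape, np.int32),
                              cells_arr > 0, {1: 1})
        oset = detect_spots(stack, "c", cells, sigma_spot_um=sigma)
        assert oset.labels.max() == 2

    def test_noise_only_false_positive_rate(self, small_phantom,
                                            truth_partition):
        """Background-only stack: fewer than 0.5 spots per cell."""
        spec, scene, _ = small_phantom
        noise = ImageStack(np.zeros((1,) + spec.stack_shape, np.float32),
                           spec.voxel_size, ["endosome"])
        stack = render(noise, spec.optics, seed=9)
        oset = detect_spots(stack, "endosome", truth_partition)
        assert oset.labels.max() / spec.n_cells < 0.5


class TestPhenotypeOrderingMeasured:
    def test_fragment_counts_ordered_with_strong_significance(self):
        """Measured per-cell Golgi fragment counts: BFA > nocodazole >
        control, each pairwise rank-sum p < 0.001 (pooled cells of matched
        full-scale phantoms)."""
        import dataclasses

        from spheroquant.phantoms import paper_default
        from spheroquant.recovery import analyze_phantom
        from spheroquant.stats import mann_whitney

        counts = {}
        for phenotype in ("control", "nocodazole", "bfa"):
            spec = dataclasses.replace(
                paper_default(seed=17, channels=("golgi",)),
                phenotype=phenotype)
            result, _ = analyze_phantom(spec)
            counts[phenotype] = result.per_cell["golgi_fragment_count"]
        assert (counts["bfa"].median() > counts["nocodazole"].median()
                > counts["control"].median())
        for hi, lo in (("bfa", "nocodazole"), ("nocodazole", "control")):
            res = mann_whitney(counts[hi], counts[lo], alternative="greater")
            assert res.p_value < 0.001
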