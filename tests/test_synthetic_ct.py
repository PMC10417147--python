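import numpy as np
import pytest
from scipy.stats import wasserstein_distance

from cbctsct import (
    AnatomyChangeSpec,
    CbctDegradationSpec,
    ConversionFunction,
    DeformationField,
    DegenerateHistogramError,
    GeometryError,
    GridSpec,
    IntensityKind,
    PhantomSpec,
    VolumeImage,
    apply_anatomy_change,
    build_joint_histogram,
    estimate_artifact_map,
    fit_conversion_function,
    generate_phantom,
    identify_tissue_classes,
    low_density_override_mask,
    make_corrcbct,
    make_gtct,
    make_virtct,
    naive_rescale,
    retract_fov,
    simulate_cbct,
    to_density,
)
from cbctsct.core_images import mask_centroid_mm
from cbctsct.synthetic_ct import CorrCbctConfig


def _img(vox, kind=IntensityKind.HU, spacing=(3.0, 3.0, 3.0)):
    return VolumeImage(np.asarray(vox, float), spacing, (0, 0, 0), kind)


class TestJointHistogram:
    def test_identity_pair_mass_on_diagonal(self, rng):
        v = rng.normal(0, 100, (16, 16, 16))
        a = _img(v)
        b = _img(v, IntensityKind.CBCT_GRAY)
        h = build_joint_histogram(a, b, np.ones(v.shape, bool), bins=(32, 32))
        # equal binning on identical values: occupied cells lie on the diagonal
        occ = np.argwhere(h.counts > 0)
        assert np.all(np.abs(occ[:, 0] - occ[:, 1]) <= 1)

    def test_total_count_equals_mask_voxels(self, rng):
        a = _img(rng.normal(size=(10, 10, 10)))
        b = _img(rng.normal(size=(10, 10, 10)), IntensityKind.CBCT_GRAY)
        mask = rng.uniform(size=(10, 10, 10)) > 0.4
        h = build_joint_histogram(a, b, mask)
        assert h.counts.sum() == mask.sum() == h.n_voxels

    def test_two_class_pair_occupies_two_modes(self):
        hu = np.full((12, 12, 12), -1000.0)
        hu[4:8] = 40.0
        gray = np.where(hu < 0, -700.0, 80.0)
        h = build_joint_histogram(_img(hu), _img(gray, IntensityKind.CBCT_GRAY), np.ones(hu.shape, bool), bins=(16, 16))
        assert (h.counts > 0).sum() == 2

    def test_empty_mask_raises(self):
        a = _img(np.zeros((4, 4, 4)))
        with pytest.raises(GeometryError):
            build_joint_histogram(a, _img(np.zeros((4, 4, 4)), IntensityKind.CBCT_GRAY), np.zeros((4, 4, 4), bool))


class TestTissueClasses:
    def _three_class_hist(self, noise=5.0, seed=0):
        rng = np.random.default_rng(seed)
        hu = np.concatenate(
            [rng.normal(-1000, 3, 40000), rng.normal(40, 12, 30000), rng.normal(700, 40, 8000)]
        )
        gray = 0.8 * hu + 40 + rng.normal(0, noise, hu.size)
        n = 19500 * 4
        a = _img(hu[:n].reshape(30, 52, 50))
        b = _img(gray[:n].reshape(30, 52, 50), IntensityKind.CBCT_GRAY)
        return build_joint_histogram(a, b, np.ones(a.voxels.shape, bool))

    def test_three_class_points_within_30_hu(self):
        pts = identify_tissue_classes(self._three_class_hist())
        assert len(pts) == 3
        for (g, h), expect in zip(pts, (-1000.0, 40.0, 700.0)):
            assert abs(h - expect) < 30.0

    def test_points_ordered_and_include_air_and_soft(self):
        pts = identify_tissue_classes(self._three_class_hist())
        grays = [g for g, _ in pts]
        assert grays == sorted(grays)
        assert pts[0][1] < -900 and abs(pts[1][1] - 40) < 60

    def test_identity_pair_points_on_diagonal(self):
        rng = np.random.default_rng(1)
        v = np.concatenate([rng.normal(-1000, 5, 30000), rng.normal(40, 10, 30000)])[:57600]
        a = _img(v.reshape(40, 40, 36))
        h = build_joint_histogram(a, a.with_voxels(a.voxels, IntensityKind.CBCT_GRAY), np.ones((40, 40, 36), bool))
        for g, hu in identify_tissue_classes(h):
            assert abs(g - hu) < 40.0

    def test_deterministic(self):
        h = self._three_class_hist()
        assert identify_tissue_classes(h) == identify_tissue_classes(h)

    def test_single_mode_degenerate(self, rng):
        v = rng.normal(0, 3, (12, 12, 12))
        a = _img(v)
        h = build_joint_histogram(a, a.with_voxels(v, IntensityKind.CBCT_GRAY), np.ones(v.shape, bool))
        with pytest.raises(DegenerateHistogramError):
            identify_tissue_classes(h)


class TestConversionFunction:
    def test_linear_interpolation_example(self):
        f = fit_conversion_function([(0.0, -1000.0), (1000.0, 0.0)])
        assert f(500.0) == pytest.approx(-500.0)

    def test_single_segment_matches_line_everywhere(self, rng):
        f = fit_conversion_function([(0.0, -1000.0), (1000.0, 0.0)])
        g = rng.uniform(-20, 1020, 100)
        expect = np.clip(-1000.0 + g, -1024, 3071)
        assert np.allclose(f(g), expect)

    def test_junctions_reproduced_exactly(self):
        pts = [(-760.0, -1000.0), (72.0, 40.0), (600.0, 700.0)]
        f = fit_conversion_function(pts)
        for g, h in pts:
            assert f(g) == h

    def test_extrapolation_clamped(self):
        f = fit_conversion_function([(0.0, -1000.0), (10.0, 3000.0)])
        assert f(1e6) == 3071.0
        assert f(-1e6) == -1024.0

    def test_non_monotone_points_isotonized_with_warning(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="cbctsct"):
            f = fit_conversion_function([(0.0, 0.0), (1.0, 100.0), (2.0, 50.0), (3.0, 200.0)])
        assert any("isotonic" in r.message for r in caplog.records)
        out = f(np.linspace(0, 3, 50))
        assert np.all(np.diff(out) >= -1e-9)

    def test_constructor_rejects_bad_junctions(self):
        with pytest.raises(ValueError):
            ConversionFunction(((0.0, 0.0),))
        with pytest.raises(ValueError):
            ConversionFunction(((0.0, 0.0), (0.0, 1.0)))
        with pytest.raises(ValueError):
            ConversionFunction(((0.0, 1.0), (1.0, 0.0)))

    def test_derivative_matches_segment_slopes(self):
        f = ConversionFunction(((0.0, 0.0), (10.0, 100.0), (30.0, 120.0)))
        assert f.derivative(5.0) == pytest.approx(10.0)
        assert f.derivative(20.0) == pytest.approx(1.0)
        assert f.derivative(-5.0) == pytest.approx(10.0)  # terminal slope

    def test_roundtrip_serialization(self):
        f = ConversionFunction(((-760.0, -1000.0), (72.0, 40.0)))
        g = ConversionFunction.from_dict(f.to_dict())
        assert g.junctions == f.junctions


class TestArtifactMap:
    def test_identical_inputs_give_zero_map(self, phantom, degraded_cbct):
        pct, _ = phantom
        _, fov, _, _ = degraded_cbct
        amap = estimate_artifact_map(pct, pct, fov)
        assert np.abs(amap.volume).max() == 0.0

    def test_planted_shading_recovered(self, phantom):
        """The simulator's default 80-HU shading field is recovered with
        >=80 % amplitude in the filter-supported interior and <15 HU mean
        residual over the retracted-FOV focus."""
        pct, _ = phantom
        deg = CbctDegradationSpec(gain=1.0, offset=0.0, shading_amplitude=80.0, noise_sd=0.0, seed=4)
        cbct, fov, _ = simulate_cbct(pct, deg)
        shading = np.where(fov, cbct.voxels - pct.voxels, 0.0)
        amap = estimate_artifact_map(cbct.with_voxels(cbct.voxels, IntensityKind.HU), pct, fov)
        focus = retract_fov(fov, pct.spacing, 20.0)
        interior = retract_fov(fov, pct.spacing, 50.0)  # 2 filter sigmas from the edge
        slope = np.polyfit(shading[interior], amap.volume[interior], 1)[0]
        assert slope >= 0.8
        assert np.abs(shading - amap.volume)[focus].mean() < 15.0

    def test_impulse_leaks_below_ten_percent(self, phantom, degraded_cbct):
        pct, _ = phantom
        _, fov, _, _ = degraded_cbct
        spike = np.zeros(pct.voxels.shape)
        spike[48, 48, 30] = 500.0
        amap = estimate_artifact_map(pct.with_voxels(pct.voxels + spike), pct, fov)
        assert np.abs(amap.volume).max() < 0.1 * 500.0

    def test_spectral_power_is_low_frequency(self, phantom):
        pct, _ = phantom
        deg = CbctDegradationSpec(gain=1.0, offset=0.0, shading_amplitude=80.0, noise_sd=0.0, seed=4)
        cbct, fov, _ = simulate_cbct(pct, deg)
        amap = estimate_artifact_map(cbct.with_voxels(cbct.voxels, IntensityKind.HU), pct, fov)
        # nearly all power below twice the filter's half-power frequency
        cutoff = 2.0 * np.sqrt(np.log(2) / 2.0) / (np.pi * amap.sigma_mm)
        assert amap.spectral_lowfreq_ratio(cutoff) > 0.9


class TestCorrCbct:
    def test_null_degradation_matches_deformed_pct(self, changed_case):
        pct, _, vfct, _, _, _ = changed_case
        deg = CbctDegradationSpec(gain=1.0, offset=0.0, shading_amplitude=0.0, noise_sd=0.0)
        cbct, fov, _ = simulate_cbct(vfct, deg)
        res = make_corrcbct(pct, cbct, fov)
        mad = np.abs(res.corrcbct.voxels - res.pct_deformed.voxels)[fov].mean()
        assert mad < 20.0

    def test_improvement_over_naive_rescale(self, changed_case, degraded_cbct, corrcbct_result):
        """Soft-tissue |HU error| vs the true treatment-day anatomy improves
        >=5x over a nominal two-point rescale of the CBCT."""
        _, _, vfct, vf_structs, _, _ = changed_case
        cbct, fov, _, _ = degraded_cbct
        soft = (
            vf_structs.masks["External"]
            & ~vf_structs.masks["Bones"]
            & ~vf_structs.masks["AirCavities"]
            & fov
        )
        err_corr = np.abs(corrcbct_result.corrcbct.voxels - vfct.voxels)[soft].mean()
        err_naive = np.abs(naive_rescale(cbct, fov).voxels - vfct.voxels)[soft].mean()
        assert err_naive >= 5.0 * err_corr

    def test_out_of_fov_equals_deformed_pct_exactly(self, degraded_cbct, corrcbct_result):
        _, fov, _, _ = degraded_cbct
        outside = ~fov
        diff = corrcbct_result.corrcbct.voxels - corrcbct_result.pct_deformed.voxels
        assert np.abs(diff[outside]).max() == 0.0

    def test_conversion_stays_monotone(self, corrcbct_result):
        g = np.array([j[0] for j in corrcbct_result.conversion.junctions])
        h = np.array([j[1] for j in corrcbct_result.conversion.junctions])
        assert np.all(np.diff(g) > 0)
        assert np.all(np.diff(h) >= 0)

    def test_iteration_change_non_increasing(self, corrcbct_result):
        deltas = [t["mean_abs_change_hu"] for t in corrcbct_result.trace if t["mean_abs_change_hu"] is not None]
        assert len(deltas) >= 1
        assert all(b <= a * 1.05 for a, b in zip(deltas, deltas[1:]))

    def test_convergence_flag_and_trace(self, corrcbct_result):
        assert corrcbct_result.converged
        assert corrcbct_result.trace[0]["iteration"] == 0

    def test_rejects_wrong_intensity_kind(self, phantom):
        pct, _ = phantom
        with pytest.raises(ValueError, match="CBCT_GRAY"):
            make_corrcbct(pct, pct, np.ones(pct.voxels.shape, bool))


class TestDensity:
    def test_calibration_anchors(self):
        img = _img([[[0.0, -1000.0, 1500.0]]])
        rho = to_density(img).voxels.ravel()
        assert rho[0] == pytest.approx(1.0)
        assert rho[1] == pytest.approx(0.001)
        assert rho[2] == pytest.approx(1.85)

    def test_interpolation_between_water_and_bone(self):
        rho = to_density(_img([[[750.0]]])).voxels.ravel()[0]
        assert rho == pytest.approx(1.0 + 750.0 / 1500.0 * 0.85)

    def test_non_monotone_calibration_rejected(self):
        with pytest.raises(ValueError, match="monotone"):
            to_density(_img([[[0.0]]]), calibration=((0.0, 1.0), (100.0, 0.5)))

    def test_density_floor_at_zero(self):
        assert to_density(_img([[[-4000.0]]])).voxels.min() >= 0.0


class TestVirtCt:
    def test_override_rule_worked_examples(self):
        # rho 1.00 vs 0.20: overridden; 1.80 vs 1.20: not (neither < 0.6);
        # equal densities: never
        assert low_density_override_mask(np.array(1.00), np.array(0.20))
        assert not low_density_override_mask(np.array(1.80), np.array(1.20))
        assert not low_density_override_mask(np.array(0.5), np.array(0.5))

    def test_boundary_values_excluded(self):
        # strict inequalities at the exact boundaries (0.3 - 0.0 is the same
        # float as the 0.3 threshold, so the difference is exactly boundary)
        assert not low_density_override_mask(np.array(0.0), np.array(0.3))  # delta exactly 0.3
        assert not low_density_override_mask(np.array(0.6), np.array(1.2))  # min exactly 0.6
        assert low_density_override_mask(np.array(0.59), np.array(1.2))

    def test_null_difference_keeps_deformed_pct(self, phantom):
        pct, _ = phantom
        field = DeformationField.identity(pct.grid)
        fov = np.ones(pct.voxels.shape, bool)
        virt, override = make_virtct(pct, pct, field, fov)
        assert not override.any()
        assert np.array_equal(virt.voxels, pct.voxels)

    def test_override_mask_matches_brute_force(self, rng):
        hu_a = rng.uniform(-1000, 1500, (32, 32, 32))
        hu_b = rng.uniform(-1000, 1500, (32, 32, 32))
        a = _img(hu_a)
        b = _img(hu_b)
        fov = np.ones(hu_a.shape, bool)
        virt, override = make_virtct(a, b, DeformationField.identity(a.grid), fov)
        rho_a = to_density(a).voxels
        rho_b = to_density(b).voxels
        expect = np.empty(hu_a.shape, bool)
        for i in range(hu_a.shape[0]):  # brute-force reevaluation
            expect[i] = (np.abs(rho_a[i] - rho_b[i]) > 0.3) & (
                np.minimum(rho_a[i], rho_b[i]) < 0.6
            )
        assert np.array_equal(override, expect)
        assert np.array_equal(virt.voxels[override], hu_b[override])
        assert np.array_equal(virt.voxels[~override], hu_a[~override])

    def test_outside_fov_never_overridden(self, rng):
        hu_a = rng.uniform(-1000, 0, (16, 16, 16))
        hu_b = np.full_like(hu_a, 500.0)
        fov = np.zeros(hu_a.shape, bool)
        fov[4:12, 4:12, 4:12] = True
        _, override = make_virtct(_img(hu_a), _img(hu_b), DeformationField.identity(_img(hu_a).grid), fov)
        assert not override[~fov].any()

    def test_shoulder_streaks_cause_false_overrides_monotonically(self, phantom):
        """Streak artifacts between the shoulders produce spurious low-density
        overrides whose count shrinks as the streak amplitude goes to zero."""
        pct, structs = phantom
        counts = []
        for amp in (600.0, 450.0, 0.0):
            deg = CbctDegradationSpec(
                gain=1.0, offset=0.0, shading_amplitude=0.0, noise_sd=0.0,
                shoulder_streak_amplitude=amp,
            )
            cbct, fov, _ = simulate_cbct(pct, deg)
            corr = cbct.with_voxels(cbct.voxels, IntensityKind.HU)  # conversion-free: gray==HU here
            virt, override = make_virtct(pct, corr, DeformationField.identity(pct.grid), fov)
            body = structs.masks["External"]
            counts.append(int((override & body).sum()))
        assert counts[0] > counts[1] > counts[2] == 0


class TestGtCt:
    def test_identity_geometry_limit(self):
        """CBCT simulated at the vfCT's own geometry: the gtCT equals the
        vfCT within interpolation tolerance."""
        vfct, _ = generate_phantom(PhantomSpec(seed=21))
        cbct, fov, _ = simulate_cbct(vfct, CbctDegradationSpec(seed=22))
        gtct, _ = make_gtct(vfct, cbct, fov)
        assert np.abs(gtct.voxels - vfct.voxels).mean() < 5.0

    def test_planted_shift_recovered(self):
        """CBCT simulated from a shifted vfCT (setup difference): the gtCT
        anatomy inside the focus lands at the CBCT position within 1 mm."""
        from cbctsct.registration import warp_image, warp_mask

        vfct, structs = generate_phantom(PhantomSpec(seed=23))
        shift = np.array([5.0, 0.0, 0.0])
        u = np.zeros(tuple(vfct.grid.shape) + (3,))
        u[...] = -shift  # pull-back: content moves +shift
        const = DeformationField(u, vfct.grid)
        moved = warp_image(vfct, const)
        cbct, fov, _ = simulate_cbct(moved, CbctDegradationSpec(noise_sd=0.0, seed=24))
        gtct, field = make_gtct(vfct, cbct, fov)
        # probe a high-contrast structure deep inside the focus region (the
        # displacement is feathered to identity at the focus boundary by
        # contract, so structures straddling the boundary cannot fully move)
        zwin = np.zeros(vfct.grid.shape, bool)
        zwin[:, :, 22:39] = True
        spine = structs.masks["Bones"] & zwin & ~structs.masks["ShoulderBones"]
        c_gt = mask_centroid_mm(warp_mask(spine, field), vfct.grid)
        c_true = mask_centroid_mm(warp_mask(spine, const), vfct.grid)
        assert np.linalg.norm(c_gt - c_true) < 1.0

    def test_intensity_content_preserved(self):
        """Deformation rearranges but does not invent intensity content."""
        vfct, structs = generate_phantom(PhantomSpec(seed=25))
        cbct, fov, _ = simulate_cbct(vfct, CbctDegradationSpec(seed=26))
        gtct, _ = make_gtct(vfct, cbct, fov)
        body = structs.masks["External"]
        d = wasserstein_distance(gtct.voxels[body], vfct.voxels[body])
        assert d < 10.0
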