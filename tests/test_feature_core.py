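"""Analytic and brute-force oracles for the signal/geometry primitives."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from kinemarker import feature_core as fc


class TestVoxelOccupancy:
    def test_single_point_single_voxel(self):
        occ = fc.voxel_occupancy(np.tile([1.0, 2.0, 3.0], (50, 1)), edge_cm=2.0)
        assert occ.n_nonempty == 1
        assert occ.total == 50
        assert fc.workspace_volume(occ) == pytest.approx(8.0)

    def test_line_segment_matches_brute_force_enumeration(self):
        """Densely sampled axis-aligned segment: voxel count by enumeration."""
        for start in (0.0, 0.5, 1.0, 1.3):
            pts = np.zeros((2001, 3))
            pts[:, 0] = np.linspace(start, start + 10.0, 2001)
            pts[:, 1:] = 0.25
            occ = fc.voxel_occupancy(pts, edge_cm=2.0)
            # brute force: bin each sample on the same snapped grid
            origin = np.floor(pts.min(axis=0) / 2.0) * 2.0
            expected = len({tuple(v) for v in
                            np.floor((pts - origin) / 2.0).astype(int)})
            assert occ.n_nonempty == expected
            assert expected in (5, 6)

    def test_box_cloud_matches_brute_force(self):
        rng = np.random.default_rng(3)
        pts = rng.uniform(0, 7.9, size=(4000, 3))
        occ = fc.voxel_occupancy(pts, edge_cm=2.0)
        origin = np.floor(pts.min(axis=0) / 2.0) * 2.0
        expected = len({tuple(v) for v in np.floor((pts - origin) / 2.0).astype(int)})
        assert occ.n_nonempty == expected

    @given(st.integers(min_value=-500, max_value=500))
    def test_grid_translation_invariance(self, shift):
        rng = np.random.default_rng(11)
        pts = rng.uniform(0, 20, size=(300, 3))
        occ0 = fc.voxel_occupancy(pts, edge_cm=2.0)
        occ1 = fc.voxel_occupancy(pts + 2.0 * shift, edge_cm=2.0)
        assert occ0.n_nonempty == occ1.n_nonempty
        assert sorted(occ0.counts.values()) == sorted(occ1.counts.values())

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            fc.voxel_occupancy(np.empty((0, 3)))

    @pytest.mark.parametrize("edge,n,expect", [(2.0, 3, 24.0), (1.0, 10, 10.0)])
    def test_volume_formula(self, edge, n, expect):
        pts = np.array([[i * edge * 1.01, 0, 0] for i in range(n)])
        occ = fc.voxel_occupancy(pts, edge_cm=edge)
        assert fc.workspace_volume(occ) == pytest.approx(expect)


class TestWorkspaceEntropy:
    def test_single_voxel_zero(self):
        occ = fc.voxel_occupancy(np.zeros((9, 3)))
        assert fc.workspace_entropy(occ) == pytest.approx(0.0)

    @pytest.mark.parametrize("k", [2, 5, 17])
    def test_uniform_occupancy_is_log_k(self, k):
        pts = np.array([[2.5 * i, 0.1, 0.1] for i in range(k) for _ in range(4)])
        occ = fc.voxel_occupancy(pts, edge_cm=2.0)
        assert occ.n_nonempty == k
        assert fc.workspace_entropy(occ) == pytest.approx(np.log(k), abs=1e-12)

    def test_counts_3_1_hand_arithmetic(self):
        pts = np.array([[0.5, 0.5, 0.5]] * 3 + [[3.0, 0.5, 0.5]])
        occ = fc.voxel_occupancy(pts, edge_cm=2.0)
        expect = (-np.log(0.75) - np.log(0.25)) / 2
        assert fc.workspace_entropy(occ) == pytest.approx(expect, abs=1e-12)
        assert expect == pytest.approx(0.8370, abs=5e-5)

    @given(st.integers(min_value=1, max_value=60))
    def test_entropy_lower_bound_is_log_k(self, seed):
        """Mean negative log occupancy is >= ln K (Jensen), = ln K iff uniform."""
        rng = np.random.default_rng(seed)
        pts = rng.uniform(0, 12, size=(rng.integers(1, 400), 3))
        occ = fc.voxel_occupancy(pts)
        h = fc.workspace_entropy(occ)
        assert h >= np.log(occ.n_nonempty) - 1e-12
        assert h >= -1e-12


class TestAutocorrelation:
    def test_lag0_is_one(self):
        rng = np.random.default_rng(1)
        c = fc.autocorrelation(rng.standard_normal(500), 50)
        assert c[0] == pytest.approx(1.0)

    def test_sinusoid_matches_cosine(self):
        fr, T = 100.0, 0.5
        t = np.arange(0, 200, 1 / fr)
        c = fc.autocorrelation(np.sin(2 * np.pi * t / T), int(T * fr))
        assert c[int(T * fr)] == pytest.approx(1.0, abs=0.02)
        assert c[int(T * fr / 2)] == pytest.approx(-1.0, abs=0.02)

    def test_white_noise_decorrelates(self):
        rng = np.random.default_rng(2)
        c = fc.autocorrelation(rng.standard_normal(100_000), 20)
        assert np.abs(c[1:]).max() < 0.02

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            fc.autocorrelation(np.ones(100), 10)


class TestAutocorrCyclePCs:
    def test_output_has_50_bins(self):
        fr, cyc = 60.0, 1.0
        t = np.arange(0, 4.0, 1 / fr)
        curves = np.vstack([np.cos(2 * np.pi * t / cyc) * (1 + 0.01 * i)
                            for i in range(5)])
        pcs, evr, vals, deg = fc.autocorr_cycle_pcs(curves, cyc, fr)
        assert pcs.shape[0] == 50

    def test_identical_channels_degenerate_spectrum(self):
        fr, cyc = 60.0, 1.0
        t = np.arange(0, 4.0, 1 / fr)
        curves = np.tile(np.cos(2 * np.pi * t / cyc), (8, 1))
        pcs, evr, vals, deg = fc.autocorr_cycle_pcs(curves, cyc, fr)
        assert deg
        assert evr[0] == pytest.approx(1.0)
        assert np.allclose(evr[1:], 0.0)

    def test_two_period_clusters_need_two_pcs(self):
        fr, cyc = 60.0, 1.0
        t = np.arange(0, 4.0, 1 / fr)
        rng = np.random.default_rng(0)
        curves = []
        for i in range(51):
            period = cyc if i < 25 else 2 * cyc
            curves.append(np.cos(2 * np.pi * t / period) * (1 + 0.02 * rng.random()))
        _, evr, _, deg = fc.autocorr_cycle_pcs(np.vstack(curves), cyc, fr)
        assert not deg
        assert evr[:2].sum() >= 0.99

    def test_insufficient_lag_span_rejected(self):
        fr, cyc = 60.0, 1.0
        curves = np.random.default_rng(0).standard_normal((3, 60))  # 1 cycle only
        with pytest.raises(ValueError):
            fc.autocorr_cycle_pcs(curves, cyc, fr)


class TestFWHM:
    def test_sinusoid_width_is_third_of_period(self):
        """cos ACF crosses 0.5 at T/6, so the full width is T/3."""
        fr, T = 200.0, 1.0
        t = np.arange(0, 300, 1 / fr)
        curve = fc.autocorrelation(np.sin(2 * np.pi * t / T), int(2 * T * fr))
        width, saturated = fc.autocorr_fwhm(curve, fr)
        assert not saturated
        assert width == pytest.approx(T / 3, rel=0.02)

    def test_gaussian_bump_closed_form(self):
        fr, s = 100.0, 0.7
        tau = np.arange(0, 10, 1 / fr)
        width, saturated = fc.autocorr_fwhm(np.exp(-tau ** 2 / (2 * s * s)), fr)
        assert not saturated
        assert width == pytest.approx(2 * s * np.sqrt(2 * np.log(2)), rel=1e-3)

    def test_never_crossing_saturates(self):
        fr = 60.0
        curve = np.full(int(10 * fr) + 1, 0.99)
        width, saturated = fc.autocorr_fwhm(curve, fr)
        assert saturated
        assert width == pytest.approx(2 * 10.0, rel=0.01)


class TestDelaySpectrum:
    def test_independent_white_channels_uniform(self):
        rng = np.random.default_rng(5)
        n, C = 20_000, 8
        spec = fc.delay_crosscorr_spectrum(rng.standard_normal((C, n)), [0])
        assert np.abs(spec.values - 1.0 / C).max() < 3.0 / np.sqrt(n)

    def test_duplicated_channels_add_null_directions(self):
        rng = np.random.default_rng(6)
        X = rng.standard_normal((5, 5000))
        base = fc.delay_crosscorr_spectrum(X, [0])
        dup = fc.delay_crosscorr_spectrum(np.vstack([X, X]), [0])
        assert dup.values[: 5].sum() >= base.values.sum() - 1e-9
        assert np.all(dup.values[5:] < 1e-10)

    @given(st.integers(min_value=0, max_value=40))
    def test_spectrum_contract(self, seed):
        rng = np.random.default_rng(seed)
        C, L = rng.integers(2, 6), rng.integers(1, 4)
        X = rng.standard_normal((C, 400))
        spec = fc.delay_crosscorr_spectrum(X, list(range(0, 10 * L, 10)))
        assert spec.values.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.diff(spec.values) <= 1e-12)
        assert np.all(spec.values >= 0)
        assert spec.n == C * L

    def test_zero_variance_channel_named(self):
        X = np.vstack([np.ones(100), np.random.default_rng(0).standard_normal(100)])
        with pytest.raises(ValueError, match=r"\[0\]"):
            fc.delay_crosscorr_spectrum(X, [0, 5])


class TestComplexity:
    def test_isotropic_noise_near_100pct(self):
        rng = np.random.default_rng(7)
        res = fc.pca_complexity(rng.standard_normal((20, 10_000)))
        assert res.complexity_pct == pytest.approx(100.0, abs=3.0)

    def test_rank_one_motion_low_complexity(self):
        t = np.linspace(0, 10, 2000)
        s = np.sin(2 * np.pi * t)
        X = np.vstack([s * (i + 1) for i in range(12)])
        res = fc.pca_complexity(X)
        assert res.complexity_pct < 10.0
        assert res.n_pcs_for[0.9] == 1

    def test_n_pcs_monotone_in_threshold(self):
        rng = np.random.default_rng(8)
        res = fc.pca_complexity(rng.standard_normal((10, 500)),
                                thresholds=(0.5, 0.8, 0.9, 0.99))
        ks = [res.n_pcs_for[q] for q in (0.5, 0.8, 0.9, 0.99)]
        assert ks == sorted(ks)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            fc.pca_complexity(np.ones((5, 100)))


class TestSTFTPower:
    def test_zero_signal_zero_power(self):
        t, rms = fc.stft_rms_power(np.zeros(600), 60.0)
        assert np.allclose(rms, 0.0)

    def test_constant_rms_and_linearity_for_tone(self):
        # 5 Hz = whole cycles per 200 ms window, so window phase cannot leak
        fr = 60.0
        tt = np.arange(0, 10, 1 / fr)
        x = np.sin(2 * np.pi * 5.0 * tt)
        _, r1 = fc.stft_rms_power(x, fr)
        interior = r1[2:-2]
        assert np.ptp(interior) / interior.mean() < 0.05
        y = np.sin(2 * np.pi * 2.0 * tt)
        _, a1 = fc.stft_rms_power(y, fr)
        _, a2 = fc.stft_rms_power(2 * y, fr)
        assert np.allclose(a2, 2 * a1, rtol=1e-9)

    def test_lowpass_attenuates_stop_band(self):
        fr = 100.0
        tt = np.arange(0, 10, 1 / fr)
        x = np.sin(2 * np.pi * 20.0 * tt)
        _, filt = fc.stft_rms_power(x, fr, lowpass_hz=10.0)
        _, raw = fc.stft_rms_power(x, fr, lowpass_hz=None)
        assert filt.mean() < 0.05 * raw.mean()

    def test_window_longer_than_signal_rejected(self):
        with pytest.raises(ValueError):
            fc.stft_rms_power(np.zeros(5), 60.0)

    def test_cycle_energy_averages_per_stride_areas(self):
        times = np.linspace(0, 10, 101)
        rms = np.ones_like(times)
        # unit-height curve: per-stride area equals stride duration
        e = fc.cycle_energy(times, rms, np.array([0.0, 2.0, 4.0]))
        assert e == pytest.approx(2.0, rel=0.06)


class TestLogisticFit:
    def test_scale_recovery_at_large_n(self):
        rng = np.random.default_rng(9)
        x = rng.logistic(0.0, 2.0, size=100_000)
        fit = fc.fit_logistic_scale(x)
        assert fit.sigma == pytest.approx(2.0, rel=0.02)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(10)
        x = rng.logistic(1.0, 0.5, size=5000)
        s1 = fc.fit_logistic_scale(x).sigma
        s2 = fc.fit_logistic_scale(3.0 * x).sigma
        assert s2 == pytest.approx(3.0 * s1, rel=1e-6)

    def test_aic_selects_logistic_on_logistic_draws(self):
        rng = np.random.default_rng(12)
        wins = sum(
            fc.aic_model_select(rng.logistic(0, 1, size=5000)) == "logistic"
            for _ in range(100))
        assert wins >= 95

    def test_zero_spread_rejected(self):
        with pytest.raises(ValueError):
            fc.fit_logistic_scale(np.ones(100))


class TestHeadPlaneArea:
    def test_stationary_head_degenerate_zero(self):
        pts = np.tile([0.0, 60.0, 0.0], (30, 1))
        area, fsd, ssd, degen = fc.head_plane_area(pts)
        assert degen
        assert area == 0.0 and fsd == 0.0 and ssd == 0.0

    def test_rectangle_boundary_hull_area(self):
        """Head tracing an L x W rectangle in the plane: hull area = L*W."""
        L, W = 8.0, 3.0
        u = np.linspace(0, 1, 400, endpoint=False)
        edge = np.concatenate
        x = edge([u * L, np.full(400, L), (1 - u) * L, np.zeros(400)])
        z = edge([np.zeros(400), u * W, np.full(400, W), (1 - u) * W])
        pts = np.column_stack([x - L / 2, np.full(1600, 60.0), z - W / 2])
        area, fsd, ssd, degen = fc.head_plane_area(pts, forward_axis=(0, 0, 1))
        assert not degen
        assert area == pytest.approx(L * W, rel=1e-6)

    def test_sds_along_frontal_and_sideways_axes(self):
        rng = np.random.default_rng(13)
        pts = np.column_stack([rng.normal(0, 1.0, 3000),
                               np.full(3000, 60.0),
                               rng.normal(0, 4.0, 3000)])
        area, fsd, ssd, _ = fc.head_plane_area(pts, forward_axis=(0, 0, 1))
        assert fsd == pytest.approx(4.0, rel=0.1)   # frontal = walking direction z
        assert ssd == pytest.approx(1.0, rel=0.1)


class TestPairwisePearson:
    def test_self_and_negated(self):
        rng = np.random.default_rng(14)
        x = rng.standard_normal(1000)
        out = fc.pairwise_pearson({"x": x, "mx": -x, "y": rng.standard_normal(1000)})
        assert out[("x", "mx")] == pytest.approx(-1.0)
        assert abs(out[("x", "y")]) < 0.1

    def test_independent_noise_bound(self):
        rng = np.random.default_rng(15)
        out = fc.pairwise_pearson({"a": rng.standard_normal(100_000),
                                   "b": rng.standard_normal(100_000)})
        assert abs(out[("a", "b")]) < 0.01

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            fc.pairwise_pearson({"a": np.ones(10), "b": np.arange(10.0)})
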