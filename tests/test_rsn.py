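"""Resting-state pipeline: generator, preprocessing, regressions, mixture model."""

import numpy as np
import pytest

from muxepi import phantom, rsn, timing
from muxepi.rsn import (
    concat_group_pca,
    correct_z,
    dual_regression,
    fit_ggm,
    generate_rsn_dataset,
    make_rsn_truth,
    predicted_sensitivity_ratio,
    preprocess,
    rsn_metrics,
    single_regression,
)


@pytest.fixture(scope="module")
def small_phantom():
    return phantom.make_brain_phantom(6, 16, seed=3)


@pytest.fixture(scope="module")
def truth(small_phantom):
    return make_rsn_truth(
        shape=(6, 16, 16), n_networks=4, duration_s=300, seed=3,
        support=small_phantom.gm_mask,
    )


def protocol(tr, flip):
    return timing.ProtocolSpec(tr=tr, flip_deg=flip, matrix=16, n_slices=6)


class TestGenerator:
    def test_deterministic(self, truth, small_phantom):
        a, _ = generate_rsn_dataset(truth, small_phantom, protocol(2.5, 90), seed=4)
        b, _ = generate_rsn_dataset(truth, small_phantom, protocol(2.5, 90), seed=4)
        assert np.array_equal(a, b)

    def test_cardiac_aliases_to_predicted_frequency(self, small_phantom):
        """1 Hz cardiac appears at |1 - 1/TR| = 0.2 Hz when TR = 2.5 s."""
        t = make_rsn_truth(
            shape=(6, 16, 16), n_networks=1, duration_s=300, seed=9,
            support=small_phantom.gm_mask, amp_pct=0.0, resp_amp_pct=0.0,
            cardiac_amp_pct=3.0, phase_walk_rad_per_sqrt_s=0.05, thermal_sigma=1e-4,
        )
        series, info = generate_rsn_dataset(t, small_phantom, protocol(2.5, 90), seed=0)
        amp = t.confounds["cardiac"]["amp_map"]
        v = np.unravel_index(np.argmax(amp), amp.shape)
        sig = series[(slice(None), *v)]
        sig = sig - sig.mean()
        f = np.fft.rfftfreq(len(sig), 2.5)
        peak = f[np.argmax(np.abs(np.fft.rfft(sig)))]
        assert peak == pytest.approx(0.2, abs=0.03)

    def test_grid_mismatch_rejected(self, truth):
        other = phantom.make_brain_phantom(4, 16, seed=0)
        with pytest.raises(ValueError):
            generate_rsn_dataset(truth, other, protocol(2.5, 90))


class TestPreprocess:
    def test_constant_series_unchanged(self):
        series = np.full((20, 4, 8, 8), 7.0)
        out = preprocess(series, tr=2.5, highpass_s=40.0, fwhm_mm=5.0)
        assert np.allclose(out, 7.0)

    def test_slow_drift_strongly_attenuated(self):
        t = np.arange(240) * 2.5
        drift = np.sin(2 * np.pi * t / 600.0)
        series = np.tile(drift[:, None, None, None], (1, 2, 4, 4))
        out = preprocess(series, tr=2.5, highpass_s=200.0, fwhm_mm=0.0)
        assert out.std() < 0.1 * series.std()

    def test_mean_preserved(self):
        rng = np.random.default_rng(0)
        series = 5.0 + rng.standard_normal((120, 2, 8, 8))
        out = preprocess(series, tr=2.5, highpass_s=200.0, fwhm_mm=0.0)
        assert np.allclose(out.mean(axis=0), series.mean(axis=0))

    def test_delta_smoothed_to_requested_fwhm(self):
        series = np.zeros((2, 1, 33, 33))
        series[:, 0, 16, 16] = 1.0
        out = preprocess(series, tr=100.0, highpass_s=150.0, fwhm_mm=5.0, voxel_mm=1.0)
        prof = out[0, 0, 16]
        half = prof.max() / 2
        width = (prof >= half).sum()
        assert width == pytest.approx(5.0, abs=1.0)

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            preprocess(np.zeros((10, 2, 4, 4)), tr=1.0, highpass_s=200.0)


class TestGroupPca:
    def test_three_datasets_concatenate_to_triple_components(self):
        rng = np.random.default_rng(0)
        datasets = [rng.standard_normal((60, 5, 8, 8)) for _ in range(3)]
        out = concat_group_pca(datasets, n_components=20)
        assert out.shape == (60, 5 * 8 * 8)

    def test_block_variances_equalised(self):
        rng = np.random.default_rng(1)
        datasets = [
            rng.standard_normal((40, 100)),
            10.0 * rng.standard_normal((40, 100)),
        ]
        out = concat_group_pca(datasets, n_components=30)
        v0 = (out[:30] ** 2).sum()
        v1 = (out[30:] ** 2).sum()
        assert v1 / v0 == pytest.approx(1.0, abs=1e-6)

    def test_full_rank_reduction_is_lossless(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((12, 40))
        out = concat_group_pca([X], n_components=12)
        Xc = X - X.mean(axis=0)
        # projection of the centred data onto the component span keeps everything
        basis = out / np.linalg.norm(out, axis=1, keepdims=True)
        proj = Xc @ basis.T @ basis
        assert np.allclose(proj, Xc, atol=1e-8)

    def test_too_many_components_rejected(self):
        with pytest.raises(ValueError):
            concat_group_pca([np.zeros((10, 50))], n_components=20)


class TestRegressions:
    def test_noise_free_series_recovered_exactly(self, truth):
        """Series built from the maps themselves: unit timecourse correlation."""
        rng = np.random.default_rng(5)
        K = truth.maps.shape[0]
        T = 80
        tcs = rng.standard_normal((T, K))
        V = truth.maps.reshape(K, -1)
        series = (tcs @ V).reshape((T,) + truth.maps.shape[1:]) + 10.0
        dr = dual_regression(series, truth.maps)
        for k in range(K):
            c = abs(np.corrcoef(dr.timecourses[:, k], tcs[:, k])[0, 1])
            assert c > 0.999

    def test_orthogonal_maps_match_single_map_regression(self):
        rng = np.random.default_rng(6)
        maps = np.zeros((2, 1, 8, 8))
        maps[0, 0, :4] = rng.random((4, 8))
        maps[1, 0, 4:] = rng.random((4, 8))
        T = 60
        tcs = rng.standard_normal((T, 2))
        series = (tcs @ maps.reshape(2, -1)).reshape((T, 1, 8, 8)) + 5.0
        series += 0.01 * rng.standard_normal(series.shape)
        dr = dual_regression(series, maps)
        sr = single_regression(series, dr.timecourses)
        for k in range(2):
            sel = maps[k] > 0
            assert np.allclose(dr.pe[k][sel], sr[k]["pe"][sel], rtol=0.05, atol=0.01)

    def test_collinear_maps_rejected_with_condition_diagnostic(self):
        maps = np.ones((2, 1, 8, 8))
        with pytest.raises(ValueError, match="condition"):
            dual_regression(np.random.default_rng(0).random((20, 1, 8, 8)), maps)

    def test_zero_regressor_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            single_regression(np.ones((10, 2, 2)), np.zeros((10, 1)))

    def test_spatial_maps_recovered_at_stated_cnr(self, small_phantom):
        """Over each network's footprint, the recovered amplitude map tracks
        the true one (10-minute run at the generator's default noise)."""
        truth = make_rsn_truth(
            shape=(6, 16, 16), n_networks=4, duration_s=600, seed=3,
            support=small_phantom.gm_mask,
        )
        series, _ = generate_rsn_dataset(truth, small_phantom, protocol(2.5, 90), seed=7)
        dr = dual_regression(series, truth.maps)
        for k in range(truth.maps.shape[0]):
            sup = small_phantom.tissue_mask & (truth.maps[k] > 0.05)
            c = np.corrcoef(dr.pe[k][sup], truth.maps[k][sup])[0, 1]
            assert c > 0.9

    def test_correlated_networks_leak_in_single_but_not_multiple(self):
        """Two overlapping networks: single regression mixes them, multiple separates."""
        rng = np.random.default_rng(8)
        maps = np.zeros((2, 1, 12, 12))
        maps[0, 0, 2:8] = 1.0
        maps[1, 0, 5:11] = 1.0       # spatial overlap rows 5-7
        T = 400
        a = rng.standard_normal(T)
        b = 0.6 * a + 0.8 * rng.standard_normal(T)   # correlated timecourses
        tcs = np.column_stack([a, b])
        series = (tcs @ maps.reshape(2, -1)).reshape((T, 1, 12, 12))
        series += 0.05 * rng.standard_normal(series.shape) + 10.0
        dr = dual_regression(series, maps)
        sr = single_regression(series, tcs)
        only0 = (maps[0] > 0) & (maps[1] == 0)
        leak_multi = np.abs(dr.pe[1][only0]).mean()
        leak_single = np.abs(sr[1]["pe"][only0]).mean()
        assert leak_single > 5 * leak_multi


class TestMixtureModel:
    def test_pure_standard_normal_recovered(self):
        z = np.random.default_rng(0).standard_normal(8000)
        fit = fit_ggm(z)
        assert abs(fit.mu0) < 0.05
        assert fit.sigma0 == pytest.approx(1.0, abs=0.05)
        assert fit.w_pos < 0.05 and fit.w_neg < 0.05
        zc = correct_z(z, fit)
        assert np.allclose(zc.corrected, (z - fit.mu0) / fit.sigma0)

    def test_shifted_null_with_gamma_tail_recovered(self):
        rng = np.random.default_rng(1)
        null = 1.5 + 2.0 * rng.standard_normal(9500)
        act = 1.5 + 4.0 + 2.0 * rng.gamma(4.0, 1.0, 500)
        fit = fit_ggm(np.concatenate([null, act]))
        zc = correct_z(np.concatenate([null, act]), fit)
        corrected_null = zc.corrected[:9500]
        assert abs(corrected_null.mean()) < 0.05
        assert corrected_null.std() == pytest.approx(1.0, abs=0.05)
        assert np.isfinite(zc.threshold)

    def test_autocorrelated_regression_null_renormalised(self):
        """Smooth regressor + AR(1) residuals inflate raw Z; correction fixes it."""
        rng = np.random.default_rng(2)

        def ar1(shape, rho):
            e = rng.standard_normal(shape)
            out = np.zeros_like(e)
            for t in range(1, shape[0]):
                out[t] = rho * out[t - 1] + e[t]
            return out

        T = 400
        x = ar1((T,), 0.8)
        noise = ar1((T, 6000), 0.8)
        X = np.column_stack([np.ones(T), (x - x.mean()) / x.std()])
        from muxepi.rsn import _stage2

        _, _, z, _ = _stage2(noise, X)
        raw = z[1]
        assert raw.std() > 1.3
        fit = fit_ggm(raw)
        zc = correct_z(raw, fit)
        assert abs(zc.corrected.mean()) < 0.05
        assert zc.corrected.std() == pytest.approx(1.0, abs=0.05)

    def test_too_few_voxels_rejected(self):
        with pytest.raises(ValueError):
            fit_ggm(np.zeros(100))


class TestMetrics:
    def test_all_null_image_has_zero_suprathreshold_mass(self):
        rng = np.random.default_rng(3)
        z = rng.standard_normal((4, 16, 16))
        fit = fit_ggm(z)
        zc = correct_z(z, fit)
        mean = np.ones_like(z)
        m = rsn_metrics(zc, np.zeros_like(z), 0.1 * np.ones_like(z), mean)
        if not np.isfinite(zc.threshold) or zc.threshold > zc.corrected.max():
            assert m.sum_z_over_threshold == 0.0
        assert m.peak_z == pytest.approx(zc.corrected.max())

    def test_joint_scaling_leaves_z_metrics_unchanged(self):
        rng = np.random.default_rng(4)
        z = rng.standard_normal((4, 16, 16)) + 2.0
        fit = fit_ggm(z)
        zc = correct_z(z, fit)
        pe = rng.random(z.shape)
        resid = rng.random(z.shape) + 0.5
        mean = np.ones_like(z)
        m1 = rsn_metrics(zc, pe, resid, mean)
        m2 = rsn_metrics(zc, 2 * pe, 2 * resid, mean)
        assert m1.peak_z == m2.peak_z
        assert m1.sum_z_over_threshold == m2.sum_z_over_threshold
        assert m2.pe_pct == pytest.approx(2 * m1.pe_pct)
        assert m1.pe_over_residual == pytest.approx(m2.pe_over_residual)

    def test_peak_coincides_with_truth_maximum(self, truth, small_phantom):
        series, _ = generate_rsn_dataset(truth, small_phantom, protocol(2.5, 90), seed=9)
        dr = dual_regression(series, truth.maps)
        k = 0
        fit = fit_ggm(dr.z[k], min_voxels=500)
        zc = correct_z(dr.z[k], fit)
        m = rsn_metrics(zc, dr.pe[k], dr.resid_sd, dr.mean_map)
        tp = np.unravel_index(np.argmax(truth.maps[k]), truth.maps[k].shape)
        assert np.linalg.norm(np.array(m.peak_index) - np.array(tp)) <= 2.0


class TestBlochPrediction:
    def test_identical_protocols_give_unity(self):
        assert predicted_sensitivity_ratio(2.5, 90, 2.5, 90) == 1.0

    def test_fast_protocol_predicts_about_15pct_gain(self):
        r = predicted_sensitivity_ratio(2.5, 90, 0.4, 50, t1=1.2)
        assert 100 * (r - 1) == pytest.approx(15.0, abs=0.5)

    def test_intermediate_protocol_matches_hand_evaluation(self):
        # closed form evaluated independently of the implementation
        e_a, e_b = np.exp(-2.5 / 1.2), np.exp(-0.8 / 1.2)
        s_a = np.sin(np.pi / 2) * (1 - e_a) / (1 - np.cos(np.pi / 2) * e_a)
        s_b = np.sin(np.pi / 3) * (1 - e_b) / (1 - np.cos(np.pi / 3) * e_b)
        expect = s_b / s_a * np.sqrt(2.5 / 0.8)
        assert predicted_sensitivity_ratio(2.5, 90, 0.8, 60, t1=1.2) == pytest.approx(expect)
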