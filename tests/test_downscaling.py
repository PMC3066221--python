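import numpy as np
import numpy.testing as npt
import pytest

from reefcast import downscaling as dn
from reefcast import synthetic_data as sd
from reefcast.climatology import MonthlySeries, monthly_climatology
from reefcast.errors import DegenerateInputError, InsufficientDataError, ParameterError


def quiet_pair(bias=0.0, amp=1.0, seed=1, sigma=0.05):
    """(model_20c, historic) with tiny noise and injected model defects."""
    hist = sd.gen_historic_sst(
        sd.site_preset("FFS", start_year=1945, n_years=55,
                       monthly_sigma=np.full(12, sigma), seed=seed)
    )
    model = sd.gen_model_sst(
        sd.site_preset("FFS", start_year=1900, n_years=100,
                       monthly_sigma=np.full(12, sigma), bias=bias,
                       seasonal_amp_factor=amp, seed=seed + 500)
    )
    return model, hist


class TestSelectionStats:
    def test_identical_series_pass_with_zero_stats(self, ffs_historic):
        stats = dn.selection_stats(ffs_historic, ffs_historic, "twin")
        assert stats.bias == pytest.approx(0.0)
        assert stats.seasonal_diff == pytest.approx(0.0)
        assert stats.passes()

    def test_injected_bias_recovered(self):
        model, hist = quiet_pair(bias=2.0)
        stats = dn.selection_stats(model, hist)
        assert stats.bias == pytest.approx(2.0, abs=0.1)

    def test_inflated_amplitude_fails_screen(self):
        model, hist = quiet_pair(amp=2.5, sigma=0.4)
        stats = dn.selection_stats(model, hist)
        assert stats.seasonal_diff > 1.0
        assert not stats.passes()

    def test_insufficient_overlap_rejected(self, ffs_historic):
        short = ffs_historic.window(1995, 1999)
        with pytest.raises(InsufficientDataError):
            dn.selection_stats(short, ffs_historic.window(1945, 1990))


class TestSelectModels:
    def test_all_zero_stats_pass(self):
        stats = [dn.SelectionStats(f"m{i}", 0.0, 0.0) for i in range(5)]
        passing, failing, _ = dn.select_models(stats)
        assert len(passing) == 5 and not failing

    def test_boundary_bias_fails_strictly(self):
        passing, failing, reasons = dn.select_models(
            [dn.SelectionStats("edge", 3.0, 0.5)]
        )
        assert not passing and len(failing) == 1
        assert "bias" in reasons["edge"]

    def test_partition_matches_brute_force_recount(self, rng):
        stats = [
            dn.SelectionStats(f"m{i}", rng.uniform(-5, 5), rng.uniform(0, 2))
            for i in range(41)
        ]
        passing, failing, _ = dn.select_models(stats)
        expected_pass = sum(
            1 for s in stats if abs(s.bias) < 3 and s.seasonal_diff < 1
        )
        assert len(passing) == expected_pass
        assert len(failing) == 41 - expected_pass

    def test_empty_list_rejected(self):
        with pytest.raises(ParameterError):
            dn.select_models([])


class TestFitDetrend:
    def test_exact_polynomial_gives_zero_residuals(self):
        years = np.repeat(np.arange(2000, 2020), 12)
        months = np.tile(np.arange(1, 13), 20)
        x = years + (months - 0.5) / 12
        x0 = x.mean()
        sst = 25 + 0.1 * (x - x0) + 0.01 * (x - x0) ** 3
        _, resid = dn.fit_detrend(MonthlySeries(years, months, sst))
        npt.assert_allclose(resid, 0.0, atol=1e-8)

    def test_sinusoid_trend_is_flat_mean(self):
        years = np.repeat(np.arange(2000, 2030), 12)
        months = np.tile(np.arange(1, 13), 30)
        sst = 25 + 3 * np.cos(2 * np.pi * (months - 8) / 12)
        series = MonthlySeries(years, months, sst)
        coeffs, resid = dn.fit_detrend(series)
        # trend carries the mean; residuals carry the full cycle
        assert coeffs[0] == pytest.approx(25.0, abs=0.05)
        assert np.std(resid) == pytest.approx(np.std(sst - sst.mean()), rel=0.05)

    def test_order_zero_subtracts_mean(self, ffs_historic):
        _, resid = dn.fit_detrend(ffs_historic, order=0)
        npt.assert_allclose(resid, ffs_historic.sst - ffs_historic.sst.mean())


class TestSeasonalScale:
    def test_identity_when_sds_match(self):
        t = dn.DownscaleTransform(0.0, np.zeros(5), np.zeros(5), 1.0, 1.0, 0.0)
        r = np.linspace(-3, 3, 50)
        npt.assert_allclose(dn.seasonal_scale(r, t), r, atol=1e-9)

    def test_output_sd_matches_historic(self, rng):
        r = rng.normal(0, 2.0, 10_000)
        t = dn.DownscaleTransform(0.0, np.zeros(5), np.zeros(5), 1.0, 2.0, 0.0)
        assert np.std(dn.seasonal_scale(r, t)) == pytest.approx(1.0, rel=0.05)

    def test_cdf_path_equals_affine_map(self, rng):
        r = rng.normal(0.3, 1.7, 1000)
        t = dn.DownscaleTransform(0.0, np.zeros(5), np.zeros(5), 0.8, 1.7, 0.3)
        npt.assert_allclose(
            dn.seasonal_scale(r, t), (r - 0.3) * 0.8 / 1.7, atol=1e-9
        )

    def test_zero_model_sd_rejected(self):
        t = dn.DownscaleTransform(0.0, np.zeros(5), np.zeros(5), 1.0, 0.0, 0.0)
        with pytest.raises(DegenerateInputError):
            dn.seasonal_scale(np.zeros(3), t)


class TestDownscaleScenario:
    def test_identity_transform_returns_scenario(self):
        hist = sd.gen_historic_sst(
            sd.site_preset("OAH", start_year=1945, n_years=55, seed=4)
        )
        scen = sd.gen_historic_sst(
            sd.site_preset("OAH", start_year=2000, n_years=50, seed=5)
        )
        out = dn.downscale_scenario(hist, scen, hist)
        # bias 0 and matching residual SDs: output ~ scenario
        npt.assert_allclose(out.sst, scen.sst, atol=0.15)

    @pytest.mark.parametrize("bias,amp", [(2.0, 1.5), (-2.0, 0.5)])
    def test_defects_removed_on_overlap(self, ffs_historic, bias, amp):
        model = sd.gen_model_sst(
            sd.site_preset("FFS", start_year=1945, n_years=55,
                           bias=bias, seasonal_amp_factor=amp, seed=77)
        )
        out = dn.downscale_scenario(model, model, ffs_historic)
        assert abs(out.sst.mean() - ffs_historic.sst.mean()) < 0.2
        _, out_res = dn.fit_detrend(out)
        _, hist_res = dn.fit_detrend(ffs_historic)
        assert 0.9 < np.std(out_res) / np.std(hist_res) < 1.1

    def test_native_trend_preserved(self, ffs_historic):
        model20 = sd.gen_model_sst(
            sd.site_preset("FFS", start_year=1945, n_years=55, bias=1.0,
                           seasonal_amp_factor=1.3, seed=88)
        )
        scen = sd.gen_model_sst(
            sd.site_preset("FFS", start_year=2000, n_years=100, bias=1.0,
                           seasonal_amp_factor=1.3, trend_per_century=3.0, seed=89)
        )
        out = dn.downscale_scenario(model20, scen, ffs_historic)
        coeffs_in, _ = dn.fit_detrend(scen)
        coeffs_out, _ = dn.fit_detrend(out)
        x = scen.frac_year
        x0 = 0.5 * (x.min() + x.max())
        poly = np.polynomial.polynomial.polyval
        rise_in = poly(x[-1] - x0, coeffs_in) - poly(x[0] - x0, coeffs_in)
        rise_out = poly(x[-1] - x0, coeffs_out) - poly(x[0] - x0, coeffs_out)
        assert rise_out == pytest.approx(rise_in, rel=0.05)

    def test_idempotent_within_tolerance(self, ffs_historic):
        model, hist = quiet_pair(bias=1.5, amp=1.4, sigma=0.3)
        once = dn.downscale_scenario(model, model, hist)
        twice = dn.downscale_scenario(once, once, hist)
        assert abs(once.sst.mean() - twice.sst.mean()) < 0.05
        assert np.std(once.sst - twice.sst) < 0.1


class TestMultiModelTrend:
    def test_trendless_sinusoid_flattens_to_mean(self):
        years = np.repeat(np.arange(2000, 2030), 12)
        months = np.tile(np.arange(1, 13), 30)
        sst = 25 + 3 * np.cos(2 * np.pi * (months - 8) / 12)
        trend = dn.multi_model_trend([MonthlySeries(years, months, sst)])
        assert trend.n_models_averaged == 1
        npt.assert_allclose(trend.trend, 25.0, atol=0.3)
        # residual 12-month amplitude < 10% of input's
        resid_amp = np.ptp([trend.trend[trend.month == m].mean() for m in range(1, 13)])
        assert resid_amp < 0.1 * 6.0

    def test_mean_of_two_trends(self):
        out = []
        for slope, seed in [(2.0, 1), (4.0, 2)]:
            p = sd.site_preset("OAH", start_year=2000, n_years=100,
                               trend_per_century=slope,
                               monthly_sigma=np.full(12, 0.01), seed=seed)
            out.append(sd.gen_historic_sst(p))
        trend = dn.multi_model_trend(out)
        rise = trend.trend[-12:].mean() - trend.trend[:12].mean()
        assert rise == pytest.approx(3.0 * 99 / 100, abs=0.15)

    def test_mismatched_spans_rejected(self, ffs_historic):
        with pytest.raises(ParameterError):
            dn.multi_model_trend([ffs_historic, ffs_historic.window(1950, 1999)])


class TestMonthlyAnomalyDistributions:
    def test_noise_free_sinusoid_zero_sd(self):
        years = np.repeat(np.arange(2000, 2030), 12)
        months = np.tile(np.arange(1, 13), 30)
        sst = 25 + 3 * np.cos(2 * np.pi * (months - 8) / 12)
        dist = dn.monthly_anomaly_distributions(MonthlySeries(years, months, sst))
        # residual per-month spread reflects only slow leakage of the
        # polynomial trend fit, far below any realistic monthly sigma
        npt.assert_allclose(dist.sd, 0.0, atol=0.1)
        npt.assert_allclose(dist.mean, 0.0, atol=1e-12)

    def test_known_sigma_pattern_recovered(self):
        sigma = np.linspace(0.3, 0.8, 12)
        p = sd.site_preset("JOH", start_year=1800, n_years=200,
                           monthly_sigma=sigma, seed=15)
        dist = dn.monthly_anomaly_distributions(sd.gen_historic_sst(p))
        assert np.all(np.abs(dist.sd - sigma) / sigma < 0.15)
        # ordering: noisiest generated month stays noisiest
        assert dist.sd[-1] > dist.sd[0]


class TestSimulateSST:
    def test_zero_sd_members_identical_to_trend_plus_cycle(self, warming_ensemble_inputs):
        trend = warming_ensemble_inputs["trend"]
        dist = warming_ensemble_inputs["distributions"]
        quiet = dn.MonthlyDistributions(dist.seasonal_anom, np.zeros(12), np.zeros(12))
        sims = dn.simulate_sst(trend, quiet, n_sims=3, seed=1)
        expected = trend.trend + dist.seasonal_anom[trend.month - 1]
        for s in sims:
            npt.assert_allclose(s.sst, expected)

    def test_ensemble_mean_tracks_trend(self, warming_ensemble_inputs):
        trend = warming_ensemble_inputs["trend"]
        dist = warming_ensemble_inputs["distributions"]
        sims = dn.simulate_sst(trend, dist, n_sims=200, seed=2)
        stack = np.stack([s.sst for s in sims])
        expected = trend.trend + dist.seasonal_anom[trend.month - 1]
        se = dist.sd[trend.month - 1] / np.sqrt(200)
        frac_within = np.mean(np.abs(stack.mean(axis=0) - expected) < 2.5 * se)
        assert frac_within > 0.95

    def test_default_member_count_is_500(self):
        import inspect

        assert inspect.signature(dn.simulate_sst).parameters["n_sims"].default == 500

    def test_members_reproducible_per_seed(self, warming_ensemble_inputs):
        trend = warming_ensemble_inputs["trend"]
        dist = warming_ensemble_inputs["distributions"]
        a = dn.simulate_sst(trend, dist, n_sims=2, seed=9)
        b = dn.simulate_sst(trend, dist, n_sims=2, seed=9)
        for x, y in zip(a, b):
            npt.assert_array_equal(x.sst, y.sst)
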