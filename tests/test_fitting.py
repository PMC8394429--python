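"""Parameter recovery: nonlinear least squares and the log-linear slope."""

import numpy as np
import pandas as pd
import pytest

from nixdry import (
    InsufficientDataError,
    IsothermalDryingModel,
    KineticParams,
    MoistureSeries,
    fit_all_st,
    fit_exponential,
    fit_loglinear,
    moisture_at_time,
    v0_series,
)
from nixdry.fitting import fits_to_table
from nixdry.synthetic import (ExperimentDesign, ZERO_NOISE, dataset_to_series,
                              default_params_for_st, generate_trajectories)

from conftest import REFERENCE_ROWS

DESIGN_TIMES = np.array(list(range(0, 121, 15)) + [2600], dtype=float)


def make_series(params: KineticParams, st_h=0.0, times=DESIGN_TIMES,
                noise_sd=0.0, seed=0) -> MoistureSeries:
    m = moisture_at_time(params, times)
    if noise_sd:
        m = m + np.random.default_rng(seed).normal(0, noise_sd, len(times))
    return MoistureSeries(st_h=st_h, observations=pd.DataFrame(
        {"time_min": times, "moisture_pct": m}))


class TestExponentialFit:
    @pytest.mark.parametrize("st", sorted(REFERENCE_ROWS))
    def test_noiseless_recovery_of_published_rows(self, st):
        row = REFERENCE_ROWS[st]
        truth = KineticParams(m0=row["m0"], me=row["me"], k=row["k"])
        res = fit_exponential(make_series(truth, st_h=st))
        assert res.params.k == pytest.approx(truth.k, rel=1e-6)
        assert res.params.me == pytest.approx(truth.me, rel=1e-6)
        assert res.params.m0 == pytest.approx(truth.m0, rel=1e-6)
        assert res.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_constant_series_rejected(self):
        series = MoistureSeries(st_h=0.0, observations=pd.DataFrame(
            {"time_min": DESIGN_TIMES, "moisture_pct": np.full_like(
                DESIGN_TIMES, 30.0)}))
        with pytest.raises(ValueError, match="constant"):
            fit_exponential(series)

    def test_too_few_time_points_rejected(self):
        truth = KineticParams(m0=47, me=5.088, k=0.0185)
        series = make_series(truth, times=np.array([0.0, 30.0, 60.0]))
        with pytest.raises(InsufficientDataError):
            fit_exponential(series)

    def test_results_diagnostics(self):
        truth = KineticParams(m0=47, me=5.088, k=0.0185)
        res = fit_exponential(make_series(truth))
        assert res.nobs == len(DESIGN_TIMES)
        assert len(res.residuals) == res.nobs
        assert res.method == "nls"
        assert res.v0 == pytest.approx(-truth.k * (truth.m0 - truth.me),
                                       rel=1e-6)
        assert "M0" in res.summary() and "R^2" in res.summary()

    def test_monte_carlo_recovery_under_default_noise(self):
        """Median relative k error < 5% and bias < 1% over 200 seeded runs
        at the 5-replicate design."""
        truth = default_params_for_st(0.0)
        rel_errors, k_hats = [], []
        for seed in range(200):
            df = generate_trajectories(
                ExperimentDesign(st_values_h=(0.0,), seed=seed))
            res = fit_exponential(dataset_to_series(df)[0.0])
            k_hats.append(res.params.k)
            rel_errors.append(abs(res.params.k - truth.k) / truth.k)
        assert np.median(rel_errors) < 0.05
        bias = abs(np.mean(k_hats) - truth.k) / truth.k
        assert bias < 0.01

    def test_r_squared_band_on_noisy_design(self, noisy_dataset):
        fits = fit_all_st(noisy_dataset)
        for st, res in fits.items():
            assert res.r_squared > 0.99


class TestLogLinearFit:
    def test_slope_exact_on_noiseless_data(self):
        # drying window only: at the 2600-min equilibrium point the excess
        # m - me underflows at percent scale and the log is undefined
        truth = KineticParams(m0=47, me=5.088, k=0.0185)
        times = np.arange(0, 121, 15, dtype=float)
        k_hat, intercept = fit_loglinear(make_series(truth, times=times),
                                         me=truth.me)
        assert k_hat == pytest.approx(truth.k, rel=1e-12)
        assert intercept == pytest.approx(0.0, abs=1e-12)

    def test_agrees_with_nls_on_low_noise_data(self):
        truth = KineticParams(m0=47, me=5.088, k=0.0185)
        times = np.arange(0, 121, 15, dtype=float)  # early window, low noise
        series = make_series(truth, times=times, noise_sd=0.05, seed=3)
        nls = fit_exponential(series)
        k_ll, _ = fit_loglinear(series, me=truth.me)
        assert k_ll == pytest.approx(nls.params.k, rel=0.02)

    def test_observation_at_or_below_me_named(self):
        truth = KineticParams(m0=47, me=5.088, k=0.0185)
        series = make_series(truth)
        with pytest.raises(ValueError, match="t=2600"):
            fit_loglinear(series, me=5.3)  # the 2600-min point sits below


class TestFitAllSt:
    def test_all_five_conditions_recovered(self, noiseless_dataset):
        fits = fit_all_st(noiseless_dataset)
        assert sorted(fits) == [0.0, 2.0, 4.0, 6.0, 8.0]
        for st, res in fits.items():
            row = REFERENCE_ROWS[st]
            assert res.params.k == pytest.approx(row["k"], rel=1e-6)
            assert res.params.me == pytest.approx(row["me"], rel=1e-6)
        table = fits_to_table(fits)
        assert list(table.columns) == ["st_h", "k", "me", "m0", "r_squared",
                                       "n_obs", "method"]

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            fit_all_st({})

    def test_single_condition_gives_one_row(self, noiseless_dataset):
        fits = fit_all_st({0.0: noiseless_dataset[0.0]})
        assert list(fits) == [0.0]

    def test_error_tagged_with_steeping_time(self):
        bad = MoistureSeries(st_h=4.0, observations=pd.DataFrame(
            {"time_min": [0.0, 15.0, 30.0], "moisture_pct": [47, 40, 35]}))
        with pytest.raises(InsufficientDataError, match="ST=4.0"):
            fit_all_st([bad])

    def test_raw_replicate_fit_close_to_mean_fit(self, noisy_dataset):
        mean_fit = fit_all_st(noisy_dataset)[0.0]
        raw_fit = fit_all_st(noisy_dataset, average_replicates=False)[0.0]
        assert raw_fit.nobs == 5 * mean_fit.nobs
        assert raw_fit.params.k == pytest.approx(mean_fit.params.k, rel=0.05)


class TestV0Series:
    def test_matches_initial_rate_definition(self, noiseless_dataset):
        fits = fit_all_st(noiseless_dataset)
        table = v0_series(fits)
        assert list(table.columns) == ["st_h", "v0", "m0"]
        for _, row in table.iterrows():
            ref = REFERENCE_ROWS[row["st_h"]]
            assert row["v0"] == pytest.approx(
                -ref["k"] * (ref["m0"] - ref["me"]), rel=1e-5)
            assert row["m0"] == pytest.approx(ref["m0"], rel=1e-6)

    def test_m0_profile_passes_through(self, noiseless_dataset):
        table = v0_series(fit_all_st(noiseless_dataset))
        m0 = table.sort_values("st_h")["m0"].to_numpy()
        assert np.all(np.diff(m0[:3]) > 0)  # rises from ST 0 to 4


class TestModelConstruction:
    def test_from_dataframe_single_st(self, noiseless_dataset):
        df = noiseless_dataset[0.0].observations.assign(steeping_time_h=0.0)
        model = IsothermalDryingModel.from_dataframe(df)
        res = model.fit()
        assert res.params.k == pytest.approx(0.0185, rel=1e-6)

    def test_from_dataframe_rejects_mixed_st_without_label(self):
        df = pd.DataFrame({"steeping_time_h": [0.0, 2.0],
                           "time_min": [0.0, 0.0],
                           "moisture_pct": [40.0, 45.0]})
        with pytest.raises(ValueError, match="several steeping times"):
            IsothermalDryingModel.from_dataframe(df)
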