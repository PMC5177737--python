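"""MAP forecasting, credibility bands and the dose-interval-trough solver."""

import numpy as np
import pytest

from hemopk.dataset import assemble_subject
from hemopk.forecast import (
    PriorSet,
    map_individual,
    posterior_band,
    report_thresholds,
    solve_regimen,
)
from hemopk.population import ErrorModel, OmegaMatrix, PopulationModel
from hemopk.simulate import default_fviii_spec, simulate_cohort, sparsify
from hemopk.structural import ONE_COMPARTMENT, concentration, time_to_level


def _priors(**kw):
    defaults = dict(
        structural=ONE_COMPARTMENT,
        theta={"CL": 0.1733, "V": 3.0},
        omega=OmegaMatrix.diagonal([0.09, 0.09]),
        error=ErrorModel("combined", sigma_add=2.0, sigma_prop=0.1),
        eta_params=("CL", "V"),
    )
    defaults.update(kw)
    return PriorSet(PopulationModel(**defaults), provenance="unit-test")


def _subject(observations, cid=1):
    return assemble_subject({"amount_iu": 3500.0, "duration_h": 0.1666},
                            observations, {"age": 30.0, "bw": 70.0},
                            baseline_measured=5.0, cid=cid)


def _no_obs_subject():
    s = _subject([{"time_h": 24.0, "conc_iul": 100.0}])
    s.records = s.records[:2]
    return s


class TestMapIndividual:
    def test_zero_observations_returns_typical_values(self):
        pri = _priors()
        eta, params = map_individual(_no_obs_subject(), pri)
        assert np.allclose(eta, 0.0, atol=1e-8)
        assert params == pytest.approx(pri.pop.theta)

    def test_rich_profile_recovers_individual_parameters(self):
        pri = _priors()
        rng = np.random.default_rng(8)
        errs = []
        for rep in range(10):
            eta_true = rng.normal(0, 0.3, size=2)
            params_true = {"CL": 0.1733 * np.exp(eta_true[0]),
                           "V": 3.0 * np.exp(eta_true[1])}
            probe = _subject([{"time_h": 1.0, "conc_iul": 100.0}])
            times = [0.25, 0.5, 1, 3, 6, 9, 12, 24, 32, 48]
            f = concentration(ONE_COMPARTMENT, params_true, probe.regimen(),
                              probe.initial_state(), times)
            y = f * (1 + 0.05 * rng.standard_normal(len(times)))
            s = _subject([{"time_h": t, "conc_iul": c} for t, c in zip(times, y)])
            _, params_hat = map_individual(s, pri)
            errs.append(abs(params_hat["CL"] / params_true["CL"] - 1))
        assert np.median(errs) < 0.10

    def test_duplicating_observations_reduces_shrinkage(self):
        pri = _priors()
        obs = [{"time_h": t, "conc_iul": c}
               for t, c in [(3.0, 700.0), (24.0, 220.0), (48.0, 60.0)]]
        eta1, _ = map_individual(_subject(obs), pri)
        eta2, _ = map_individual(_subject(obs + obs), pri)
        assert np.all(np.abs(eta2) >= np.abs(eta1) - 1e-9)


class TestPosteriorBand:
    def test_band_ordering_everywhere(self):
        fc = posterior_band(_subject([{"time_h": 24.0, "conc_iul": 150.0}]),
                            _priors(), n_draws=500, seed=4)
        assert np.all(fc.lower <= fc.median + 1e-12)
        assert np.all(fc.median <= fc.upper + 1e-12)

    def test_seeded_band_reproducible(self):
        s = _subject([{"time_h": 24.0, "conc_iul": 150.0}])
        f1 = posterior_band(s, _priors(), n_draws=400, seed=11)
        f2 = posterior_band(s, _priors(), n_draws=400, seed=11)
        assert np.array_equal(f1.lower, f2.lower)

    def test_zero_observations_band_matches_prior_predictive(self):
        pri = _priors()
        s = _no_obs_subject()
        fc = posterior_band(s, pri, n_draws=4000, seed=21)
        rng = np.random.default_rng(99)
        etas = rng.multivariate_normal(np.zeros(2), pri.pop.omega.matrix, size=4000)
        t_check = np.array([6.0, 24.0, 48.0])
        curves = np.empty((4000, t_check.size))
        for i, e in enumerate(etas):
            p = {"CL": 0.1733 * np.exp(e[0]), "V": 3.0 * np.exp(e[1])}
            curves[i] = concentration(ONE_COMPARTMENT, p, s.regimen(),
                                      s.initial_state(), t_check)
        for j, t in enumerate(t_check):
            idx = np.argmin(np.abs(fc.time_grid - t))
            for q, band in ((2.5, fc.lower), (50, fc.median), (97.5, fc.upper)):
                ref = np.percentile(curves[:, j], q)
                assert band[idx] == pytest.approx(ref, rel=0.10)

    def test_more_samples_narrow_the_band(self):
        pri = _priors()
        rng = np.random.default_rng(17)
        times6 = [1.0, 6.0, 12.0, 24.0, 36.0, 48.0]
        narrower = 0
        for rep in range(5):
            eta = rng.normal(0, 0.3, 2)
            p = {"CL": 0.1733 * np.exp(eta[0]), "V": 3.0 * np.exp(eta[1])}
            probe = _no_obs_subject()
            f = concentration(ONE_COMPARTMENT, p, probe.regimen(),
                              probe.initial_state(), times6)
            y = f * (1 + 0.08 * rng.standard_normal(6))
            obs6 = [{"time_h": t, "conc_iul": c} for t, c in zip(times6, y)]
            obs2 = obs6[3:5]
            w2 = posterior_band(_subject(obs2), pri, n_draws=600, seed=rep).band_width_mean
            w6 = posterior_band(_subject(obs6), pri, n_draws=600, seed=rep).band_width_mean
            narrower += w6 < w2
        assert narrower >= 4


class TestThresholdReport:
    def test_threshold_time_ordering(self):
        fc = posterior_band(_subject([{"time_h": 24.0, "conc_iul": 150.0}]),
                            _priors(), n_draws=500, seed=6)
        rep = report_thresholds(fc)
        ts = [rep["thresholds"][x]["time_h"] for x in (0.05, 0.02, 0.01)]
        defined = [t for t in ts if t is not None]
        assert defined == sorted(defined)

    def test_lower_bound_crossing_before_median(self):
        fc = posterior_band(_subject([{"time_h": 24.0, "conc_iul": 150.0}]),
                            _priors(), n_draws=500, seed=6)
        from hemopk.forecast import _first_crossing

        for thr in (50.0, 20.0):
            t_low = _first_crossing(fc.time_grid, fc.lower, thr, fc.end_of_infusion_h)
            t_med = _first_crossing(fc.time_grid, fc.median, thr, fc.end_of_infusion_h)
            if t_low is not None and t_med is not None:
                assert t_low <= t_med + 1e-9

    def test_threshold_at_baseline_never_reached(self):
        pri = _priors()
        fc = posterior_band(_subject([{"time_h": 24.0, "conc_iul": 150.0}]),
                            pri, n_draws=300, seed=2)
        rep = report_thresholds(fc, thresholds_iu_ml=[0.005])
        assert rep["thresholds"][0.005]["status"] == "never falls below"

    def test_deterministic_limit_matches_closed_form_inversion(self):
        pri = _priors(omega=OmegaMatrix.diagonal([1e-8, 1e-8]))
        times = [0.5, 1, 3, 6, 9, 12, 24, 32, 48]
        probe = _no_obs_subject()
        f = concentration(ONE_COMPARTMENT, pri.pop.theta, probe.regimen(),
                          probe.initial_state(), times)
        s = _subject([{"time_h": t, "conc_iul": c} for t, c in zip(times, f)])
        fc = posterior_band(s, pri, n_draws=400, seed=3)
        rep = report_thresholds(fc)
        for thr_ml in (0.05, 0.02, 0.01):
            t_exact = time_to_level(ONE_COMPARTMENT, pri.pop.theta, s.regimen(),
                                    s.initial_state(), thr_ml * 1000.0)
            got = rep["thresholds"][thr_ml]["time_h"]
            assert got == pytest.approx(t_exact, abs=0.1)


class TestSolveRegimen:
    PARAMS = {"CL": 0.1733, "V": 3.0}

    def test_doubling_dose_doubles_trough_above_baseline(self):
        r1 = solve_regimen(ONE_COMPARTMENT, self.PARAMS, 70.0,
                           dose_iu_per_kg=30.0, interval_h=48.0)
        r2 = solve_regimen(ONE_COMPARTMENT, self.PARAMS, 70.0,
                           dose_iu_per_kg=60.0, interval_h=48.0)
        assert (r2["trough_iu_ml"] - 0.005) == pytest.approx(
            2 * (r1["trough_iu_ml"] - 0.005), rel=1e-9)

    def test_trough_at_baseline_needs_no_dosing(self):
        r = solve_regimen(ONE_COMPARTMENT, self.PARAMS, 70.0,
                          dose_iu_per_kg=30.0, trough_iu_ml=0.005)
        assert r["interval_h"] == np.inf
        assert r["note"] == "achieved without dosing"

    def test_round_trip_consistency(self):
        r = solve_regimen(ONE_COMPARTMENT, self.PARAMS, 70.0,
                          dose_iu_per_kg=45.0, trough_iu_ml=0.02)
        back = solve_regimen(ONE_COMPARTMENT, self.PARAMS, 70.0,
                             dose_iu_per_kg=45.0, interval_h=r["interval_h"])
        assert abs(back["trough_iu_ml"] - 0.02) * 1000 < 0.1  # < 0.1 IU/L

    def test_infeasible_trough_reported(self):
        r = solve_regimen(ONE_COMPARTMENT, self.PARAMS, 70.0,
                          dose_iu_per_kg=0.01, trough_iu_ml=0.5)
        assert not r["feasible"]

    def test_exactly_two_inputs_required(self):
        with pytest.raises(ValueError, match="exactly two"):
            solve_regimen(ONE_COMPARTMENT, self.PARAMS, 70.0, dose_iu_per_kg=30.0)


class TestPriorSet:
    def test_prior_requires_positive_definite_omega(self):
        with pytest.raises(ValueError, match="positive definite"):
            _priors(omega=OmegaMatrix.diagonal([0.09, 0.0]))

    def test_yaml_round_trip(self, tmp_path):
        pri = _priors()
        path = tmp_path / "priors.yaml"
        pri.save(path)
        back = PriorSet.load(path)
        assert back.pop.theta == pri.pop.theta
        assert back.provenance == "unit-test"


class TestEndToEndSparseForecast:
    def test_sparse_forecast_tracks_truth(self):
        spec = default_fviii_spec(n_subjects=10, seed=606)
        ds, gt = simulate_cohort(spec)
        pri = PriorSet(spec.truth, "truth")
        sparse = sparsify(ds, [3.0, 24.0, 48.0])
        for s in sparse.subjects[:3]:
            _, params = map_individual(s, pri)
            cl_true = float(gt.subjects.set_index("cid").loc[s.cid, "theta_CL"])
            assert abs(params["CL"] / cl_true - 1) < 0.5
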