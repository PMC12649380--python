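"""Fatigue extraction, Weibull AFT fitting, breakpoint search, endurance state."""

import itertools

import numpy as np
import pandas as pd
import pytest
from lifelines import WeibullAFTFitter

from flumefish.endurance import (AFTModel, akaike_weights, breakpoint_search,
                                 c_index, endurance_state, fatigue_time,
                                 fatigue_records_from_steps, fit_aft,
                                 fit_weibull_aft, model_selection, predict_T)
from flumefish.errors import (FitError, StructuralError,
                              UndefinedStatisticError)
from flumefish.synth import AFTTruth, gen_fatigue

from conftest import simulate_fatigue_dataset


class TestFatigueTime:
    def test_count_over_rate(self):
        vs = np.concatenate([np.full(36, 5.0), np.full(10, 2.0)])
        rec = fatigue_time(vs, frame_rate=18.0)
        assert rec["T_s"] == pytest.approx(2.0)

    def test_all_below_threshold_excluded(self):
        with pytest.raises(StructuralError):
            fatigue_time(np.full(20, 3.0), 18.0)

    def test_mean_supra_threshold_speed(self):
        rec = fatigue_time(np.array([4.0, 5.0, 6.0, 1.0]), 18.0)
        assert rec["mean_Vs_bls"] == pytest.approx(5.0)

    def test_excursion_splitting(self):
        steps = pd.DataFrame({
            "fish_id": "f", "vs_bls": [5, 5, 1, 1, 6, 6, 6],
            "x_m": np.arange(7) * 0.1, "x1_m": np.arange(1, 8) * 0.1})
        recs = fatigue_records_from_steps(steps, 0.4, 18.0)
        assert len(recs) == 2
        assert recs["T_s"].tolist() == pytest.approx([2 / 18, 3 / 18])

    def test_traversal_censors(self):
        n = 60
        steps = pd.DataFrame({
            "fish_id": "f", "vs_bls": np.full(n, 6.0),
            "x_m": np.arange(n) * 0.11,
            "x1_m": np.arange(1, n + 1) * 0.11})
        recs = fatigue_records_from_steps(steps, 0.4, 18.0,
                                          test_area_length=6.0)
        assert bool(recs["censored"].iloc[0])


class TestWeibullAFT:
    def _simulate(self, rng, n=300, beta=(2.0, -0.5), sigma=0.4,
                  censor_at=None):
        x = rng.uniform(0, 4, n)
        log_t = beta[0] + beta[1] * x + sigma * np.log(rng.exponential(size=n))
        t = np.exp(log_t)
        cens = np.zeros(n, dtype=bool)
        if censor_at is not None:
            cens = t > censor_at
            t = np.minimum(t, censor_at)
        return x[:, None], t, cens

    def test_matches_lifelines(self, rng):
        """Same MLE as the reference Weibull AFT implementation."""
        X, t, cens = self._simulate(rng, censor_at=8.0)
        ours = fit_weibull_aft(X, t, cens, ("x",))
        df = pd.DataFrame({"T": t, "E": ~cens, "x": X[:, 0]})
        ll = WeibullAFTFitter().fit(df, "T", "E")
        ref_beta = [ll.params_[("lambda_", "Intercept")],
                    ll.params_[("lambda_", "x")]]
        assert ours.beta == pytest.approx(ref_beta, rel=1e-3, abs=1e-4)
        # lifelines rho_ is 1/sigma
        assert ours.log_scale == pytest.approx(
            -float(ll.params_[("rho_", "Intercept")]), rel=1e-3, abs=1e-4)
        assert ours.loglik == pytest.approx(
            float(ll.log_likelihood_), rel=1e-6)

    def test_scale_equivariance(self, rng):
        """Doubling all times shifts the intercept by ln 2, slopes unchanged."""
        X, t, cens = self._simulate(rng)
        a = fit_weibull_aft(X, t, cens, ("x",))
        b = fit_weibull_aft(X, 2 * t, cens, ("x",))
        assert b.beta[0] - a.beta[0] == pytest.approx(np.log(2), abs=1e-5)
        assert b.beta[1] == pytest.approx(a.beta[1], abs=1e-6)
        assert b.log_scale == pytest.approx(a.log_scale, abs=1e-6)

    def test_null_slopes_center_on_zero(self, rng):
        means = []
        for _ in range(40):
            X, t, cens = self._simulate(rng, n=120, beta=(2.0, 0.0))
            means.append(fit_weibull_aft(X, t, cens, ("x",)).beta[1])
        se = np.std(means, ddof=1) / np.sqrt(len(means))
        assert abs(np.mean(means)) < 3 * se + 1e-3

    def test_all_censored_inestimable(self):
        with pytest.raises(FitError):
            fit_weibull_aft(np.ones((10, 1)), np.ones(10),
                            np.ones(10, dtype=bool))

    def test_positive_times_required(self):
        with pytest.raises(StructuralError):
            fit_weibull_aft(np.ones((5, 1)), np.array([1, 2, 0, 4, 5.0]),
                            np.zeros(5, dtype=bool))


class TestBreakpointModel:
    def test_two_regime_fit_recovers_truth(self, rng, reference_truth):
        rec = simulate_fatigue_dataset(rng, reference_truth,
                                       n_prolonged=400, n_sprint=400)
        model = fit_aft(rec, ("Vs", "BL"), breakpoint=6.13)
        assert model.prolonged.beta[1] == pytest.approx(-0.94, abs=0.1)
        assert model.sprint.beta[2] == pytest.approx(-7.81, abs=1.5)
        assert model.prolonged.log_scale == pytest.approx(-0.86, abs=0.15)
        assert model.sprint.log_scale == pytest.approx(-0.50, abs=0.15)

    def test_breakpoint_search_locates_planted_break(self, rng,
                                                     reference_truth):
        rec = simulate_fatigue_dataset(rng, reference_truth)
        model = breakpoint_search(rec, ("Vs", "BL"))
        assert model.breakpoint == pytest.approx(6.13, abs=0.35)
        cols = {"breakpoint", "aic", "c_index", "n_prolonged", "n_sprint"}
        assert cols.issubset(model.candidates.columns)
        # the chosen candidate minimises AIC over the table
        assert model.aic == pytest.approx(model.candidates["aic"].min())

    def test_single_regime_data_gains_little(self, rng):
        """Without a planted break the two-regime AIC barely improves."""
        truth = AFTTruth(breakpoint=99.0)    # prolonged model everywhere
        vs = rng.uniform(3.83, 9.0, 150)
        bl = rng.normal(0.3916, 0.045, 150)
        rec = gen_fatigue(pd.DataFrame({"mean_Vs_bls": vs, "BL_m": bl}),
                          truth, rng=rng, censor_fraction=0.05)
        single = fit_aft(rec, ("Vs", "BL"))
        best = breakpoint_search(rec, ("Vs", "BL"))
        # a break costs 4 extra parameters; any gain should be modest noise
        assert best.aic > single.aic - 10.0

    def test_min_candidates_required(self):
        rec = pd.DataFrame({"mean_Vs_bls": [5.0, 5.0], "T_s": [1.0, 2.0],
                            "censored": [False, False], "BL_m": [0.4, 0.4]})
        with pytest.raises(FitError):
            breakpoint_search(rec, ("Vs",))


class TestAkaikeWeights:
    def test_single_model(self):
        assert akaike_weights([123.4]) == pytest.approx([1.0])

    def test_two_equal(self):
        assert akaike_weights([10.0, 10.0]) == pytest.approx([0.5, 0.5])

    def test_reported_selection_table(self):
        w = akaike_weights([802.62, 804.50, 806.24])
        assert np.round(w, 2).tolist() == [0.64, 0.25, 0.11]

    def test_shift_invariance_and_normalisation(self, rng):
        aic = rng.uniform(100, 120, 6)
        w = akaike_weights(aic)
        assert w.sum() == pytest.approx(1.0)
        assert akaike_weights(aic + 55.5) == pytest.approx(w)


class TestModelSelection:
    def test_enumerates_fifteen_subsets(self, rng, reference_truth):
        rec = simulate_fatigue_dataset(rng, reference_truth)
        rec["Temp_C"] = rng.normal(12.8, 0.3, len(rec))
        rec["DO_mgL"] = rng.normal(6.18, 0.06, len(rec))
        table = model_selection(rec, breakpoint=6.13)
        assert len(table) == 15
        assert table.loc[table["aic"].notna(), "w"].sum() == pytest.approx(1.0)

    def test_true_covariates_rank_first(self, rng, reference_truth):
        rec = simulate_fatigue_dataset(rng, reference_truth,
                                       n_prolonged=150, n_sprint=300)
        rec["Temp_C"] = rng.normal(12.8, 0.3, len(rec))
        rec["DO_mgL"] = rng.normal(6.18, 0.06, len(rec))
        table = model_selection(rec, breakpoint=6.13)
        top = table.iloc[0]["covariates"]
        assert "Vs" in top and "BL" in top


class TestCIndex:
    @staticmethod
    def brute_force(t, pred, event):
        """All-pairs enumeration of Harrell's concordance."""
        num = den = 0.0
        for i, j in itertools.combinations(range(len(t)), 2):
            lo, hi = (i, j) if t[i] < t[j] else (j, i)
            if not event[lo]:
                continue            # shorter time censored: not comparable
            den += 1
            if pred[lo] < pred[hi]:
                num += 1
            elif pred[lo] == pred[hi]:
                num += 0.5
        return num / den if den else None

    def _model_with_pred(self, pred):
        """One-regime stub whose linear predictor equals `pred` via Vs."""
        model = AFTModel.from_coefficients(
            99.0, ("Vs",),
            {"Intercept": 0.0, "Vs": 1.0, "Log(scale)": 0.0},
            {"Intercept": 0.0, "Vs": 1.0, "Log(scale)": 0.0})
        return model

    def test_perfect_and_reversed(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        rec = pd.DataFrame({"T_s": t, "censored": False, "mean_Vs_bls": t})
        model = self._model_with_pred(t)
        assert c_index(model, rec) == pytest.approx(1.0)
        rec_rev = rec.assign(mean_Vs_bls=-t)
        assert c_index(model, rec_rev) == pytest.approx(0.0)

    def test_matches_brute_force_on_random_instances(self, rng):
        model = self._model_with_pred(None)
        for _ in range(25):
            n = rng.integers(3, 9)
            t = rng.exponential(size=n) + 0.1    # distinct times
            pred = np.round(rng.normal(size=n), 1)   # occasional pred ties
            event = rng.random(n) > 0.3
            if not event.any():
                continue
            rec = pd.DataFrame({"T_s": t, "censored": ~event,
                                "mean_Vs_bls": pred})
            want = self.brute_force(t, pred, event)
            if want is None:
                with pytest.raises(UndefinedStatisticError):
                    c_index(model, rec)
                continue
            assert c_index(model, rec) == pytest.approx(want, abs=1e-12)


class TestPrediction:
    def test_body_size_ratio_prolonged(self, reference_model):
        r = predict_T(reference_model, 5.0, 0.40) / predict_T(
            reference_model, 5.0, 0.35)
        assert r == pytest.approx(np.exp(6.98 * 0.05), rel=1e-12)
        assert round(r, 1) == 1.4

    def test_body_size_ratio_sprint(self, reference_model):
        r = predict_T(reference_model, 7.0, 0.40) / predict_T(
            reference_model, 7.0, 0.35)
        assert r == pytest.approx(np.exp(-7.81 * 0.05), rel=1e-12)
        assert round(r, 2) == 0.68

    def test_zero_slope_constant(self):
        model = AFTModel.from_coefficients(
            6.0, ("Vs",),
            {"Intercept": 2.0, "Vs": 0.0}, {"Intercept": 2.0, "Vs": 0.0})
        assert predict_T(model, 5.0, 0.4) == pytest.approx(np.exp(2.0))
        assert predict_T(model, 8.0, 0.4) == pytest.approx(np.exp(2.0))

    def test_below_threshold_out_of_support(self, reference_model):
        with pytest.raises(StructuralError):
            predict_T(reference_model, 2.0, 0.4)


class TestEnduranceState:
    def test_starts_full(self, reference_model):
        E = endurance_state(np.array([5.0]), 18.0, reference_model, 0.4)
        assert E[0] == pytest.approx(1.0)

    def test_full_depletion_at_predicted_time(self, reference_model):
        vs = 5.0
        T = predict_T(reference_model, vs, 0.40)
        n = int(round(T * 18.0))
        E = endurance_state(np.full(n, vs), 18.0, reference_model, 0.40)
        assert E[-1] == pytest.approx(0.0, abs=1e-6)
        Eh = endurance_state(np.full(n // 2, vs), 18.0, reference_model, 0.40)
        assert Eh[-1] == pytest.approx(0.5, abs=0.01)

    def test_monotone_bounded(self, reference_model, rng):
        vs = rng.uniform(1.0, 9.0, 300)
        E = endurance_state(vs, 18.0, reference_model, 0.40)
        assert np.all(np.diff(E) <= 1e-15)
        assert E.min() >= 0.0 and E.max() <= 1.0

    def test_sub_threshold_costs_nothing(self, reference_model):
        E = endurance_state(np.full(100, 2.0), 18.0, reference_model, 0.40)
        assert np.allclose(E, 1.0)
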