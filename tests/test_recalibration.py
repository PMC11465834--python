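"""Log-log multiplier: transform identities, estimation, stratified mode."""

import json

import numpy as np
import pandas as pd
import pytest

import dkdrisk as dk
from dkdrisk.recalibration import RecalibrationError

from conftest import make_records


class TestApplyDelta:
    def test_zero_delta_is_identity(self):
        grid = np.linspace(0.001, 0.999, 50)
        np.testing.assert_allclose(dk.apply_delta(grid, 0.0), grid, rtol=1e-14)

    @pytest.mark.parametrize("risk,delta,expected", [
        (0.10, 1.212, 1 - 0.9 ** np.exp(1.212)),    # ~0.2981
        (0.10, -2.107, 1 - 0.9 ** np.exp(-2.107)),  # ~0.01273
        (0.01, 0.343, 1 - 0.99 ** np.exp(0.343)),
        (0.10, 1.143, 1 - 0.9 ** np.exp(1.143)),
    ])
    def test_published_multipliers_brute_force(self, risk, delta, expected):
        assert dk.apply_delta(risk, delta) == pytest.approx(expected, rel=1e-12)

    def test_strictly_increasing_in_risk_and_delta(self):
        grid = np.linspace(0.01, 0.9, 40)
        out = dk.apply_delta(grid, 0.7)
        assert np.all(np.diff(out) > 0)
        deltas = np.linspace(-2, 2, 30)
        series = [dk.apply_delta(0.2, d) for d in deltas]
        assert np.all(np.diff(series) > 0)

    def test_boundaries(self):
        assert dk.apply_delta(0.0, 1.0) == 0.0
        with pytest.warns(UserWarning):
            out = dk.apply_delta(1.0, 1.0)
        assert 0.0 < out <= 1.0
        with pytest.raises(RecalibrationError):
            dk.apply_delta(1.2, 0.0)


class TestEstimateDelta:
    def test_zero_when_observed_matches_predicted_cumhaz(self):
        p = np.full(200, 0.30)
        rec = make_records([1] * 60 + [0] * 140, [3.0] * 60 + [7.0] * 140)
        delta = dk.estimate_delta(p, rec, 7.0, observed="crude")
        assert delta == pytest.approx(0.0, abs=1e-12)

    def test_inverse_of_apply_delta_example(self):
        # crude observed 0.298 with all predictions 0.1 recovers ~1.212
        n, events = 500, 149
        p = np.full(n, 0.10)
        rec = make_records([1] * events + [0] * (n - events),
                           [3.0] * events + [7.0] * (n - events))
        delta = dk.estimate_delta(p, rec, 7.0, observed="crude")
        assert delta == pytest.approx(1.212, abs=2e-3)

    def test_conservation_identities_exact(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(0.05, 0.6, 300)
        y = rng.random(300) < 0.4
        rec = make_records(y, np.where(y, 3.0, 7.0))
        delta = dk.estimate_delta(p, rec, 7.0, observed="km")
        obs, _ = dk.km_risk(rec, 7.0)
        h = -np.log1p(-p)
        h_new = -np.log1p(-dk.apply_delta(p, delta))
        # total cumulative hazard scales by exp(delta); mean matches -ln(1-O)
        assert h_new.sum() == pytest.approx(np.exp(delta) * h.sum(), rel=1e-10)
        assert h_new.mean() == pytest.approx(-np.log1p(-obs), rel=1e-10)

    def test_zero_events_is_an_error_with_guidance(self):
        rec = make_records([0] * 50, [7.0] * 50)
        with pytest.raises(RecalibrationError, match="no events"):
            dk.estimate_delta(np.full(50, 0.1), rec, 7.0)

    def test_parameter_recovery_small(self, baseline_small):
        """Injected delta* = 0.5 on a homogeneous hazard is recovered within
        3 MC SEs (reduced replicate count; full strength runs elsewhere)."""
        h = 0.06
        hz = dk.TrueHazardSpec(base_hazard={"microalbuminuria": h}, true_delta=0.5)
        p = np.full(len(baseline_small), -np.expm1(-7 * h))
        est = []
        for r in range(40):
            rec = dk.latent_event_records(baseline_small, hz,
                                          censor_rate_per_year=0.02, seed=300 + r)
            est.append(dk.estimate_delta(p, rec[rec.outcome == "microalbuminuria"], 7.0))
        est = np.array(est)
        se = est.std(ddof=1) / np.sqrt(len(est))
        assert abs(est.mean() - 0.5) < 3 * se

    def test_mle_variant_agrees_without_censoring(self):
        rng = np.random.default_rng(9)
        p = rng.uniform(0.2, 0.4, 2000)
        true_delta = 0.4
        y = rng.random(2000) < dk.apply_delta(p, true_delta)
        rec = make_records(y, np.where(y, 3.0, 7.0))
        mm = dk.estimate_delta(p, rec, 7.0, observed="crude", method="moment")
        mle = dk.estimate_delta(p, rec, 7.0, method="mle")
        assert mm == pytest.approx(true_delta, abs=0.15)
        assert mle == pytest.approx(mm, abs=0.05)


class TestStratified:
    def rec_and_risks(self, seed=12, n=2000, delta=0.8):
        rng = np.random.default_rng(seed)
        p = rng.uniform(0.02, 0.5, n)
        y = rng.random(n) < dk.apply_delta(p, delta)
        risks = pd.Series(p, index=np.arange(1, n + 1))
        rec = make_records(y, np.where(y, 3.0, 7.0), ids=np.arange(1, n + 1))
        return risks, rec

    def test_single_stratum_reproduces_global_bitwise(self):
        risks, rec = self.rec_and_risks()
        params_g = dk.global_recalibrate(risks, rec, 7.0, outcome="microalbuminuria")
        params_s = dk.stratified_recalibrate(risks, rec, [1.0], 7.0,
                                             outcome="microalbuminuria")
        assert params_s.strata[0][1] == params_g.delta
        np.testing.assert_array_equal(params_s.apply(risks.to_numpy()),
                                      dk.apply_delta(risks.to_numpy(), params_g.delta))

    def test_homogeneous_miscalibration_gives_equal_strata(self):
        # narrow predicted-risk spread keeps the moment estimator's
        # within-stratum aggregation comparable across strata
        rng = np.random.default_rng(12)
        n = 20000
        p = rng.uniform(0.1, 0.3, n)
        y = rng.random(n) < dk.apply_delta(p, 0.5)
        risks = pd.Series(p, index=np.arange(1, n + 1))
        rec = make_records(y, np.where(y, 3.0, 7.0), ids=np.arange(1, n + 1))
        params_g = dk.global_recalibrate(risks, rec, 7.0)
        params_s = dk.stratified_recalibrate(risks, rec, [0.2], 7.0)
        for _, d in params_s.strata:
            assert d == pytest.approx(params_g.delta, abs=0.08)

    def test_published_two_stratum_fixture_evaluation(self):
        params = dk.FIG1_PARAMS["macroalbuminuria"]
        out = params.apply(np.array([0.01, 0.10]))
        assert out[0] == pytest.approx(1 - 0.99 ** np.exp(0.343), rel=1e-12)
        assert out[1] == pytest.approx(1 - 0.9 ** np.exp(1.143), rel=1e-12)

    def test_routing_uses_original_risk_with_step_preserved(self):
        params = dk.FIG1_PARAMS["macroalbuminuria"]
        below = params.apply(0.0239)
        above = params.apply(0.0241)
        # the recalibrated mapping jumps at the 2.4% boundary
        assert above - below > 0.02

    def test_eventless_stratum_named_in_error(self):
        risks, rec = self.rec_and_risks(n=200)
        rec.loc[risks[risks < 0.1].index - 1, "occurred"] = False
        with pytest.raises(RecalibrationError, match="stratum 1"):
            dk.stratified_recalibrate(risks, rec, [0.1], 7.0)

    def test_threshold_validation(self):
        risks, rec = self.rec_and_risks(n=100)
        with pytest.raises(RecalibrationError):
            dk.stratified_recalibrate(risks, rec, [0.3, 0.1], 7.0)


class TestParamsObject:
    def test_serialization_roundtrip(self, tmp_path):
        for params in dk.FIG1_PARAMS.values():
            path = tmp_path / f"{params.outcome}.json"
            params.save(path)
            loaded = dk.RecalibrationParams.load(path)
            assert loaded == params

    def test_invalid_modes_rejected(self):
        with pytest.raises(RecalibrationError):
            dk.RecalibrationParams(outcome="x", mode="global", delta=None)
        with pytest.raises(RecalibrationError):
            dk.RecalibrationParams(outcome="x", mode="stratified",
                                   strata=((0.5, 0.1), (0.4, 0.2)))
        with pytest.raises(RecalibrationError):
            dk.RecalibrationParams(outcome="x", mode="stratified",
                                   strata=((0.5, 0.1),))  # must cover (0, 1]

    def test_shipped_fixture_matches_code_constants(self):
        import importlib.resources as resources
        raw = json.loads((resources.files("dkdrisk") / "data"
                          / "fig1_recalibration.json").read_text())
        for outcome, params in dk.FIG1_PARAMS.items():
            assert dk.RecalibrationParams.from_dict(raw[outcome]) == params


class TestReport:
    def test_global_recalibration_preserves_auroc(self):
        rng = np.random.default_rng(30)
        n = 1000
        p = rng.uniform(0.05, 0.6, n)
        y = rng.random(n) < dk.apply_delta(p, 0.6)
        risks = pd.Series(p, index=np.arange(n))
        rec = make_records(y, np.where(y, 3.0, 7.0), ids=np.arange(n))
        params = dk.global_recalibrate(risks, rec, 7.0, outcome="microalbuminuria")
        before = dk.decile_calibration(risks, rec, 7.0)
        after = dk.decile_calibration(params.apply(risks), rec, 7.0)
        comp = dk.recalibration_report(before, after, params)
        assert comp["auroc_changed"] is False
        assert comp["before"]["auroc"] == comp["after"]["auroc"]

    def test_zero_delta_reports_identical_fields(self):
        rng = np.random.default_rng(31)
        n = 600
        p = rng.uniform(0.1, 0.5, n)
        y = rng.random(n) < p
        risks = pd.Series(p, index=np.arange(n))
        rec = make_records(y, np.where(y, 3.0, 7.0), ids=np.arange(n))
        params = dk.RecalibrationParams(outcome="x", mode="global", delta=0.0)
        before = dk.decile_calibration(risks, rec, 7.0)
        after = dk.decile_calibration(params.apply(risks), rec, 7.0)
        comp = dk.recalibration_report(before, after, params)
        assert comp["before"] == pytest.approx(comp["after"])

    def test_recalibration_improves_slope(self, baseline_large):
        """Injected miscalibration: the after-slope is closer to 1 than the
        before-slope in nearly all replicates."""
        hz = dk.default_hazard_spec(true_delta=1.0)
        eq = hz.to_equation("microalbuminuria")
        p = dk.predict_cohort(eq, baseline_large)
        improved = 0
        reps = 30
        for r in range(reps):
            rec = dk.latent_event_records(baseline_large, hz, seed=500 + r)
            rec = rec[rec.outcome == "microalbuminuria"]
            params = dk.global_recalibrate(p, rec, 7.0)
            before = dk.decile_calibration(p, rec, 7.0)
            after = dk.decile_calibration(params.apply(p), rec, 7.0)
            improved += abs(after.slope - 1) < abs(before.slope - 1)
        assert improved >= int(0.9 * reps)

    def test_propose_threshold_detects_sign_change(self):
        pred = np.linspace(0.05, 0.5, 10)
        obs = pred.copy()
        obs[:5] -= 0.03
        obs[5:] += 0.03
        table = pd.DataFrame({"mean_predicted": pred, "observed_risk": obs})
        threshold = dk.propose_stratum_threshold(table)
        assert threshold == pytest.approx(0.5 * (pred[4] + pred[5]))
        assert dk.propose_stratum_threshold(
            pd.DataFrame({"mean_predicted": pred, "observed_risk": pred + 0.05})) is None
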