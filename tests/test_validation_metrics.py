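"""AUROC, Kaplan-Meier/Greenwood, decile calibration, and the GND test."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import dkdrisk as dk
from dkdrisk.validation_metrics import MetricError, decile_table, gnd_test

from conftest import make_records


def brute_force_auroc(risks, events):
    r = np.asarray(risks, float)
    y = np.asarray(events, bool)
    pos, neg = r[y], r[~y]
    wins = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


class TestAuroc:
    def test_perfect_separation(self):
        assert dk.auroc([0.9, 0.8, 0.1], [1, 1, 0]) == 1.0

    def test_all_ties(self):
        assert dk.auroc([0.3] * 6, [1, 0, 1, 0, 0, 1]) == 0.5

    def test_small_example_matches_pairwise_count(self):
        assert dk.auroc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == 0.75

    def test_matches_brute_force_and_sklearn(self):
        from sklearn.metrics import roc_auc_score
        rng = np.random.default_rng(1)
        for _ in range(50):
            n = rng.integers(4, 50)
            r = rng.choice([0.1, 0.2, 0.2, 0.5, 0.9], size=n)
            y = rng.random(n) < 0.4
            if y.all() or not y.any():
                continue
            ours = dk.auroc(r, y)
            assert ours == brute_force_auroc(r, y)
            assert ours == pytest.approx(roc_auc_score(y, r), abs=1e-12)

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(0.01, 0.99), min_size=4, max_size=30))
    def test_invariant_under_monotone_transform(self, risks):
        rng = np.random.default_rng(7)
        y = rng.random(len(risks)) < 0.5
        if y.all() or not y.any():
            return
        r = np.asarray(risks)
        assert dk.auroc(r, y) == pytest.approx(dk.auroc(np.log(r / (1 - r)), y))

    def test_single_class_rejected(self):
        with pytest.raises(MetricError):
            dk.auroc([0.1, 0.2], [1, 1])


class TestKmRisk:
    def test_no_censoring_is_binomial(self):
        rec = make_records([1, 1, 1] + [0] * 7, [2.0] * 3 + [7.0] * 7)
        risk, var = dk.km_risk(rec, 7.0)
        assert risk == pytest.approx(0.30)
        assert var == pytest.approx(0.3 * 0.7 / 10)

    def test_zero_events(self):
        rec = make_records([0] * 5, [7.0] * 5)
        assert dk.km_risk(rec, 7.0) == (0.0, 0.0)

    def test_staggered_censoring_matches_hand_product_limit(self):
        # events at t=1 (n=5) and t=3 (n=3), censor at t=2:
        # S(5) = (4/5)(2/3) = 8/15; Greenwood: S^2 [1/(5*4) + 1/(3*2)]
        rec = make_records([1, 0, 1, 0, 0], [1.0, 2.0, 3.0, 5.0, 5.0])
        risk, var = dk.km_risk(rec, 5.0)
        assert risk == pytest.approx(7 / 15, rel=1e-12)
        assert var == pytest.approx((8 / 15) ** 2 * (1 / 20 + 1 / 6), rel=1e-12)

    def test_matches_lifelines_estimate(self):
        from lifelines import KaplanMeierFitter
        rng = np.random.default_rng(3)
        t = rng.exponential(5.0, 300)
        c = rng.exponential(7.0, 300)
        obs = np.minimum(t, c)
        d = t <= c
        rec = make_records(d, obs)
        risk, _ = dk.km_risk(rec, 4.0)
        kmf = KaplanMeierFitter().fit(obs, d)
        assert risk == pytest.approx(
            1 - float(kmf.survival_function_at_times(4.0).iloc[0]), abs=1e-10)

    def test_events_beyond_horizon_do_not_count(self):
        rec = make_records([1, 1, 0], [2.0, 9.0, 7.0])
        risk, _ = dk.km_risk(rec, 7.0)
        assert risk == pytest.approx(1 / 3)


def constructed_deciles(pred, obs, n=100, events=20, var=1e-4):
    return pd.DataFrame({
        "decile": np.arange(1, len(pred) + 1),
        "n": n, "n_events": events,
        "mean_predicted": pred, "observed_risk": obs,
        "greenwood_var": var,
    })


class TestCalibrationLine:
    def test_identity_when_observed_equals_predicted(self):
        pred = np.linspace(0.05, 0.5, 10)
        slope, intercept = dk.calibration_line(constructed_deciles(pred, pred))
        assert slope == pytest.approx(1.0, abs=1e-10)
        assert intercept == pytest.approx(0.0, abs=1e-10)

    def test_doubled_observed_gives_slope_two(self):
        pred = np.linspace(0.05, 0.4, 10)
        slope, intercept = dk.calibration_line(constructed_deciles(pred, 2 * pred))
        assert slope == pytest.approx(2.0, abs=1e-10)
        assert intercept == pytest.approx(0.0, abs=1e-10)

    def test_degenerate_means_rejected(self):
        with pytest.raises(MetricError):
            dk.calibration_line(constructed_deciles(np.full(10, 0.2), np.full(10, 0.3)))

    def test_slope_near_one_under_true_calibration(self):
        """Events drawn with probability equal to the prediction: the mean
        decile slope over replicates sits at 1 within Monte-Carlo error."""
        rng = np.random.default_rng(11)
        slopes = []
        for _ in range(100):
            p = rng.uniform(0.05, 0.6, 1000)
            y = rng.random(1000) < p
            risks = pd.Series(p, index=np.arange(1000))
            rec = make_records(y, np.full(1000, 7.0), ids=np.arange(1000))
            rep = dk.decile_calibration(risks, rec, 7.0)
            slopes.append(rep.slope)
        mean = np.mean(slopes)
        se = np.std(slopes, ddof=1) / np.sqrt(len(slopes))
        assert abs(mean - 1.0) < 3 * se + 1e-3


class TestGnd:
    def test_zero_residuals_give_zero_statistic(self):
        pred = np.linspace(0.05, 0.5, 10)
        stat, df, p = gnd_test(constructed_deciles(pred, pred))
        assert stat == 0.0 and p == 1.0 and df == 10

    def test_quadratic_form_arithmetic(self):
        table = constructed_deciles(np.array([0.1, 0.3]),
                                    np.array([0.15, 0.3]), var=0.001)
        stat, df, _ = gnd_test(table)
        assert stat == pytest.approx(2.5, rel=1e-12)
        assert df == 2

    def test_invariant_to_group_relabeling(self):
        rng = np.random.default_rng(2)
        pred = np.sort(rng.uniform(0.1, 0.5, 10))
        obs = pred + rng.normal(0, 0.02, 10)
        table = constructed_deciles(pred, obs, var=0.002)
        stat1, df1, p1 = gnd_test(table)
        shuffled = table.sample(frac=1, random_state=4).reset_index(drop=True)
        stat2, df2, p2 = gnd_test(shuffled)
        assert stat1 == pytest.approx(stat2) and df1 == df2
        assert stat1 >= 0.0

    def test_sparse_group_merged_into_lower_decile(self):
        table = constructed_deciles(np.linspace(0.1, 0.5, 5),
                                    np.linspace(0.1, 0.5, 5), var=0.001)
        table.loc[2, "n_events"] = 2  # below the merge threshold
        _, df, _ = gnd_test(table)
        assert df == 4  # 5 groups -> 4 after merging

    def test_type_one_error_near_nominal(self):
        """Perfectly calibrated world: rejection at alpha=0.05 is ~5%
        (moderate replicate count; the full-strength check runs elsewhere)."""
        rng = np.random.default_rng(21)
        rejections = 0
        reps = 150
        for _ in range(reps):
            p = rng.uniform(0.2, 0.6, 1000)
            y = rng.random(1000) < p
            risks = pd.Series(p, index=np.arange(1000))
            rec = make_records(y, np.full(1000, 7.0), ids=np.arange(1000))
            _, _, pval = gnd_test(decile_table(risks, rec, 7.0))
            rejections += pval < 0.05
        rate = rejections / reps
        assert 0.01 < rate < 0.10


class TestDecileCalibration:
    def test_group_sizes_partition_cohort(self):
        rng = np.random.default_rng(5)
        n = 97
        risks = pd.Series(rng.random(n), index=np.arange(n))
        rec = make_records(rng.random(n) < 0.3, np.full(n, 7.0), ids=np.arange(n))
        table = decile_table(risks, rec, 7.0)
        assert table["n"].sum() == n
        assert table["n"].max() - table["n"].min() <= 1

    def test_observed_deciles_conserve_overall_risk(self):
        """No censoring: the n-weighted mean of decile observed risks equals
        the overall crude event fraction."""
        rng = np.random.default_rng(6)
        n = 1000
        p = rng.uniform(0.1, 0.6, n)
        y = rng.random(n) < p
        risks = pd.Series(p, index=np.arange(n))
        rec = make_records(y, np.full(n, 7.0), ids=np.arange(n))
        table = decile_table(risks, rec, 7.0)
        weighted = (table["n"] * table["observed_risk"]).sum() / n
        assert weighted == pytest.approx(y.mean(), rel=1e-12)

    def test_small_cohort_rejected(self):
        risks = pd.Series([0.1] * 10, index=np.arange(10))
        rec = make_records([0] * 10, [7.0] * 10, ids=np.arange(10))
        with pytest.raises(MetricError):
            dk.decile_calibration(risks, rec, 7.0)
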