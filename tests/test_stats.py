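"""Statistical machinery: oracles, hand computations and parameter recovery."""

import itertools

import numpy as np
import pandas as pd
import pytest

from hematotox.errors import StatisticalError
from hematotox.stats import (aalen_johansen, cox_fit, fisher_exact,
                             group_compare, km_fit, logistic_fit, logrank,
                             mann_whitney, nrm_cuminc, roc, spearman)

from conftest import make_outcome, make_record


def auc_pair_counting(scores, outcome):
    """Exhaustive pair-counting oracle: wins + half-ties over all pos/neg pairs."""
    pos = [s for s, o in zip(scores, outcome) if o]
    neg = [s for s, o in zip(scores, outcome) if not o]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0
               for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestROC:
    def test_perfect_separation(self):
        assert roc([0, 0, 1, 1], [False, False, True, True]).auc == 1.0

    @pytest.mark.parametrize("scores, outcome", [
        ([0, 1, 2, 3], [False, False, True, True]),
        ([0, 1, 2, 3], [False, True, False, True]),
        ([1, 1, 2, 2, 3], [False, True, False, True, True]),
    ])
    def test_matches_pair_counting_oracle(self, scores, outcome):
        assert roc(scores, outcome).auc == pytest.approx(
            auc_pair_counting(scores, outcome))

    def test_complete_ties_give_half(self):
        assert roc([2, 2, 2, 2], [True, True, False, False]).auc == 0.5

    def test_one_class_raises(self):
        with pytest.raises(StatisticalError):
            roc([1, 2, 3], [True, True, True])

    def test_invariant_under_monotone_transform(self, rng):
        scores = rng.normal(size=60)
        outcome = rng.random(60) < 0.4
        if outcome.all() or not outcome.any():
            outcome[0] = ~outcome[0]
        a = roc(scores, outcome).auc
        b = roc(np.exp(3 * scores) + 7, outcome).auc
        assert a == pytest.approx(b)

    def test_youden_operating_point(self):
        res = roc([0, 1, 2, 3, 4, 5], [0, 0, 0, 1, 1, 1])
        assert res.operating_point["cutoff"] == 3
        assert res.operating_point["sensitivity"] == 1.0
        assert res.operating_point["specificity"] == 1.0


class TestSpearman:
    def test_perfect_monotone(self):
        r, _, slope = spearman([1, 2, 3, 4], [2, 4, 6, 8])
        assert r == pytest.approx(1.0)
        assert slope == pytest.approx(2.0)

    def test_small_example_against_rank_formula(self):
        # ranks of y: (3, 1, 2); sum d^2 = 4 + 1 + 1; r = 1 - 6*6/24 = -0.5
        r, _, _ = spearman([1, 2, 3], [3, 1, 2])
        assert r == pytest.approx(-0.5)

    def test_noise_free_slope_self_check(self):
        x = np.arange(0, 8)
        y = 2.48 * x + 1.0
        _, _, slope = spearman(x, y)
        assert slope == pytest.approx(2.48)

    def test_constant_input_raises(self):
        with pytest.raises(StatisticalError):
            spearman([1, 1, 1], [1, 2, 3])


class TestKaplanMeier:
    def test_no_events_flat_median_not_reached(self):
        curve = km_fit([5, 6, 7], [0, 0, 0])
        assert curve.at(7) == 1.0
        assert not curve.median_reached

    def test_product_limit_and_midpoint_median(self):
        curve = km_fit([1, 2, 3, 4], [1, 1, 1, 1])
        assert curve.at(1) == pytest.approx(0.75)
        assert curve.at(2) == pytest.approx(0.5)
        assert curve.at(3) == pytest.approx(0.25)
        assert curve.median == pytest.approx(2.5)

    def test_uncensored_equals_empirical_survival(self, rng):
        times = rng.integers(1, 20, size=25).astype(float)
        curve = km_fit(times, np.ones(25, int))
        for t in np.unique(times):
            assert curve.at(t) == pytest.approx((times > t).mean())

    def test_censoring_changes_risk_set(self):
        curve = km_fit([1, 2, 3, 4], [1, 0, 1, 0])
        # after censoring at 2, risk set at t=3 is 2 -> S = 0.75 * 0.5
        assert curve.at(3) == pytest.approx(0.375)

    def test_empty_raises(self):
        with pytest.raises(StatisticalError):
            km_fit([], [])


class TestLogrank:
    def test_identical_groups_p_one(self):
        t = [1, 2, 3, 4]; e = [1, 1, 0, 1]
        chi2, p = logrank(t, e, t, e)
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_asymptotic_agrees_with_lifelines(self, rng):
        from lifelines.statistics import logrank_test
        ta = rng.exponential(5, 40); tb = rng.exponential(9, 35)
        ea = np.ones(40, int); eb = (rng.random(35) < 0.8).astype(int)
        chi2, p = logrank(ta, ea, tb, eb)
        ref = logrank_test(ta, tb, ea, eb)
        assert chi2 == pytest.approx(ref.test_statistic, rel=1e-6)
        assert p == pytest.approx(ref.p_value, rel=1e-6)

    def test_exact_mode_matches_permutation_oracle(self, rng):
        """Exact p equals brute-force relabeling with lifelines statistics."""
        from lifelines.statistics import logrank_test
        times = np.array([1.0, 2.0, 2.0, 3.0, 5.0, 6.0, 8.0, 9.0])
        events = np.array([1, 1, 0, 1, 1, 0, 1, 1])
        n_b = 4
        chi2_obs, p_exact = logrank(times[:n_b], events[:n_b],
                                    times[n_b:], events[n_b:], method="exact")
        count = total = 0
        for combo in itertools.combinations(range(len(times)), n_b):
            mask = np.zeros(len(times), bool)
            mask[list(combo)] = True
            ref = logrank_test(times[mask], times[~mask],
                               events[mask], events[~mask])
            total += 1
            if ref.test_statistic >= chi2_obs - 1e-9:
                count += 1
        assert p_exact == pytest.approx(count / total)


class TestAalenJohansen:
    def test_hand_example_four_patients(self):
        """NRM at month 2, progression death at 4, two censored at 12."""
        curve = aalen_johansen([2, 4, 12, 12],
                               ["NRM", "progression_death", None, None])
        assert curve.at("NRM", 2) == pytest.approx(0.25)
        assert curve.at("NRM", 12) == pytest.approx(0.25)
        assert curve.at("progression_death", 4) == pytest.approx(0.25)

    def test_identity_event_free_plus_incidences(self, rng):
        n = 60
        times = rng.exponential(10, n)
        causes = rng.choice(["a", "b", None], n, p=[0.4, 0.3, 0.3])
        curve = aalen_johansen(times, causes, ["a", "b"])
        total = curve.event_free + curve.incidence["a"] + curve.incidence["b"]
        assert np.allclose(total, 1.0)

    def test_single_cause_reduces_to_one_minus_km(self, rng):
        times = rng.exponential(5, 40)
        events = (rng.random(40) < 0.7).astype(int)
        causes = ["NRM" if e else None for e in events]
        aj = aalen_johansen(times, causes, ["NRM"])
        km = km_fit(times, events)
        for t in aj.times:
            assert aj.at("NRM", t) == pytest.approx(1 - km.at(t))

    def test_nrm_all_progression_curve_zero(self):
        recs = [make_record(f"P{i}", outcome=make_outcome(
            3.0, 1, 5.0, 1, "progression", "PD")) for i in range(4)]
        curve = nrm_cuminc(recs)
        assert curve.at("NRM", 12) == 0.0

    def test_nrm_death_without_cause_rejected(self):
        rec = make_record("A", outcome=make_outcome(3.0, 1, 3.0, 1,
                                                    "infection", "PD"))
        object.__setattr__(rec.outcome, "death_cause", "none")
        with pytest.raises(StatisticalError):
            nrm_cuminc([rec])


class TestRegression:
    def test_cox_recovers_moderate_hazard_ratio(self, rng):
        n = 1500
        x = rng.integers(0, 2, n)
        t = rng.exponential(1 / (0.05 * np.exp(np.log(3.5) * x)))
        df = pd.DataFrame({"x": x, "time": np.minimum(t, 40),
                           "event": (t <= 40).astype(int)})
        fit = cox_fit(df, ["x"], "time", "event")
        lo, hi = fit.table.loc["x", ["ci_lower", "ci_upper"]]
        assert lo < 3.5 < hi
        assert fit.tie_handling == "efron"

    def test_cox_constant_covariate_raises(self):
        df = pd.DataFrame({"x": [1, 1, 1, 1], "time": [1, 2, 3, 4],
                           "event": [1, 1, 0, 1]})
        with pytest.raises(StatisticalError, match="constant"):
            cox_fit(df, ["x"], "time", "event")

    def test_cox_collinear_covariates_raise(self, rng):
        x = rng.integers(0, 2, 50).astype(float)
        df = pd.DataFrame({"x": x, "y": 1 - x,
                           "time": rng.exponential(5, 50),
                           "event": np.ones(50, int)})
        with pytest.raises(StatisticalError, match="collinear"):
            cox_fit(df, ["x", "y"], "time", "event")

    def test_logistic_recovers_odds_ratio(self, rng):
        n = 2000
        x = rng.integers(0, 2, n)
        p = 1 / (1 + np.exp(-(-1.2 + np.log(4.9) * x)))
        df = pd.DataFrame({"x": x, "y": (rng.random(n) < p).astype(int)})
        fit = logistic_fit(df, ["x"], "y")
        lo, hi = fit.table.loc["x", ["ci_lower", "ci_upper"]]
        assert lo < 4.9 < hi

    def test_logistic_null_covariate_or_near_one(self, rng):
        n = 2000
        df = pd.DataFrame({"x": rng.integers(0, 2, n),
                           "y": rng.integers(0, 2, n)})
        fit = logistic_fit(df, ["x"], "y")
        assert fit.ratio("x") == pytest.approx(1.0, abs=0.3)

    def test_logistic_perfect_separation_raises(self):
        df = pd.DataFrame({"x": [0, 0, 0, 1, 1, 1], "y": [0, 0, 0, 1, 1, 1]})
        with pytest.raises(StatisticalError):
            logistic_fit(df, ["x"], "y")


class TestGroupCompare:
    def test_fisher_hand_example(self):
        res = fisher_exact([[3, 1], [1, 3]])
        assert res.p_value == pytest.approx(34 / 70)

    def test_identical_multisets_p_one(self):
        res = mann_whitney([1, 2, 3], [1, 2, 3])
        assert res.p_value == pytest.approx(1.0)

    @pytest.mark.parametrize("x, y", [
        ((1.0, 3.0, 5.0), (2.0, 4.0, 6.0, 8.0)),
        ((1.0, 1.0, 2.0), (2.0, 3.0, 3.0)),
        ((10.0, 2.0), (3.0, 4.0, 5.0)),
    ])
    def test_exact_mode_matches_full_enumeration(self, x, y):
        """Exact p equals a brute-force oracle with pair-counting U."""
        def u_stat(a, b):
            return sum(1.0 if ai > bi else 0.5 if ai == bi else 0.0
                       for ai in a for bi in b)
        pooled = list(x) + list(y)
        mu = len(x) * len(y) / 2
        obs = abs(u_stat(x, y) - mu)
        count = total = 0
        for combo in itertools.combinations(range(len(pooled)), len(x)):
            a = [pooled[i] for i in combo]
            b = [pooled[i] for i in range(len(pooled)) if i not in combo]
            total += 1
            if abs(u_stat(a, b) - mu) >= obs - 1e-9:
                count += 1
        res = mann_whitney(x, y, method="exact")
        assert res.p_value == pytest.approx(count / total)

    def test_dispatch(self):
        assert group_compare([[3, 1], [1, 3]]).test == "fisher_exact"
        res = group_compare([1.0, 2.0, 5.0, 6.0], ["a", "a", "b", "b"])
        assert res.test == "mann_whitney"

    def test_empty_group_raises(self):
        with pytest.raises(StatisticalError):
            mann_whitney([], [1, 2])
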