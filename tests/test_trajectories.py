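"""Daily-grid expansion, neutropenia metrics and recovery phenotypes."""

import numpy as np
import pytest

from hematotox.cohort import LabSeries
from hematotox.errors import CohortValidationError
from hematotox.trajectories import (classify_phenotype, cytopenia_flags,
                                    daily_grid, neutropenia_metrics,
                                    severe_neutropenia_days)

from conftest import make_record


def locf_oracle(days, values, start, end):
    """Brute-force LOCF expansion: list of value-or-None per day."""
    out = []
    for day in range(start, end + 1):
        prior = [v for d, v in zip(days, values) if d <= day]
        out.append(prior[-1] if prior else None)
    return out


def max_run_oracle(flags):
    best = cur = 0
    for f in flags:
        cur = cur + 1 if f else 0
        best = max(best, cur)
    return best


class TestDailyGrid:
    def test_daily_measurements_identity(self):
        s = LabSeries((0, 1, 2, 3), (1.0, 2.0, 3.0, 4.0))
        g = daily_grid(s, (0, 3))
        assert list(g.values) == [1.0, 2.0, 3.0, 4.0]
        assert all(p == "measured" for p in g.provenance)

    def test_locf_between_measurements(self):
        s = LabSeries((0, 5), (0.3, 0.8))
        g = daily_grid(s, (0, 5))
        assert list(g.values) == [0.3, 0.3, 0.3, 0.3, 0.3, 0.8]
        assert list(g.provenance) == ["measured"] + ["carried_forward"] * 4 + \
            ["measured"]

    def test_no_backfill_before_first_measurement(self):
        s = LabSeries((3, 6), (1.0, 2.0))
        g = daily_grid(s, (0, 10))
        assert np.isnan(g.values[:3]).all()
        assert list(g.provenance[:3]) == ["unknown"] * 3

    def test_empty_series_raises(self):
        with pytest.raises(CohortValidationError):
            daily_grid(LabSeries((), ()), (0, 10))


class TestSevereNeutropeniaDays:
    def test_all_normal_is_zero(self):
        rec = make_record(anc=[(d, 2.0) for d in range(0, 61, 5)])
        assert severe_neutropenia_days(rec) == 0

    def test_hand_counted_window(self):
        pairs = [(d, 0.4 if 2 <= d <= 10 else 1.0) for d in range(0, 61)]
        assert severe_neutropenia_days(make_record(anc=pairs)) == 9

    def test_locf_carries_severe_values(self):
        rec = make_record(anc=[(0, 0.4), (5, 0.8)])
        assert severe_neutropenia_days(rec) == 5

    def test_no_in_window_measurement_raises(self):
        rec = make_record(anc=[(-3, 2.0)])
        with pytest.raises(CohortValidationError):
            severe_neutropenia_days(rec)

    def test_measured_mode_counts_only_draw_days(self):
        rec = make_record(anc=[(0, 0.4), (5, 0.8)])
        assert severe_neutropenia_days(rec, mode="measured") == 1

    def test_monotone_under_pointwise_increase(self, rng):
        days = tuple(sorted(rng.choice(61, size=20, replace=False)))
        values = tuple(rng.uniform(0, 2, size=20))
        rec = make_record(anc=list(zip(days, values)))
        bumped = make_record(anc=list(zip(days, (v + 0.3 for v in values))))
        assert severe_neutropenia_days(bumped) <= severe_neutropenia_days(rec)


class TestPhenotype:
    def test_continuous_severe_14_days_is_aplastic(self):
        pairs = [(d, 0.3) for d in range(0, 15)] + [(d, 1.8) for d in
                                                    range(15, 101, 3)]
        assert classify_phenotype(make_record(anc=pairs)).label == "aplastic"

    def test_always_recovered_is_quick(self):
        pairs = [(d, 1.8) for d in range(0, 101, 2)]
        assert classify_phenotype(make_record(anc=pairs)).label == "quick"

    def test_recovery_then_late_dip_is_intermittent(self):
        pairs = [(0, 1.2), (10, 1.6), (20, 1.4), (25, 0.8), (30, 1.4),
                 (60, 1.8), (100, 1.8)]
        assert classify_phenotype(make_record(anc=pairs)).label == "intermittent"

    def test_early_dip_before_day_21_is_quick(self):
        pairs = [(0, 1.2), (10, 1.6), (15, 0.8), (18, 1.4), (30, 1.8),
                 (100, 1.8)]
        assert classify_phenotype(make_record(anc=pairs)).label == "quick"

    def test_aplastic_takes_precedence_over_intermittent(self):
        pairs = ([(0, 1.8)] + [(d, 0.3) for d in range(2, 17)]
                 + [(20, 1.8), (30, 0.8), (40, 1.8), (100, 1.8)])
        assert classify_phenotype(make_record(anc=pairs)).label == "aplastic"

    def test_short_followup_flagged_low_confidence(self):
        res = classify_phenotype(make_record(anc=[(0, 1.8), (10, 1.8)]))
        assert res.low_confidence

    def test_phenotypes_partition_random_trajectories(self, rng):
        for _ in range(50):
            days = tuple(sorted(rng.choice(101, size=30, replace=False)))
            values = tuple(np.round(rng.uniform(0, 3, size=30), 2))
            res = classify_phenotype(make_record(anc=list(zip(days, values))))
            assert res.label in ("quick", "intermittent", "aplastic")


class TestNeutropeniaMetrics:
    def test_protracted_profound_run(self):
        pairs = ([(0, 1.0), (1, 1.0), (2, 1.0)]
                 + [(d, 0.05) for d in range(3, 10)]
                 + [(d, 1.8) for d in range(10, 101, 3)])
        m = neutropenia_metrics(make_record(anc=pairs))
        assert m.protracted_profound and m.profound_d0_100
        assert m.protracted_severe and m.severe_days_d0_60 == 7

    def test_window_assignment_d31_100(self):
        pairs = [(d, 0.4 if d == 40 else 1.8) for d in range(0, 101)]
        m = neutropenia_metrics(make_record(anc=pairs))
        assert m.severe_d31_100 and not m.severe_d0_30

    def test_all_normal_all_false(self):
        pairs = [(d, 2.0) for d in range(0, 101, 2)]
        m = neutropenia_metrics(make_record(anc=pairs))
        assert m.severe_days_d0_60 == 0 and m.phenotype == "quick"
        assert not any([m.severe_d0_30, m.severe_d31_100, m.protracted_severe,
                        m.profound_d0_100, m.protracted_profound, m.prolonged])

    def test_prolonged_at_day_21_boundary(self):
        pairs = [(d, 0.9 if d == 21 else 1.8) for d in range(0, 101)]
        assert neutropenia_metrics(make_record(anc=pairs)).prolonged
        pairs = [(d, 0.9 if d == 20 else 1.8) for d in range(0, 101)]
        assert not neutropenia_metrics(make_record(anc=pairs)).prolonged

    def test_denser_sampling_of_step_function_is_invariant(self, rng):
        """Adding draws that equal the LOCF value changes nothing."""
        days = sorted(rng.choice(101, size=12, replace=False))
        values = list(np.round(rng.uniform(0, 2, size=12), 2))
        rec = make_record(anc=list(zip(days, values)))
        grid = daily_grid(rec.anc_series, (0, 100))
        extra_days = [d for d in rng.choice(101, size=30, replace=False)
                      if d not in days and not np.isnan(grid.values[d])]
        dense_pairs = list(zip(days, values)) + [
            (d, float(grid.values[d])) for d in extra_days]
        dense = make_record(anc=dense_pairs)
        if any(0 <= d <= 60 for d in days):
            assert severe_neutropenia_days(dense) == severe_neutropenia_days(rec)
        assert neutropenia_metrics(dense).phenotype == \
            neutropenia_metrics(rec).phenotype

    def test_run_lengths_match_brute_force_on_random_grids(self, rng):
        from hematotox.trajectories import _max_run, _threshold_days
        for _ in range(200):
            n = int(rng.integers(5, 40))
            days = tuple(sorted(rng.choice(101, size=n, replace=False)))
            values = tuple(np.round(rng.uniform(0, 1.5, size=n), 2))
            rec = make_record(anc=list(zip(days, values)))
            grid = daily_grid(rec.anc_series, (0, 100))
            expected = locf_oracle(days, values, 0, 100)
            got = [None if np.isnan(v) else v for v in grid.values]
            assert got == expected
            severe_flags = [v is not None and v < 0.5 for v in expected]
            assert _max_run(_threshold_days(grid, 0.5)) == \
                max_run_oracle(severe_flags)


class TestCytopeniaFlags:
    def test_platelet_threshold(self):
        rec = make_record(platelets=[(12, 45.0)], hemoglobin=[(0, 10.0)])
        assert cytopenia_flags(rec).severe_thrombocytopenia_d0_30 is True

    def test_transfusion_triggers_anemia_flag(self):
        rec = make_record(hemoglobin=[(0, 10.0), (40, 9.0)], prbc_days=(40,),
                          platelets=[(0, 150.0)])
        f = cytopenia_flags(rec)
        assert f.severe_anemia_d31_100 is True
        assert f.severe_anemia_d0_30 is False

    def test_missing_series_is_not_evaluable(self):
        rec = make_record(platelets=[(5, 100.0)], hemoglobin=[(5, 10.0)])
        f = cytopenia_flags(rec)
        assert f.severe_thrombocytopenia_d31_100 is None
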