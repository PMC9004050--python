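"""Reason breakdowns, survival/retention rates, median survival time."""

import math

import numpy as np
import pandas as pd
import pytest

from llinsurv.matrix import build_matrix, clean
from llinsurv.rates import (
    DegenerateSlopeError,
    RateEstimate,
    ReasonBreakdown,
    median_survival_time,
    reason_breakdown,
    retention_rate,
    round_accounting,
    survival_rate,
)
from llinsurv.simulate import SimulationConfig, simulate_cohort

from conftest import traj_matrix


class TestReasonBreakdown:
    def test_percentages_from_counts(self):
        bd = ReasonBreakdown.from_counts(
            6,
            {
                "given_away": 42,
                "stolen": 8,
                "exchanged": 20,
                "damaged_discarded": 10,
                "repurposed": 1,
            },
        )
        assert bd.total == 81
        assert bd.percentages["given_away"] == 51.85
        assert bd.percentages["exchanged"] == 24.69
        assert bd.percentages["damaged_discarded"] == 12.35

    def test_single_cause_is_100_percent(self):
        bd = ReasonBreakdown.from_counts(12, {"stolen": 7})
        assert bd.percentages["stolen"] == 100.0
        assert bd.total == 7

    def test_zero_absent_gives_nan_percentages(self):
        bd = ReasonBreakdown.from_counts(6, {})
        assert bd.total == 0
        assert all(math.isnan(p) for p in bd.percentages.values())

    def test_breakdown_from_matrix_counts_first_cause(self):
        m = traj_matrix(
            ["PNNN", "PDDD", "PPPP"],
            reasons={(0, 1): "given_away", (1, 1): "damaged_discarded"},
        )
        bd = reason_breakdown(m, 24)
        assert bd.counts["given_away"] == 1
        assert bd.counts["damaged_discarded"] == 1
        assert bd.total == 2


class TestAccounting:
    def test_present_plus_absent_equals_surveyed(self, small_cohort):
        cfg, roster, obs, _ = small_cohort
        m = clean(build_matrix(roster, obs, rounds=cfg.rounds))
        for r in cfg.rounds:
            present, absent, surveyed = round_accounting(m, r)
            assert present + absent == surveyed

    def test_unsurveyed_not_counted(self):
        m = traj_matrix(["PP--", "PPPP", "PN-N"], reasons={(2, 1): "stolen"})
        assert round_accounting(m, 12) == (2, 1, 3)
        assert round_accounting(m, 24) == (1, 0, 1)


class TestSurvivalRate:
    def test_all_present_and_serviceable_is_100(self):
        m = traj_matrix(["PPPP"] * 10)
        est = survival_rate(m, None, 12)
        assert (est.numerator, est.denominator, est.proportion) == (10, 10, 100.0)
        assert est.ci_high == 100.0

    def test_half_torn_with_no_not_found_losses(self):
        m = traj_matrix(["PPPP"] * 20)
        phi = pd.DataFrame(
            {
                "net_id": [f"N{i:03d}" for i in range(10)],
                "round": [12] * 10,
                "phi": [700] * 10,
            }
        )
        est = survival_rate(m, phi, 12)
        assert (est.numerator, est.denominator) == (10, 20)
        assert est.ci_low < 50.0 < est.ci_high

    def test_not_found_family_excluded_from_denominator(self):
        # 5 present, 3 given away: denominator drops the given-away nets
        m = traj_matrix(
            ["PPPP"] * 5 + ["PNNN"] * 3,
            reasons={(i, 1): "given_away" for i in range(5, 8)},
        )
        est = survival_rate(m, None, 24)
        assert (est.numerator, est.denominator) == (5, 5)
        # discarded nets, by contrast, stay in the denominator
        m2 = traj_matrix(
            ["PPPP"] * 5 + ["PDDD"] * 3,
            reasons={(i, 1): "damaged_discarded" for i in range(5, 8)},
        )
        est2 = survival_rate(m2, None, 24)
        assert (est2.numerator, est2.denominator) == (5, 8)

    def test_zero_denominator_is_undefined(self):
        m = traj_matrix(["PNNN"], reasons={(0, 1): "stolen"})
        est = survival_rate(m, None, 24)
        assert est.denominator == 0 and math.isnan(est.proportion)

    def test_tracks_configured_cumulative_survival(self):
        # no missingness, no reporting noise: the survival rate at round k
        # (no torn nets enter: phi table omitted) matches the configured
        # cumulative presence among non-given-away nets, and with losses
        # drawn only from the discard family it equals the raw fraction.
        s = (0.95, 0.85, 0.8, 0.9)
        cfg = SimulationConfig(
            seed=12,
            n_households=5000,
            nets_per_household_mean=1.0,
            brands={"A": s},
            household_sd=0.0,
            zone_log_odds=0.0,
            attrition_cause_weights=[(0, 0, 0, 1, 0)] * 4,
            missingness=(0, 0, 0, 0),
            not_found_noise=0.0,
            discard_lag_prob=0.0,
        )
        roster, obs, _ = simulate_cohort(cfg)
        m = clean(build_matrix(roster, obs, rounds=cfg.rounds))
        for k, r in enumerate(cfg.rounds):
            expected = float(np.prod(s[: k + 1]))
            est = survival_rate(m, None, r)
            se = 100 * np.sqrt(expected * (1 - expected) / est.denominator)
            assert abs(est.proportion - 100 * expected) < 4 * se


class TestRetentionRate:
    def test_no_losses_is_100(self):
        est = retention_rate(traj_matrix(["PPPP"] * 4), 36)
        assert est.proportion == 100.0

    def test_given_away_stays_in_denominator(self):
        m = traj_matrix(
            ["PPPP"] * 80 + ["PNNN"] * 20,
            reasons={(i, 1): "given_away" for i in range(80, 100)},
        )
        est = retention_rate(m, 24)
        assert (est.numerator, est.denominator) == (80, 100)
        assert est.proportion == 80.0

    def test_discarded_excluded_from_denominator(self):
        m = traj_matrix(
            ["PPPP"] * 80 + ["PDDD"] * 20,
            reasons={(i, 1): "damaged_discarded" for i in range(80, 100)},
        )
        est = retention_rate(m, 24)
        assert (est.numerator, est.denominator) == (80, 80)
        assert est.proportion == 100.0

    def test_equal_to_survival_rate_without_losses(self):
        m = traj_matrix(["PPPP"] * 15)
        s = survival_rate(m, None, 12)
        r = retention_rate(m, 12)
        assert (s.numerator, s.denominator) == (r.numerator, r.denominator)


class TestMedianSurvivalTime:
    def test_median_reached_at_t1(self):
        assert median_survival_time(1, 2, 50, 20).tm == 1.0

    def test_symmetric_crossing(self):
        assert median_survival_time(1, 2, 75, 25).tm == 1.5

    def test_full_drop(self):
        assert median_survival_time(1, 2, 100, 0).tm == 1.5

    def test_exact_formula(self):
        mst = median_survival_time(1, 2, 80, 40)
        assert mst.tm == 1 + (2 - 1) * (80 - 50) / (80 - 40)

    def test_time_shift_invariance(self):
        base = median_survival_time(1, 2, 75, 25).tm
        shifted = median_survival_time(1 + 3, 2 + 3, 75, 25).tm
        assert shifted == base + 3

    def test_projection_warning_above_85(self):
        assert median_survival_time(1, 2, 86, 40).projection_warning
        assert not median_survival_time(1, 2, 85, 40).projection_warning

    def test_extrapolation_flagged(self):
        mst = median_survival_time(1, 2, 95, 75)  # crosses 50% after t2
        assert mst.tm > 2 and mst.extrapolated

    def test_ci_pairs_lower_with_lower(self):
        mst = median_survival_time(1, 2, 75, 25, ci1=(65, 85), ci2=(15, 35))
        lo = 1 + (65 - 50) / (65 - 15)
        hi = 1 + (85 - 50) / (85 - 35)
        assert mst.ci_low == pytest.approx(min(lo, hi))
        assert mst.ci_high == pytest.approx(max(lo, hi))

    def test_equal_rates_rejected(self):
        with pytest.raises(DegenerateSlopeError):
            median_survival_time(1, 2, 60, 60)


def test_rate_estimate_validates_counts():
    with pytest.raises(ValueError):
        RateEstimate.from_counts(6, "SURVIVAL", 5, 4)
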