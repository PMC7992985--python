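"""Calibration recovery and sampling properties of the synthetic input model."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import gaussian_kde

from ortheater.patient_generation import (
    CLASSES,
    SPECIALTIES,
    ArrivalModel,
    Calibration,
    CalibrationError,
    DurationModel,
    assign_urgency_split,
    classify_duration_class,
    default_calibration,
    generate_weekly_elective_pool,
    sample_arrival_counts,
    sample_arrival_times,
    sample_case_durations,
    sample_weekly_demand,
)

from conftest import zero_arrival_model


def _daytime_draws(model, rng, n=10_000):
    urgent = {s: np.empty(n) for s in SPECIALTIES}
    emerg = np.empty(n)
    for i in range(n):
        c = sample_arrival_counts("day", i % 5, model, rng)
        for s in SPECIALTIES:
            urgent[s][i] = c[(s, "urgent")]
        emerg[i] = c[("ANY", "emergency")]
    return urgent, emerg


class TestArrivalCounts:
    def test_daytime_means_recover_calibrated_rates(self, rng):
        """Sampled weekday arrival means match the calibrated per-specialty
        urgent rates, their 12.6 total, and the 2.8 daytime emergency rate."""
        model = ArrivalModel()
        urgent, emerg = _daytime_draws(model, rng)
        assert np.mean(urgent["TS"]) == pytest.approx(4.7, rel=0.03)
        total = sum(np.mean(urgent[s]) for s in SPECIALTIES)
        assert total == pytest.approx(12.6, rel=0.03)
        assert np.mean(emerg) == pytest.approx(2.8, rel=0.03)

    def test_night_means_recover_calibrated_rates(self, rng):
        model = ArrivalModel()
        urgents = np.empty(10_000)
        emerg = np.empty(10_000)
        for i in range(10_000):
            c = sample_arrival_counts("night", i % 7, model, rng)
            urgents[i] = sum(c[(s, "urgent")] for s in SPECIALTIES)
            emerg[i] = c[("ANY", "emergency")]
        assert urgents.mean() == pytest.approx(0.48, rel=0.03)
        assert emerg.mean() == pytest.approx(0.8, rel=0.03)

    def test_zero_rate_generates_zero(self, rng):
        model = zero_arrival_model()
        for i in range(50):
            c = sample_arrival_counts("day", i % 7, model, rng)
            assert all(v == 0 for v in c.values())

    def test_poisson_variance_matches_mean(self, rng):
        """The default counting family is Poisson: sample variance tracks the
        sample mean."""
        model = ArrivalModel()
        urgent, _ = _daytime_draws(model, rng)
        x = urgent["TS"]
        assert x.var() == pytest.approx(x.mean(), rel=0.07)

    def test_negative_rate_rejected(self):
        with pytest.raises(CalibrationError):
            ArrivalModel(urgent_day_rate={"TS": -1.0})

    def test_weekend_daytime_urgents_off_by_default(self, rng):
        model = ArrivalModel()
        c = sample_arrival_counts("day", 6, model, rng)
        assert all(c[(s, "urgent")] == 0 for s in SPECIALTIES)
        # emergencies keep arriving on weekends
        assert c[("ANY", "emergency")] >= 0


class TestArrivalTimes:
    def test_zero_count_empty(self, rng):
        assert len(sample_arrival_times(0, "day", rng)) == 0

    def test_times_inside_window_and_sorted(self, rng):
        t = sample_arrival_times(300, "day", rng)
        assert ((t >= 360) & (t < 1320)).all()
        assert (np.diff(t) >= 0).all()
        t = sample_arrival_times(300, "night", rng)
        assert ((t >= 1320) & (t < 1800)).all()

    def test_uniform_placement_mean_is_window_midpoint(self, rng):
        t = sample_arrival_times(10_000, "day", rng)
        assert t.mean() == pytest.approx((360 + 1320) / 2, rel=0.01)


class TestUrgencySplit:
    @pytest.mark.parametrize("fraction,expected", [(1.0, "very_urgent"), (0.0, "semi_urgent")])
    def test_degenerate_fractions(self, rng, fraction, expected):
        model = ArrivalModel(very_urgent_fraction=fraction)
        assert all(assign_urgency_split(model, rng) == expected for _ in range(50))

    def test_half_split(self, rng):
        model = ArrivalModel()
        draws = [assign_urgency_split(model, rng) for _ in range(10_000)]
        share = draws.count("very_urgent") / len(draws)
        assert share == pytest.approx(0.5, abs=0.02)


class TestCaseDurations:
    def test_presence_mean_recovered(self, rng):
        """Mean induction + occupation of elective GVT short cases reproduces
        the calibrated 74-minute presence mean."""
        model = DurationModel()
        total = np.empty(10_000)
        for i in range(10_000):
            ind, occ, _ = sample_case_durations("GVT", "elective", "short", model, rng)
            total[i] = ind + occ
        assert total.mean() == pytest.approx(74.0, rel=0.03)

    def test_degenerate_dispersion_is_exact(self, rng):
        model = DurationModel(cv=0.0, cleaning_cv=0.0)
        ind, occ, clean = sample_case_durations("VS", "elective", "medium", model, rng)
        assert ind + occ == pytest.approx(135.0)
        assert ind == pytest.approx(0.2 * 135.0)
        assert clean == pytest.approx(15.0)

    def test_class_means_strictly_increase(self):
        model = DurationModel()
        for spec in SPECIALTIES:
            m = [model.presence_mean(spec, c) for c in CLASSES]
            assert m[0] < m[1] < m[2]

    def test_all_durations_positive(self, rng):
        model = DurationModel()
        for _ in range(500):
            spec = SPECIALTIES[int(rng.integers(len(SPECIALTIES)))]
            cls = CLASSES[int(rng.integers(3))]
            acuity = ("elective", "semi_urgent", "very_urgent", "emergency")[int(rng.integers(4))]
            for d in sample_case_durations(spec, acuity, cls, model, rng):
                assert d > 0

    def test_emergency_cases_longer_and_more_variable(self, rng):
        model = DurationModel()
        el = np.array([sum(sample_case_durations("TS", "elective", "medium", model, rng)[:2]) for _ in range(4000)])
        em = np.array([sum(sample_case_durations("TS", "emergency", "medium", model, rng)[:2]) for _ in range(4000)])
        assert em.mean() > el.mean()
        assert em.std() > el.std()

    def test_cardiac_occupation_is_bimodal(self, rng):
        """CAR occupation draws show two density modes near the configured
        mixture component means."""
        model = DurationModel()
        occ = np.array(
            [sample_case_durations("CAR", "elective", "medium", model, rng)[1] for _ in range(10_000)]
        )
        kde = gaussian_kde(occ, bw_method=0.12)
        grid = np.linspace(occ.min(), np.quantile(occ, 0.99), 400)
        dens = kde(grid)
        interior = (dens[1:-1] > dens[:-2]) & (dens[1:-1] > dens[2:])
        modes = grid[1:-1][interior]
        assert len(modes) >= 2
        occ_mean = 0.8 * 204.0
        lo_target = (1 - model.car_mixture_spread) * occ_mean
        hi_target = (1 + model.car_mixture_spread) * occ_mean
        assert any(abs(m - lo_target) / lo_target < 0.25 for m in modes)
        assert any(abs(m - hi_target) / hi_target < 0.25 for m in modes)

    def test_missing_specialty_rejected(self, rng):
        with pytest.raises(CalibrationError):
            sample_case_durations("XXX", "elective", "short", DurationModel(), rng)


class TestDurationClassification:
    def test_boundary_is_inclusive_left(self):
        model = DurationModel(class_threshold_override={"GVT": (100.0, 200.0)})
        assert classify_duration_class("GVT", 100.0, model) == "short"
        assert classify_duration_class("GVT", 100.1, model) == "medium"
        assert classify_duration_class("GVT", 200.0, model) == "medium"
        assert classify_duration_class("GVT", 201.0, model) == "long"

    def test_inverted_thresholds_rejected(self):
        with pytest.raises(CalibrationError):
            DurationModel(class_threshold_override={"GVT": (200.0, 100.0)})

    def test_terciles_split_draws_into_thirds(self, rng):
        """The default thresholds are terciles of the elective presence
        mixture, so each class receives about a third of sampled cases."""
        model = DurationModel()
        t1, t2 = model.class_thresholds("TS")
        assert t1 < t2
        draws = np.empty(10_000)
        for i in range(10_000):
            cls = CLASSES[int(rng.integers(3))]
            ind, occ, _ = sample_case_durations("TS", "elective", cls, model, rng)
            draws[i] = ind + occ
        shares = [
            (draws <= t1).mean(),
            ((draws > t1) & (draws <= t2)).mean(),
            (draws > t2).mean(),
        ]
        for s in shares:
            assert s == pytest.approx(1 / 3, abs=0.03)

    @settings(derandomize=True, max_examples=50)
    @given(st.floats(min_value=1.0, max_value=2000.0))
    def test_classification_is_monotone(self, duration):
        model = DurationModel()
        order = {c: i for i, c in enumerate(CLASSES)}
        c1 = classify_duration_class("NS", duration, model)
        c2 = classify_duration_class("NS", duration + 50.0, model)
        assert order[c2] >= order[c1]


class TestWeeklyGeneration:
    def test_elective_pool_calibrated_to_weekly_mean(self, calibration, mss, rng):
        sizes = [
            len(generate_weekly_elective_pool(calibration, mss, rng, week=w)) for w in range(300)
        ]
        assert np.mean(sizes) == pytest.approx(calibration.elective_weekly_mean, rel=0.03)

    def test_pool_departments_cover_mss(self, calibration, mss, rng):
        pool = generate_weekly_elective_pool(calibration, mss, rng, week=0)
        assert {p.specialty for p in pool} <= set(mss.departments)
        assert all(p.acuity == "elective" for p in pool)

    def test_weekly_demand_totals_and_mix(self, calibration, rng):
        """Total generated surgical demand averages ~345/week and electives
        are close to 72% of all generated patients."""
        demand = sample_weekly_demand(calibration, rng, weeks=1000)
        total = demand["elective"] + demand["urgent"] + demand["emergency"]
        assert total.mean() == pytest.approx(345.0, rel=0.03)
        share = demand["elective"].sum() / total.sum()
        assert share == pytest.approx(0.72, abs=0.02)

    def test_degenerate_mix_all_elective(self, mss, rng):
        calib = Calibration(arrival=zero_arrival_model())
        demand = sample_weekly_demand(calib, rng, weeks=400)
        assert demand["urgent"].sum() == 0 and demand["emergency"].sum() == 0
        total = demand["elective"]
        assert total.mean() == pytest.approx(345.0, rel=0.03)
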