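"""Reference likelihood: hand-derived values, conservation, and oracles."""

import itertools
import math

import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from eventfuse.hazards import HazardSpec
from eventfuse.likelihood import (
    MarkRecord,
    ModelParams,
    RadioRecord,
    SurveySchedule,
    detection_loglik_binomial,
    joint_loglik,
    loglik_marked,
    loglik_radio,
    tail_probability,
)
from eventfuse.model import CompiledLikelihood

from conftest import random_piecewise_spec


def constant_params(rate, p=1.0):
    return ModelParams(
        hazard=HazardSpec(log_rates=np.log([rate])), detection_p=p
    )


class TestLoglikRadio:
    def test_interval_censored_death_hand_value(self, weekly_schedule):
        # S(0->14) * (1 - S(14->21)) at rate 0.01/day
        rec = RadioRecord(entry=0.0, last_alive=14.0, first_dead=21.0)
        expected = -0.14 + math.log(1.0 - math.exp(-0.07))
        got = loglik_radio(rec, constant_params(0.01), weekly_schedule)
        assert got == pytest.approx(expected, abs=1e-12)
        assert got == pytest.approx(-2.834056, abs=5e-6)

    def test_right_censored_pure_survival(self, weekly_schedule):
        rec = RadioRecord(entry=0.0, last_alive=28.0)
        got = loglik_radio(rec, constant_params(0.01), weekly_schedule)
        assert got == pytest.approx(-0.28, abs=1e-12)

    def test_vanishing_hazard_gives_certain_survival(self, weekly_schedule):
        rec = RadioRecord(entry=0.0, last_alive=28.0)
        got = loglik_radio(rec, constant_params(1e-15), weekly_schedule)
        assert got == pytest.approx(0.0, abs=1e-12)

    def test_invalid_interval_rejected(self):
        with pytest.raises(ValueError):
            RadioRecord(entry=0.0, last_alive=21.0, first_dead=14.0)

    def test_optional_detection_term_for_collared_animals(self, weekly_schedule):
        """The generality variant adds Bernoulli terms up to the last
        sighting when collared animals were searched for like marked ones."""
        rec = RadioRecord(
            entry=0.0, last_alive=28.0,
            detections=np.array([1, 0, 1, 0]),
        )
        params = constant_params(0.01, p=0.4)
        base = loglik_radio(rec, params, weekly_schedule)
        with_det = loglik_radio(
            rec, params, weekly_schedule, include_detection=True
        )
        assert with_det - base == pytest.approx(
            detection_loglik_binomial(2, 3, 0.4)
        )


class TestDetectionBinomial:
    def test_hand_value(self):
        got = detection_loglik_binomial(3, 5, 0.4)
        assert got == pytest.approx(3 * math.log(0.4) + 2 * math.log(0.6))
        assert got == pytest.approx(-3.77052, abs=5e-6)

    def test_no_opportunities_contribute_nothing(self):
        assert detection_loglik_binomial(0, 0, 0.3) == 0.0
        assert detection_loglik_binomial(0, 0, 0.0) == 0.0

    def test_certain_detection_of_all_sightings(self):
        assert detection_loglik_binomial(7, 7, 1.0) == 0.0

    def test_more_sightings_than_surveys_rejected(self):
        with pytest.raises(ValueError):
            detection_loglik_binomial(6, 5, 0.4)


class TestTailProbability:
    def test_zero_detection_gives_total_probability_one(self, rng):
        # with p = 0 the death mixture plus survival must exhaust probability
        for _ in range(10):
            spec = random_piecewise_spec(rng)
            schedule = SurveySchedule(
                stimes=np.sort(rng.uniform(1.0, 90.0, size=5)), study_end=95.0
            )
            rec = MarkRecord(entry=0.5)
            params = ModelParams(hazard=spec, detection_p=0.0)
            assert tail_probability(rec, params, schedule) == 1.0

    def test_two_term_enumeration_hand_value(self):
        # last seen day 5, one remaining survey at day 10 = study end:
        # die in (5,10] OR survive and be missed once
        schedule = SurveySchedule(stimes=np.array([5.0, 10.0]), study_end=10.0)
        rec = MarkRecord(entry=0.0, last_seen=5.0, n_sightings=1)
        params = constant_params(0.1, p=0.5)
        expected = (1 - math.exp(-0.5)) + math.exp(-0.5) * 0.5
        got = tail_probability(rec, params, schedule)
        assert got == pytest.approx(expected, abs=1e-12)
        assert got == pytest.approx(0.69673, abs=5e-6)

    def test_certain_detection_leaves_only_early_death(self):
        schedule = SurveySchedule(stimes=np.array([5.0, 10.0]), study_end=10.0)
        rec = MarkRecord(entry=0.0, last_seen=5.0, n_sightings=1)
        params = constant_params(0.1, p=1.0)
        expected = 1 - math.exp(-0.5)  # must die before the next survey
        assert tail_probability(rec, params, schedule) == pytest.approx(expected)

    def test_dead_recovery_records_have_no_tail(self):
        schedule = SurveySchedule(stimes=np.array([5.0, 10.0]), study_end=10.0)
        rec = MarkRecord(entry=0.0, last_seen=5.0, n_sightings=1, first_dead=10.0)
        with pytest.raises(ValueError):
            tail_probability(rec, constant_params(0.1, 0.5), schedule)


def enumerate_history_probability(spec, p, entry, schedule):
    """Sum exp(loglik_marked) over every observable detection history."""
    n = schedule.surveys_in(entry, schedule.study_end).size
    total = 0.0
    params = ModelParams(hazard=spec, detection_p=p)
    for bits in itertools.product((0, 1), repeat=n):
        rec = MarkRecord.from_history(entry, list(bits), schedule)
        total += math.exp(loglik_marked(rec, params, schedule))
    return total


class TestConservation:
    @pytest.mark.parametrize("n_surveys", [1, 2, 3, 4])
    @pytest.mark.parametrize("p", [0.0, 0.3, 0.8, 1.0])
    def test_marked_histories_exhaust_probability(self, n_surveys, p):
        schedule = SurveySchedule(
            stimes=7.0 * np.arange(1, n_surveys + 1),
            study_end=7.0 * n_surveys + 3.0,
        )
        spec = HazardSpec(log_rates=np.log([0.03]))
        total = enumerate_history_probability(spec, p, 2.0, schedule)
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_conservation_with_piecewise_hazard_and_random_designs(self, rng):
        for _ in range(8):
            spec = random_piecewise_spec(rng, max_intervals=3, t_max=40.0)
            n = int(rng.integers(1, 5))
            stimes = np.sort(rng.uniform(3.0, 35.0, size=n))
            schedule = SurveySchedule(stimes=stimes, study_end=40.0)
            p = float(rng.uniform(0.05, 0.95))
            entry = float(rng.uniform(0.0, stimes[0] - 0.5))
            total = enumerate_history_probability(spec, p, entry, schedule)
            assert total == pytest.approx(1.0, abs=1e-10)


class TestLoglikMarked:
    def test_never_detected_reduces_to_tail_from_entry(self, rng):
        schedule = SurveySchedule(stimes=np.array([7.0, 14.0]), study_end=14.0)
        spec = HazardSpec(log_rates=np.log([0.05]))
        params = ModelParams(hazard=spec, detection_p=0.4)
        rec = MarkRecord(entry=1.0)
        assert loglik_marked(rec, params, schedule) == pytest.approx(
            math.log(tail_probability(rec, params, schedule))
        )

    def test_no_detection_and_no_sightings_is_uninformative(self):
        schedule = SurveySchedule(stimes=np.array([7.0, 14.0]), study_end=14.0)
        rec = MarkRecord(entry=1.0)
        assert loglik_marked(rec, constant_params(0.1, 0.0), schedule) == 0.0

    def test_three_element_composition(self):
        schedule = SurveySchedule(stimes=np.array([5.0, 10.0]), study_end=10.0)
        rec = MarkRecord(entry=0.0, last_seen=5.0, n_sightings=1)
        params = constant_params(0.1, p=0.5)
        tail = tail_probability(rec, params, schedule)
        expected = -0.5 + math.log(0.5) + math.log(tail)
        assert loglik_marked(rec, params, schedule) == pytest.approx(expected)

    def test_monotone_decreasing_in_p_for_all_miss_history(self):
        schedule = SurveySchedule(
            stimes=np.array([7.0, 14.0, 21.0]), study_end=21.0
        )
        rec = MarkRecord(entry=1.0)
        values = [
            loglik_marked(rec, constant_params(0.02, p), schedule)
            for p in np.linspace(0.01, 0.99, 25)
        ]
        assert all(a > b for a, b in zip(values[:-1], values[1:]))

    def test_discretization_oracle_for_observed_history(self):
        """Fine-bin latent-death enumeration converges to the likelihood."""
        schedule = SurveySchedule(stimes=np.array([5.0, 10.0, 15.0]),
                                  study_end=15.0)
        spec = HazardSpec(log_rates=np.log([0.07]))
        p = 0.45
        params = ModelParams(hazard=spec, detection_p=p)
        rec = MarkRecord.from_history(1.0, [1, 0, 0], schedule)
        dt = 0.002
        grid = np.arange(1.0, 15.0, dt)
        lam = 0.07
        prob = 0.0
        # death in (t, t+dt): detection opportunities at surveys < t
        for t in grid:
            p_die = math.exp(-lam * (t - 1.0)) * (1 - math.exp(-lam * dt))
            seen = [s for s in schedule.stimes if s <= t]
            if not (len(seen) >= 1):
                continue
            p_hist = p * (1 - p) ** (len(seen) - 1)  # seen at 5, missed later
            prob += p_die * p_hist
        p_surv = math.exp(-lam * (15.0 - 1.0)) * p * (1 - p) ** 2
        prob += p_surv
        got = math.exp(loglik_marked(rec, params, schedule))
        assert got == pytest.approx(prob, rel=5e-3)


class TestJointLoglik:
    def test_singleton_dataset_equals_radio_contribution(self, weekly_schedule):
        rec = RadioRecord(entry=0.0, last_alive=14.0, first_dead=21.0)
        params = constant_params(0.01)
        assert joint_loglik([rec], [], params, weekly_schedule) == (
            loglik_radio(rec, params, weekly_schedule)
        )

    def test_additive_over_concatenated_datasets(self, weekly_schedule):
        r1 = RadioRecord(entry=0.0, last_alive=14.0, first_dead=21.0)
        r2 = RadioRecord(entry=7.0, last_alive=35.0)
        m1 = MarkRecord(entry=1.0)
        params = constant_params(0.01, 0.3)
        total = joint_loglik([r1, r2], [m1], params, weekly_schedule)
        parts = joint_loglik([r1], [], params, weekly_schedule) + joint_loglik(
            [r2], [m1], params, weekly_schedule
        )
        assert total == pytest.approx(parts)

    def test_empty_dataset_rejected(self, weekly_schedule):
        with pytest.raises(ValueError):
            joint_loglik([], [], constant_params(0.01), weekly_schedule)

    def test_known_fate_mle_matches_grid_search_oracle(self, rng):
        """With p=1 and only radio records, the integrated likelihood is the
        classical interval-censored known-fate likelihood; its optimum must
        match an exhaustive grid search."""
        schedule = SurveySchedule.weekly(140.0)
        true_rate = 0.02
        records = []
        for _ in range(60):
            entry = float(rng.integers(0, 10))
            death = entry + rng.exponential(1 / true_rate)
            stimes = schedule.stimes
            if death > stimes[-1]:
                records.append(RadioRecord(entry=entry, last_alive=stimes[-1]))
            else:
                j = int(np.searchsorted(stimes, death, side="left"))
                r = stimes[j - 1] if j > 0 else entry
                records.append(
                    RadioRecord(entry=entry, last_alive=max(r, entry),
                                first_dead=float(stimes[j]))
                )

        def nll(log_rate):
            return -joint_loglik(
                records, [], constant_params(math.exp(log_rate)), schedule
            )

        grid = np.linspace(math.log(0.001), math.log(0.2), 4001)
        grid_best = grid[np.argmin([nll(g) for g in grid])]
        smooth = minimize_scalar(
            nll, bounds=(math.log(1e-4), math.log(0.5)), method="bounded"
        ).x
        assert math.exp(grid_best) == pytest.approx(
            math.exp(smooth), abs=1e-3
        )


class TestCompiledAgainstReference:
    def test_equality_on_randomized_mixed_datasets(self, rng):
        from eventfuse.simulation import SimConfig, simulate_dataset

        for seed in range(3):
            cfg = SimConfig(
                annual_survival=float(rng.uniform(0.2, 0.8)),
                detection_p=float(rng.uniform(0.1, 0.9)),
                n_radio=12, n_marked=15, n_replicates=2, seed=seed,
            )
            radio, marked, _ = simulate_dataset(
                cfg, np.random.default_rng(seed)
            )
            schedule = cfg.schedule()
            spec = cfg.hazard_spec()
            compiled = CompiledLikelihood(radio, marked, schedule, spec)
            for _ in range(4):
                rates = np.exp(rng.uniform(-7.0, -4.0, size=2))
                p = float(rng.uniform(0.05, 0.95))
                params = ModelParams(
                    hazard=HazardSpec(
                        log_rates=np.log(rates), season=spec.season
                    ),
                    detection_p=p,
                )
                ref = joint_loglik(radio, marked, params, schedule)
                fast = compiled.loglik(rates, p)
                assert fast == pytest.approx(ref, rel=1e-10)
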