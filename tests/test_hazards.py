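"""Hazard evaluation, exact integration, and the annual-survival design map."""

import math

import numpy as np
import pytest
from scipy.integrate import quad

from eventfuse.hazards import (
    CovariateEffect,
    HazardSpec,
    SeasonCalendar,
    annual_survival_to_rates,
    cumulative_hazard,
    exposures,
    hazard_at,
    survival_prob,
)

from conftest import random_piecewise_spec


class TestAnnualSurvivalToRates:
    @pytest.mark.parametrize(
        "annual_survival, lam1_4dp, lam2_5dp",
        [
            (0.25, 0.0030, 0.00607),
            (0.55, 0.0013, 0.00262),
            (0.85, 0.0004, 0.00071),
        ],
    )
    def test_design_rates_at_printed_rounding(
        self, annual_survival, lam1_4dp, lam2_5dp
    ):
        lam1, lam2 = annual_survival_to_rates(annual_survival, 2.0, 92, 365)
        assert round(lam1, 4) == lam1_4dp
        assert round(lam2, 5) == lam2_5dp

    def test_closed_form_solves_the_annual_survival_equation(self):
        for s in (0.1, 0.25, 0.55, 0.85, 0.99):
            lam1, lam2 = annual_survival_to_rates(s, 2.0, 92, 365)
            assert lam2 == pytest.approx(2.0 * lam1)
            assert math.exp(-lam1 * 273 - lam2 * 92) == pytest.approx(s)

    def test_rates_vanish_as_survival_approaches_one(self):
        lam1, lam2 = annual_survival_to_rates(1 - 1e-12, 2.0, 92, 365)
        assert lam1 < 1e-14 and lam2 < 1e-14

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.2, 1.7])
    def test_rejects_survival_outside_unit_interval(self, bad):
        with pytest.raises(ValueError):
            annual_survival_to_rates(bad, 2.0)


class TestHazardAt:
    def test_constant_rate_is_identity(self, constant_spec):
        assert hazard_at(constant_spec, None, None, 5.0) == pytest.approx(0.01)

    def test_seasonal_lookup_inside_hunting_window(self, seasonal_spec):
        assert hazard_at(seasonal_spec, None, None, 300.0) == pytest.approx(
            0.0060669
        )
        assert hazard_at(seasonal_spec, None, None, 100.0) == pytest.approx(
            0.0030335
        )

    def test_seasonal_lookup_is_periodic(self, seasonal_spec):
        assert hazard_at(seasonal_spec, None, None, 300.0 + 365.0) == (
            pytest.approx(0.0060669)
        )

    def test_hazard_ratio_covariate_doubles_rate(self, constant_spec):
        effect = CovariateEffect(
            coefficients=np.array([math.log(2.0)]), names=["x"]
        )
        assert hazard_at(
            constant_spec, effect, {"x": 1.0}, 5.0
        ) == pytest.approx(0.02)

    def test_unknown_covariate_name_raises(self, constant_spec):
        effect = CovariateEffect(coefficients=np.array([0.5]), names=["x"])
        with pytest.raises(KeyError):
            hazard_at(constant_spec, effect, {"y": 1.0}, 5.0)


class TestCumulativeHazard:
    def test_constant_rate_times_duration(self, constant_spec):
        assert cumulative_hazard(
            constant_spec, None, None, 0.0, 100.0
        ) == pytest.approx(1.0)

    def test_design_year_integrates_to_minus_log_survival(self, seasonal_spec):
        # by construction of the annual-survival design: one full year of the
        # two-season hazard must integrate to -ln(0.25)
        h = cumulative_hazard(seasonal_spec, None, None, 1.0, 366.0)
        assert h == pytest.approx(-math.log(0.25), rel=1e-4)

    def test_empty_interval_is_zero(self, seasonal_spec):
        assert cumulative_hazard(seasonal_spec, None, None, 42.0, 42.0) == 0.0

    def test_reversed_interval_raises(self, constant_spec):
        with pytest.raises(ValueError):
            cumulative_hazard(constant_spec, None, None, 5.0, 1.0)

    def test_additive_over_any_partition(self, rng):
        for _ in range(20):
            spec = random_piecewise_spec(rng)
            t0, t1 = np.sort(rng.uniform(0.0, 100.0, size=2))
            cuts = np.sort(rng.uniform(t0, t1, size=3))
            total = cumulative_hazard(spec, None, None, t0, t1)
            pieces = 0.0
            grid = [t0, *cuts, t1]
            for a, b in zip(grid[:-1], grid[1:]):
                pieces += cumulative_hazard(spec, None, None, a, b)
            assert pieces == pytest.approx(total, abs=1e-12)

    def test_matches_adaptive_quadrature_oracle(self, rng):
        for _ in range(15):
            spec = random_piecewise_spec(rng)
            t0, t1 = np.sort(rng.uniform(0.0, 100.0, size=2))
            exact = cumulative_hazard(spec, None, None, t0, t1)
            oracle, _ = quad(
                lambda u: hazard_at(spec, None, None, u),
                t0,
                t1,
                points=spec.change_points[
                    (spec.change_points > t0) & (spec.change_points < t1)
                ],
                limit=200,
            )
            assert exact == pytest.approx(oracle, abs=1e-10)

    def test_seasonal_matches_quadrature_across_years(self, seasonal_spec):
        season_edges = [274, 366, 639, 731, 1004, 1096, 1369, 1461]
        for t0, t1 in [(1, 366), (30, 477), (100, 1569)]:
            exact = cumulative_hazard(seasonal_spec, None, None, t0, t1)
            oracle, _ = quad(
                lambda u: hazard_at(seasonal_spec, None, None, u),
                t0, t1,
                points=[e for e in season_edges if t0 < e < t1],
                limit=500,
            )
            assert exact == pytest.approx(oracle, abs=1e-10)

    def test_exposures_sum_to_duration(self, rng):
        for _ in range(10):
            spec = random_piecewise_spec(rng)
            t0, t1 = np.sort(rng.uniform(0.0, 100.0, size=2))
            assert exposures(spec, t0, t1).sum() == pytest.approx(t1 - t0)


from hypothesis import given, settings, strategies as st  # noqa: E402


class TestHazardProperties:
    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(
        rates=st.lists(
            st.floats(1e-5, 0.5), min_size=1, max_size=4
        ),
        times=st.lists(
            st.floats(0.0, 200.0), min_size=3, max_size=3, unique=True
        ),
    )
    def test_cumulative_hazard_additive_and_nonnegative(self, rates, times):
        cps = np.linspace(10.0, 150.0, len(rates) - 1) if len(rates) > 1 else []
        spec = HazardSpec(log_rates=np.log(rates), change_points=cps)
        a, b, c = sorted(times)
        h_ab = cumulative_hazard(spec, None, None, a, b)
        h_bc = cumulative_hazard(spec, None, None, b, c)
        h_ac = cumulative_hazard(spec, None, None, a, c)
        assert h_ab >= 0.0 and h_bc >= 0.0
        assert h_ac == pytest.approx(h_ab + h_bc, abs=1e-9, rel=1e-9)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(
        start=st.integers(1, 200),
        length=st.integers(1, 165),
        t0=st.floats(0.0, 800.0),
        span=st.floats(0.0, 800.0),
    )
    def test_seasonal_exposure_split_is_consistent(self, start, length, t0, span):
        season = SeasonCalendar(start, start + length - 1)
        spec = HazardSpec(log_rates=np.log([0.001, 0.002]), season=season)
        off, on = exposures(spec, t0, t0 + span)
        assert off >= -1e-9 and on >= -1e-9
        assert off + on == pytest.approx(span, abs=1e-9)
        # one full period always contains exactly one season's worth
        off_y, on_y = exposures(spec, t0, t0 + season.period)
        assert on_y == pytest.approx(season.season_length, abs=1e-9)


class TestSurvivalProb:
    def test_constant_closed_form(self, constant_spec):
        assert survival_prob(
            constant_spec, None, None, 0.0, 100.0
        ) == pytest.approx(math.exp(-1.0))

    def test_design_year_returns_annual_survival(self):
        lam1, lam2 = annual_survival_to_rates(0.25, 2.0, 92, 365)
        spec = HazardSpec(
            log_rates=np.log([lam1, lam2]), season=SeasonCalendar(274, 365)
        )
        assert survival_prob(spec, None, None, 1.0, 366.0) == pytest.approx(0.25)

    def test_empty_interval_certain_survival(self, seasonal_spec):
        assert survival_prob(seasonal_spec, None, None, 7.0, 7.0) == 1.0

    def test_monotone_nonincreasing_in_endpoint(self, rng):
        spec = random_piecewise_spec(rng)
        t1s = np.linspace(0.0, 100.0, 40)
        probs = [survival_prob(spec, None, None, 0.0, t) for t in t1s]
        assert all(a >= b for a, b in zip(probs[:-1], probs[1:]))


class TestSpecValidation:
    def test_decreasing_change_points_rejected(self):
        with pytest.raises(ValueError):
            HazardSpec(log_rates=np.zeros(3), change_points=[5.0, 2.0])

    def test_rate_count_must_match_intervals(self):
        with pytest.raises(ValueError):
            HazardSpec(log_rates=np.zeros(3), change_points=[5.0])

    def test_seasonal_requires_two_rates(self):
        with pytest.raises(ValueError):
            HazardSpec(log_rates=np.zeros(3), season=SeasonCalendar())

    def test_roundtrip_serialization(self, seasonal_spec):
        rebuilt = HazardSpec.from_dict(seasonal_spec.to_dict())
        assert np.allclose(rebuilt.log_rates, seasonal_spec.log_rates)
        assert rebuilt.season == seasonal_spec.season


class TestCovariateEffect:
    def test_standardization_is_recorded_and_reversible(self):
        effect = CovariateEffect(
            coefficients=np.array([-0.35]),
            names=["mass"],
            standardization={"mass": (10.0, 2.0)},
        )
        z = effect.standardize("mass", 14.0)
        assert z == pytest.approx(2.0)
        raw_scale = effect.destandardize_coefficients()
        assert raw_scale[0] * 2.0 == pytest.approx(-0.35)

    def test_one_coefficient_per_name_enforced(self):
        with pytest.raises(ValueError):
            CovariateEffect(coefficients=np.array([1.0, 2.0]), names=["x"])
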