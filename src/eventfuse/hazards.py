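"""Piecewise-constant hazard functions on a continuous day-scale time axis.

The package models event (death) times with hazards that are constant within
intervals.  Two interval layouts are supported:

* ``piecewise`` — intervals delimited by explicit, strictly increasing change
  points on the time axis (used, e.g., for age-structured chick hazards);
* a calendar-periodic *season* layout — two rates (off-season / in-season)
  with the in-season window repeating every ``period`` days (used for the
  hunting-season simulation design).

All intervals are half-open ``[a, b)``.  The seasonal calendar is expressed
in day-of-study-year coordinates (365-day years, no leap years): with the
study year starting January 1 a 10/1–12/31 season occupies days 274–365 (the
``SeasonCalendar`` defaults); the simulation design instead anchors its study
year at the season opening (see ``simulation``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SeasonCalendar",
    "HazardSpec",
    "CovariateEffect",
    "hazard_at",
    "cumulative_hazard",
    "survival_prob",
    "annual_survival_to_rates",
    "exposures",
]


@dataclass(frozen=True)
class SeasonCalendar:
    """Periodic two-state calendar: in-season on days ``[start_day, end_day]``.

    Days are 1-based day-of-year; the in-season window is the half-open time
    interval ``[start_day, end_day + 1)`` repeated with the given period.
    """

    start_day: int = 274
    end_day: int = 365
    period: float = 365.0

    def __post_init__(self) -> None:
        if not (1 <= self.start_day <= self.end_day <= self.period):
            raise ValueError("require 1 <= start_day <= end_day <= period")

    @property
    def season_length(self) -> float:
        return float(self.end_day - self.start_day + 1)

    def in_season(self, t):
        """True where time ``t`` falls inside the seasonal window."""
        pos = np.mod(np.asarray(t, dtype=float) - 1.0, self.period)
        return (pos >= self.start_day - 1) & (pos < self.end_day)

    def season_time(self, t0: float, t1: float) -> float:
        """Lebesgue measure of in-season time within ``[t0, t1)``."""
        s0 = float(self.start_day)
        s1 = float(self.end_day + 1)
        L = s1 - s0

        def below(x: float) -> float:
            k = np.floor((x - s0) / self.period)
            return k * L + min(max(x - s0 - k * self.period, 0.0), L)

        return below(t1) - below(t0)


@dataclass
class HazardSpec:
    """A piecewise-constant hazard: per-interval log rates (per day).

    ``change_points`` delimit the intervals when ``season`` is ``None``;
    with ``k`` change points there are ``k + 1`` intervals covering the whole
    axis.  When ``season`` is set there must be exactly two rates —
    off-season first, in-season second — and interval lookup is periodic.

    ``age_offsets`` are optional per-interval additive offsets on the log
    scale (used by the random-walk age model); they must align with the
    intervals.
    """

    log_rates: np.ndarray
    change_points: np.ndarray = field(default_factory=lambda: np.empty(0))
    season: SeasonCalendar | None = None
    age_offsets: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.log_rates = np.atleast_1d(np.asarray(self.log_rates, dtype=float))
        self.change_points = np.atleast_1d(
            np.asarray(self.change_points, dtype=float)
        )
        if self.season is not None:
            if self.change_points.size:
                raise ValueError("seasonal specs take no explicit change points")
            if self.log_rates.size != 2:
                raise ValueError(
                    "seasonal specs need exactly 2 rates (off-season, in-season)"
                )
        else:
            if np.any(np.diff(self.change_points) <= 0):
                raise ValueError("change_points must be strictly increasing")
            if self.log_rates.size != self.change_points.size + 1:
                raise ValueError("need one rate per interval")
        if not np.all(np.isfinite(self.log_rates)):
            raise ValueError("log rates must be finite")
        if self.age_offsets is not None:
            self.age_offsets = np.asarray(self.age_offsets, dtype=float)
            if self.age_offsets.shape != self.log_rates.shape:
                raise ValueError("age_offsets must align with intervals")

    @property
    def kind(self) -> str:
        if self.season is not None:
            return "seasonal"
        return "constant" if self.log_rates.size == 1 else "piecewise"

    @property
    def n_intervals(self) -> int:
        return self.log_rates.size

    @property
    def rates(self) -> np.ndarray:
        """Per-interval baseline rates, age offsets folded in."""
        lr = self.log_rates
        if self.age_offsets is not None:
            lr = lr + self.age_offsets
        return np.exp(lr)

    def interval_index(self, t):
        """Index of the rate interval containing time ``t``."""
        t = np.asarray(t, dtype=float)
        if self.season is not None:
            return self.season.in_season(t).astype(int)
        return np.searchsorted(self.change_points, t, side="right")

    def to_dict(self) -> dict:
        out: dict = {"log_rates": self.log_rates.tolist()}
        if self.season is not None:
            out["season"] = {
                "start_day": self.season.start_day,
                "end_day": self.season.end_day,
                "period": self.season.period,
            }
        else:
            out["change_points"] = self.change_points.tolist()
        if self.age_offsets is not None:
            out["age_offsets"] = self.age_offsets.tolist()
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "HazardSpec":
        season = None
        if d.get("season") is not None:
            season = SeasonCalendar(**d["season"])
        return cls(
            log_rates=np.asarray(d["log_rates"], dtype=float),
            change_points=np.asarray(d.get("change_points", []), dtype=float),
            season=season,
            age_offsets=(
                np.asarray(d["age_offsets"], dtype=float)
                if d.get("age_offsets") is not None
                else None
            ),
        )


@dataclass
class CovariateEffect:
    """Log-linear proportional-hazards coefficients.

    Exponentiated coefficients are hazard ratios for a one-unit (one standard
    deviation, for standardized continuous covariates) increase.
    ``standardization`` maps covariate name -> (mean, sd), applied once when
    the linear predictor is evaluated on raw values.
    """

    coefficients: np.ndarray
    names: list[str]
    standardization: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coefficients = np.atleast_1d(
            np.asarray(self.coefficients, dtype=float)
        )
        if self.coefficients.size != len(self.names):
            raise ValueError("one coefficient per named covariate")

    def standardize(self, name: str, value: float) -> float:
        if name in self.standardization:
            mean, sd = self.standardization[name]
            return (value - mean) / sd
        return value

    def destandardize_coefficients(self) -> np.ndarray:
        """Coefficients on the raw covariate scale (per-unit, not per-SD)."""
        out = self.coefficients.copy()
        for i, name in enumerate(self.names):
            if name in self.standardization:
                out[i] = out[i] / self.standardization[name][1]
        return out

    def linear_predictor(self, covariates) -> float:
        """Dot product of coefficients with (standardized) covariate values.

        ``covariates`` may be a mapping name -> value or a sequence aligned
        with ``names`` (assumed already standardized in the latter case).
        """
        if covariates is None:
            if self.coefficients.size:
                raise ValueError("covariate values required")
            return 0.0
        if isinstance(covariates, dict):
            total = 0.0
            for i, name in enumerate(self.names):
                if name not in covariates:
                    raise KeyError(f"unknown or missing covariate {name!r}")
                value = covariates[name]
                if value is None or (
                    isinstance(value, float) and np.isnan(value)
                ):
                    raise ValueError(
                        f"covariate {name!r} is missing; impute upstream"
                    )
                total += self.coefficients[i] * self.standardize(name, value)
            return float(total)
        x = np.asarray(covariates, dtype=float)
        if x.size != self.coefficients.size:
            raise ValueError("covariate vector length mismatch")
        return float(self.coefficients @ x)


def _lp(effect: CovariateEffect | None, covariates) -> float:
    if effect is None:
        return 0.0
    return effect.linear_predictor(covariates)


def exposures(spec: HazardSpec, t0: float, t1: float) -> np.ndarray:
    """Per-interval time spent in ``[t0, t1)``; sums to ``t1 - t0``.

    This is the workhorse behind exact cumulative hazards: for a
    piecewise-constant hazard, the integral is ``exposures @ rates``.
    """
    if t0 > t1:
        raise ValueError(f"require t0 <= t1, got ({t0}, {t1})")
    if spec.season is not None:
        on = spec.season.season_time(t0, t1)
        return np.array([(t1 - t0) - on, on])
    edges = np.concatenate(([-np.inf], spec.change_points, [np.inf]))
    lo = np.maximum(edges[:-1], t0)
    hi = np.minimum(edges[1:], t1)
    return np.maximum(hi - lo, 0.0)


def hazard_at(
    spec: HazardSpec,
    effect: CovariateEffect | None,
    covariates,
    t,
) -> float:
    """Hazard rate (per day) at time ``t`` including covariate multipliers."""
    idx = spec.interval_index(t)
    lr = spec.log_rates[idx]
    if spec.age_offsets is not None:
        lr = lr + spec.age_offsets[idx]
    return np.exp(lr + _lp(effect, covariates))


def cumulative_hazard(
    spec: HazardSpec,
    effect: CovariateEffect | None,
    covariates,
    t0: float,
    t1: float,
) -> float:
    """Exact integral of the hazard over ``[t0, t1]``; additive in ``t``."""
    base = float(exposures(spec, t0, t1) @ spec.rates)
    return base * np.exp(_lp(effect, covariates))


def survival_prob(
    spec: HazardSpec,
    effect: CovariateEffect | None,
    covariates,
    t0: float,
    t1: float,
) -> float:
    """P(survive to t1 | alive at t0) = exp(-cumulative hazard)."""
    return float(np.exp(-cumulative_hazard(spec, effect, covariates, t0, t1)))


def annual_survival_to_rates(
    annual_survival: float,
    hazard_ratio: float,
    hunting_days: int = 92,
    year_days: int = 365,
) -> tuple[float, float]:
    """Seasonal daily rates implied by an annual survival probability.

    Solves ``exp(-l1*(year_days - hunting_days) - r*l1*hunting_days) = S``
    with the in-season rate constrained to ``r`` times the off-season rate:

        l1 = -ln(S) / ((year_days - hunting_days) + r * hunting_days)

    Returns ``(off_season_rate, in_season_rate)``.
    """
    if not 0.0 < annual_survival < 1.0:
        raise ValueError("annual survival must lie strictly in (0, 1)")
    if hazard_ratio <= 0:
        raise ValueError("hazard ratio must be positive")
    if not 0 <= hunting_days <= year_days:
        raise ValueError("hunting_days must lie in [0, year_days]")
    lam1 = -np.log(annual_survival) / (
        (year_days - hunting_days) + hazard_ratio * hunting_days
    )
    return float(lam1), float(hazard_ratio * lam1)
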