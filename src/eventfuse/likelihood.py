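"""Joint likelihood for mixed known-fate and unknown-fate encounter data.

Two kinds of individuals contribute:

* **Radio-collared (known fate).**  Their status is ascertained at every
  check, so the event time is known to an interval ``[r, s]`` (last-known
  alive, first-known dead) or right-censored (``s = inf``).  Contribution:
  ``S(e -> r) * (1 - S(r -> s))`` for deaths, ``S(e -> r)`` when censored,
  conditioning on survival to the entry time ``e`` (staggered entry / left
  truncation).

* **Marked (unknown fate).**  They are detected imperfectly at discrete
  surveys with probability ``p`` while alive.  Contribution: survival to the
  last sighting, a binomial detection term over the surveys between entry and
  the last sighting, and a *tail* term mixing every explanation of the empty
  end of the history — death in some inter-survey interval (which censors the
  later detection opportunities) or survival with repeated non-detection.

The joint likelihood multiplies both components and shares the hazard
parameters between them — that sharing is what lets unknown-fate individuals
inform the hazard at all.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .hazards import CovariateEffect, HazardSpec, survival_prob

__all__ = [
    "SurveySchedule",
    "RadioRecord",
    "MarkRecord",
    "ModelParams",
    "loglik_radio",
    "detection_loglik_binomial",
    "tail_probability",
    "loglik_marked",
    "joint_loglik",
]

_TINY = 1e-300  # underflow guard before taking logs


@dataclass(frozen=True)
class SurveySchedule:
    """Ordered survey times (days) plus the study end."""

    stimes: np.ndarray
    study_end: float

    def __post_init__(self) -> None:
        stimes = np.atleast_1d(np.asarray(self.stimes, dtype=float))
        object.__setattr__(self, "stimes", stimes)
        if stimes.size == 0:
            raise ValueError("schedule needs at least one survey")
        if np.any(np.diff(stimes) <= 0):
            raise ValueError("survey times must be strictly increasing")
        if stimes[-1] > self.study_end:
            raise ValueError("surveys must not run past study_end")

    @property
    def n_surveys(self) -> int:
        return self.stimes.size

    def surveys_in(self, t0: float, t1: float) -> np.ndarray:
        """Survey times in the half-open-from-the-left window ``(t0, t1]``."""
        lo = np.searchsorted(self.stimes, t0, side="right")
        hi = np.searchsorted(self.stimes, t1, side="right")
        return self.stimes[lo:hi]

    @classmethod
    def weekly(cls, study_end: float, period: float = 7.0) -> "SurveySchedule":
        n = int(math.floor(study_end / period))
        return cls(stimes=period * np.arange(1, n + 1), study_end=study_end)


@dataclass
class RadioRecord:
    """Known-fate individual: entry ``e``, last-alive ``r``, first-dead ``s``.

    ``s = inf`` marks right censoring.  ``detections`` (optional) are
    per-survey 0/1 indicators, only used when the optional detection term is
    switched on.
    """

    entry: float
    last_alive: float
    first_dead: float = np.inf
    covariates: dict = field(default_factory=dict)
    detections: np.ndarray | None = None
    ident: str | None = None

    def __post_init__(self) -> None:
        if self.entry > self.last_alive:
            raise ValueError("entry must not exceed last_alive")
        if self.last_alive >= self.first_dead:
            raise ValueError("last_alive must precede first_dead")

    @property
    def censored(self) -> bool:
        return not np.isfinite(self.first_dead)


@dataclass
class MarkRecord:
    """Unknown-fate individual with an imperfect-detection sighting history.

    ``last_seen`` is the time of the last survey with a detection (``None``
    if never seen — then survival conditions from entry).  ``n_sightings``
    counts detections.  Default ``first_dead = inf``: most marked animals are
    right-censored; a finite ``first_dead`` (dead recovery) replaces the tail
    with an interval-death term.
    """

    entry: float
    last_seen: float | None = None
    n_sightings: int = 0
    first_dead: float = np.inf
    covariates: dict = field(default_factory=dict)
    history: np.ndarray | None = None
    ident: str | None = None

    def __post_init__(self) -> None:
        if self.last_seen is None:
            if self.n_sightings != 0:
                raise ValueError("sightings recorded but no last_seen time")
        else:
            if self.n_sightings < 1:
                raise ValueError("last_seen set but no sightings counted")
            if self.last_seen <= self.entry:
                raise ValueError("last_seen must follow entry")
        if np.isfinite(self.first_dead) and self.first_dead <= (
            self.last_seen if self.last_seen is not None else self.entry
        ):
            raise ValueError("first_dead must follow the last sighting")

    @property
    def last_known_alive(self) -> float:
        """Time the animal was last known alive (entry if never seen)."""
        return self.entry if self.last_seen is None else self.last_seen

    @classmethod
    def from_history(
        cls,
        entry: float,
        history,
        schedule: SurveySchedule,
        first_dead: float = np.inf,
        covariates: dict | None = None,
        ident: str | None = None,
    ) -> "MarkRecord":
        """Build a record from 0/1 indicators over surveys after ``entry``."""
        history = np.asarray(history, dtype=int)
        avail = schedule.surveys_in(entry, schedule.study_end)
        if history.size != avail.size:
            raise ValueError(
                f"history length {history.size} != surveys after entry "
                f"({avail.size})"
            )
        seen = np.flatnonzero(history)
        last_seen = float(avail[seen[-1]]) if seen.size else None
        return cls(
            entry=entry,
            last_seen=last_seen,
            n_sightings=int(history.sum()),
            first_dead=first_dead,
            covariates=covariates or {},
            history=history,
            ident=ident,
        )


@dataclass
class ModelParams:
    """Bundled parameters: hazard spec, covariate effect, detection prob."""

    hazard: HazardSpec
    detection_p: float = 1.0
    effect: CovariateEffect | None = None
    imputed: dict = field(default_factory=dict)
    imputation_probs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.detection_p <= 1.0:
            raise ValueError("detection probability must lie in [0, 1]")

    def covariate_values(self, rec) -> dict | None:
        """Record covariates with any imputed values substituted."""
        if self.effect is None:
            return None
        cov = dict(rec.covariates)
        if rec.ident is not None and rec.ident in self.imputed:
            cov.update(self.imputed[rec.ident])
        return cov


def _logS(params: ModelParams, cov, t0: float, t1: float) -> float:
    """log survival probability over [t0, t1]."""
    s = survival_prob(params.hazard, params.effect, cov, t0, t1)
    return float(np.log(max(s, _TINY)))


def loglik_radio(
    rec: RadioRecord,
    params: ModelParams,
    schedule: SurveySchedule,
    include_detection: bool = False,
) -> float:
    """Log-likelihood contribution of a known-fate (radio-collared) record.

    ``include_detection`` adds Bernoulli terms for the sighting indicators
    between entry and the last sighting; off by default (detection of a
    working transmitter is effectively certain, so the term carries
    information only when collared animals were searched for like marked
    ones).
    """
    cov = params.covariate_values(rec)
    ll = _logS(params, cov, rec.entry, rec.last_alive)
    if not rec.censored:
        s_rs = survival_prob(
            params.hazard, params.effect, cov, rec.last_alive, rec.first_dead
        )
        ll += float(np.log(max(1.0 - s_rs, _TINY)))
    if include_detection and rec.detections is not None:
        seen = np.flatnonzero(rec.detections)
        if seen.size:
            n_avail = seen[-1] + 1
            nn = int(rec.detections[: n_avail].sum())
            ll += detection_loglik_binomial(nn, n_avail, params.detection_p)
    if not np.isfinite(ll):
        raise FloatingPointError("non-finite radio log-likelihood")
    return ll


def detection_loglik_binomial(nn: int, n_avail: int, p: float) -> float:
    """Bernoulli-product detection term: ``nn ln p + (n_avail-nn) ln(1-p)``.

    ``n_avail`` counts the surveys from the first survey after entry through
    the last survey at which the animal was seen.  Uses the convention
    ``0 * ln 0 = 0`` (no opportunities contribute nothing).  No binomial
    coefficient: the history records *which* surveys had sightings.
    """
    if not 0 <= nn <= n_avail:
        raise ValueError(f"need 0 <= nn <= n_avail, got ({nn}, {n_avail})")
    ll = 0.0
    if nn:
        ll += nn * math.log(max(p, _TINY))
    if n_avail - nn:
        ll += (n_avail - nn) * math.log(max(1.0 - p, _TINY))
    return ll


def tail_probability(
    rec: MarkRecord,
    params: ModelParams,
    schedule: SurveySchedule,
) -> float:
    """Probability of the empty end of a marked animal's history.

    Starting from the last-known-alive time ``t*``, the animal either died in
    some inter-survey interval — censoring all later detection opportunities
    (the post-death latent histories sum to one and drop out) — or survived
    through the last survey while being missed every time.  With remaining
    survey times ``t_1 < ... < t_K`` after ``t*`` and ``q = 1 - p``:

        tail = sum_k [S(t*->t_{k-1}) - S(t*->t_k)] q^(k-1)  +  S(t*->t_K) q^K

    which telescopes to ``1 - p * sum_k S(t*->t_k) q^(k-1)``.  Death at
    exactly a survey time counts as death before the survey.  Time after the
    last survey is treated as informationless, so the final survival factor
    runs to the last survey, not the study end.
    """
    if np.isfinite(rec.first_dead):
        raise ValueError("tail term applies to right-censored records only")
    p = params.detection_p
    cov = params.covariate_values(rec)
    t_star = rec.last_known_alive
    remaining = schedule.surveys_in(t_star, schedule.study_end)
    if remaining.size == 0 or p == 0.0:
        return 1.0
    q = 1.0 - p
    total = 0.0
    for k, t_k in enumerate(remaining):
        surv = survival_prob(params.hazard, params.effect, cov, t_star, t_k)
        total += surv * q**k
    return float(1.0 - p * total)


def loglik_marked(
    rec: MarkRecord,
    params: ModelParams,
    schedule: SurveySchedule,
) -> float:
    """Log-likelihood contribution of an unknown-fate (marked) record.

    Three multiplicative elements: survival while known alive, the binomial
    detection term over surveys between entry and the last sighting, and the
    never-seen-again tail (or an interval-death term for dead recoveries).
    """
    cov = params.covariate_values(rec)
    t_star = rec.last_known_alive
    surv = survival_prob(params.hazard, params.effect, cov, rec.entry, t_star)
    ll = float(np.log(max(surv, _TINY)))
    n_avail = schedule.surveys_in(rec.entry, t_star).size
    ll += detection_loglik_binomial(rec.n_sightings, n_avail, params.detection_p)
    if np.isfinite(rec.first_dead):
        s_rs = survival_prob(
            params.hazard, params.effect, cov, t_star, rec.first_dead
        )
        ll += float(np.log(max(1.0 - s_rs, _TINY)))
        missed = schedule.surveys_in(t_star, rec.first_dead).size
        # surveys between the last sighting and death were certain misses
        ll += detection_loglik_binomial(0, missed, params.detection_p)
    else:
        ll += float(np.log(max(tail_probability(rec, params, schedule), _TINY)))
    if not np.isfinite(ll):
        raise FloatingPointError("non-finite marked log-likelihood")
    return ll


def joint_loglik(
    radio_records,
    mark_records,
    params: ModelParams,
    schedule: SurveySchedule,
    include_detection: bool = False,
) -> float:
    """Sum of per-record contributions; hazard parameters are shared.

    The sharing of hazard parameters across the known-fate and unknown-fate
    components is what integrates the two data sources.
    """
    radio_records = list(radio_records)
    mark_records = list(mark_records)
    if not radio_records and not mark_records:
        raise ValueError("empty dataset")
    ll = 0.0
    for rec in radio_records:
        ll += loglik_radio(rec, params, schedule, include_detection)
    for rec in mark_records:
        ll += loglik_marked(rec, params, schedule)
    return ll
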