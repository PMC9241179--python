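"""Synthetic stand-ins for unpublished model inputs, with known ground truth.

Two inputs of the decision model are not publicly tabulated: the multistate
regression parameters of the long-term natural-history phase (estimated from
a retrospective clinical dataset) and the national lifetable.  This module
generates both synthetically —

* :func:`simulate_histories` draws subject-level multistate event histories
  under known proportional-hazard parameters, so the likelihood fitter in
  :mod:`visioncea.progression` can be tested by parameter recovery;
* :func:`synthetic_lifetable` builds a Gompertz–Makeham lifetable;
* :func:`plausible_longterm_params` returns a clinically plausible Weibull
  parameter set (``provenance="synthetic"``) so the whole pipeline runs
  without any download.

Every generator returns the generating parameters alongside (or as) its
output; tests never reverse-engineer the truth from the data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .model_config import (
    Lifetable,
    MultistateParams,
    ValidationError,
)

__all__ = [
    "EventHistory",
    "simulate_histories",
    "histories_to_frame",
    "histories_from_frame",
    "synthetic_lifetable",
    "plausible_longterm_params",
]


@dataclass
class EventHistory:
    """One subject's exactly-observed path through the vision states.

    ``states[k]`` is entered at ``times[k]`` (years); the subject is censored
    in ``states[-1]`` at ``censor_time``.  States strictly worsen along the
    path and entry times strictly increase.
    """

    subject_id: int
    states: list[int]
    times: list[float]
    censor_time: float

    def __post_init__(self) -> None:
        if len(self.states) != len(self.times) or not self.states:
            raise ValidationError("history: states and times must align, non-empty")
        if any(b <= a for a, b in zip(self.states, self.states[1:])):
            raise ValidationError("history: states must strictly worsen")
        if any(b <= a for a, b in zip(self.times, self.times[1:])):
            raise ValidationError("history: entry times must strictly increase")
        if self.censor_time < self.times[-1]:
            raise ValidationError("history: censor_time before last entry")

    @property
    def intervals(self) -> list[tuple[int, float, float, int | None]]:
        """(state, t_start, t_stop, next_state-or-None) at-risk intervals."""
        out = []
        for k, (s, t0) in enumerate(zip(self.states, self.times)):
            if k + 1 < len(self.states):
                out.append((s, t0, self.times[k + 1], self.states[k + 1]))
            else:
                out.append((s, t0, self.censor_time, None))
        return out


# -- cumulative-hazard inversion per family ---------------------------------

def _cumhaz(t: np.ndarray | float, family: str, shape: float, rate: float):
    """Cumulative baseline hazard H0(t) of the documented parametrizations."""
    t = np.asarray(t, dtype=float)
    if family == "exponential":
        return rate * t
    if family == "weibull":
        return rate * t ** shape
    if family == "gompertz":
        return (rate / shape) * np.expm1(shape * t)
    if family == "loglogistic":
        return np.log1p((rate * t) ** shape)
    if family == "lognormal":
        mu, sigma = -math.log(rate), 1.0 / shape
        with np.errstate(divide="ignore"):
            z = (np.log(np.maximum(t, 1e-300)) - mu) / sigma
        return np.where(t <= 0, 0.0, -stats.norm.logsf(z))
    raise ValidationError(f"unknown family {family!r}")


def _invert_cumhaz(h: float, family: str, shape: float, rate: float) -> float:
    """Solve H0(t) = h for t (h > 0)."""
    if family == "exponential":
        return h / rate
    if family == "weibull":
        return (h / rate) ** (1.0 / shape)
    if family == "gompertz":
        return math.log1p(shape * h / rate) / shape
    if family == "loglogistic":
        return math.expm1(h) ** (1.0 / shape) / rate
    if family == "lognormal":
        mu, sigma = -math.log(rate), 1.0 / shape
        return math.exp(mu + sigma * stats.norm.isf(math.exp(-h)))
    raise ValidationError(f"unknown family {family!r}")


def simulate_histories(
    params: MultistateParams,
    n: int,
    max_follow_up: float,
    seed: int,
    start_state: int = 1,
) -> list[EventHistory]:
    """Simulate ``n`` forward multistate paths under ``params``.

    From state *i* at model time *t*, the enabled destinations *j > i* compete
    with intensities ``HR_ij * h0(t)``.  Because all transitions share the
    baseline hazard, the total exit intensity is ``(sum HR_ij) * h0(t)``; the
    exit time is drawn by closed-form inversion of the cumulative baseline
    hazard and the destination by the hazard-ratio proportions (which are
    time-invariant under proportional hazards).  Subjects are censored at
    ``max_follow_up`` years.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    out: list[EventHistory] = []
    hr = {t: math.exp(b) for t, b in params.log_hr.items()}
    for sid in range(n):
        state, t = int(start_state), 0.0
        states, times = [state], [0.0]
        while True:
            dests = [(j, hr[(state, j)]) for (i, j) in params.transitions if i == state]
            if not dests:
                break
            total = sum(w for _, w in dests)
            target = _cumhaz(t, params.family, params.shape, params.rate) + \
                rng.exponential() / total
            t_next = _invert_cumhaz(target, params.family, params.shape, params.rate)
            if t_next >= max_follow_up:
                break
            weights = np.array([w for _, w in dests]) / total
            state = int(dests[rng.choice(len(dests), p=weights)][0])
            t = max(t_next, t + 1e-12)  # strict increase under float rounding
            states.append(state)
            times.append(t)
        out.append(EventHistory(sid, states, times, max_follow_up))
    return out


def histories_to_frame(histories: list[EventHistory]) -> pd.DataFrame:
    """Long-format frame: one row per state entry plus a terminal censor row."""
    rows = []
    for h in histories:
        for s, t in zip(h.states, h.times):
            rows.append((h.subject_id, s, t, 0))
        rows.append((h.subject_id, h.states[-1], h.censor_time, 1))
    return pd.DataFrame(
        rows, columns=["subject_id", "state", "entry_time_years", "censored_flag"]
    )


def histories_from_frame(frame: pd.DataFrame) -> list[EventHistory]:
    out = []
    for sid, grp in frame.groupby("subject_id", sort=True):
        grp = grp.sort_values("entry_time_years", kind="stable")
        cens = grp[grp["censored_flag"] == 1]
        if len(cens) != 1:
            raise ValidationError(f"subject {sid}: expected exactly one censor row")
        body = grp[grp["censored_flag"] == 0]
        out.append(
            EventHistory(
                int(sid),
                [int(s) for s in body["state"]],
                [float(t) for t in body["entry_time_years"]],
                float(cens["entry_time_years"].iloc[0]),
            )
        )
    return out


def synthetic_lifetable(
    a: float = 2e-5, b: float = 0.095, c: float = 5e-4, max_age: int = 110
) -> Lifetable:
    """Gompertz–Makeham lifetable: ``q(age) = 1 - exp(-(c + a e^{b age}))``.

    A synthetic stand-in for a national lifetable; the defaults give a modern
    high-income mortality profile (q rising from ~6e-4 in childhood to near 1
    past age 105).
    """
    if min(a, b, c) < 0:
        raise ValidationError("lifetable parameters must be non-negative")
    ages = np.arange(0, max_age + 1)
    q = 1.0 - np.exp(-(c + a * np.exp(b * ages)))
    return Lifetable(ages, np.clip(q, 0.0, 1.0))


#: canonical synthetic long-term parameter values (Weibull, accelerating
#: decline, ~10-year median HS1->HS2 sojourn before competing exits)
_CANONICAL_SHAPE = 1.5
_CANONICAL_RATE = math.log(2.0) / 10.0 ** 1.5
_CANONICAL_LOG_HR = {
    (1, 2): 0.0,
    (1, 3): math.log(0.35),
    (1, 4): math.log(0.12),
    (1, 5): math.log(0.05),
    (2, 3): math.log(1.30),
    (2, 4): math.log(0.40),
    (2, 5): math.log(0.15),
    (3, 4): math.log(1.70),
    (3, 5): math.log(0.50),
    (4, 5): math.log(2.20),
}


def plausible_longterm_params(seed: int | None = None) -> MultistateParams:
    """A labelled-synthetic Weibull multistate parameter set.

    Shape > 1 (decline accelerates with time from baseline), hazard ratios
    increasing for adjacent transitions deeper into the disease and smaller
    for state-skipping jumps, reference HS1->HS2 median sojourn of roughly a
    decade.  ``seed=None`` returns the canonical values exactly; an integer
    seed applies a small lognormal jitter (~5%) for randomized property tests.
    """
    shape, rate = _CANONICAL_SHAPE, _CANONICAL_RATE
    log_hr = dict(_CANONICAL_LOG_HR)
    if seed is not None:
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        shape *= math.exp(rng.normal(0.0, 0.05))
        rate *= math.exp(rng.normal(0.0, 0.05))
        for t in list(log_hr):
            if t != (1, 2):
                log_hr[t] += rng.normal(0.0, 0.05)
    return MultistateParams(
        family="weibull",
        shape=shape,
        rate=rate,
        log_hr=log_hr,
        provenance="synthetic",
    )
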