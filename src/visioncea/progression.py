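"""Long-term natural-history machinery.

Visual decline after the first model year follows a time-inhomogeneous
forward-only multistate process over HS1..HS5.  Every forward transition
(i -> j, j > i) shares a single baseline hazard — that of the reference
HS1 -> HS2 transition — scaled by a transition-specific hazard ratio
(proportional hazards, pooled estimation).  Baseline hazard forms, with
``g = shape`` and ``l = rate``:

=============  ===========================================  =====================
family         hazard h0(t)                                 cumulative H0(t)
=============  ===========================================  =====================
exponential    ``l``                                        ``l t``
weibull        ``g l t**(g-1)``                             ``l t**g``
gompertz       ``l exp(g t)``                               ``(l/g)(e^{g t}-1)``
loglogistic    ``l g (l t)**(g-1) / (1 + (l t)**g)``        ``log(1 + (l t)**g)``
lognormal      ``pdf/sf of LogNormal(mu=-log l, s=1/g)``    ``-log sf(t)``
=============  ===========================================  =====================

The time argument is years since model start (the clock is configurable at
the engine level): the process is Markov in model time, not in state-entry
time.  Per-cycle transition probability matrices are the matrix exponential
of the generator integrated over the cycle; because all intensities are the
shared baseline times constants, generators at different times commute and
this product integral is exact, with the cycle integral of the baseline
hazard available in closed form for every family.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, special, stats
from scipy.linalg import expm

from .model_config import (
    FORWARD_TRANSITIONS,
    REFERENCE_TRANSITION,
    MultistateParams,
    ValidationError,
)
from .synthetic_data import EventHistory

__all__ = [
    "hazard",
    "cumulative_hazard",
    "generator_matrix",
    "cycle_transition_matrix",
    "derive_hs5_row",
    "MultistateFit",
    "FitError",
    "fit_multistate",
]

logger = logging.getLogger(__name__)

#: offset used when a point hazard must be evaluated at a singular t = 0
T_EPSILON = 1e-6


class FitError(RuntimeError):
    """Multistate likelihood fitting failed."""


def _check_transition(transition: tuple[int, int]) -> tuple[int, int]:
    t = (int(transition[0]), int(transition[1]))
    if t not in FORWARD_TRANSITIONS:
        raise ValidationError(
            f"transition HS{t[0]}->HS{t[1]} is not a forward (worsening) transition"
        )
    return t


def baseline_hazard(t, family: str, shape: float, rate: float):
    """Baseline hazard h0(t) for the reference transition (vectorized in t)."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValidationError("hazard: t must be >= 0")
    if family == "exponential":
        return np.full_like(t, rate)
    if family == "weibull":
        with np.errstate(divide="ignore"):
            return shape * rate * t ** (shape - 1.0)
    if family == "gompertz":
        return rate * np.exp(shape * t)
    if family == "loglogistic":
        with np.errstate(divide="ignore", invalid="ignore"):
            u = (rate * t) ** shape
            h = np.where(t > 0, shape * u / (np.maximum(t, 1e-300) * (1.0 + u)), np.inf)
        if shape > 1:
            h = np.where(t == 0, 0.0, h)
        elif shape == 1:
            h = np.where(t == 0, rate, h)
        return h
    if family == "lognormal":
        mu, sigma = -math.log(rate), 1.0 / shape
        with np.errstate(divide="ignore"):
            z = (np.log(np.maximum(t, 1e-300)) - mu) / sigma
        logpdf = stats.norm.logpdf(z) - np.log(sigma * np.maximum(t, 1e-300))
        return np.where(t <= 0, 0.0, np.exp(logpdf - special.log_ndtr(-z)))
    raise ValidationError(f"unknown family {family!r}")


def cumulative_hazard(t, family: str, shape: float, rate: float):
    """Cumulative baseline hazard H0(t) (closed form; vectorized in t)."""
    from .synthetic_data import _cumhaz  # single closed-form source

    return _cumhaz(t, family, shape, rate)


def hazard(t: float, transition: tuple[int, int], params: MultistateParams) -> float:
    """Transition intensity (per year) at model time ``t``.

    Baseline hazard of the documented parametrization times the transition's
    hazard ratio relative to HS1 -> HS2.  Raises for backward transitions and
    negative times; a disabled transition has intensity 0.
    """
    tr = _check_transition(transition)
    if t < 0:
        raise ValidationError("hazard: t must be >= 0")
    hr = params.hazard_ratio(tr)
    if hr == 0.0:
        return 0.0
    return float(baseline_hazard(t, params.family, params.shape, params.rate)) * hr


def generator_matrix(t: float, params: MultistateParams) -> np.ndarray:
    """5x5 transition-intensity (generator) matrix among HS1..HS5 at time t.

    Strictly lower-triangular entries are 0 (no improvement in the long-term
    phase); rows sum to 0.
    """
    h0 = float(baseline_hazard(t, params.family, params.shape, params.rate))
    q = h0 * _structure_matrix(params)
    return q


def _structure_matrix(params: MultistateParams) -> np.ndarray:
    """Constant matrix M with M[i,j] = HR_ij off-diagonal, rows summing to 0,
    so that Q(t) = h0(t) * M."""
    m = np.zeros((5, 5))
    for (i, j) in params.transitions:
        m[i - 1, j - 1] = params.hazard_ratio((i, j))
    np.fill_diagonal(m, -m.sum(axis=1))
    return m


def cycle_transition_matrix(
    t: float,
    params: MultistateParams,
    dt: float = 1.0,
) -> np.ndarray:
    """One-cycle probability matrix: ``expm`` of the generator integrated
    over ``[t, t + dt]``.

    Because every transition intensity is the shared baseline hazard times a
    constant, the integrated generator is the structure matrix scaled by
    ``H0(t + dt) - H0(t)``, available in closed form for all five families —
    so the integral is exact even where the hazard itself is singular at
    t = 0 (shape < 1), where the singularity is integrable.
    """
    if dt <= 0:
        raise ValidationError("cycle_transition_matrix: dt must be > 0")
    if t < 0:
        raise ValidationError("cycle_transition_matrix: t must be >= 0")
    integrated = float(
        cumulative_hazard(t + dt, params.family, params.shape, params.rate)
        - cumulative_hazard(t, params.family, params.shape, params.rate)
    )
    p = expm(_structure_matrix(params) * integrated)
    # clean the tiny negative round-off expm can leave
    p = np.clip(p, 0.0, 1.0)
    p[np.tril_indices(5, k=-1)] = 0.0
    p /= p.sum(axis=1, keepdims=True)
    return p


def derive_hs5_row(hs4_row: np.ndarray) -> np.ndarray:
    """First-year HS5 row imputed from the HS4 row.

    No trial patients starting in the worst state were observed at 12 months,
    so HS5 patients are assumed to move in the same direction and by the same
    number of steps as HS4 patients: each HS4 destination shifts one state
    worse, with mass that would pass beyond HS5 clamped at HS5.
    """
    row = np.asarray(hs4_row, dtype=float)
    if row.shape != (5,):
        raise ValidationError("derive_hs5_row: expected a 5-vector")
    if abs(float(row.sum()) - 1.0) > 1e-9 or np.any(row < 0):
        raise ValidationError("derive_hs5_row: input is not a probability row")
    out = np.zeros(5)
    out[1:] = row[:4]
    out[4] += row[4]
    return out


# ---------------------------------------------------------------------------
# exact-time multistate maximum likelihood
# ---------------------------------------------------------------------------


@dataclass
class MultistateFit:
    """Result of :func:`fit_multistate`."""

    params: MultistateParams
    loglik: float
    n_params: int
    n_events: int
    aic: float
    bic: float
    converged: bool
    message: str


def _prepare_data(histories: list[EventHistory], transitions):
    """Flatten histories into event and at-risk-interval arrays."""
    trans_index = {t: k for k, t in enumerate(transitions)}
    ev_t, ev_k = [], []
    iv_t0, iv_t1 = [], []
    iv_mask = []  # row: indicator over transitions enabled from the interval's state
    from_state = {i: [t for t in transitions if t[0] == i] for i in range(1, 6)}
    for h in histories:
        for state, t0, t1, nxt in h.intervals:
            enabled = from_state.get(state, [])
            if nxt is not None:
                tr = (state, nxt)
                if tr not in trans_index:
                    raise FitError(
                        f"observed transition HS{state}->HS{nxt} is not in the "
                        "fitted transition set"
                    )
                ev_t.append(t1)
                ev_k.append(trans_index[tr])
            if not enabled:
                continue
            row = np.zeros(len(transitions))
            for tr in enabled:
                row[trans_index[tr]] = 1.0
            iv_t0.append(t0)
            iv_t1.append(t1)
            iv_mask.append(row)
    return (
        np.asarray(ev_t),
        np.asarray(ev_k, dtype=int),
        np.asarray(iv_t0),
        np.asarray(iv_t1),
        np.asarray(iv_mask) if iv_mask else np.zeros((0, len(transitions))),
    )


def fit_multistate(
    histories: list[EventHistory],
    family: str = "weibull",
    transitions: tuple[tuple[int, int], ...] | None = None,
) -> MultistateFit:
    """Maximum-likelihood fit of the pooled proportional-hazards multistate
    model to exactly-observed histories.

    The log-likelihood is the sum over observed transitions of
    ``log h0(t_event) + beta_k`` minus, for every at-risk interval in state
    *i*, ``sum_j HR_ij * (H0(t_stop) - H0(t_start))``.  HS1 -> HS2 is the
    reference (beta fixed at 0).  Returns point estimates with the
    log-likelihood and AIC/BIC (n = number of observed transitions) for
    family comparison.

    Raises :class:`FitError` when the reference transition has no events
    (the baseline hazard would be unidentified — reparametrize with a
    different reference) or when the optimiser fails to converge.
    """
    if transitions is None:
        transitions = FORWARD_TRANSITIONS
    transitions = tuple(_check_transition(t) for t in transitions)
    if REFERENCE_TRANSITION not in transitions:
        raise FitError("reference transition HS1->HS2 must be in the fitted set")
    ev_t, ev_k, iv_t0, iv_t1, iv_mask = _prepare_data(list(histories), transitions)
    n_events = len(ev_t)
    ref_idx = transitions.index(REFERENCE_TRANSITION)
    if not np.any(ev_k == ref_idx):
        raise FitError(
            "no events observed for the reference transition HS1->HS2; "
            "refit with a reference transition that has events"
        )
    # drop transitions with no events except the reference: their beta -> -inf
    keep = sorted({ref_idx} | set(ev_k.tolist()))
    fit_transitions = tuple(transitions[k] for k in keep)
    remap = {old: new for new, old in enumerate(keep)}
    ev_k = np.array([remap[k] for k in ev_k], dtype=int)
    iv_mask = iv_mask[:, keep]
    ref_idx = remap[transitions.index(REFERENCE_TRANSITION)]
    n_beta = len(fit_transitions) - 1
    beta_slots = [k for k in range(len(fit_transitions)) if k != ref_idx]

    has_shape = family != "exponential"
    ev_t_safe = np.maximum(ev_t, T_EPSILON)

    def unpack(theta):
        pos = 0
        if has_shape:
            shape = math.exp(theta[pos]); pos += 1
        else:
            shape = 1.0
        rate = math.exp(theta[pos]); pos += 1
        beta = np.zeros(len(fit_transitions))
        beta[beta_slots] = theta[pos:]
        return shape, rate, beta

    def neg_loglik(theta):
        shape, rate, beta = unpack(theta)
        with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
            h0 = baseline_hazard(ev_t_safe, family, shape, rate)
            ll = float(np.sum(np.log(np.maximum(h0, 1e-300)) + beta[ev_k]))
            H = cumulative_hazard(iv_t1, family, shape, rate) - cumulative_hazard(
                iv_t0, family, shape, rate
            )
            hr_sum = iv_mask @ np.exp(beta)
            ll -= float(np.sum(hr_sum * H))
        return np.inf if not np.isfinite(ll) else -ll

    # starting values: exponential rate from reference-state person-time
    state1 = iv_mask[:, ref_idx] > 0
    pt1 = float(np.sum(iv_t1[state1] - iv_t0[state1])) or 1.0
    rate0 = max(np.sum(ev_k == ref_idx) / pt1, 1e-6)
    x0 = ([0.0] if has_shape else []) + [math.log(rate0)] + [0.0] * n_beta
    res = optimize.minimize(neg_loglik, np.asarray(x0), method="L-BFGS-B")
    if not res.success:
        raise FitError(f"optimiser did not converge: {res.message} (nit={res.nit})")
    shape, rate, beta = unpack(res.x)
    log_hr = {t: float(b) for t, b in zip(fit_transitions, beta)}
    params = MultistateParams(
        family=family, shape=shape, rate=rate, log_hr=log_hr, provenance="fitted"
    )
    k = len(res.x)
    ll = -float(res.fun)
    return MultistateFit(
        params=params,
        loglik=ll,
        n_params=k,
        n_events=n_events,
        aic=2 * k - 2 * ll,
        bic=k * math.log(max(n_events, 1)) - 2 * ll,
        converged=bool(res.success),
        message=str(res.message),
    )
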