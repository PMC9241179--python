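"""Cohort trace construction over the 85-year horizon.

Each strategy's trace is built cycle by cycle: in cycle 1 the trial-informed
first-year matrix applies (with the HS5 row imputed from the HS4 row); for
the gene-therapy arm the cohort then holds its state until the treatment
effect ends (base case: through year 40), after which — and from cycle 2 for
standard of care — the parametric long-term matrices take over.  Background
mortality from the lifetable is applied after the vision transition within
each cycle, identically across health states (the model carries excess costs
of impairment, not excess mortality).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import progression
from .model_config import ConfigError, ModelConfig, ValidationError

__all__ = ["Trace", "vision_matrix_for_cycle", "run_trace"]

_COLUMNS = ["HS1", "HS2", "HS3", "HS4", "HS5", "DEAD"]


@dataclass
class Trace:
    """Occupancy of the six states at the end of each cycle.

    Row 0 is the baseline distribution (DEAD = 0); row c the distribution at
    the end of cycle c.  ``ages[c]`` is the cohort mean age at the end of
    cycle c (start_age + c).
    """

    strategy: str
    occupancy: np.ndarray  # (horizon + 1, 6)
    ages: np.ndarray       # (horizon + 1,)

    def __post_init__(self) -> None:
        occ = np.asarray(self.occupancy, dtype=float)
        if occ.ndim != 2 or occ.shape[1] != 6:
            raise ValidationError("trace: occupancy must be (cycles+1, 6)")
        if np.any(occ < -1e-12):
            raise ValidationError("trace: negative occupancy")
        if np.any(np.abs(occ.sum(axis=1) - 1.0) > 1e-9):
            raise ValidationError("trace: rows must sum to 1")
        if np.any(np.diff(occ[:, 5]) < -1e-12):
            raise ValidationError("trace: DEAD column must be non-decreasing")
        self.occupancy = occ

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0] - 1

    @property
    def alive(self) -> np.ndarray:
        """Occupancy over HS1..HS5 only, shape (cycles + 1, 5)."""
        return self.occupancy[:, :5]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.occupancy, columns=_COLUMNS)
        df.insert(0, "age", self.ages)
        df.insert(0, "cycle", np.arange(self.occupancy.shape[0]))
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _effect_end_cycle(effect_duration: float) -> int:
    """Last cycle covered by the treatment effect (whole cycles, ceil)."""
    return int(math.ceil(effect_duration))


def _longterm_window(strategy: str, cycle: int, config: ModelConfig) -> float:
    """Start time (years) at which the long-term generator is integrated for
    this cycle, under the configured progression clock."""
    settings = config.settings
    if settings.progression_clock == "model_time":
        return float(cycle - 1)
    # time_since_effect_end: hazard clock restarts when structured decline
    # begins — after year 1 for SoC, after the effect window for VN
    origin = 1 if strategy == "SoC" else _effect_end_cycle(settings.effect_duration)
    return float(cycle - 1 - origin)


def vision_matrix_for_cycle(
    strategy: str,
    cycle: int,
    config: ModelConfig,
    cache: dict | None = None,
) -> np.ndarray:
    """5x5 vision transition matrix applied during ``cycle`` (1-based).

    Cycle 1 uses the strategy's first-year matrix with the HS5 row handled
    per ``settings.hs5_row_rule``; the gene-therapy arm then holds state
    (identity) through the effect window; afterwards — and from cycle 2 for
    standard of care — the long-term matrix for the cycle's time window is
    used.  ``cache`` (optional dict) memoizes long-term matrices by window
    start so the two arms share work under the common model-time clock.
    """
    settings = config.settings
    if cycle < 1 or cycle > settings.horizon:
        raise ValidationError(
            f"cycle {cycle} outside 1..{settings.horizon}"
        )
    if strategy not in config.initial_matrices:
        raise ConfigError(f"unknown strategy {strategy!r}")
    if cycle == 1:
        m = config.initial_matrices[strategy].matrix.copy()
        rule = settings.hs5_row_rule
        if rule == "shift_from_hs4":
            m[4] = progression.derive_hs5_row(m[3])
        elif rule == "stay":
            m[4] = np.eye(5)[4]
        return m
    if strategy == "VN" and cycle <= _effect_end_cycle(settings.effect_duration):
        return np.eye(5)
    t0 = _longterm_window(strategy, cycle, config)
    key = round(t0, 9)
    if cache is not None and key in cache:
        return cache[key]
    m = progression.cycle_transition_matrix(t0, config.multistate, dt=1.0)
    if cache is not None:
        cache[key] = m
    return m


def run_trace(
    strategy: str,
    config: ModelConfig,
    cache: dict | None = None,
) -> Trace:
    """Build the full cohort trace for one strategy.

    For each cycle the alive occupancy is advanced by the cycle's vision
    matrix, then thinned by the lifetable probability ``q(age)`` with the
    released mass moved to DEAD; the lookup age is
    ``floor(start_age + cycle - 1)`` (integer-aged lifetable, age at the
    start of the cycle).
    """
    settings = config.settings
    horizon = settings.horizon
    occ = np.zeros((horizon + 1, 6))
    occ[0, :5] = config.cohort.occupancy
    ages = config.cohort.start_age + np.arange(horizon + 1)
    if cache is None:
        cache = {}
    for cycle in range(1, horizon + 1):
        p = vision_matrix_for_cycle(strategy, cycle, config, cache=cache)
        alive = occ[cycle - 1, :5] @ p
        total_before = occ[cycle - 1].sum()
        q = config.lifetable.q(int(math.floor(config.cohort.start_age + cycle - 1)))
        occ[cycle, :5] = alive * (1.0 - q)
        occ[cycle, 5] = occ[cycle - 1, 5] + alive.sum() * q
        if abs(occ[cycle].sum() - total_before) > 1e-12:
            raise ValidationError(f"mass not conserved at cycle {cycle}")
    return Trace(strategy=strategy, occupancy=occ, ages=ages)
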