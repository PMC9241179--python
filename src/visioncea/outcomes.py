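"""Accrual of QALYs, life years, blindness-free years and costs from a trace.

Outcomes are valued on end-of-cycle occupancy (no half-cycle correction by
default; a settings switch averages adjacent rows instead).  The first model
year is undiscounted; cycle c carries the factor ``1/(1+r)^(c-1)``.  One-off
treatment-related quantities (acquisition bundle, eligibility testing,
adverse-event costs and the one-off adverse-event QALY loss) are attributed
to cycle 1 of the gene-therapy arm, undiscounted — all modelled adverse
events are peri-treatment.

Cost components, per cycle and perspective:

* healthcare — excess hospitalisations (HS2-5, 65+), technical assistance
  (all states, age-banded multipliers), community and residential care
  (HS2-5, 65+);
* societal add-ons — excess education (HS2-5, <18), productivity loss
  (HS2-5, 18-64, at the configured loss fraction of the average salary) and
  informal caregiver time (65+, 25% of hours counted).

Age bands follow the cohort mean age for the cycle (single-cohort model), so
the 65+ items switch on when the mean age crosses 65.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model_config import (
    AdverseEventSpec,
    ConfigError,
    CostInputs,
    ModelConfig,
    ModelSettings,
    UtilitySet,
    ValidationError,
)
from .markov_engine import Trace

__all__ = [
    "discount_factor",
    "discount_factors",
    "ae_qaly_loss",
    "qaly_total",
    "life_years",
    "blindness_free_years",
    "treatment_and_testing_costs",
    "cycle_resource_costs",
    "StrategyResult",
    "evaluate_strategy",
]

ONE_OFF_COMPONENTS = ("treatment", "eligibility", "adverse_events")
HEALTHCARE_COMPONENTS = (
    "hospitalisation",
    "technical_assistance",
    "community_care",
    "residential_care",
)
SOCIETAL_COMPONENTS = ("education", "productivity", "caregiver")
ALL_COMPONENTS = ONE_OFF_COMPONENTS + HEALTHCARE_COMPONENTS + SOCIETAL_COMPONENTS


def discount_factor(cycle: int, rate: float) -> float:
    """Discount factor for cycle ``cycle`` (1-based); cycle 1 is undiscounted."""
    if cycle < 1:
        raise ValidationError("discount_factor: cycle must be >= 1")
    if rate < 0:
        raise ValidationError("discount_factor: rate must be >= 0")
    return 1.0 / (1.0 + rate) ** (cycle - 1)


def discount_factors(horizon: int, rate: float) -> np.ndarray:
    """Vector of factors for cycles 1..horizon."""
    return 1.0 / (1.0 + rate) ** np.arange(horizon)


def ae_qaly_loss(events: list[AdverseEventSpec]) -> float:
    """One-off QALY loss from peri-treatment adverse events:
    sum of probability x decrement x duration in years."""
    return float(
        sum(e.probability * e.decrement * e.duration_months / 12.0 for e in events)
    )


def _cycle_occupancy(trace: Trace, settings: ModelSettings) -> np.ndarray:
    """(horizon, 6) occupancy credited to cycles 1..horizon."""
    occ = trace.occupancy
    if settings.half_cycle_correction:
        return 0.5 * (occ[:-1] + occ[1:])
    return occ[1:]


def qaly_total(
    trace: Trace,
    utilities: UtilitySet,
    ae_loss: float,
    settings: ModelSettings,
) -> tuple[float, float]:
    """(discounted, undiscounted) QALYs; ``ae_loss`` is subtracted once,
    undiscounted (cycle-1 attribution). DEAD contributes nothing."""
    if utilities.values.shape != (5,):
        raise ConfigError("utilities must cover HS1..HS5")
    occ = _cycle_occupancy(trace, settings)
    per_cycle = occ[:, :5] @ utilities.values
    df = discount_factors(trace.n_cycles, settings.discount_rate)
    return float(per_cycle @ df - ae_loss), float(per_cycle.sum() - ae_loss)


def life_years(trace: Trace, settings: ModelSettings) -> tuple[float, float]:
    """(discounted, undiscounted) years alive (HS1..HS5)."""
    alive = _cycle_occupancy(trace, settings)[:, :5].sum(axis=1)
    df = discount_factors(trace.n_cycles, settings.discount_rate)
    return float(alive @ df), float(alive.sum())


def blindness_free_years(trace: Trace, settings: ModelSettings) -> tuple[float, float]:
    """(discounted, undiscounted) years outside the blindness state HS5."""
    free = _cycle_occupancy(trace, settings)[:, :4].sum(axis=1)
    df = discount_factors(trace.n_cycles, settings.discount_rate)
    return float(free @ df), float(free.sum())


def treatment_and_testing_costs(
    strategy: str,
    costs: CostInputs,
    events: list[AdverseEventSpec],
) -> dict[str, float]:
    """One-off cycle-1 cost components (CHF): treatment bundle, eligibility
    testing scaled up by the eligible fraction, and expected adverse-event
    treatment costs. All zero for the standard-of-care arm."""
    if strategy != "VN":
        return {k: 0.0 for k in ONE_OFF_COMPONENTS}
    if costs.eligible_fraction <= 0:
        raise ConfigError("costs.eligible_fraction must be > 0")
    treatment = (
        costs.vn_acquisition
        + costs.n_administrations * costs.surgery_per_administration
        + costs.prednisone_regimen
        + costs.n_control_visits * costs.control_visit_cost
    )
    eligibility = costs.eligibility_test_cost / costs.eligible_fraction
    ae = sum(e.probability * e.cost for e in events)
    return {
        "treatment": float(treatment),
        "eligibility": float(eligibility),
        "adverse_events": float(ae),
    }


def cycle_resource_costs(
    occupancy: np.ndarray,
    age: float,
    costs: CostInputs,
    settings: ModelSettings,
) -> dict[str, float]:
    """Undiscounted visual-impairment cost components for one cycle.

    ``occupancy`` is the 6-vector (or 5-vector) of state occupancy credited
    to the cycle; ``age`` the cohort mean age during the cycle.  Societal
    components are zero unless ``settings.perspective == "societal"``.
    """
    occ = np.asarray(occupancy, dtype=float)
    hs1 = float(occ[0])
    hs2 = float(occ[1])
    hs25 = float(occ[1:5].sum())
    hs35 = float(occ[2:5].sum())
    senior = age >= 65
    child = age < 18
    out = dict.fromkeys(HEALTHCARE_COMPONENTS + SOCIETAL_COMPONENTS, 0.0)
    if senior:
        out["hospitalisation"] = (
            hs25 * costs.excess_hospitalisations_per_year * costs.hospitalisation_cost
        )
        out["community_care"] = (
            costs.community_care_fraction * hs25 * costs.community_care_annual
        )
        out["residential_care"] = (
            costs.residential_care_fraction * hs25 * costs.residential_care_annual
        )
    mult = (
        costs.technical_multiplier_hs25_senior
        if senior
        else costs.technical_multiplier_hs25_adult
    )
    out["technical_assistance"] = costs.technical_assistance_annual * (
        costs.technical_multiplier_hs1 * hs1 + mult * hs25
    )
    if settings.perspective == "societal":
        if child:
            out["education"] = hs25 * costs.education_annual
        elif not senior:
            out["productivity"] = (
                hs25 * settings.productivity_loss_fraction * costs.salary_annual
            )
        else:
            out["caregiver"] = (
                costs.caregiver_hourly_cost
                * costs.caregiver_counted_fraction
                * (
                    costs.caregiver_hours_hs1 * hs1
                    + costs.caregiver_hours_hs2 * hs2
                    + costs.caregiver_hours_hs35 * hs35
                )
            )
    return out


@dataclass
class StrategyResult:
    """Discounted and undiscounted totals for one strategy."""

    strategy: str
    perspective: str
    qalys: float
    qalys_undiscounted: float
    life_years: float
    life_years_undiscounted: float
    blindness_free_years: float
    blindness_free_years_undiscounted: float
    components: dict[str, float] = field(default_factory=dict)
    components_undiscounted: dict[str, float] = field(default_factory=dict)

    def _total(self, comps: dict[str, float]) -> float:
        keys = ONE_OFF_COMPONENTS + HEALTHCARE_COMPONENTS
        if self.perspective == "societal":
            keys = keys + SOCIETAL_COMPONENTS
        return float(sum(comps[k] for k in keys))

    @property
    def resource_use(self) -> float:
        """Discounted healthcare resource-use total (Table-style line)."""
        return float(sum(self.components[k] for k in HEALTHCARE_COMPONENTS))

    @property
    def total_cost(self) -> float:
        return self._total(self.components)

    @property
    def total_cost_undiscounted(self) -> float:
        return self._total(self.components_undiscounted)

    @property
    def total_healthcare_cost(self) -> float:
        return float(
            sum(self.components[k] for k in ONE_OFF_COMPONENTS + HEALTHCARE_COMPONENTS)
        )

    def ledger_frame(self) -> pd.DataFrame:
        rows = [
            (k, self.components_undiscounted[k], self.components[k])
            for k in ALL_COMPONENTS
        ]
        return pd.DataFrame(rows, columns=["component", "undiscounted", "discounted"])


def evaluate_strategy(
    trace: Trace,
    config: ModelConfig,
    utilities: UtilitySet | None = None,
) -> StrategyResult:
    """Accrue all outcomes for one strategy's trace under the configuration."""
    settings = config.settings
    utilities = utilities if utilities is not None else config.utilities
    loss = ae_qaly_loss(config.adverse_events) if trace.strategy == "VN" else 0.0
    q_d, q_u = qaly_total(trace, utilities, loss, settings)
    ly_d, ly_u = life_years(trace, settings)
    bfy_d, bfy_u = blindness_free_years(trace, settings)

    comps_d = dict.fromkeys(ALL_COMPONENTS, 0.0)
    comps_u = dict.fromkeys(ALL_COMPONENTS, 0.0)
    one_off = treatment_and_testing_costs(
        trace.strategy, config.costs, config.adverse_events
    )
    for k, v in one_off.items():  # cycle 1, factor 1: same either way
        comps_d[k] = v
        comps_u[k] = v
    occ = _cycle_occupancy(trace, settings)
    df = discount_factors(trace.n_cycles, settings.discount_rate)
    for cycle in range(1, trace.n_cycles + 1):
        age = config.cohort.start_age + cycle - 1
        cyc = cycle_resource_costs(occ[cycle - 1], age, config.costs, settings)
        for k, v in cyc.items():
            comps_u[k] += v
            comps_d[k] += v * df[cycle - 1]
    return StrategyResult(
        strategy=trace.strategy,
        perspective=settings.perspective,
        qalys=q_d,
        qalys_undiscounted=q_u,
        life_years=ly_d,
        life_years_undiscounted=ly_u,
        blindness_free_years=bfy_d,
        blindness_free_years_undiscounted=bfy_u,
        components=comps_d,
        components_undiscounted=comps_u,
    )
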