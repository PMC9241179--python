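"""One-way (tornado) and probabilistic sensitivity analysis.

Uncertain inputs are addressed by dotted path names, e.g.
``"utilities.HS2"``, ``"costs.technical_assistance_annual"``,
``"ae.cataract.probability"`` or ``"multistate.log_hr.HS2->HS3"``.  The
one-way analysis reruns the full deterministic model at each parameter's low
and high value (default ±20% when no confidence interval is supplied) with
everything else at base, and ranks parameters by the spread they induce in
the cost-per-QALY ratio.  The gene-therapy acquisition price is treated as
fixed, and the first-year transition matrices are not varied, in either
analysis.

The probabilistic analysis redraws every uncertain parameter per iteration:
Normal for the long-term regression parameters, Beta (method of moments)
for probabilities and absolute utilities, Gamma (method of moments) for
utility decrements, resource use and costs.  No published standard errors
exist, so the default dispersion is SE = 20% of the mean, overridable per
parameter.  Utility sets containing negative values (HUI3) are shifted onto
[0, 1] for Beta drawing and shifted back.  Draws are reproducible given the
seed and iteration index.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import cea
from .model_config import ModelConfig, ValidationError

__all__ = [
    "get_param",
    "set_param",
    "list_parameters",
    "ParamRange",
    "TornadoEntry",
    "default_tornado_specs",
    "tornado",
    "UncertainParam",
    "psa_parameters",
    "PSASample",
    "draw_psa_sample",
    "PSAResult",
    "run_psa",
    "ceac",
    "tornado_plot",
    "ceac_plot",
]

_UTILITY_SHIFT = 0.05  # HUI3 support is [-0.05, 1]


# ---------------------------------------------------------------------------
# dotted-path parameter access
# ---------------------------------------------------------------------------


def _ae_by_name(config: ModelConfig, name: str):
    for ae in config.adverse_events:
        if ae.name == name:
            return ae
    raise KeyError(name)


def list_parameters(config: ModelConfig) -> list[str]:
    """All addressable scalar parameter paths for this configuration."""
    import dataclasses

    names = [f"utilities.HS{k}" for k in range(1, 6)]
    for ae in config.adverse_events:
        names += [f"ae.{ae.name}.{f}" for f in
                  ("decrement", "duration_months", "probability", "cost")]
    names += [
        f"costs.{f.name}"
        for f in dataclasses.fields(config.costs)
        if f.name not in ("n_administrations", "n_control_visits")
    ]
    names += ["multistate.shape", "multistate.rate"]
    names += [
        f"multistate.log_hr.HS{i}->HS{j}"
        for (i, j) in config.multistate.transitions
        if (i, j) != (1, 2)
    ]
    names += ["cohort.start_age", "settings.productivity_loss_fraction"]
    return names


def get_param(config: ModelConfig, name: str) -> float:
    parts = name.split(".")
    try:
        if parts[0] == "utilities":
            return float(config.utilities.values[int(parts[1][2:]) - 1])
        if parts[0] == "ae":
            return float(getattr(_ae_by_name(config, parts[1]), parts[2]))
        if parts[0] == "costs":
            return float(getattr(config.costs, parts[1]))
        if parts[0] == "multistate":
            if parts[1] == "log_hr":
                i, j = parts[2].split("->")
                return float(config.multistate.log_hr[(int(i[2:]), int(j[2:]))])
            return float(getattr(config.multistate, parts[1]))
        if parts[0] == "cohort":
            return float(getattr(config.cohort, parts[1]))
        if parts[0] == "settings":
            return float(getattr(config.settings, parts[1]))
    except (AttributeError, KeyError, IndexError, ValueError):
        pass
    raise ValidationError(
        f"unknown parameter {name!r}; valid names: {', '.join(list_parameters(config))}"
    )


def set_param(config: ModelConfig, name: str, value: float) -> None:
    """Set a scalar parameter in place (no structural re-validation: one-way
    and probabilistic draws may legitimately break e.g. the packaged
    utilities' monotonicity)."""
    get_param(config, name)  # raises a helpful error for unknown names
    parts = name.split(".")
    if parts[0] == "utilities":
        config.utilities.values[int(parts[1][2:]) - 1] = value
    elif parts[0] == "ae":
        setattr(_ae_by_name(config, parts[1]), parts[2], value)
    elif parts[0] == "costs":
        setattr(config.costs, parts[1], value)
    elif parts[0] == "multistate":
        if parts[1] == "log_hr":
            i, j = parts[2].split("->")
            config.multistate.log_hr[(int(i[2:]), int(j[2:]))] = value
        else:
            setattr(config.multistate, parts[1], value)
    elif parts[0] == "cohort":
        setattr(config.cohort, parts[1], value)
    elif parts[0] == "settings":
        setattr(config.settings, parts[1], value)


# ---------------------------------------------------------------------------
# one-way (tornado) analysis
# ---------------------------------------------------------------------------


@dataclass
class ParamRange:
    """Low/high values for one parameter of the one-way analysis."""

    name: str
    low: float
    high: float


@dataclass
class TornadoEntry:
    name: str
    low: float
    high: float
    icer_low: float
    icer_high: float

    @property
    def width(self) -> float:
        return abs(self.icer_high - self.icer_low)


#: parameter groups varied in the one-way analysis (acquisition price fixed;
#: first-year matrices not covered)
_TORNADO_EXCLUDE = {"costs.vn_acquisition", "cohort.start_age"}


def default_tornado_specs(config: ModelConfig, spread: float = 0.2) -> list[ParamRange]:
    """±``spread`` ranges for every varied parameter (no CIs are published).

    Utilities are capped at 1 on the high side; log hazard ratios are varied
    by scaling the hazard ratio itself by (1∓spread).
    """
    specs = []
    for name in list_parameters(config):
        if name in _TORNADO_EXCLUDE or name == "settings.productivity_loss_fraction":
            continue
        base = get_param(config, name)
        if name.startswith("multistate.log_hr."):
            low = base + math.log1p(-spread)
            high = base + math.log1p(spread)
        else:
            low, high = base * (1 - spread), base * (1 + spread)
            if name.startswith("utilities.") or name.endswith(
                ("probability", "eligible_fraction")
            ):
                high = min(high, 1.0)
        specs.append(ParamRange(name, low, high))
    return specs


def _icer_value(config: ModelConfig) -> float:
    """Cost-per-QALY ratio for ranking purposes (raw ΔC/ΔE, sign kept)."""
    r = cea.run_comparison(config)
    if r.incremental_qalys == 0:
        return math.inf if r.incremental_cost > 0 else 0.0
    return r.incremental_cost / r.incremental_qalys


def tornado(
    config: ModelConfig, param_specs: list[ParamRange] | None = None
) -> list[TornadoEntry]:
    """One-way sensitivity analysis; entries sorted by bar width, descending."""
    if param_specs is None:
        param_specs = default_tornado_specs(config)
    entries = []
    for spec in param_specs:
        values = []
        for v in (spec.low, spec.high):
            cfg = config.copy()
            set_param(cfg, spec.name, v)
            values.append(_icer_value(cfg))
        entries.append(
            TornadoEntry(spec.name, spec.low, spec.high, values[0], values[1])
        )
    entries.sort(key=lambda e: e.width, reverse=True)
    return entries


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis
# ---------------------------------------------------------------------------


@dataclass
class UncertainParam:
    name: str
    mean: float
    se: float
    dist: str            # normal | beta | gamma
    shift: float = 0.0   # beta support is [-shift, 1]


def psa_parameters(
    config: ModelConfig,
    se_fraction: float = 0.2,
    se_overrides: dict[str, float] | None = None,
) -> list[UncertainParam]:
    """Uncertain-parameter list with distribution assignments.

    Long-term regression parameters (shape, rate, log hazard ratios) are
    Normal; probabilities (adverse-event rates, eligibility and care
    fractions) and absolute utilities are Beta; utility decrements, resource
    use quantities and unit costs are Gamma.  The acquisition price and the
    first-year transition matrices are fixed.
    """
    se_overrides = se_overrides or {}
    shift = _UTILITY_SHIFT if float(config.utilities.values.min()) <= 0 else 0.0
    beta_cost_fields = {
        "eligible_fraction",
        "community_care_fraction",
        "residential_care_fraction",
        "caregiver_counted_fraction",
    }
    out: list[UncertainParam] = []

    def add(name: str, dist: str, p_shift: float = 0.0) -> None:
        mean = get_param(config, name)
        se = se_overrides.get(name, se_fraction * abs(mean))
        out.append(UncertainParam(name, mean, se, dist, p_shift))

    add("multistate.shape", "normal")
    add("multistate.rate", "normal")
    for (i, j) in config.multistate.transitions:
        if (i, j) != (1, 2):
            add(f"multistate.log_hr.HS{i}->HS{j}", "normal")
    for k in range(1, 6):
        add(f"utilities.HS{k}", "beta", shift)
    for ae in config.adverse_events:
        add(f"ae.{ae.name}.probability", "beta")
        add(f"ae.{ae.name}.decrement", "gamma")
        add(f"ae.{ae.name}.duration_months", "gamma")
        add(f"ae.{ae.name}.cost", "gamma")
    import dataclasses

    for f in dataclasses.fields(config.costs):
        if f.name in ("vn_acquisition", "n_administrations", "n_control_visits"):
            continue
        add(f"costs.{f.name}", "beta" if f.name in beta_cost_fields else "gamma")
    return out


def _draw(rng: np.random.Generator, p: UncertainParam) -> float:
    if p.se == 0.0:
        return p.mean
    if p.dist == "normal":
        return float(rng.normal(p.mean, p.se))
    if p.dist == "gamma":
        if p.mean <= 0:
            return p.mean
        shape = (p.mean / p.se) ** 2
        scale = p.se ** 2 / p.mean
        return float(rng.gamma(shape, scale))
    if p.dist == "beta":
        scale = 1.0 + p.shift
        m = (p.mean + p.shift) / scale
        v = (p.se / scale) ** 2
        if m <= 0.0 or m >= 1.0:
            return p.mean
        if v >= m * (1 - m):
            raise ValidationError(
                f"{p.name}: SE {p.se} too large for Beta moment matching "
                f"at mean {p.mean}"
            )
        nu = m * (1 - m) / v - 1.0
        return float(rng.beta(m * nu, (1 - m) * nu) * scale - p.shift)
    raise ValidationError(f"{p.name}: unknown distribution {p.dist!r}")


@dataclass
class PSASample:
    iteration: int
    values: dict[str, float]
    delta_cost: float | None = None
    delta_qalys: float | None = None
    valid: bool = True


def draw_psa_sample(
    config: ModelConfig,
    seed: int,
    iteration: int,
    se_fraction: float = 0.2,
    parameters: list[UncertainParam] | None = None,
) -> PSASample:
    """Draw one reproducible parameter vector (stream keyed by seed and
    iteration; parameter order is fixed)."""
    if parameters is None:
        parameters = psa_parameters(config, se_fraction=se_fraction)
    rng = np.random.default_rng([int(seed), int(iteration)])
    values = {}
    for p in parameters:
        v = _draw(rng, p)
        if p.name in ("multistate.shape", "multistate.rate"):
            v = max(v, 1e-6)  # Normal draws clipped to the positive domain
        values[p.name] = v
    return PSASample(iteration=iteration, values=values)


def _apply_sample(config: ModelConfig, sample: PSASample) -> ModelConfig:
    cfg = config.copy()
    for name, value in sample.values.items():
        set_param(cfg, name, value)
    return cfg


@dataclass
class PSAResult:
    samples: list[PSASample] = field(default_factory=list)
    n_failed: int = 0
    threshold: float = 100_000.0

    @property
    def deltas(self) -> tuple[np.ndarray, np.ndarray]:
        ok = [s for s in self.samples if s.valid]
        return (
            np.array([s.delta_cost for s in ok]),
            np.array([s.delta_qalys for s in ok]),
        )

    def probability_cost_effective(self, threshold: float | None = None) -> float:
        lam = self.threshold if threshold is None else threshold
        dc, de = self.deltas
        return float(np.mean(lam * de - dc > 0))

    def summary(self) -> dict:
        dc, de = self.deltas
        return {
            "n": len(dc),
            "n_failed": self.n_failed,
            "mean_incremental_cost": float(dc.mean()),
            "mean_incremental_qalys": float(de.mean()),
            "probability_cost_effective": self.probability_cost_effective(),
            "threshold": self.threshold,
        }

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"iteration": s.iteration, "delta_cost": s.delta_cost,
             "delta_qalys": s.delta_qalys, **s.values}
            for s in self.samples
            if s.valid
        ]
        return pd.DataFrame(rows)


def run_psa(
    config: ModelConfig,
    n_iterations: int,
    seed: int,
    se_fraction: float = 0.2,
    se_overrides: dict[str, float] | None = None,
    threshold: float | None = None,
) -> PSAResult:
    """Monte-Carlo propagation of parameter uncertainty.

    Each iteration redraws the uncertain parameters, reruns both arms and
    records the incremental cost and QALYs.  Iterations whose drawn vector
    yields an invalid model (e.g. a Normal draw breaking a structural
    constraint) are flagged, excluded and counted.
    """
    if n_iterations < 1:
        raise ValidationError("run_psa: n_iterations must be >= 1")
    parameters = psa_parameters(config, se_fraction, se_overrides)
    result = PSAResult(
        threshold=config.settings.wtp_threshold if threshold is None else threshold
    )
    for it in range(n_iterations):
        sample = draw_psa_sample(config, seed, it, parameters=parameters)
        try:
            cfg = _apply_sample(config, sample)
            r = cea.run_comparison(cfg)
            sample.delta_cost = r.incremental_cost
            sample.delta_qalys = r.incremental_qalys
        except (ValidationError, ValueError, FloatingPointError):
            sample.valid = False
            result.n_failed += 1
        result.samples.append(sample)
    return result


def ceac(
    samples: list[PSASample], thresholds: np.ndarray
) -> np.ndarray:
    """Cost-effectiveness acceptability curve.

    For each willingness-to-pay λ, the fraction of samples with positive net
    monetary benefit λ·ΔE − ΔC.  Monotone non-decreasing in λ whenever every
    sample has ΔE > 0.
    """
    thresholds = np.asarray(thresholds, dtype=float)
    if thresholds.size == 0:
        raise ValidationError("ceac: empty threshold grid")
    ok = [s for s in samples if s.valid]
    if not ok:
        raise ValidationError("ceac: no valid samples")
    dc = np.array([s.delta_cost for s in ok])
    de = np.array([s.delta_qalys for s in ok])
    return np.array([float(np.mean(lam * de - dc > 0)) for lam in thresholds])


# ---------------------------------------------------------------------------
# plotting helpers
# ---------------------------------------------------------------------------


def tornado_plot(entries: list[TornadoEntry], top: int = 10, ax=None):
    """Horizontal bar chart of the most influential one-way parameters."""
    import matplotlib.pyplot as plt

    entries = entries[:top][::-1]
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 0.5 * len(entries) + 1.5))
    base = [0.5 * (e.icer_low + e.icer_high) for e in entries]
    for k, e in enumerate(entries):
        ax.barh(k, e.icer_high - e.icer_low, left=e.icer_low, color="#4878a8")
    ax.set_yticks(range(len(entries)))
    ax.set_yticklabels([e.name for e in entries])
    ax.set_xlabel("cost per QALY (CHF)")
    del base
    return ax


def ceac_plot(thresholds, fractions, ax=None):
    """Acceptability-curve plot."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(thresholds, fractions, marker=".")
    ax.set_xlabel("willingness to pay (CHF per QALY)")
    ax.set_ylabel("probability cost-effective")
    ax.set_ylim(-0.02, 1.02)
    return ax
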