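"""Named scenario catalogue and runner.

Scenarios apply declared overrides to a base configuration and return the
full strategy comparison: societal perspective at 80% or 50% productivity
loss, alternative treatment-effect durations (7.5 / 20 years / lifetime),
alternative long-term hazard families, HUI3 utilities, alternative health
state assignment rules (user-supplied first-year matrices required),
discount rates 0%..5%, and the assumption that first-year HS5 patients stay
put instead of mirroring the HS4 movement.

The family scenarios require parameters refit under the alternative family.
Published per-family estimates are not available, so unless the
configuration supplies them (``multistate_alternatives``), they are
calibrated synthetically: histories are simulated from the base parameters
(fixed seed) and the requested family is fitted to them — labelled
``provenance="synthetic"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import cea, progression, synthetic_data
from .model_config import ConfigError, InitialTransitionMatrix, ModelConfig

__all__ = ["ScenarioSpec", "CATALOGUE", "run_scenario", "run_all"]

_CALIBRATION_N = 1500
_CALIBRATION_SEED = 20_220_628
_CALIBRATION_FOLLOW_UP = 60.0


@dataclass
class ScenarioSpec:
    """Declared overrides of one scenario relative to the base case."""

    name: str
    settings: dict[str, object] = field(default_factory=dict)
    utilities: str | None = None       # label into config.utility_alternatives
    family: str | None = None          # alternative long-term hazard family
    requires_matrices: str | None = None  # vf_only | best_eye

    def describe(self) -> str:
        bits = [f"{k}={v}" for k, v in self.settings.items()]
        if self.utilities:
            bits.append(f"utilities={self.utilities}")
        if self.family:
            bits.append(f"family={self.family}")
        if self.requires_matrices:
            bits.append("requires user-supplied first-year matrices")
        return ", ".join(bits) or "base case"


def _catalogue() -> dict[str, ScenarioSpec]:
    specs = [
        ScenarioSpec("base"),
        ScenarioSpec(
            "societal_80",
            settings={"perspective": "societal", "productivity_loss_fraction": 0.80},
        ),
        ScenarioSpec(
            "societal_50",
            settings={"perspective": "societal", "productivity_loss_fraction": 0.50},
        ),
        ScenarioSpec("duration_7.5", settings={"effect_duration": 7.5}),
        ScenarioSpec("duration_20", settings={"effect_duration": 20.0}),
        ScenarioSpec("duration_lifetime", settings={"effect_duration": 85.0}),
        ScenarioSpec("family_gompertz", family="gompertz"),
        ScenarioSpec("family_loglogistic", family="loglogistic"),
        ScenarioSpec("family_lognormal", family="lognormal"),
        ScenarioSpec("family_exponential", family="exponential"),
        ScenarioSpec("utilities_hui3", utilities="HUI3"),
        ScenarioSpec("vf_only", requires_matrices="vf_only"),
        ScenarioSpec("best_eye", requires_matrices="best_eye"),
        ScenarioSpec("hs5_stay", settings={"hs5_row_rule": "stay"}),
    ]
    for pct in range(6):
        specs.append(
            ScenarioSpec(f"discount_{pct}", settings={"discount_rate": pct / 100})
        )
    return {s.name: s for s in specs}


CATALOGUE: dict[str, ScenarioSpec] = _catalogue()


def _family_params(config: ModelConfig, family: str):
    """Long-term parameters under an alternative family: user-supplied if
    present, else synthetically calibrated against the base parameters."""
    if family in config.multistate_alternatives:
        return config.multistate_alternatives[family]
    histories = synthetic_data.simulate_histories(
        config.multistate,
        n=_CALIBRATION_N,
        max_follow_up=_CALIBRATION_FOLLOW_UP,
        seed=_CALIBRATION_SEED,
    )
    fit = progression.fit_multistate(histories, family=family)
    fit.params.provenance = "synthetic"
    return fit.params


def run_scenario(
    name: str,
    config: ModelConfig,
    user_matrices: dict[str, InitialTransitionMatrix] | None = None,
) -> cea.CEAResult:
    """Run one named scenario and return the strategy comparison.

    ``vf_only`` and ``best_eye`` redefine health-state assignment and need
    first-year matrices that are not publicly tabulated: they must be
    supplied through ``user_matrices`` ({"VN": ..., "SoC": ...}) or the run
    errors out.
    """
    if name not in CATALOGUE:
        raise ConfigError(
            f"unknown scenario {name!r}; catalogue: {', '.join(sorted(CATALOGUE))}"
        )
    spec = CATALOGUE[name]
    cfg = config.copy()
    for key, value in spec.settings.items():
        if not hasattr(cfg.settings, key):
            raise ConfigError(f"scenario {name}: unknown settings key {key!r}")
        setattr(cfg.settings, key, value)
    if spec.settings.get("effect_duration") == 85.0:
        cfg.settings.effect_duration = float(cfg.settings.horizon)  # lifetime
    utilities = None
    if spec.utilities is not None:
        if spec.utilities not in cfg.utility_alternatives:
            raise ConfigError(
                f"scenario {name}: utility set {spec.utilities!r} not configured"
            )
        utilities = cfg.utility_alternatives[spec.utilities]
    if spec.family is not None:
        cfg.multistate = _family_params(config, spec.family)
    if spec.requires_matrices is not None:
        if not user_matrices:
            raise ConfigError(
                f"scenario {name}: unprinted input required — supply first-year "
                "matrices for the alternative health-state assignment"
            )
        cfg.initial_matrices = dict(user_matrices)
    return cea.run_comparison(cfg, utilities=utilities)


def run_all(
    config: ModelConfig,
    names: list[str] | None = None,
) -> pd.DataFrame:
    """Run the catalogue (minus scenarios needing unprinted inputs) and
    tabulate results in results-table column order."""
    if names is None:
        names = [
            n for n, s in CATALOGUE.items() if s.requires_matrices is None
        ]
    results = {}
    for name in names:
        results[name] = run_scenario(name, config)
    return cea.results_frame(results)


def effective_duration(name: str) -> float | None:
    """Treatment-effect duration implied by a duration scenario, else None."""
    spec = CATALOGUE.get(name)
    if spec is None:
        return None
    val = spec.settings.get("effect_duration")
    return None if val is None else float(val)
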