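"""Domain types, parameter tables and configuration I/O.

The model describes patients with *RPE65*-mediated inherited retinal disease
moving through five vision-related health states plus death:

========  =====================================================
state     description (worst of visual acuity / visual field)
========  =====================================================
HS1       moderate visual impairment
HS2       severe visual impairment
HS3       profound visual impairment
HS4       counting fingers
HS5       hand motion / light perception / no light perception
DEAD      absorbing death state
========  =====================================================

Severity strictly increases HS1 < HS2 < ... < HS5; HS5 is counted as
"blindness" for blindness-free-year accounting.  All base-case parameters
(first-year transition matrices, utilities, adverse-event inputs, unit costs,
baseline cohort, settings) are packaged in :func:`fixture_config`.  The
long-term multistate regression parameters and the national lifetable are not
public; the packaged defaults for those two slots are clearly labelled
synthetic stand-ins from :mod:`visioncea.synthetic_data`.

Configurations are read and written as one YAML document referencing CSV
tables for the transition matrices and the lifetable.
"""

from __future__ import annotations

import csv
import dataclasses
import math
from dataclasses import dataclass, field
from enum import IntEnum
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import yaml

__all__ = [
    "HealthState",
    "ALIVE_STATES",
    "FORWARD_TRANSITIONS",
    "REFERENCE_TRANSITION",
    "ConfigError",
    "ValidationError",
    "BaselineCohort",
    "InitialTransitionMatrix",
    "MultistateParams",
    "weibull_scale_to_rate",
    "weibull_rate_to_scale",
    "Lifetable",
    "UtilitySet",
    "AdverseEventSpec",
    "CostInputs",
    "ModelSettings",
    "ModelConfig",
    "fixture_config",
    "load_config",
    "save_config",
]


class ConfigError(ValueError):
    """Malformed or unreadable configuration document."""


class ValidationError(ValueError):
    """A parameter value violates a structural invariant."""


class HealthState(IntEnum):
    """Ordinal vision health states; DEAD is absorbing and outside the order."""

    HS1 = 1
    HS2 = 2
    HS3 = 3
    HS4 = 4
    HS5 = 5
    DEAD = 6

    @property
    def is_alive(self) -> bool:
        return self is not HealthState.DEAD


ALIVE_STATES: tuple[HealthState, ...] = tuple(s for s in HealthState if s.is_alive)
N_ALIVE = len(ALIVE_STATES)

#: every (i, j) worsening pair among the five alive states, i < j
FORWARD_TRANSITIONS: tuple[tuple[int, int], ...] = tuple(
    (i, j) for i in range(1, 6) for j in range(i + 1, 6)
)

#: the HS1 -> HS2 transition anchoring the proportional-hazard structure
REFERENCE_TRANSITION: tuple[int, int] = (1, 2)

_STATE_NAMES = [s.name for s in ALIVE_STATES]


def _check(cond: bool, msg: str) -> None:
    if not cond:
        raise ValidationError(msg)


def _as_vector(values: Iterable[float], n: int, what: str) -> np.ndarray:
    arr = np.asarray(list(values), dtype=float)
    if arr.shape != (n,):
        raise ValidationError(f"{what}: expected {n} values, got shape {arr.shape}")
    return arr


@dataclass
class BaselineCohort:
    """Starting age and health-state mix of the modelled cohort."""

    start_age: float = 15.1
    occupancy: np.ndarray = field(
        default_factory=lambda: np.array([0.23, 0.32, 0.23, 0.19, 0.03])
    )

    def __post_init__(self) -> None:
        self.occupancy = _as_vector(self.occupancy, N_ALIVE, "baseline occupancy")
        _check(self.start_age >= 0, "cohort.start_age: must be non-negative")
        _check(
            bool(np.all(self.occupancy >= 0) and np.all(self.occupancy <= 1)),
            "cohort.occupancy: proportions must lie in [0, 1]",
        )
        _check(
            abs(float(self.occupancy.sum()) - 1.0) <= 1e-9,
            f"cohort.occupancy: must sum to 1 (got {self.occupancy.sum()!r})",
        )


@dataclass
class InitialTransitionMatrix:
    """One-year transition probabilities among HS1..HS5 for the first cycle.

    Rows are the state at baseline, columns the state at 12 months.  Backward
    (improving) moves are allowed here only: the first model year reflects the
    randomised-trial outcomes, after which decline is one-directional.
    """

    strategy: str
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (N_ALIVE, N_ALIVE):
            raise ValidationError(
                f"initial matrix ({self.strategy}): expected 5x5, got {m.shape}"
            )
        _check(
            bool(np.all(m >= 0) and np.all(m <= 1)),
            f"initial matrix ({self.strategy}): entries must lie in [0, 1]",
        )
        rowsums = m.sum(axis=1)
        bad = np.where(np.abs(rowsums - 1.0) > 1e-9)[0]
        if bad.size:
            raise ValidationError(
                f"initial matrix ({self.strategy}): row {_STATE_NAMES[bad[0]]} "
                f"sums to {rowsums[bad[0]]!r}, expected 1"
            )
        self.matrix = m


def _transition_key(t: tuple[int, int]) -> str:
    return f"HS{t[0]}->HS{t[1]}"


def _parse_transition(key: str) -> tuple[int, int]:
    try:
        a, b = key.split("->")
        return int(a.removeprefix("HS")), int(b.removeprefix("HS"))
    except Exception as exc:  # noqa: BLE001
        raise ConfigError(f"multistate.log_hr: bad transition key {key!r}") from exc


_FAMILIES = ("exponential", "weibull", "gompertz", "loglogistic", "lognormal")


@dataclass
class MultistateParams:
    """Proportional-hazards multistate parameters for the long-term phase.

    The baseline hazard belongs to the reference HS1->HS2 transition; every
    other forward transition scales it by a hazard ratio ``exp(log_hr)``.
    Parametrization (documented, fixed): for the Weibull family the baseline
    hazard is ``h0(t) = shape * rate * t**(shape - 1)`` so the cumulative
    baseline hazard is ``rate * t**shape``; the exponential family is the
    ``shape = 1`` special case.  See :mod:`visioncea.progression` for the
    Gompertz, log-logistic and log-normal forms.

    ``log_hr`` maps enabled forward transitions to log hazard ratios; the
    reference transition must carry log-HR 0 (ratio 1).  Transitions absent
    from the map are disabled (intensity 0).  ``se`` optionally carries
    standard errors keyed by ``"shape"``, ``"rate"`` or a transition key such
    as ``"HS1->HS3"``; when absent it is recorded as None, never defaulted.
    """

    family: str
    shape: float
    rate: float
    log_hr: dict[tuple[int, int], float]
    se: dict[str, float] | None = None
    provenance: str = "user"

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValidationError(
                f"multistate.family: {self.family!r} not in {_FAMILIES}"
            )
        _check(self.shape > 0, "multistate.shape: must be > 0")
        _check(self.rate > 0, "multistate.rate: must be > 0")
        if self.family == "exponential" and self.shape != 1.0:
            raise ValidationError("multistate: exponential family requires shape == 1")
        cleaned: dict[tuple[int, int], float] = {}
        for key, val in self.log_hr.items():
            t = _parse_transition(key) if isinstance(key, str) else tuple(key)
            _check(
                t in FORWARD_TRANSITIONS,
                f"multistate.log_hr: {_transition_key(t)} is not a forward transition",
            )
            _check(
                math.isfinite(val),
                f"multistate.log_hr[{_transition_key(t)}]: must be finite",
            )
            cleaned[t] = float(val)
        _check(
            REFERENCE_TRANSITION in cleaned,
            "multistate.log_hr: reference transition HS1->HS2 must be present",
        )
        _check(
            cleaned[REFERENCE_TRANSITION] == 0.0,
            "multistate.log_hr: reference HS1->HS2 must have log hazard ratio 0",
        )
        self.log_hr = cleaned

    @property
    def transitions(self) -> tuple[tuple[int, int], ...]:
        """Enabled forward transitions, in canonical order."""
        return tuple(t for t in FORWARD_TRANSITIONS if t in self.log_hr)

    def hazard_ratio(self, transition: tuple[int, int]) -> float:
        """Hazard ratio of a transition relative to HS1->HS2 (0 if disabled)."""
        lhr = self.log_hr.get(tuple(transition))
        return 0.0 if lhr is None else math.exp(lhr)


def weibull_scale_to_rate(shape: float, scale: float) -> float:
    """Convert an accelerated-failure-time scale ``sigma`` (``H0 = (t/sigma)**shape``)
    to the rate ``lambda`` of this package's ``H0 = lambda * t**shape`` form."""
    return scale ** (-shape)


def weibull_rate_to_scale(shape: float, rate: float) -> float:
    """Inverse of :func:`weibull_scale_to_rate`."""
    return rate ** (-1.0 / shape)


@dataclass
class Lifetable:
    """Annual background death probabilities ``q(age)`` by integer age.

    Lookups beyond the last tabulated age return 1 (certain death); lookups
    below the first tabulated age are a configuration error.
    """

    ages: np.ndarray
    qx: np.ndarray

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=int)
        qx = np.asarray(self.qx, dtype=float)
        _check(ages.ndim == 1 and ages.size >= 1, "lifetable: needs >= 1 row")
        _check(qx.shape == ages.shape, "lifetable: ages and qx lengths differ")
        _check(
            bool(np.all(np.diff(ages) == 1)),
            "lifetable: ages must be consecutive integers",
        )
        _check(
            bool(np.all((qx >= 0) & (qx <= 1))),
            "lifetable: q(age) must lie in [0, 1]",
        )
        self.ages, self.qx = ages, qx

    def q(self, age: int) -> float:
        age = int(age)
        if age < int(self.ages[0]):
            raise ConfigError(
                f"lifetable does not cover age {age} (starts at {self.ages[0]})"
            )
        if age > int(self.ages[-1]):
            return 1.0
        return float(self.qx[age - int(self.ages[0])])


@dataclass
class UtilitySet:
    """Health-state utility values (1 = full health; may be negative)."""

    label: str
    values: np.ndarray

    def __post_init__(self) -> None:
        v = _as_vector(self.values, N_ALIVE, f"utilities ({self.label})")
        _check(bool(np.all(v <= 1.0)), f"utilities ({self.label}): must be <= 1")
        _check(
            bool(np.all(np.diff(v) <= 0)),
            f"utilities ({self.label}): must be non-increasing HS1..HS5",
        )
        self.values = v


@dataclass
class AdverseEventSpec:
    """A peri-treatment adverse event of the gene-therapy arm."""

    name: str
    decrement: float        # utility decrement while the event lasts
    duration_months: float
    probability: float      # proportion of treated patients affected
    cost: float             # one-off treatment cost, CHF

    def __post_init__(self) -> None:
        _check(0 <= self.probability <= 1, f"ae.{self.name}.probability: in [0,1]")
        _check(self.duration_months > 0, f"ae.{self.name}.duration_months: > 0")
        _check(self.decrement >= 0, f"ae.{self.name}.decrement: >= 0")
        _check(self.cost >= 0, f"ae.{self.name}.cost: >= 0")


@dataclass
class CostInputs:
    """Unit costs (CHF) and resource-use quantities.

    Healthcare items cover the one-off treatment bundle, eligibility testing
    and the recurring costs of visual impairment; societal items (education,
    productivity, informal care) enter only under the societal perspective.
    """

    vn_acquisition: float = 759_968.0
    surgery_per_administration: float = 3_474.0
    n_administrations: int = 2
    prednisone_regimen: float = 86.0
    control_visit_cost: float = 271.0
    n_control_visits: int = 4
    eligibility_test_cost: float = 271.0
    eligible_fraction: float = 0.55
    # recurring costs of visual impairment
    excess_hospitalisations_per_year: float = 0.2     # HS2-5, age 65+
    hospitalisation_cost: float = 12_543.0
    technical_assistance_annual: float = 2_133.0
    technical_multiplier_hs1: float = 1.00
    technical_multiplier_hs25_adult: float = 0.96     # ages 18-64 (and <18, see docs)
    technical_multiplier_hs25_senior: float = 1.34    # ages 65+
    community_care_fraction: float = 0.06             # of HS2-5 aged 65+
    community_care_annual: float = 7_063.0
    residential_care_fraction: float = 0.30           # of HS2-5 aged 65+
    residential_care_annual: float = 64_537.0
    # societal perspective items
    education_annual: float = 21_094.0                # HS2-5 aged < 18
    salary_annual: float = 42_843.0                   # productivity base, 18-64
    caregiver_hours_hs1: float = 144.0                # patients aged 65+
    caregiver_hours_hs2: float = 676.0
    caregiver_hours_hs35: float = 1_608.0
    caregiver_counted_fraction: float = 0.25
    caregiver_hourly_cost: float = 43.0

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            val = getattr(self, f.name)
            _check(val >= 0, f"costs.{f.name}: must be >= 0")
        _check(0 < self.eligible_fraction <= 1, "costs.eligible_fraction: in (0, 1]")


_PERSPECTIVES = ("healthcare", "societal")
_CLOCKS = ("model_time", "time_since_effect_end")
_HS5_RULES = ("shift_from_hs4", "stay", "as_given")


@dataclass
class ModelSettings:
    """Run-level settings for one strategy comparison."""

    cycle_length: float = 1.0
    horizon: int = 85
    discount_rate: float = 0.03
    perspective: str = "healthcare"
    productivity_loss_fraction: float = 0.80
    effect_duration: float = 40.0     # years the gene-therapy effect persists
    progression_clock: str = "model_time"
    wtp_threshold: float = 100_000.0  # CHF per QALY
    half_cycle_correction: bool = False
    hs5_row_rule: str = "shift_from_hs4"

    def __post_init__(self) -> None:
        _check(self.horizon >= 1, "settings.horizon: must be >= 1")
        _check(self.discount_rate >= 0, "settings.discount_rate: must be >= 0")
        _check(self.effect_duration >= 1, "settings.effect_duration: must be >= 1")
        _check(self.cycle_length == 1.0, "settings.cycle_length: only annual cycles supported")
        _check(
            self.perspective in _PERSPECTIVES,
            f"settings.perspective: {self.perspective!r} not in {_PERSPECTIVES}",
        )
        _check(
            self.progression_clock in _CLOCKS,
            f"settings.progression_clock: {self.progression_clock!r} not in {_CLOCKS}",
        )
        _check(
            self.hs5_row_rule in _HS5_RULES,
            f"settings.hs5_row_rule: {self.hs5_row_rule!r} not in {_HS5_RULES}",
        )
        _check(
            0 <= self.productivity_loss_fraction <= 1,
            "settings.productivity_loss_fraction: in [0, 1]",
        )


@dataclass
class ModelConfig:
    """Everything needed to run both strategies once."""

    cohort: BaselineCohort
    initial_matrices: dict[str, InitialTransitionMatrix]
    multistate: MultistateParams
    lifetable: Lifetable
    utilities: UtilitySet
    adverse_events: list[AdverseEventSpec]
    costs: CostInputs
    settings: ModelSettings
    #: alternative utility sets selectable by scenarios, keyed by label
    utility_alternatives: dict[str, UtilitySet] = field(default_factory=dict)
    #: user-supplied long-term parameters per family, for family scenarios
    multistate_alternatives: dict[str, MultistateParams] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for label in ("VN", "SoC"):
            _check(label in self.initial_matrices, f"initial matrix missing: {label}")

    def copy(self) -> "ModelConfig":
        import copy as _copy

        return _copy.deepcopy(self)


# ---------------------------------------------------------------------------
# packaged base-case parameter set (first-year matrices, utilities, AEs,
# costs: printed trial/tariff inputs; long-term params & lifetable: synthetic)
# ---------------------------------------------------------------------------

SOC_INITIAL_MATRIX = np.array(
    [
        [1.00, 0.00, 0.00, 0.00, 0.00],
        [0.25, 0.50, 0.00, 0.25, 0.00],
        [0.00, 0.00, 1.00, 0.00, 0.00],
        [0.00, 0.00, 1.00, 0.00, 0.00],
        [0.00, 0.00, 0.00, 1.00, 0.00],
    ]
)

VN_INITIAL_MATRIX = np.array(
    [
        [1.00, 0.00, 0.00, 0.00, 0.00],
        [0.83, 0.17, 0.00, 0.00, 0.00],
        [0.50, 0.50, 0.00, 0.00, 0.00],
        [0.50, 0.00, 0.25, 0.25, 0.00],
        [0.00, 0.50, 0.00, 0.25, 0.25],
    ]
)

EQ5D5L_UTILITIES = (0.71, 0.62, 0.52, 0.35, 0.15)
HUI3_UTILITIES = (0.52, 0.36, 0.22, 0.14, -0.04)

ADVERSE_EVENTS = (
    ("cataract", 0.14, 1.0, 0.15, 4_869.0),
    ("eye_inflammation", 0.30, 3.6, 0.10, 52.0),
    ("increased_iop", 0.10, 1.0, 0.20, 220.0),
)


def fixture_config(
    multistate: MultistateParams | None = None,
    lifetable: Lifetable | None = None,
    settings: ModelSettings | None = None,
) -> ModelConfig:
    """Return the packaged base-case configuration.

    First-year matrices, utilities, adverse events, unit costs, baseline
    cohort and settings are the published base-case inputs.  The long-term
    multistate parameters and the lifetable default to labelled synthetic
    stand-ins (``provenance == "synthetic"``): results produced from them
    exercise the full pipeline but do not reproduce the published totals.
    Pass real values to either argument to override.
    """
    from . import synthetic_data  # deferred: synthetic_data imports this module

    if multistate is None:
        multistate = synthetic_data.plausible_longterm_params()
    if lifetable is None:
        lifetable = synthetic_data.synthetic_lifetable()
    return ModelConfig(
        cohort=BaselineCohort(),
        initial_matrices={
            "VN": InitialTransitionMatrix("VN", VN_INITIAL_MATRIX.copy()),
            "SoC": InitialTransitionMatrix("SoC", SOC_INITIAL_MATRIX.copy()),
        },
        multistate=multistate,
        lifetable=lifetable,
        utilities=UtilitySet("EQ-5D-5L", np.array(EQ5D5L_UTILITIES)),
        adverse_events=[AdverseEventSpec(*row) for row in ADVERSE_EVENTS],
        costs=CostInputs(),
        settings=settings if settings is not None else ModelSettings(),
        utility_alternatives={
            "HUI3": UtilitySet("HUI3", np.array(HUI3_UTILITIES)),
        },
    )


# ---------------------------------------------------------------------------
# configuration I/O: YAML document + CSV tables
# ---------------------------------------------------------------------------


def _write_matrix_csv(path: Path, matrix: np.ndarray) -> None:
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["state", *_STATE_NAMES])
        for name, row in zip(_STATE_NAMES, matrix):
            w.writerow([name, *[repr(float(x)) for x in row]])


def _read_matrix_csv(path: Path) -> np.ndarray:
    try:
        with path.open(newline="") as fh:
            rows = list(csv.reader(fh))
    except OSError as exc:
        raise ConfigError(f"cannot read matrix table {path}: {exc}") from exc
    if not rows or rows[0] != ["state", *_STATE_NAMES]:
        raise ConfigError(f"{path}: expected header 'state,{','.join(_STATE_NAMES)}'")
    body = {r[0]: [float(x) for x in r[1:]] for r in rows[1:]}
    try:
        return np.array([body[name] for name in _STATE_NAMES])
    except KeyError as exc:
        raise ConfigError(f"{path}: missing row for state {exc.args[0]}") from exc


def _write_lifetable_csv(path: Path, lt: Lifetable) -> None:
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["age", "qx"])
        for age, q in zip(lt.ages, lt.qx):
            w.writerow([int(age), repr(float(q))])


def _read_lifetable_csv(path: Path) -> Lifetable:
    try:
        with path.open(newline="") as fh:
            rows = list(csv.reader(fh))
    except OSError as exc:
        raise ConfigError(f"cannot read lifetable {path}: {exc}") from exc
    if not rows or rows[0] != ["age", "qx"]:
        raise ConfigError(f"{path}: expected header 'age,qx'")
    ages = [int(r[0]) for r in rows[1:]]
    qx = [float(r[1]) for r in rows[1:]]
    return Lifetable(np.array(ages), np.array(qx))


def _multistate_to_doc(p: MultistateParams) -> dict:
    return {
        "family": p.family,
        "shape": float(p.shape),
        "rate": float(p.rate),
        "log_hr": {_transition_key(t): float(v) for t, v in p.log_hr.items()},
        "se": None if p.se is None else {k: float(v) for k, v in p.se.items()},
        "provenance": p.provenance,
    }


def _multistate_from_doc(doc: Mapping) -> MultistateParams:
    try:
        return MultistateParams(
            family=doc["family"],
            shape=float(doc["shape"]),
            rate=float(doc["rate"]),
            log_hr={_parse_transition(k): float(v) for k, v in doc["log_hr"].items()},
            se=doc.get("se"),
            provenance=doc.get("provenance", "user"),
        )
    except KeyError as exc:
        raise ConfigError(f"multistate block: missing key {exc.args[0]!r}") from exc


def save_config(config: ModelConfig, path: str | Path) -> None:
    """Write a configuration as ``<path>`` (YAML) plus sibling CSV tables."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    stem = path.stem
    files = {
        "initial_matrix_vn": f"{stem}_initial_vn.csv",
        "initial_matrix_soc": f"{stem}_initial_soc.csv",
        "lifetable": f"{stem}_lifetable.csv",
    }
    _write_matrix_csv(path.parent / files["initial_matrix_vn"],
                      config.initial_matrices["VN"].matrix)
    _write_matrix_csv(path.parent / files["initial_matrix_soc"],
                      config.initial_matrices["SoC"].matrix)
    _write_lifetable_csv(path.parent / files["lifetable"], config.lifetable)
    doc = {
        "cohort": {
            "start_age": float(config.cohort.start_age),
            "occupancy": [float(x) for x in config.cohort.occupancy],
        },
        "settings": {
            f.name: getattr(config.settings, f.name)
            for f in dataclasses.fields(ModelSettings)
        },
        "utilities": {
            "label": config.utilities.label,
            "values": [float(x) for x in config.utilities.values],
        },
        "utility_alternatives": {
            label: [float(x) for x in us.values]
            for label, us in config.utility_alternatives.items()
        },
        "adverse_events": [
            {
                "name": ae.name,
                "decrement": float(ae.decrement),
                "duration_months": float(ae.duration_months),
                "probability": float(ae.probability),
                "cost": float(ae.cost),
            }
            for ae in config.adverse_events
        ],
        "costs": {
            f.name: getattr(config.costs, f.name)
            for f in dataclasses.fields(CostInputs)
        },
        "multistate": _multistate_to_doc(config.multistate),
        "multistate_alternatives": {
            fam: _multistate_to_doc(p)
            for fam, p in config.multistate_alternatives.items()
        },
        "files": files,
    }
    with path.open("w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_config(path: str | Path) -> ModelConfig:
    """Load and validate a configuration written by :func:`save_config`.

    Raises :class:`ConfigError` for malformed documents (naming the offending
    key) and :class:`ValidationError` when a value violates an invariant.
    """
    path = Path(path)
    try:
        with path.open() as fh:
            doc = yaml.safe_load(fh)
    except (OSError, yaml.YAMLError) as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(doc, Mapping):
        raise ConfigError(f"{path}: top level must be a mapping")

    def need(key: str) -> object:
        if key not in doc:
            raise ConfigError(f"{path}: missing top-level key {key!r}")
        return doc[key]

    files = need("files")
    cohort_doc = need("cohort")
    cohort = BaselineCohort(
        start_age=float(cohort_doc["start_age"]),
        occupancy=np.asarray(cohort_doc["occupancy"], dtype=float),
    )
    settings = ModelSettings(**dict(need("settings")))
    util_doc = need("utilities")
    utilities = UtilitySet(util_doc["label"], np.asarray(util_doc["values"], float))
    util_alt = {
        label: UtilitySet(label, np.asarray(vals, float))
        for label, vals in (doc.get("utility_alternatives") or {}).items()
    }
    aes = [AdverseEventSpec(**ae) for ae in need("adverse_events")]
    costs = CostInputs(**dict(need("costs")))
    multistate = _multistate_from_doc(need("multistate"))
    ms_alt = {
        fam: _multistate_from_doc(d)
        for fam, d in (doc.get("multistate_alternatives") or {}).items()
    }
    base = path.parent
    vn = InitialTransitionMatrix("VN", _read_matrix_csv(base / files["initial_matrix_vn"]))
    soc = InitialTransitionMatrix("SoC", _read_matrix_csv(base / files["initial_matrix_soc"]))
    lifetable = _read_lifetable_csv(base / files["lifetable"])
    return ModelConfig(
        cohort=cohort,
        initial_matrices={"VN": vn, "SoC": soc},
        multistate=multistate,
        lifetable=lifetable,
        utilities=utilities,
        adverse_events=aes,
        costs=costs,
        settings=settings,
        utility_alternatives=util_alt,
        multistate_alternatives=ms_alt,
    )
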