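# Methods

## Model

`visioncea` implements a two-phase Markov cohort model comparing one-time
gene therapy (voretigene neparvovec, "VN") against best supportive care
("SoC") for inherited retinal disease caused by biallelic *RPE65* mutations.
The cohort moves over annual cycles through five vision-related health
states — HS1 (moderate visual impairment) to HS5 (hand motion / light
perception / no light perception, counted as blindness) — plus an absorbing
death state. The base cohort starts at mean age 15.1 years with occupancy
(0.23, 0.32, 0.23, 0.19, 0.03) over HS1..HS5 and runs for 85 one-year
cycles, a lifetime horizon.

**First year.** Transitions follow the trial-informed strategy-specific
5×5 matrices; improvement is possible only here. No trial patients starting
in HS5 were observed at 12 months, so the HS5 row is imputed from the HS4
row by shifting every destination one state worse, clamped at HS5
(configurable: `hs5_row_rule` also supports `stay` and `as_given`).

**Treatment-effect window.** VN patients then hold their state (identity
matrix) through the end of the effect window — base case 40 years. A
non-integer duration D (the 7.5-year scenario) covers whole cycles up to
ceil(D); the approximation slightly extends the effect and is applied
consistently in both directions of comparison.

**Long-term phase.** From cycle 2 (SoC) or after the effect window (VN),
decline follows a forward-only time-inhomogeneous multistate process. Every
forward transition i→j (j > i, state-skipping allowed) shares the baseline
hazard of the reference HS1→HS2 transition scaled by a transition-specific
hazard ratio. Baseline families and parametrizations (shape γ, rate λ):

| family      | h0(t)                    | H0(t)            |
|-------------|--------------------------|------------------|
| exponential | λ                        | λt               |
| weibull     | γλt^(γ−1)                | λt^γ             |
| gompertz    | λe^(γt)                  | (λ/γ)(e^(γt)−1)  |
| loglogistic | λγ(λt)^(γ−1)/(1+(λt)^γ) | log(1+(λt)^γ)    |
| lognormal   | pdf/sf, μ=−logλ, σ=1/γ   | −log sf(t)       |

An adapter converts Weibull scale-form parameters ((t/σ)^γ) to this rate
form, since externally estimated parameters may be published in either.
The hazard clock is **model time** (years since baseline), the classical
memoryless reading; an alternative `time_since_effect_end` clock restarting
at the end of the initial/effect phase is exposed because the one-cohort
wording does not strictly exclude it. Under the default clock both arms
share each cycle's matrix and the engine caches them.

**Intensities → probabilities.** The per-cycle matrix is
`expm(M · [H0(t+dt) − H0(t)])` where M is the constant hazard-ratio
structure matrix. Because all intensities are proportional to one baseline,
generators at different times commute and this is the exact product
integral; the cycle integral of the baseline hazard is closed-form for all
five families (including the integrable singularity of shape < 1 hazards at
t = 0). The acceptance suite verifies the result against an independent
brute-force forward-equation (Kolmogorov) oracle — an Euler product over
10,000 substeps, Richardson-extrapolated against the 5,000-substep grid to
cancel the oracle's own first-order error — to 1e-6.

**Mortality.** Background mortality is lifetable-based, identical across
health states (the model carries excess costs of impairment, not excess
mortality), applied after the vision transition within each cycle at lookup
age floor(start_age + cycle − 1). Lookups beyond the last tabulated age
return q = 1. The order (vision first, death second) is fixed and its
numerical effect is small at the young ages where the arms differ most.

## Outcomes

Cycle c carries discount factor 1/(1+r)^(c−1) (first year undiscounted,
base r = 3% applied to costs and effects alike). Occupancy is valued at end
of cycle; a `half_cycle_correction` switch (default off) averages adjacent
rows instead. QALYs weight occupancy by health-state utilities (EQ-5D-5L
base set 0.71/0.62/0.52/0.35/0.15; HUI3 alternative
0.52/0.36/0.22/0.14/−0.04); death contributes nothing; age-dependent
utility adjustment is deliberately not modelled. Peri-treatment adverse
events (cataract, eye inflammation, raised intraocular pressure) enter as a
one-off VN QALY loss Σ p·decrement·(months/12) = 0.0124 and as one-off
expected treatment costs, both attributed to cycle 1 undiscounted.
Blindness-free years sum occupancy over HS1..HS4.

Costs (CHF, price years 2018–2019, no inflation machinery): the VN arm
carries acquisition (759,968) + two administrations (2×3,474) + prednisone
(86) + four control visits (4×271) = 768,086, eligibility testing scaled by
the 55% eligible fraction (271/0.55 ≈ 493), and expected adverse-event
costs (779.55). Recurring visual-impairment costs use the cohort mean age
per cycle for band membership (single-cohort model: the 65+ items switch on
at cycle 51, age 65.1): excess hospitalisations, technical assistance with
age-banded multipliers (the published multipliers cover 18–64 and 65+; the
under-18 band uses the adjacent 0.96 value), community and residential care.
The societal perspective adds excess education (< 18), productivity losses
(18–64, loss fraction 0.8 base / 0.5 scenario, HS2–5 only — HS1 is treated
as not work-limiting) and informal caregiver time (65+, 25% of hours
counted). Published internal arithmetic gaps are reproduced as-is from the
unit-cost table: the treatment bundle computes 768,086 against a printed
768,087, and adverse-event costs compute 779.55 against a printed 768,
consistent with unprinted unrounded unit costs upstream of that table.

The comparison reports increments (VN − SoC), the ICER only for genuine
trade-offs (dominance otherwise), cost per blindness-free year, and net
monetary benefit λ·ΔE − ΔC. ICERs are displayed to the nearest CHF with
increments carried at full precision.

## Uncertainty analysis

**One-way.** Each varied parameter is rerun at ±20% (no published
confidence intervals) with all else at base; the acquisition price is fixed
and first-year matrices are not varied. Bars are ranked by the induced
spread in the cost-per-QALY ratio; a top-10 view and plot are provided.

**Probabilistic.** Per iteration every uncertain parameter is redrawn:
Normal for the long-term regression parameters (shape and rate clipped to
the positive domain), Beta by method of moments for probabilities and
absolute utilities (negative-valued utility sets are shifted onto [−0.05, 1]
and back), Gamma by method of moments for decrements, resource use and
costs. Default dispersion is SE = 20% of the mean (overridable per
parameter), mirroring the deterministic ±20% convention and keeping Beta
moment-matching feasible for all packaged values; infeasible user-supplied
SEs raise an error naming the parameter. Parameter correlations are not
modelled. Draws are keyed by (seed, iteration) and bit-reproducible;
iterations producing invalid models are excluded and counted. The CEAC
reports, per willingness-to-pay λ, the fraction of iterations with positive
net monetary benefit.

## Synthetic inputs and what tests do (not) show

Two inputs are not publicly tabulated: the long-term multistate regression
estimates and the national lifetable. The package ships labelled synthetic
stand-ins (`provenance="synthetic"`), so headline numbers computed from the
default configuration exercise the full pipeline but are not reproductions
of the published totals; supply real parameters via configuration to
reproduce them. The synthetic choices, made once on clinical plausibility:

* **Long-term parameters** — Weibull shape 1.5 (decline accelerating with
  time from baseline), reference HS1→HS2 median sojourn ≈ 10 years, hazard
  ratios rising for adjacent transitions deeper into the disease
  (1.3 / 1.7 / 2.2) and smaller for state-skipping jumps (0.05–0.5).
* **Lifetable** — Gompertz–Makeham, q(age) = 1 − exp(−(c + a·e^(b·age)))
  with a = 2e-5, b = 0.095, c = 5e-4: a modern high-income mortality
  profile reaching q ≈ 1 past age 105.
* **Event histories** — exactly observed forward paths simulated by
  closed-form inversion of the cumulative baseline hazard, with
  destinations drawn by hazard-ratio proportions. Real natural-history data
  would be panel-observed (interval-censored); the exact-time likelihood
  fitted here is a deliberate simplification, so parameter-recovery tests
  validate the estimator under exact observation only.

The alternative-family scenarios require per-family refits that are not
published; absent user-supplied parameters they are calibrated by
simulating n = 1,500 histories from the base synthetic truth (fixed seed)
and fitting the requested family, labelled synthetic.

Passing tests therefore show: the engine conserves mass and respects the
phase structure, the intensity-to-probability conversion solves the forward
equations, the likelihood recovers generating parameters (within 10% at
n = 5,000 histories), accrual reproduces hand arithmetic from the published
tables, and orderings (discounting, effect duration, perspective) match the
published pattern. They do not validate the synthetic natural-history
parameters against real patients.

## Numerical choices and problem sizes

Annual cycles only; horizon 85; expm via SciPy with round-off clipped and
rows renormalised (drift < 1e-10). The MLE optimises log-shape, log-rate
and log hazard ratios with L-BFGS-B from an exponential person-time start;
transitions with no observed events are dropped from the fit (their MLE is
−∞); non-convergence raises with optimiser diagnostics; AIC/BIC use the
observed transition count. Event times in the likelihood are floored at
1e-6 years to keep singular hazards finite. Default test and demonstration
sizes — 100 randomized trace configurations, 5,000 histories for recovery,
1,000 PSA iterations in the reproduction script (10,000 in the CLI default,
matching the published analysis; ~16 ms per iteration) — are the package's
own balance of statistical resolution against a few minutes of runtime.

## Known limitations

No interval-censored likelihood; no parameter correlations in the PSA; no
excess mortality of severe impairment; no age-dependent utilities; no
microsimulation (cohort means only — age bands switch for the whole cohort
at once); no efficiency frontier beyond two strategies; the `vf_only` and
`best_eye` health-state-assignment scenarios require user-supplied
first-year matrices and otherwise error by design.
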