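# visioncea

A Markov cohort cost-effectiveness model of one-time gene therapy
(voretigene neparvovec, VN) versus standard of care (SoC) in inherited
retinal disease caused by biallelic *RPE65* mutations, for health
economists and HTA analysts who want the published Swiss analysis as
tested, reusable, scriptable code rather than a spreadsheet.

## The model

A cohort (mean age 15.1y) moves over 85 annual cycles through five vision
health states HS1 (moderate visual impairment) … HS5 (hand motion / light
perception / none; "blindness") plus death. Year 1 uses trial-informed
transition matrices per arm (the unobserved HS5 row is imputed by shifting
the HS4 row one state worse). VN patients then hold their state for the
assumed treatment-effect duration (base 40 years); afterwards — and from
year 2 under SoC — decline follows a forward-only multistate process with
proportional hazards: every transition i→j scales the reference HS1→HS2
baseline hazard h₀(t) (Weibull base case, h₀(t) = γλt^(γ−1)) by a hazard
ratio, with t measured from baseline. Cycle matrices are
P = expm(M·[H₀(t+1) − H₀(t)]) for the hazard-ratio structure matrix M.
Lifetable mortality applies uniformly after each vision transition.

QALYs weight occupancy by EQ-5D-5L state utilities (one-off adverse-event
QALY loss of 0.0124 for VN); costs cover the treatment bundle, eligibility
testing, adverse events and age-banded costs of visual impairment, with
societal add-ons (education, productivity, caregivers) as a perspective
switch. The headline result is the ICER = ΔC/ΔE in CHF per QALY gained,
with tornado and probabilistic sensitivity analysis (Beta/Gamma/Normal
draws, CEAC) and the published scenario catalogue (effect durations,
hazard families, HUI3 utilities, discount rates 0–5%, societal
perspectives, HS5 handling).

Two inputs of the original analysis are not public — the long-term
multistate regression estimates and the Swiss lifetable. The package ships
clearly labelled synthetic stand-ins (`provenance="synthetic"`) so
everything runs out of the box; supply real values via configuration to
reproduce the published totals. See `docs/methods.md` for assumptions,
parametrizations and limitations.

## Worked example

```python
import visioncea as v

config = v.fixture_config()          # packaged base case
result = v.run_comparison(config)    # runs both arms, 85 cycles each
print(result.summary_text())
```

```
Perspective: healthcare
                                               SoC          VN  Difference
Blindness-free years                          9.94       24.83       14.89
QALYs                                         8.18       16.95        8.76
Total costs (CHF)                          129,381     899,762     770,382
Status: tradeoff
ICER (CHF per QALY gained): 87,894
ICER (CHF per blindness-free year gained): 51,729
NMB at CHF 100,000/QALY: 106,109
```

Read it as: under the synthetic natural-history parameters, treatment
costs CHF 770,382 more per patient over a lifetime (discounted at 3%),
buys 8.76 QALYs and 14.89 blindness-free years, i.e. CHF 87,894 per QALY
gained — cost-effective at a CHF 100,000/QALY willingness to pay (positive
net monetary benefit). With the real (non-public) inputs supplied, the
same pipeline reproduces the published totals instead.

Scenarios, one-way and probabilistic sensitivity analysis:

```python
from visioncea import scenarios, sensitivity

scenarios.run_all(config)                      # catalogue as a DataFrame
entries = sensitivity.tornado(config)          # ranked one-way analysis
psa = sensitivity.run_psa(config, 10_000, seed=1)
psa.probability_cost_effective(100_000.0)
```

or from a shell:

```sh
visioncea run --scenario base
visioncea run-all --out results/
visioncea tornado --top 10 --out results/
visioncea psa -n 10000 --seed 1 --out results/
```

Configurations round-trip through one YAML document plus CSV tables
(`v.save_config` / `v.load_config`).

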