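# microgbd

A desk-scale, fully testable reimplementation of the injuries morbidity
and mortality estimation chain used in global burden-of-disease work.  It
is written for epidemiologists and methodologists who want to study,
teach or stress-test the machinery of burden estimation — ensemble
cause-of-death modelling, hierarchy-consistent mortality correction, the
multi-stage non-fatal pipeline and DALY assembly — without access to the
production data and infrastructure.  Everything runs on a synthetic world
with known ground truth.

## What it computes

For each cause of injury *c* (road injuries, falls, drowning, ...) and
demographic cell (location, year, age group, sex):

- **Deaths / CSMR** — an ensemble of covariate submodels fit in ln-rate
  and logit-cause-fraction space, weighted by out-of-sample predictive
  validity (RMSE on test–train holdouts), then rescaled so sub-causes sum
  to parents and all causes to the all-injury envelope.
- **YLL** = deaths × e(a), with e(a) the residual life expectancy at the
  age of death from a reference life table built from the lowest observed
  mortality rate at each age across populations over 5 million.
- **Incidence** — non-fatal observations crosswalked to the inpatient
  reference definition (value / ratio per care category), fit log-linearly,
  and thinned by the excess-mortality hazard f over the acute window:
  i_surv = i·exp(−f·w).
- **Nature split** — p(nature | cause, age, sex), the probability that
  each of the 47 natures of injury (hip fracture, TBI, ...) is the most
  disabling outcome, estimated from dual-coded data as a
  Dirichlet–multinomial posterior mean.
- **YLD** = Σ_natures (P_short·DW_short + P_long·DW_long) × population,
  with short-term prevalence = incidence × duration and long-term
  prevalence from the ODE dP/dt = i(1−P) − (m+f)P, followed by a
  comorbidity microsimulation that combines co-occurring weights as
  1 − Π(1 − DW_k).
- **DALY** = YLL + YLD, with 95% uncertainty intervals from draws.

Sexual violence runs a separate non-fatal-only branch (survey crosswalk
for penetrative-only definitions, binomial logit prevalence model,
short-term disability per prevalent case).

## Worked example

```python
from microgbd import LifeTable, yll_for_death, count_injury_permutations
from microgbd import load_crosswalk_table, expand_to_category, build_nature_registry

lt = LifeTable.from_pairs([(0.0, 85.0), (25.0, 60.0), (50.0, 38.0)])
print("YLLs for one road-injury death at age 25:", yll_for_death(25.0, lt))
print("YLLs for one death at age 50:            ", yll_for_death(50.0, lt))

xwalk = load_crosswalk_table()
print("Outpatient falls per inpatient case:     ",
      expand_to_category(1.0, "falls", "outpatient", xwalk))

natures = build_nature_registry()
print("Short-term DW, spinal cord lesion (neck):",
      natures.dw_short("Spinal cord lesion at neck level"))
print("Orderings of 10 natures of injury:       ",
      f"{count_injury_permutations(10):,}")
```

prints

```
YLLs for one road-injury death at age 25: 60.0
YLLs for one death at age 50:             38.0
Outpatient falls per inpatient case:      6.91
Short-term DW, spinal cord lesion (neck): 0.7319
Orderings of 10 natures of injury:        3,628,800
```

A death at 25 with 60 years of residual life expectancy contributes 60
years of life lost; an inpatient falls case implies 6.91 outpatient cases;
a person-year lived with a neck-level spinal cord lesion carries 0.7319
years lived with disability; and the factorial growth of multi-injury
combinations is why only the single most disabling nature is modelled.

The full chain runs from the command line:

```bash
microgbd run --seed 1 --out results/run --n-draws 50   # simulate → ... → report
microgbd simulate --seed 1 --out data/                 # input tables + ground truth
microgbd registry validate                             # bundled registries
```

`results/run/results.csv` holds mean / lower / upper per cause, measure
(csmr, yll, yld, daly) and demographic cell; `manifest.json` records the
config checksum and seed so reruns are bit-identical.

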