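# tempodisc

Hierarchical Bayesian modelling of **delay discounting** (intertemporal
choice): how steeply people devalue a reward — money or food — as its
delivery recedes into the future.

The package is aimed at researchers in neuroeconomics and behavioural
biostatistics who run adaptive titration tasks: a participant repeatedly
chooses between a smaller immediate reward and a larger delayed one (40
units after 2 days to 1 year), while an amount-adjustment staircase (steps
10, 5, 2.5, 1 from a 20-unit start) drives the immediate offer toward the
indifference point at each delay. `tempodisc` provides:

* a **task simulator** that reproduces the staircase exactly and generates
  cohorts of synthetic discounters from any implemented model, plus the
  standard quality-control filters (>90% one-sided choosers, >12 s
  reaction times on most trials);
* **eight choice models** — five option-based subjective-value (SV) models
  (exponential and hyperbolic discounting, with and without time scaling
  `s`) and three attribute-wise heuristics (ITCH, DRIFT, TRADE) — behind a
  lapse-limited logistic choice rule
  `p(delayed) = (1 − 2·error)·logit⁻¹(SV_delayed − SV_immediate) + error`;
* **hierarchical MCMC estimation** (uniform hyperpriors over population
  mean/SD, truncated-normal participant levels, a slice-within-Gibbs
  sampler with interweaved non-centered scale updates) with split-Rhat
  diagnostics;
* **WAIC model comparison** on the negative-log scale (lower = better) with
  paired-difference standard errors;
* **validation tools**: parameter recovery, highest-density intervals, and
  the food-vs-money contrast of the discount rate `k` via the 95% HDI of
  per-draw population-level differences.

The core quantity throughout is the discount rate `k` (e.g.
`SV = A·exp(−(kD)^s)` for exponential discounting with scaling): higher `k`
means steeper devaluation, i.e. more impulsive choice.

## Worked example

```python
from tempodisc import (FitConfig, build_model, compare_fits, condition_contrast,
                       fit, qc_filter, rhat, simulate_cohort)

pop = {"food":  {"k": (0.06, 0.02), "error": (0.05, 0.02)},
       "money": {"k": (0.03, 0.02), "error": (0.05, 0.02)}}
dataset, truth = simulate_cohort(12, pop, "exp", seed=8)   # 1,440 trials
retained, report = qc_filter(dataset)                      # nobody excluded here

cfg = FitConfig(warmup=1000, draws=400, chains=2, seed=8)
fits = {c: fit(build_model(retained, c, "exp"), cfg) for c in ("food", "money")}
print(rhat(fits["food"]).max())                            # 1.051 -> converged

comp = compare_fits({"exp": fits["food"],
                     "hyp": fit(build_model(retained, "food", "hyp"), cfg)})
print(comp.table)
c = condition_contrast(fits["food"], fits["money"])
print(c.summary())
```

Output (abbreviated):

```
model   waic    se  p_waic  rank  delta_to_best  se_delta  significant
  exp 237.77 16.36   16.33     1           0.00      0.00         True
  hyp 348.31 15.11   18.24     2         110.54     13.86        False
delta k (food - money): mean 0.0361, 95% HDI [0.0203, 0.0579], excludes 0: True
```

Reading the numbers: the generating exponential model beats the hyperbola
by 110.5 WAIC points (about 8 paired-difference SEs — decisively), and the
population discount rate recovered for "food" exceeds "money" by ≈ 0.036
per day with a 95% HDI excluding zero, matching the simulated truth
(0.06 vs 0.03). Population posterior means were 0.059 and 0.023.

The same pipeline is scriptable from the shell:

```bash
tempodisc simulate --model exp --n-participants 12 --seed 8 --out data/choices.csv
tempodisc fit --data data/choices.csv --model exp --condition food \
          --warmup 1000 --draws 400 --out fits/exp_food.csv
tempodisc contrast --fit-a fits/exp_food.csv --fit-b fits/exp_money.csv \
          --out contrast.json
```

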