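# Methods

## Scientific setting

`tempodisc` models intertemporal choice: a decision-maker repeatedly chooses
between a smaller immediate reward and a larger delayed one (here a fixed 40
units — Euros or food portions — delivered after 2 days, 2 weeks, or 1, 3, 6
or 12 months). The immediate offer is titrated by an amount-adjustment
staircase so that, over five choices per delay, it homes in on the
participant's indifference point. The package provides the full analysis
chain for such data: a simulator of the task, hierarchical Bayesian
estimation of eight competing choice models, WAIC model comparison,
parameter-recovery validation, and a population-level contrast of discount
rates between reward conditions.

## Choice models

Option-based (subjective value, SV) models discount the delayed amount `A`
at delay `D` (days):

| model | SV(A, D) |
|---|---|
| `exp` | `A·exp(−kD)` |
| `exp_scaled` | `A·exp(−(kD)^s)` |
| `hyp` | `A/(1 + kD)` |
| `hyp_delay_scaled` | `A/(1 + k·D^s)` |
| `hyp_denom_scaled` | `A/(1 + kD)^s` |

`k > 0` (day⁻¹-like) measures impulsivity; `s > 0` rescales time
sensitivity, with `s = 1` recovering the unscaled model and `s < 1`
compressing long delays. The decision value of a trial is
`SV(delayed) − SV(immediate)`; an immediate option's SV is its amount.

Attribute-wise heuristics compare amounts (`x1` immediate, `x2` delayed) and
delays (`t1 = 0`, `t2`) directly:

* **ITCH** — `β_xA(x2−x1) + β_xR(x2−x1)/((x2+x1)/2) + β_tA(t2−t1) +
  β_tR(t2−t1)/((t2+t1)/2)`. Relative terms are normalized by the two-option
  mean, the canonical form of the model.
* **DRIFT** — `β_xA·z(x2−x1) + β_xR·z((x2−x1)/x1) + β_tA·z(t2−t1) +
  β_xt·z((x2/x1)^(1/(t2−t1)) − 1)`. The standardizer `z(·)` is injectable.
  The default for model fitting z-scores each factor within
  participant-and-condition (regression-style origin of the model), falling
  back to zeros when a factor has no variance; an identity standardizer is
  available and is the default for single-trial evaluation.
* **TRADE** — with `v(x) = log(1+scaling2·x)/scaling2` and
  `w(t) = log(1+scaling3·t)/scaling3`:
  `dv = (v(x2) − v(x1)) − scaling1·(w(t2) − w(t1))`. The sign convention is
  chosen so that longer delays penalize the delayed option; the opposite
  sign would make delay attractive, contradicting discounting. `scaling2`
  and `scaling3` must be positive for the logarithms to exist.

All decision values feed a lapse-limited inverse logit,

    p(delayed) = (1 − 2·error)·exp(dv)/(1 + exp(dv)) + error,

restricting choice probabilities to `[error, 1 − error]`. Numerical policy:
exponent arguments are clipped at ±700 and the logistic is evaluated on the
chosen option's side of the likelihood, so contrary choices at saturated
probabilities give finite log-likelihoods whenever `error > 0`; a final
clamp removes 1-ulp bound overshoot.

## Task simulator

The staircase starts each five-trial block at an immediate offer of 20
units; after choices 1–4 the offer moves by 10, 5, 2.5 and 1 units (up after
a delayed choice, down after an immediate one). Each run presents the six
delays in a fresh uniformly random order, one block per delay; two runs per
condition give 60 trials per participant and condition, with run order
food–money–food–money (configurable). Calendar conversion is 1 week = 7 d,
1 month = 30 d, 1 year = 365 d. Brute-force enumeration of all choice paths
keeps offers on a half-unit grid inside [1.5, 38.5].

Cohorts are generated by drawing participant parameters from normal
population distributions truncated to each parameter's support (`k, s,
scalings > 0`; `error ∈ (0, 0.2]`; regression weights unbounded), then
sampling choices Bernoulli from the generative model's choice probability.
Default generating conditions used across the validation suites — chosen as
typical of healthy adult cohorts on this task — are population `k` mean 0.05
(SD 0.02) per day for exponential-family models (0.08, SD 0.04, for the
hyperbola, whose `k` trades off differently against delay), time scaling
`s` mean 0.6 (SD 0.1) when a distinctly scaled generator is needed, and
lapse rate 0.05 (SD 0.02). All randomness flows from explicit integer
seeds; regenerating with the stored seed reproduces a dataset bit for bit.

The titration indifference point of a block is defined as the immediate
amount a hypothetical sixth trial would offer (final offer adjusted once
more by the final 1-unit step in the direction of the final choice) — the
standard estimate for this staircase; with a lapse-free thresholded
responder it converges to the generative SV within one final step size.

Quality control mirrors standard practice for this task: participants
choosing the same option in strictly more than 90% of their pooled trials
are excluded as non-discounters, and, when reaction times are recorded,
participants exceeding 12 s on more than half of their trials are excluded
as inattentive.

### What the simulator does not emulate

Simulated agents are stationary and memoryless: no fatigue, learning,
session or order effects, no reaction times tied to difficulty, and no
heterogeneity beyond the truncated-normal population. Passing recovery and
contrast suites therefore demonstrates that the estimation machinery is
correct and well calibrated *under the model class*, not that real cohorts
satisfy these assumptions.

## Hierarchical estimation

For each condition and model, every free parameter `p` (decision parameters
plus `error`) gets population mean `p_mu` and SD `p_sd` with independent
uniform hyperpriors:

| parameter | Mu range | SD range | start (Mu, SD) |
|---|---|---|---|
| k | [e⁻¹⁰, e⁻²] | [10⁻², 3] | (e⁻²·⁵, 1) |
| s | (0, 4] | [0.01, 3] | (1, 1) |
| weights/scalers | [−1, 1] | (0, 1] | (0.5, 0.5) |
| error | (0, 0.2] | (0, 0.2] | (0.1, 0.1) |

Participant-level values are Normal(`p_mu`, `p_sd`) truncated to the
parameter's support; choices are Bernoulli through the choice rule. Open
interval endpoints are measure-zero under a continuous prior and are
realized numerically by nudging the bound inward by 10⁻¹². Although the
TRADE scalers' Mu range extends to −1, their participant-level support is
(0, ∞), so negative population means simply concentrate participants near
zero.

Sampling is by component-wise slice-within-Gibbs (Neal 2003, stepping-out
and shrinkage). Participant-level parameters are conditionally independent
given the population level and are updated as vectors in one pass;
population means and SDs are updated as scalars. Each sweep additionally
performs an interweaved non-centered update of every `p_sd` (holding the
participants' z-scores fixed and re-mapping), which decouples the
population SD from the participant values in weak-likelihood regimes — the
move that otherwise dominates the autocorrelation budget. Slice sampling
needs no gradients or acceptance tuning and respects the bounded supports
exactly; it replaces gradient-based samplers without changing the target
posterior. Chains start from the table's starting points (jittered per
chain), and proposal widths adapt during warm-up only (every 100 sweeps, to
2.5× the recent draw SD). Full-scale defaults are 60,000 warm-up iterations
and 1,500 retained draws; the validation suites use reduced settings
(2,000/500 for convergence checks, shorter for replicated simulations) so a
complete run fits a single CPU. Four chains by default make split-Rhat
computable; the rank-normalized split-Rhat (via ArviZ) above 1.1 on any
parameter is flagged as non-convergence. A constant chain is reported as
Rhat 1.0 by convention.

Design choices made where the design was genuinely open: the centered
parameterization with an interweaved scale move was preferred over a fully
non-centered one because participant likelihoods here are informative (60
trials each) and slice sampling updates constrained coordinates directly;
the per-parameter truncation bounds at the support edge (rather than, say,
a positivity-enforcing transform) keep the participant-level prior exactly
the truncated normal stated above.

## Model comparison

WAIC is computed from the stored pointwise log-likelihood matrix on the
negative-log scale: `lppd_i = log mean_draws exp(loglik_i)`, complexity
`p_i = var_draws(loglik_i)` (sample variance, `S − 1` denominator), `WAIC =
−Σ(lppd_i − p_i)`, `SE = √N · SD_i` of the per-observation contributions.
Lower is better. Models fitted to identical observations are ranked
ascending; the winner is flagged "significantly better" when it beats the
runner-up by more than twice the SE of the paired per-observation
difference — the standard information-criterion yardstick. The deviance
scale (×2) is a trivial rescaling left to the caller.

## Validation and contrasts

* **HDI** — shortest contiguous interval containing `⌈mass·n⌉` sorted
  draws; cross-checked against exhaustive window search.
* **Parameter recovery** — simulate from known participant parameters,
  refit, Pearson-correlate posterior means against truth per parameter;
  zero-variance truths are reported as undefined (`r = nan`) rather than
  silently dropped.
* **Condition contrast** — per-draw difference of population-level
  `k_mu` between two fitted conditions, summarized by its mean and 95% HDI.
  The population level is used because only there does the per-draw delta
  form a proper posterior; a participant-mean aggregate is available as an
  option. An HDI touching zero at one end counts as directional only when
  the interval is non-degenerate.

## Problem sizes used by the validation suites

Reduced-scale settings were chosen so the whole suite runs serially on one
CPU: convergence and recovery checks use 10–20 participants with
2,000/500-draw chains; the model-recovery matrix uses 10 replicates per
generator at n = 5 with 300/150-draw chains; the contrast power checks use
10 replicates per scenario at n = 20 with 600/250-draw chains. These sizes
are validation-suite defaults, not statements about the precision
achievable at full scale.

## Known limitations

* The slice sampler is serial; chains do not run in parallel.
* `s` is weakly identified from 60 titrated trials: its posterior is broad
  and recovery correlations for `s` (and for near-constant `error`) are
  expected to be poor even when `k` recovers well. Conclusions should rest
  on `k`.
* WAIC assumes conditionally independent observations; trials within a
  titration block are independent only given the participant's parameters.
* The HDI routine targets unimodal posteriors (contiguous interval).
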