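"""Intertemporal-choice models and the probabilistic choice rule.

Two families of models for the choice between a smaller-immediate and a
larger-delayed reward are implemented:

* **Option-based (subjective value) models** assign each option a discounted
  worth ``SV(A, D)`` and compare the two options on that common scale.  Five
  variants are provided: exponential and hyperbolic discounting, each with or
  without an additional time-scaling exponent ``s`` (two scaling placements
  exist for the hyperbola).
* **Attribute-wise (heuristic) models** compare amounts and delays directly
  across options without computing an explicit discounted value: ITCH
  (intertemporal choice heuristic), DRIFT (dual reasoning and implicit
  framework theory) and the trade-off model (TRADE).

Either family yields a scalar decision value ``dv`` favouring the delayed
option when positive; a lapse-limited inverse-logit choice rule maps ``dv``
to the probability of choosing the delayed reward, restricted to
``[error, 1 - error]``.

All decision-value functions are pure and accept scalars or NumPy arrays.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "SV_MODELS",
    "HEURISTIC_MODELS",
    "ALL_MODELS",
    "MODEL_PARAMS",
    "Option",
    "SVModelParams",
    "HeuristicParams",
    "ChoiceRuleParams",
    "ChoiceTrial",
    "subjective_value",
    "decision_value_itch",
    "decision_value_drift",
    "decision_value_trade",
    "decision_value",
    "choice_probability",
    "log_likelihood",
    "standardize",
]

SV_MODELS = ("exp", "exp_scaled", "hyp", "hyp_delay_scaled", "hyp_denom_scaled")
HEURISTIC_MODELS = ("ITCH", "DRIFT", "TRADE")
ALL_MODELS = SV_MODELS + HEURISTIC_MODELS

#: free parameters per model, excluding the choice-rule lapse term
MODEL_PARAMS: dict[str, tuple[str, ...]] = {
    "exp": ("k",),
    "exp_scaled": ("k", "s"),
    "hyp": ("k",),
    "hyp_delay_scaled": ("k", "s"),
    "hyp_denom_scaled": ("k", "s"),
    "ITCH": ("beta_xA", "beta_xR", "beta_tA", "beta_tR"),
    "DRIFT": ("beta_xA", "beta_xR", "beta_tA", "beta_xt"),
    "TRADE": ("scaling1", "scaling2", "scaling3"),
}

# exponent clip keeping exp() finite in double precision
_EXP_CLIP = 700.0


@dataclass(frozen=True)
class Option:
    """A reward option: an amount (Euros or food portions) after a delay in days."""

    amount: float
    delay: float = 0.0

    def __post_init__(self) -> None:
        if self.amount <= 0:
            raise ValueError(f"option amount must be > 0, got {self.amount}")
        if self.delay < 0:
            raise ValueError(f"option delay must be >= 0 days, got {self.delay}")


@dataclass(frozen=True)
class SVModelParams:
    """Parameters of an option-based discounting model.

    ``k`` is the discount rate (steeper devaluation with delay for larger k);
    ``s`` is the time-scaling exponent, present only for the ``*_scaled``
    models, where ``s = 1`` recovers the unscaled counterpart.
    """

    model_id: str
    k: float
    s: float | None = None

    def __post_init__(self) -> None:
        if self.model_id not in SV_MODELS:
            raise ValueError(f"unknown SV model {self.model_id!r}")
        if not self.k > 0:
            raise ValueError(f"discount rate k must be > 0, got {self.k}")
        scaled = self.model_id.endswith("_scaled")
        if scaled:
            if self.s is None or not self.s > 0:
                raise ValueError(f"{self.model_id} requires scaling exponent s > 0")
        elif self.s is not None:
            raise ValueError(f"{self.model_id} takes no scaling exponent s")


@dataclass(frozen=True)
class HeuristicParams:
    """Weights of an attribute-wise heuristic model.

    ITCH uses four regression-style weights on absolute/relative amount and
    delay differences; DRIFT swaps the relative-delay term for an
    implied-interest-rate term (``beta_xt``); TRADE uses three positive
    scalers of its logarithmic value and delay functions.  Fields not used by
    ``model_id`` must be left unset.
    """

    model_id: str
    beta_xA: float | None = None
    beta_xR: float | None = None
    beta_tA: float | None = None
    beta_tR: float | None = None
    beta_xt: float | None = None
    scaling1: float | None = None
    scaling2: float | None = None
    scaling3: float | None = None

    def __post_init__(self) -> None:
        if self.model_id not in HEURISTIC_MODELS:
            raise ValueError(f"unknown heuristic model {self.model_id!r}")
        required = MODEL_PARAMS[self.model_id]
        for name in ("beta_xA", "beta_xR", "beta_tA", "beta_tR", "beta_xt",
                     "scaling1", "scaling2", "scaling3"):
            value = getattr(self, name)
            if name in required and value is None:
                raise ValueError(f"{self.model_id} requires parameter {name}")
            if name not in required and value is not None:
                raise ValueError(f"{self.model_id} does not use parameter {name}")
        if self.model_id == "TRADE":
            if not (self.scaling2 > 0 and self.scaling3 > 0):  # type: ignore[operator]
                raise ValueError("TRADE scaling2 and scaling3 must be > 0")


@dataclass(frozen=True)
class ChoiceRuleParams:
    """Lapse-limited inverse-logit choice rule; ``error`` bounds p in [error, 1-error]."""

    error: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.error <= 0.2:
            raise ValueError(f"lapse rate must lie in [0, 0.2], got {self.error}")


@dataclass(frozen=True)
class ChoiceTrial:
    """One intertemporal decision between an immediate and a delayed option.

    ``choice`` is 0 for the immediate and 1 for the delayed option.
    """

    participant_id: str
    condition: str
    run: int
    block: int
    trial: int
    immediate: Option
    delayed: Option
    choice: int
    rt: float | None = None

    def __post_init__(self) -> None:
        if self.choice not in (0, 1):
            raise ValueError(f"choice must be 0 (immediate) or 1 (delayed), got {self.choice}")
        if self.immediate.delay != 0:
            raise ValueError("the immediate option must have delay 0")


# ---------------------------------------------------------------------------
# option-based models
# ---------------------------------------------------------------------------

def subjective_value(option: Option | None = None, params: SVModelParams | None = None,
                     *, amount=None, delay=None):
    """Discounted worth of ``option`` under an option-based model.

    Either pass an :class:`Option` or the ``amount``/``delay`` arrays for
    vectorized evaluation.  The value of a zero-delay option equals its
    amount for every model, and ``0 < SV <= amount`` always.
    """
    if params is None:
        raise TypeError("params is required")
    if option is not None:
        amount, delay = option.amount, option.delay
    A = np.asarray(amount, dtype=float)
    D = np.asarray(delay, dtype=float)
    k, s, m = params.k, params.s, params.model_id
    if m == "exp":
        sv = A * np.exp(-np.minimum(k * D, _EXP_CLIP))
    elif m == "exp_scaled":
        sv = A * np.exp(-np.minimum((k * D) ** s, _EXP_CLIP))
    elif m == "hyp":
        sv = A / (1.0 + k * D)
    elif m == "hyp_delay_scaled":
        sv = A / (1.0 + k * D ** s)
    else:  # hyp_denom_scaled
        sv = A / (1.0 + k * D) ** s
    return sv if sv.ndim else float(sv)


# ---------------------------------------------------------------------------
# attribute-wise models
# ---------------------------------------------------------------------------

def _unpack(trial_or_options):
    """Return (x1, t1, x2, t2) from a ChoiceTrial or an (immediate, delayed) pair."""
    if isinstance(trial_or_options, ChoiceTrial):
        imm, dly = trial_or_options.immediate, trial_or_options.delayed
    else:
        imm, dly = trial_or_options
    return imm.amount, imm.delay, dly.amount, dly.delay


def standardize(values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Z-score an array (population SD), falling back to zeros when SD = 0.

    This is the default standardizer for DRIFT's ``z(.)`` terms, applied
    within participant and condition so that each factor is on a comparable
    scale across that participant's trials.
    """
    v = np.asarray(values, dtype=float)
    sd = v.std()
    if sd == 0:
        return np.zeros_like(v)
    return (v - v.mean()) / sd


def identity_standardizer(values):
    """Pass-through alternative to :func:`standardize` (no z-scoring)."""
    return np.asarray(values, dtype=float)


def decision_value_itch(trial, params: HeuristicParams):
    """ITCH decision value: weighted absolute and relative amount/delay differences.

    Relative terms are normalized by the two-option mean, e.g.
    ``(x2 - x1) / ((x2 + x1) / 2)``.
    """
    if params.model_id != "ITCH":
        raise ValueError("params are not for ITCH")
    x1, t1, x2, t2 = _unpack(trial)
    if (params.beta_xR != 0 and x1 + x2 == 0) or (params.beta_tR != 0 and t1 + t2 == 0):
        raise ZeroDivisionError("degenerate denominator in ITCH relative term")
    dv = params.beta_xA * (x2 - x1) + params.beta_tA * (t2 - t1)
    if params.beta_xR != 0:
        dv += params.beta_xR * (x2 - x1) / ((x2 + x1) / 2.0)
    if params.beta_tR != 0:
        dv += params.beta_tR * (t2 - t1) / ((t2 + t1) / 2.0)
    return dv


def drift_features(x1, t1, x2, t2) -> np.ndarray:
    """Raw DRIFT factors (before standardization), stacked as columns.

    Columns: absolute amount difference, relative amount difference
    (normalized by the immediate amount), absolute delay difference, and the
    per-day implied growth rate ``(x2/x1)**(1/(t2-t1)) - 1``.
    """
    x1, t1, x2, t2 = (np.asarray(v, dtype=float) for v in (x1, t1, x2, t2))
    if np.any(t2 <= t1):
        raise ValueError("DRIFT implied rate undefined for t2 <= t1")
    if np.any(x1 <= 0):
        raise ValueError("DRIFT relative terms require x1 > 0")
    rate = (x2 / x1) ** (1.0 / (t2 - t1)) - 1.0
    cols = np.broadcast_arrays(x2 - x1, (x2 - x1) / x1, t2 - t1, rate)
    return np.column_stack([np.atleast_1d(c) for c in cols])


def decision_value_drift(trial, params: HeuristicParams,
                         standardizer: Callable = identity_standardizer):
    """DRIFT decision value on a single trial.

    ``standardizer`` is applied to each factor; for a single trial the
    default is the identity (z-scoring is only meaningful across a
    participant's trial set — see :func:`drift_design_matrix`).
    """
    if params.model_id != "DRIFT":
        raise ValueError("params are not for DRIFT")
    x1, t1, x2, t2 = _unpack(trial)
    f = drift_features(x1, t1, x2, t2)[0]
    z = [float(np.asarray(standardizer([v]))[0]) for v in f]
    return (params.beta_xA * z[0] + params.beta_xR * z[1]
            + params.beta_tA * z[2] + params.beta_xt * z[3])


def drift_design_matrix(x1, t1, x2, t2, standardizer: Callable = standardize,
                        groups=None) -> np.ndarray:
    """Standardized DRIFT factor matrix for a trial set.

    Each factor is passed through ``standardizer`` within ``groups`` (e.g.
    participant codes) when given, otherwise over the whole set.
    """
    raw = drift_features(x1, t1, x2, t2)
    out = np.empty_like(raw)
    if groups is None:
        for j in range(raw.shape[1]):
            out[:, j] = np.asarray(standardizer(raw[:, j]))
    else:
        groups = np.asarray(groups)
        for g in np.unique(groups):
            m = groups == g
            for j in range(raw.shape[1]):
                out[m, j] = np.asarray(standardizer(raw[m, j]))
    return out


def itch_design_matrix(x1, t1, x2, t2) -> np.ndarray:
    """ITCH factor matrix (columns match beta_xA, beta_xR, beta_tA, beta_tR)."""
    x1, t1, x2, t2 = (np.asarray(v, dtype=float) for v in (x1, t1, x2, t2))
    return np.column_stack([
        x2 - x1,
        (x2 - x1) / ((x2 + x1) / 2.0),
        t2 - t1,
        (t2 - t1) / ((t2 + t1) / 2.0),
    ])


def trade_decision_values(x1, t1, x2, t2, scaling1, scaling2, scaling3):
    """Vectorized TRADE decision values; see :func:`decision_value_trade`."""
    x1, t1, x2, t2 = (np.asarray(v, dtype=float) for v in (x1, t1, x2, t2))
    if not (np.all(np.asarray(scaling2) > 0) and np.all(np.asarray(scaling3) > 0)):
        raise ValueError("TRADE scaling2 and scaling3 must be > 0")
    v = lambda x, a: np.log1p(a * x) / a
    dv = (v(x2, scaling2) - v(x1, scaling2)) - scaling1 * (v(t2, scaling3) - v(t1, scaling3))
    return dv


def decision_value_trade(trial, params: HeuristicParams):
    """TRADE decision value: log-scaled amount gain minus the scaled delay cost.

    With ``v(x) = log(1 + scaling2*x)/scaling2`` and
    ``w(t) = log(1 + scaling3*t)/scaling3``:
    ``dv = (v(x2) - v(x1)) - scaling1*(w(t2) - w(t1))``, so longer delays
    penalize the delayed option.
    """
    if params.model_id != "TRADE":
        raise ValueError("params are not for TRADE")
    x1, t1, x2, t2 = _unpack(trial)
    return float(trade_decision_values(x1, t1, x2, t2,
                                       params.scaling1, params.scaling2, params.scaling3))


def decision_value(trial, params, standardizer: Callable = identity_standardizer):
    """Decision value of a single trial under any of the eight models.

    For option-based models this is ``SV(delayed) - SV(immediate)``.
    """
    if isinstance(params, SVModelParams):
        imm, dly = (trial.immediate, trial.delayed) if isinstance(trial, ChoiceTrial) else trial
        return subjective_value(dly, params) - subjective_value(imm, params)
    if params.model_id == "ITCH":
        return decision_value_itch(trial, params)
    if params.model_id == "DRIFT":
        return decision_value_drift(trial, params, standardizer)
    return decision_value_trade(trial, params)


# ---------------------------------------------------------------------------
# choice rule and likelihood
# ---------------------------------------------------------------------------

def choice_probability(decision_value, rule: ChoiceRuleParams = ChoiceRuleParams()):
    """Probability of choosing the delayed option.

    ``p = (1 - 2*error) * exp(dv)/(1 + exp(dv)) + error`` — an inverse logit
    whose range is compressed to ``[error, 1 - error]`` by the lapse term.
    Numerically stable for any finite ``dv`` (the exponent is clipped, never
    the probability).
    """
    dv = np.clip(np.asarray(decision_value, dtype=float), -_EXP_CLIP, _EXP_CLIP)
    # branch on sign so exp() never overflows
    logistic = np.where(dv >= 0, 1.0 / (1.0 + np.exp(-dv)),
                        np.exp(np.minimum(dv, 0)) / (1.0 + np.exp(np.minimum(dv, 0))))
    p = (1.0 - 2.0 * rule.error) * logistic + rule.error
    # exact bound satisfaction at logistic saturation (1-ulp overshoot)
    p = np.clip(p, rule.error, 1.0 - rule.error)
    return p if p.ndim else float(p)


def choice_log_likelihood(choices, decision_value, rule: ChoiceRuleParams):
    """Pointwise log-likelihood computed stably from decision values.

    Evaluates the logistic on the chosen option's side (``dv`` for a delayed
    choice, ``-dv`` for an immediate one) so that the probability of the
    observed choice never rounds to 0 or 1 while the lapse rate is positive.
    """
    from scipy.special import expit

    dv = np.clip(np.asarray(decision_value, dtype=float), -_EXP_CLIP, _EXP_CLIP)
    z = np.where(np.asarray(choices) == 1, dv, -dv)
    lik = rule.error + (1.0 - 2.0 * rule.error) * expit(z)
    with np.errstate(divide="ignore"):
        return np.log(lik)


def bernoulli_log_likelihood(choices, probs):
    """Pointwise Bernoulli log-likelihood ``c*log p + (1-c)*log(1-p)``."""
    c = np.asarray(choices, dtype=float)
    p = np.asarray(probs, dtype=float)
    with np.errstate(divide="ignore"):
        return np.where(c == 1, np.log(p), np.log1p(-p))


def log_likelihood(trials: Iterable[ChoiceTrial], params,
                   rule: ChoiceRuleParams = ChoiceRuleParams(),
                   standardizer: Callable = identity_standardizer) -> float:
    """Summed Bernoulli log-likelihood of observed choices under one model.

    Finite whenever ``rule.error > 0``; raises on an empty trial list.
    """
    trials = list(trials)
    if not trials:
        raise ValueError("log_likelihood requires at least one trial")
    dvs = np.array([decision_value(t, params, standardizer) for t in trials])
    choices = np.array([t.choice for t in trials])
    return float(choice_log_likelihood(choices, dvs, rule).sum())
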