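"""Validation and condition contrasts: parameter recovery, HDI, delta-k.

Parameter recovery is the standard pipeline self-check: simulate choices
from known participant parameters, refit with the identical machinery, and
correlate the posterior-mean estimates with the generating values.  The
condition contrast compares discount rates between reward types on the
population level: per-draw differences of the population mean of ``k``
summarised by their mean and 95% highest density interval (HDI).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .inference import FitConfig, PosteriorSamples, build_model, fit
from .task import StaircaseConfig, simulate_from_params

__all__ = [
    "RecoveryResult",
    "ConditionContrast",
    "hdi",
    "parameter_recovery",
    "condition_contrast",
    "cross_condition_correlation",
]


def hdi(samples, mass: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous interval containing ``ceil(mass * n)`` samples.

    Requires at least 20 draws; suitable for the unimodal posteriors this
    package produces (an HDI of a multimodal posterior is not contiguous).
    """
    x = np.sort(np.asarray(samples, dtype=float).ravel())
    n = x.size
    if n < 20:
        raise ValueError(f"hdi requires >= 20 samples, got {n}")
    if not 0.0 < mass < 1.0:
        raise ValueError("mass must lie strictly between 0 and 1")
    m = int(np.ceil(mass * n))
    widths = x[m - 1:] - x[: n - m + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + m - 1])


@dataclass
class RecoveryResult:
    """Per-parameter Pearson correlation between generating and recovered values."""

    correlations: pd.DataFrame  # columns: parameter, r, p, n
    pairs: pd.DataFrame         # columns: participant_id, parameter, true, recovered

    def r(self, parameter: str) -> float:
        row = self.correlations[self.correlations["parameter"] == parameter]
        if row.empty:
            raise KeyError(parameter)
        return float(row["r"].iloc[0])


def _pearson(x, y) -> tuple[float, float]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("correlation requires n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:  # constant input: r undefined
        return float("nan"), float("nan")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def parameter_recovery(true_params: pd.DataFrame, model_id: str,
                       condition: str = "food",
                       config: StaircaseConfig = StaircaseConfig(),
                       seed: int = 0,
                       fit_config: FitConfig = FitConfig()) -> RecoveryResult:
    """Simulate from known parameters, refit, and correlate truth vs estimate.

    ``true_params`` is the long-format table produced by
    :func:`tempodisc.task.simulate_cohort` (participant_id, condition,
    parameter, value); only rows of ``condition`` are used.  Degenerate
    (zero-variance) generating values yield ``r = nan``.
    """
    sub = true_params[true_params["condition"] == condition]
    if sub["participant_id"].nunique() < 3:
        raise ValueError("parameter recovery requires >= 3 participants")
    dataset = simulate_from_params(sub, model_id, config, seed=seed)
    samples = fit(build_model(dataset, condition, model_id), fit_config)

    rows, pair_rows = [], []
    for pname in samples.param_names:
        truth = (sub[sub["parameter"] == pname]
                 .set_index(sub[sub["parameter"] == pname]["participant_id"].astype(str))
                 ["value"])
        est = samples.participant_means(pname)
        common = [pid for pid in samples.participant_ids if pid in truth.index]
        t = truth.loc[common].to_numpy(dtype=float)
        e = est.loc[common].to_numpy(dtype=float)
        r, p = _pearson(t, e)
        rows.append({"parameter": pname, "r": r, "p": p, "n": len(common)})
        for pid, tv, ev in zip(common, t, e):
            pair_rows.append({"participant_id": pid, "parameter": pname,
                              "true": tv, "recovered": ev})
    return RecoveryResult(pd.DataFrame(rows), pd.DataFrame(pair_rows))


@dataclass
class ConditionContrast:
    """Posterior of a population-level difference between two conditions."""

    delta: np.ndarray
    mean: float
    hdi_low: float
    hdi_high: float
    excludes_zero: bool
    parameter: str = "k"
    labels: tuple[str, str] = ("food", "money")

    def summary(self) -> dict:
        return {"parameter": self.parameter,
                "contrast": f"{self.labels[0]} - {self.labels[1]}",
                "mean": self.mean, "hdi_low": self.hdi_low,
                "hdi_high": self.hdi_high, "excludes_zero": self.excludes_zero}


def condition_contrast(samples_a: PosteriorSamples, samples_b: PosteriorSamples,
                       parameter: str = "k", mass: float = 0.95,
                       level: str = "population") -> ConditionContrast:
    """Per-draw difference (A − B) of a parameter between two fitted conditions.

    Both fits must come from the same model with equal draw counts.  The
    default contrasts the population-level mean (``<parameter>_mu`` draws);
    ``level="participant"`` instead differences the across-participant mean
    of the participant-level draws.
    """
    if samples_a.model_id != samples_b.model_id:
        raise ValueError(f"fits are from different models: "
                         f"{samples_a.model_id} vs {samples_b.model_id}")
    if level == "population":
        a = samples_a.population_draws(parameter)
        b = samples_b.population_draws(parameter)
    elif level == "participant":
        a = samples_a.posterior[parameter].mean(axis=2).reshape(-1)
        b = samples_b.posterior[parameter].mean(axis=2).reshape(-1)
    else:
        raise ValueError("level must be 'population' or 'participant'")
    if a.shape != b.shape:
        raise ValueError(f"draw counts differ ({a.size} vs {b.size}); "
                         "refit with matching configurations or resample")
    delta = a - b
    lo, hi = hdi(delta, mass)
    # an interval touching 0 at one end counts as exclusion only when it is
    # non-degenerate (a point mass at 0 does not indicate a direction)
    excludes = bool((hi <= 0.0 and lo < 0.0) or (lo >= 0.0 and hi > 0.0))
    return ConditionContrast(
        delta=delta, mean=float(delta.mean()), hdi_low=lo, hdi_high=hi,
        excludes_zero=excludes, parameter=parameter,
        labels=(samples_a.condition, samples_b.condition))


def cross_condition_correlation(samples_a: PosteriorSamples,
                                samples_b: PosteriorSamples,
                                parameter: str = "k") -> tuple[float, float]:
    """Pearson r (with two-sided p) of paired participant posterior means."""
    ka = samples_a.participant_means(parameter)
    kb = samples_b.participant_means(parameter)
    common = [p for p in ka.index if p in kb.index]
    return _pearson(ka.loc[common], kb.loc[common])
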