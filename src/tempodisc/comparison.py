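"""WAIC model comparison on the negative-log scale.

The Watanabe–Akaike information criterion estimates out-of-sample predictive
accuracy from the pointwise posterior log-likelihoods of a fitted model:

    lppd_i = log( mean over draws of exp(loglik_i) )
    p_i    = var over draws of loglik_i          (effective-complexity term)
    WAIC   = -sum_i (lppd_i - p_i)

On this negative-log scale lower values indicate better expected fit.  The
standard error is ``sqrt(N) * SD`` of the per-observation contributions, and
pairwise model differences use the SE of the paired per-observation
contrasts, which is the meaningful uncertainty for a difference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .inference import PosteriorSamples

__all__ = ["waic", "waic_pointwise", "rank_models", "ComparisonResult"]


def _as_matrix(loglik: np.ndarray) -> np.ndarray:
    """Coerce (chain, draw, obs) or (draws, obs) log-likelihoods to (S, N)."""
    ll = np.asarray(loglik, dtype=float)
    if ll.ndim == 3:
        ll = ll.reshape(-1, ll.shape[-1])
    if ll.ndim != 2:
        raise ValueError("log-likelihood must be (draws, observations) "
                         "or (chain, draw, observations)")
    if not np.isfinite(ll).all():
        bad = np.argwhere(~np.isfinite(ll).all(axis=0)).ravel()
        raise ValueError(f"non-finite log-likelihood for observation(s) {bad[:10].tolist()}")
    return ll


def waic_pointwise(loglik: np.ndarray) -> np.ndarray:
    """Per-observation WAIC contributions ``-(lppd_i - p_i)``, shape (N,)."""
    ll = _as_matrix(loglik)
    S = ll.shape[0]
    lppd = np.logaddexp.reduce(ll, axis=0) - np.log(S)
    p = ll.var(axis=0, ddof=1) if S > 1 else np.zeros(ll.shape[1])
    return -(lppd - p)


def waic(loglik: np.ndarray) -> tuple[float, float, float]:
    """WAIC on the negative-log scale: returns ``(waic, se, p_waic)``."""
    ll = _as_matrix(loglik)
    S, N = ll.shape
    pointwise = waic_pointwise(ll)
    p_waic = float(ll.var(axis=0, ddof=1).sum()) if S > 1 else 0.0
    se = float(np.sqrt(N) * pointwise.std(ddof=1)) if N > 1 else 0.0
    return float(pointwise.sum()), se, p_waic


@dataclass
class ComparisonResult:
    """Ranked WAIC table; ``table`` columns: model, waic, se, p_waic, rank,
    delta_to_best, se_delta, significant."""

    table: pd.DataFrame

    @property
    def best(self) -> str:
        return str(self.table.iloc[0]["model"])

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def rank_models(pointwise_logliks: dict[str, np.ndarray]) -> ComparisonResult:
    """Rank ≥ 2 models fitted to identical observations by WAIC.

    ``pointwise_logliks`` maps model name to its (chain, draw, obs) or
    (draws, obs) log-likelihood array.  A model is flagged significant when
    its WAIC beats the runner-up by more than twice the SE of the paired
    per-observation difference.
    """
    if len(pointwise_logliks) < 2:
        raise ValueError("rank_models needs at least two fitted models")
    mats = {m: _as_matrix(ll) for m, ll in pointwise_logliks.items()}
    sizes = {m: ll.shape[1] for m, ll in mats.items()}
    if len(set(sizes.values())) != 1:
        raise ValueError(f"models were fitted to different observation sets: {sizes}")
    N = next(iter(sizes.values()))

    rows = []
    contrib = {}
    for m, ll in mats.items():
        w, se, p = waic(ll)
        contrib[m] = waic_pointwise(ll)
        rows.append({"model": m, "waic": w, "se": se, "p_waic": p})
    table = pd.DataFrame(rows).sort_values("waic", kind="mergesort").reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)

    best = table.iloc[0]["model"]
    deltas, se_deltas, signif = [], [], []
    for _, row in table.iterrows():
        m = row["model"]
        diff = contrib[m] - contrib[best]
        delta = float(diff.sum())
        se_d = float(np.sqrt(N) * diff.std(ddof=1)) if N > 1 else 0.0
        deltas.append(delta)
        se_deltas.append(se_d)
        signif.append(False)
    table["delta_to_best"] = deltas
    table["se_delta"] = se_deltas
    # the winner is "significantly better" if it beats the runner-up by > 2 SE
    if len(table) >= 2:
        runner = table.iloc[1]
        signif[0] = bool(runner["delta_to_best"] > 2.0 * runner["se_delta"]
                         and runner["se_delta"] > 0)
    table["significant"] = signif
    return ComparisonResult(table)


def compare_fits(fits: dict[str, PosteriorSamples]) -> ComparisonResult:
    """Convenience wrapper ranking fitted :class:`PosteriorSamples` objects."""
    return rank_models({m: s.log_likelihood for m, s in fits.items()})
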