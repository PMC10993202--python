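"""Hierarchical Bayesian estimation of the eight intertemporal-choice models.

Model structure, fit separately per condition (food / money):

* population level — for each free parameter ``p`` (the model's decision
  parameters plus the lapse term ``error``), a mean ``p_mu`` and spread
  ``p_sd`` with independent uniform hyperpriors over fixed ranges
  (:data:`DEFAULT_PRIORS`);
* participant level — each participant's value drawn from
  ``Normal(p_mu, p_sd)`` truncated to the parameter's support
  (k > 0, s > 0, TRADE scalers > 0, error in (0, 0.2], weights unbounded);
* observation level — each choice is Bernoulli with probability given by the
  lapse-limited inverse-logit of the trial's decision value.

Sampling uses a component-wise slice-within-Gibbs scheme (Neal 2003):
participant-level parameters are updated jointly as vectors (they are
conditionally independent across participants given the population level),
and the population means/SDs as scalars.  Slice sampling needs no gradients
or step-size tuning, always accepts, and respects the bounded supports
exactly; proposal widths are adapted during warm-up only.  Pointwise
log-likelihoods are stored for every retained draw, which is what WAIC-based
model comparison consumes downstream.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit as _expit
from scipy.special import log_ndtr

from . import models as _m
from .models import MODEL_PARAMS
from .task import PARAM_SUPPORT, ChoiceDataset

__all__ = [
    "PriorSpec",
    "ParamPrior",
    "DEFAULT_PRIORS",
    "FitConfig",
    "PosteriorSamples",
    "HierarchicalModel",
    "build_model",
    "fit",
    "rhat",
    "split_rhat",
]

_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)
_EPS = 1e-12  # numerical stand-in for open interval endpoints


@dataclass(frozen=True)
class ParamPrior:
    """Uniform hyperprior ranges and the chain starting point for one parameter."""

    mu_range: tuple[float, float]
    sd_range: tuple[float, float]
    start: tuple[float, float]  # (mu, sd)


#: predefined hyperpriors: uniform ranges for the population mean and SD of
#: every parameter, with the sampler's starting points
DEFAULT_PRIORS: dict[str, ParamPrior] = {
    "k": ParamPrior((math.exp(-10.0), math.exp(-2.0)), (1e-2, 3.0), (math.exp(-2.5), 1.0)),
    "s": ParamPrior((_EPS, 4.0), (0.01, 3.0), (1.0, 1.0)),
    **{name: ParamPrior((-1.0, 1.0), (_EPS, 1.0), (0.5, 0.5))
       for name in ("beta_xA", "beta_xR", "beta_tA", "beta_tR", "beta_xt",
                    "scaling1", "scaling2", "scaling3")},
    "error": ParamPrior((_EPS, 0.2), (_EPS, 0.2), (0.1, 0.1)),
}


@dataclass(frozen=True)
class PriorSpec:
    """Per-parameter hyperprior table; defaults to :data:`DEFAULT_PRIORS`."""

    params: Mapping[str, ParamPrior] = field(default_factory=lambda: dict(DEFAULT_PRIORS))

    def __getitem__(self, name: str) -> ParamPrior:
        return self.params[name]


@dataclass(frozen=True)
class FitConfig:
    """MCMC settings.  Full-scale defaults follow the study protocol
    (60,000 warm-up iterations, 1,500 retained draws); tests and quick runs
    pass reduced values."""

    warmup: int = 60_000
    draws: int = 1_500
    chains: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.warmup, self.draws, self.chains) < 1:
            raise ValueError("warmup, draws and chains must all be >= 1")


class HierarchicalModel:
    """Sampleable description of one model applied to one condition's data."""

    def __init__(self, dataset: ChoiceDataset, condition: str, model_id: str,
                 priors: PriorSpec | None = None):
        if model_id not in _m.ALL_MODELS:
            raise ValueError(f"unknown model {model_id!r}")
        self.model_id = model_id
        self.condition = condition
        self.priors = priors or PriorSpec()
        df = dataset.select(condition)
        self.participant_ids = sorted(df["participant_id"].astype(str).unique())
        self.n_participants = len(self.participant_ids)
        codes = {pid: i for i, pid in enumerate(self.participant_ids)}
        self.pidx = df["participant_id"].astype(str).map(codes).to_numpy()
        self.x1 = df["amount_immediate"].to_numpy(dtype=float)
        self.t1 = np.zeros_like(self.x1)
        self.x2 = df["amount_delayed"].to_numpy(dtype=float)
        self.t2 = df["delay_days"].to_numpy(dtype=float)
        self.choice = df["choice"].to_numpy(dtype=float)
        self.n_trials = len(df)
        self.param_names = list(MODEL_PARAMS[model_id]) + ["error"]
        self.supports = {p: PARAM_SUPPORT[p] for p in self.param_names}
        if model_id == "ITCH":
            self._X = _m.itch_design_matrix(self.x1, self.t1, self.x2, self.t2)
        elif model_id == "DRIFT":
            self._X = _m.drift_design_matrix(self.x1, self.t1, self.x2, self.t2,
                                             groups=self.pidx)
        else:
            self._X = None

    @property
    def n_free_parameters(self) -> int:
        """Population (mu, sd per parameter) plus participant-level parameters."""
        P = len(self.param_names)
        return 2 * P + P * self.n_participants

    # -- likelihood ---------------------------------------------------------

    def decision_values(self, theta: np.ndarray) -> np.ndarray:
        """Per-trial decision values for participant-parameter matrix
        ``theta`` of shape (n_params, n_participants)."""
        by = {p: theta[j][self.pidx] for j, p in enumerate(self.param_names)}
        m = self.model_id
        if m in _m.SV_MODELS:
            k = by["k"]
            if m == "exp":
                sv2 = self.x2 * np.exp(-np.minimum(k * self.t2, 700.0))
            elif m == "exp_scaled":
                sv2 = self.x2 * np.exp(-np.minimum((k * self.t2) ** by["s"], 700.0))
            elif m == "hyp":
                sv2 = self.x2 / (1.0 + k * self.t2)
            elif m == "hyp_delay_scaled":
                sv2 = self.x2 / (1.0 + k * self.t2 ** by["s"])
            else:
                sv2 = self.x2 / (1.0 + k * self.t2) ** by["s"]
            return sv2 - self.x1  # immediate option: delay 0, SV = amount
        if m in ("ITCH", "DRIFT"):
            B = np.column_stack([by[p] for p in self.param_names[:-1]])  # per-trial weights
            return (self._X * B).sum(axis=1)
        return _m.trade_decision_values(self.x1, self.t1, self.x2, self.t2,
                                        by["scaling1"], by["scaling2"], by["scaling3"])

    def pointwise_loglik(self, theta: np.ndarray) -> np.ndarray:
        """Per-trial Bernoulli log-likelihood for one draw of ``theta``."""
        dv = np.clip(self.decision_values(theta), -700.0, 700.0)
        err = theta[-1][self.pidx]
        z = np.where(self.choice == 1, dv, -dv)
        # logistic on the chosen side: graceful underflow, no log(0)
        lik = err + (1.0 - 2.0 * err) * _expit(z)
        return np.log(lik)

    def participant_loglik(self, theta: np.ndarray) -> np.ndarray:
        """Likelihood summed per participant, shape (n_participants,)."""
        return np.bincount(self.pidx, weights=self.pointwise_loglik(theta),
                           minlength=self.n_participants)


def build_model(dataset: ChoiceDataset, condition: str, model_id: str,
                priors: PriorSpec | None = None) -> HierarchicalModel:
    """Assemble the hierarchical model for ``model_id`` on one condition."""
    return HierarchicalModel(dataset, condition, model_id, priors)


# ---------------------------------------------------------------------------
# truncated-normal helpers
# ---------------------------------------------------------------------------

def _log_trunc_mass(mu, sd, lo, hi):
    """log P(lo < X < hi) for X ~ Normal(mu, sd)."""
    if lo == -np.inf and hi == np.inf:
        return 0.0
    if hi == np.inf:
        return log_ndtr((mu - lo) / sd)
    if lo == -np.inf:
        return log_ndtr((hi - mu) / sd)
    lb = log_ndtr((hi - mu) / sd)
    la = log_ndtr((lo - mu) / sd)
    diff = la - lb
    if diff > -1e-14:  # essentially no mass inside the interval
        return -745.0
    return lb + np.log1p(-np.exp(diff))


def _truncnorm_logpdf(x, mu, sd, lo, hi):
    z = (x - mu) / sd
    lp = -0.5 * z * z - np.log(sd) - _LOG_SQRT_2PI - _log_trunc_mass(mu, sd, lo, hi)
    return np.where((x > lo) & (x < hi) | ((x == hi) & np.isfinite(hi)), lp, -np.inf)


# ---------------------------------------------------------------------------
# slice sampler
# ---------------------------------------------------------------------------

def _slice_update(x, logp, w, lo, hi, rng, max_step_out=16, max_shrink=200):
    """One slice-sampling update of a vector of independent coordinates.

    ``logp`` maps a full candidate vector to per-coordinate log densities;
    coordinates must be conditionally independent of one another.  The
    bracket is clamped to (lo, hi).
    """
    x = np.array(x, dtype=float, copy=True)  # logp may share buffers with x's source
    m = x.size
    lp0 = logp(x)
    y = lp0 - rng.exponential(size=m)  # log slice height
    u = rng.uniform(size=m)
    L = np.maximum(x - w * u, lo)
    R = np.minimum(L + w, hi)
    R = np.maximum(R, x)  # keep x inside [L, R] after clamping
    L = np.minimum(L, x)
    for _ in range(max_step_out):
        open_L = (logp(L) > y) & (L > lo)
        open_R = (logp(R) > y) & (R < hi)
        if not (open_L.any() or open_R.any()):
            break
        L = np.where(open_L, np.maximum(L - w, lo), L)
        R = np.where(open_R, np.minimum(R + w, hi), R)
    accepted = np.zeros(m, dtype=bool)
    out = x.copy()
    for _ in range(max_shrink):
        prop = L + (R - L) * rng.uniform(size=m)
        cand = np.where(accepted, out, prop)
        lp = logp(cand)
        newly = ~accepted & (lp >= y)
        out[newly] = prop[newly]
        accepted |= newly
        if accepted.all():
            break
        shrink = ~accepted
        left = shrink & (prop < x)
        L = np.where(left, prop, L)
        R = np.where(shrink & ~left, prop, R)
    out[~accepted] = x[~accepted]  # pathological shrink failure: keep current
    return out


class _ChainState:
    __slots__ = ("mu", "sd", "theta")

    def __init__(self, mu, sd, theta):
        self.mu, self.sd, self.theta = mu, sd, theta


def _init_chain(model: HierarchicalModel, rng: np.random.Generator) -> _ChainState:
    P, n = len(model.param_names), model.n_participants
    mu = np.empty(P)
    sd = np.empty(P)
    theta = np.empty((P, n))
    for j, p in enumerate(model.param_names):
        prior = model.priors[p]
        mu_lo, mu_hi = prior.mu_range
        sd_lo, sd_hi = prior.sd_range
        jit = 0.05 * (mu_hi - mu_lo)
        mu[j] = float(np.clip(prior.start[0] + jit * rng.normal(), mu_lo, mu_hi))
        sd[j] = float(np.clip(prior.start[1] * math.exp(0.1 * rng.normal()), sd_lo, sd_hi))
        lo, hi = model.supports[p]
        # moderate spread at initialisation keeps starting likelihoods sane
        spread = min(sd[j], 0.25 * (sd_lo + sd_hi))
        draws = mu[j] + spread * rng.standard_normal(n * 50).reshape(50, n)
        ok = (draws > lo) & (draws < hi)
        first = np.argmax(ok, axis=0)
        if not ok.any(axis=0).all():
            raise RuntimeError(f"failed to initialise {p} inside its support")
        theta[j] = draws[first, np.arange(n)]
    return _ChainState(mu, sd, theta)


def _run_chain(model: HierarchicalModel, config: FitConfig, rng: np.random.Generator,
               progress: bool = False):
    P, n = len(model.param_names), model.n_participants
    state = _init_chain(model, rng)
    if not np.isfinite(model.participant_loglik(state.theta)).all():
        raise RuntimeError("non-finite initial likelihood; check the data and priors")

    w_theta = np.empty(P)
    w_mu = np.empty(P)
    w_sd = np.empty(P)
    for j, p in enumerate(model.param_names):
        prior = model.priors[p]
        w_mu[j] = 0.25 * (prior.mu_range[1] - prior.mu_range[0])
        w_sd[j] = 0.25 * (prior.sd_range[1] - prior.sd_range[0])
        w_theta[j] = max(0.5 * prior.start[1], 1e-4)

    mu_draws = np.empty((config.draws, P))
    sd_draws = np.empty((config.draws, P))
    theta_draws = np.empty((config.draws, P, n))
    adapt_win: list[np.ndarray] = []
    total = config.warmup + config.draws

    for it in range(total):
        for j, p in enumerate(model.param_names):
            lo, hi = model.supports[p]
            mu_j, sd_j = state.mu[j], state.sd[j]

            def logp_theta(vec, j=j, mu_j=mu_j, sd_j=sd_j, lo=lo, hi=hi):
                prior_lp = _truncnorm_logpdf(vec, mu_j, sd_j, lo, hi)
                th = state.theta
                old = th[j].copy()
                th[j] = vec
                like = model.participant_loglik(th)
                th[j] = old
                return prior_lp + like

            state.theta[j] = _slice_update(state.theta[j], logp_theta,
                                           w_theta[j], lo, hi, rng)

            th_j = state.theta[j]
            prior = model.priors[p]

            def logp_mu(v, j=j, th_j=th_j, lo=lo, hi=hi):
                return np.array([
                    _truncnorm_logpdf(th_j, vv, state.sd[j], lo, hi).sum() for vv in v])

            state.mu[j] = _slice_update(np.array([state.mu[j]]), logp_mu, w_mu[j],
                                        prior.mu_range[0], prior.mu_range[1], rng)[0]

            def logp_sd(v, j=j, th_j=th_j, lo=lo, hi=hi):
                return np.array([
                    _truncnorm_logpdf(th_j, state.mu[j], vv, lo, hi).sum() for vv in v])

            state.sd[j] = _slice_update(np.array([state.sd[j]]), logp_sd, w_sd[j],
                                        prior.sd_range[0], prior.sd_range[1], rng)[0]

            # Interweaved non-centered scale update (ASIS): holding the
            # participants' z-scores fixed decouples the population SD from
            # the participant values, which otherwise mix slowly whenever the
            # likelihood constrains them only weakly.
            z_j = (state.theta[j] - state.mu[j]) / state.sd[j]

            def logp_sd_nc(v, j=j, z_j=z_j, lo=lo, hi=hi):
                out = np.empty(v.size)
                th = state.theta
                old = th[j].copy()
                for idx, sd_c in enumerate(v):
                    th_c = state.mu[j] + sd_c * z_j
                    if np.any(th_c <= lo) or np.any(th_c >= hi):
                        out[idx] = -np.inf
                        continue
                    th[j] = th_c
                    like = model.participant_loglik(th).sum()
                    out[idx] = like - model.n_participants * _log_trunc_mass(
                        state.mu[j], sd_c, lo, hi)
                th[j] = old
                return out

            new_sd = _slice_update(np.array([state.sd[j]]), logp_sd_nc, w_sd[j],
                                   prior.sd_range[0], prior.sd_range[1], rng)[0]
            state.theta[j] = state.mu[j] + new_sd * z_j
            state.sd[j] = new_sd

        if it < config.warmup:
            adapt_win.append(state.theta.copy())
            if len(adapt_win) == 100:
                arr = np.stack(adapt_win)  # (100, P, n)
                w_theta = np.maximum(2.5 * arr.std(axis=0).mean(axis=1), 1e-5)
                adapt_win.clear()
        else:
            d = it - config.warmup
            mu_draws[d] = state.mu
            sd_draws[d] = state.sd
            theta_draws[d] = state.theta

    return mu_draws, sd_draws, theta_draws


@dataclass
class PosteriorSamples:
    """Posterior draws plus pointwise log-likelihoods and fit metadata.

    ``posterior`` maps ``"<p>_mu"``/``"<p>_sd"`` to (chain, draw) arrays and
    each participant-level parameter name to a (chain, draw, participant)
    array.  ``log_likelihood`` has shape (chain, draw, trial).
    """

    posterior: dict[str, np.ndarray]
    log_likelihood: np.ndarray
    param_names: list[str]
    participant_ids: list[str]
    model_id: str
    condition: str
    config: FitConfig

    def population_draws(self, param: str) -> np.ndarray:
        """Flattened draws of a population-level mean, e.g. ``k``."""
        return self.posterior[f"{param}_mu"].reshape(-1)

    def participant_means(self, param: str) -> pd.Series:
        """Posterior-mean participant-level estimates for one parameter."""
        means = self.posterior[param].mean(axis=(0, 1))
        return pd.Series(means, index=self.participant_ids, name=param)

    def to_inference_data(self):
        import arviz as az
        post = {k: v for k, v in self.posterior.items()}
        coords = {"participant": self.participant_ids}
        dims = {p: ["participant"] for p in self.param_names}
        return az.from_dict(posterior=post, coords=coords, dims=dims,
                            log_likelihood={"choice": self.log_likelihood})

    # -- persistence (long CSV + JSON sidecar) ------------------------------

    def save(self, path) -> None:
        path = Path(path)
        rows = []
        for name, arr in self.posterior.items():
            C, D = arr.shape[:2]
            if arr.ndim == 2:
                for c in range(C):
                    rows.append(pd.DataFrame({
                        "chain": c, "draw": np.arange(D), "parameter": name,
                        "participant_id": "POP", "value": arr[c]}))
            else:
                for c in range(C):
                    for i, pid in enumerate(self.participant_ids):
                        rows.append(pd.DataFrame({
                            "chain": c, "draw": np.arange(D), "parameter": name,
                            "participant_id": pid, "value": arr[c, :, i]}))
        pd.concat(rows, ignore_index=True).to_csv(path, index=False)
        meta = {"model_id": self.model_id, "condition": self.condition,
                "param_names": self.param_names,
                "participant_ids": self.participant_ids,
                "config": dataclasses.asdict(self.config)}
        path.with_suffix(".meta.json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, path) -> "PosteriorSamples":
        path = Path(path)
        df = pd.read_csv(path)
        meta = json.loads(path.with_suffix(".meta.json").read_text())
        chains = int(df["chain"].max()) + 1
        draws = int(df["draw"].max()) + 1
        pids = [str(p) for p in meta["participant_ids"]]
        posterior: dict[str, np.ndarray] = {}
        for name, sub in df.groupby("parameter"):
            if (sub["participant_id"] == "POP").all():
                arr = np.empty((chains, draws))
                for c, csub in sub.groupby("chain"):
                    arr[c] = csub.sort_values("draw")["value"].to_numpy()
            else:
                arr = np.empty((chains, draws, len(pids)))
                for (c, pid), csub in sub.groupby(["chain", "participant_id"]):
                    arr[c, :, pids.index(str(pid))] = \
                        csub.sort_values("draw")["value"].to_numpy()
            posterior[name] = arr
        return cls(posterior=posterior, log_likelihood=np.zeros((chains, draws, 0)),
                   param_names=meta["param_names"], participant_ids=pids,
                   model_id=meta["model_id"], condition=meta["condition"],
                   config=FitConfig(**meta["config"]))


def fit(model: HierarchicalModel, config: FitConfig = FitConfig()) -> PosteriorSamples:
    """Sample the hierarchical posterior and store pointwise log-likelihoods.

    Chains run sequentially from seeds split off ``config.seed``; the same
    seed and configuration reproduce the draws exactly.
    """
    P, n = len(model.param_names), model.n_participants
    seqs = np.random.SeedSequence(config.seed).spawn(config.chains)
    mu_all = np.empty((config.chains, config.draws, P))
    sd_all = np.empty((config.chains, config.draws, P))
    th_all = np.empty((config.chains, config.draws, P, n))
    for c, seq in enumerate(seqs):
        rng = np.random.default_rng(seq)
        mu_all[c], sd_all[c], th_all[c] = _run_chain(model, config, rng)

    posterior: dict[str, np.ndarray] = {}
    for j, p in enumerate(model.param_names):
        posterior[f"{p}_mu"] = mu_all[:, :, j]
        posterior[f"{p}_sd"] = sd_all[:, :, j]
        posterior[p] = th_all[:, :, j, :]

    loglik = np.empty((config.chains, config.draws, model.n_trials))
    for c in range(config.chains):
        for d in range(config.draws):
            loglik[c, d] = model.pointwise_loglik(th_all[c, d])
    if not np.isfinite(loglik).all():
        raise RuntimeError("non-finite pointwise log-likelihood in retained draws")

    return PosteriorSamples(posterior=posterior, log_likelihood=loglik,
                            param_names=list(model.param_names),
                            participant_ids=list(model.participant_ids),
                            model_id=model.model_id, condition=model.condition,
                            config=config)


# ---------------------------------------------------------------------------
# convergence diagnostics
# ---------------------------------------------------------------------------

def split_rhat(draws: np.ndarray) -> float:
    """Rank-normalized split-Rhat of a (chain, draw) array (1.0 if constant)."""
    draws = np.asarray(draws, dtype=float)
    if draws.ndim != 2 or draws.shape[0] < 2:
        raise ValueError("split_rhat needs a (chain, draw) array with >= 2 chains")
    if np.ptp(draws) == 0:
        return 1.0
    import arviz as az
    return float(np.asarray(az.rhat(az.convert_to_dataset(draws[:, :, None]))["x"]).item())


def rhat(samples: PosteriorSamples, threshold: float = 1.1) -> pd.Series:
    """Split-Rhat for every free parameter (population and participant level).

    Values above ``threshold`` (1.1 by convention) indicate chains that have
    not mixed; inspect and refit with a longer warm-up.
    """
    if samples.posterior[f"{samples.param_names[0]}_mu"].shape[0] < 2:
        raise ValueError("Rhat requires at least 2 chains")
    out = {}
    for name, arr in samples.posterior.items():
        if arr.ndim == 2:
            out[name] = split_rhat(arr)
        else:
            for i, pid in enumerate(samples.participant_ids):
                out[f"{name}[{pid}]"] = split_rhat(arr[:, :, i])
    series = pd.Series(out, name="rhat")
    bad = series[series > threshold]
    if len(bad):
        import warnings
        warnings.warn(f"{len(bad)} parameter(s) with Rhat > {threshold}: "
                      f"{bad.index.tolist()[:5]}", stacklevel=2)
    return series
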