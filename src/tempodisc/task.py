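"""Adaptive amount-adjustment task: simulator, indifference points and QC.

The task titrates the immediate offer toward each participant's indifference
point.  The delayed reward is fixed at 40 units; the immediate offer starts
at 20 units and, after each of the first four choices in a five-trial block,
moves up (delayed chosen) or down (immediate chosen) by steps of 10, 5, 2.5
and 1 unit.  Each run presents the six delays (2 d, 2 wk, 1, 3, 6 mo, 1 yr)
in random order, one five-trial block per delay; each condition (food,
money) comprises two runs, interleaved food-money-food-money.

The simulator draws choices from any of the eight implemented choice models
through the lapse-limited logistic choice rule, so the same engine serves
parameter-recovery studies, model-recovery studies and power analyses.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .models import (
    ALL_MODELS,
    HEURISTIC_MODELS,
    MODEL_PARAMS,
    SV_MODELS,
    ChoiceRuleParams,
    ChoiceTrial,
    HeuristicParams,
    Option,
    SVModelParams,
    choice_probability,
    decision_value,
)

__all__ = [
    "StaircaseConfig",
    "ChoiceDataset",
    "PARAM_SUPPORT",
    "next_offer",
    "simulate_block",
    "simulate_participant_condition",
    "simulate_from_params",
    "simulate_cohort",
    "empirical_indifference_point",
    "indifference_points",
    "qc_filter",
    "make_params",
]

#: support (lower, upper) of each participant-level parameter
PARAM_SUPPORT: dict[str, tuple[float, float]] = {
    "k": (0.0, np.inf),
    "s": (0.0, np.inf),
    "beta_xA": (-np.inf, np.inf),
    "beta_xR": (-np.inf, np.inf),
    "beta_tA": (-np.inf, np.inf),
    "beta_tR": (-np.inf, np.inf),
    "beta_xt": (-np.inf, np.inf),
    "scaling1": (0.0, np.inf),
    "scaling2": (0.0, np.inf),
    "scaling3": (0.0, np.inf),
    "error": (0.0, 0.2),
}

CSV_COLUMNS = ["participant_id", "condition", "run", "block", "trial",
               "delay_days", "amount_immediate", "amount_delayed", "choice", "rt_s"]


@dataclass(frozen=True)
class StaircaseConfig:
    """Layout and titration rules of the amount-adjustment task."""

    initial_immediate: float = 20.0
    steps: tuple[float, ...] = (10.0, 5.0, 2.5, 1.0)
    delayed_amount: float = 40.0
    delays_days: tuple[float, ...] = (2.0, 14.0, 30.0, 90.0, 180.0, 365.0)
    choices_per_block: int = 5
    blocks_per_run: int = 6
    runs_per_condition: int = 2
    run_order: tuple[str, ...] = ("food", "money", "food", "money")

    def __post_init__(self) -> None:
        if len(self.steps) != self.choices_per_block - 1:
            raise ValueError("need one titration step per choice after the first")
        if self.blocks_per_run != len(self.delays_days):
            raise ValueError("one block per delay: blocks_per_run must equal len(delays_days)")

    @property
    def trials_per_condition(self) -> int:
        return self.runs_per_condition * self.blocks_per_run * self.choices_per_block

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1))

    @classmethod
    def from_json(cls, path) -> "StaircaseConfig":
        d = json.loads(Path(path).read_text())
        for key in ("steps", "delays_days", "run_order"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class ChoiceDataset:
    """Long-format trial table plus provenance metadata when synthetic.

    ``trials`` columns follow :data:`CSV_COLUMNS`; ``choice`` is 0 for the
    immediate and 1 for the delayed option.
    """

    trials: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def participants(self) -> list[str]:
        return sorted(self.trials["participant_id"].unique())

    @property
    def conditions(self) -> list[str]:
        return sorted(self.trials["condition"].unique())

    def select(self, condition: str) -> pd.DataFrame:
        sub = self.trials[self.trials["condition"] == condition]
        if sub.empty:
            raise ValueError(f"no trials for condition {condition!r}")
        return sub.reset_index(drop=True)

    def to_csv(self, path) -> None:
        self.trials.to_csv(path, index=False, columns=CSV_COLUMNS)
        if self.meta:
            Path(path).with_suffix(".meta.json").write_text(json.dumps(self.meta, indent=1))

    @classmethod
    def from_csv(cls, path) -> "ChoiceDataset":
        df = pd.read_csv(path)
        missing = [c for c in CSV_COLUMNS[:-1] if c not in df.columns]  # rt_s optional
        if missing:
            raise ValueError(f"choice CSV missing required columns: {missing}")
        if "rt_s" not in df.columns:
            df["rt_s"] = np.nan
        bad = df.index[~df["choice"].isin([0, 1])]
        if len(bad):
            raise ValueError(f"choice must be 0/1; offending rows: {list(bad[:5])}")
        meta_path = Path(path).with_suffix(".meta.json")
        meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
        df["participant_id"] = df["participant_id"].astype(str)
        return cls(df, meta)


def next_offer(current: float, choice: int, trial_index: int,
               config: StaircaseConfig = StaircaseConfig()) -> float:
    """Immediate amount offered after the choice on trial ``trial_index`` (1-4).

    Choosing the delayed reward raises the next immediate offer by
    ``steps[trial_index - 1]``; choosing the immediate reward lowers it by
    the same amount.
    """
    if not 1 <= trial_index <= len(config.steps):
        raise IndexError(f"trial_index must be in 1..{len(config.steps)}, got {trial_index}")
    step = config.steps[trial_index - 1]
    return current + step if choice == 1 else current - step


def _choice_prob(offer: float, delay: float, params, rule, config) -> float:
    imm = Option(offer, 0.0)
    dly = Option(config.delayed_amount, delay)
    return choice_probability(decision_value((imm, dly), params), rule)


def simulate_block(delay: float, params, rule: ChoiceRuleParams,
                   rng: np.random.Generator,
                   config: StaircaseConfig = StaircaseConfig(),
                   participant_id: str = "sim", condition: str = "food",
                   run: int = 1, block: int = 1,
                   deterministic: bool = False) -> list[ChoiceTrial]:
    """Simulate one five-choice titration block at a single delay.

    Choices are Bernoulli draws from the model's choice probability;
    ``deterministic=True`` instead thresholds the probability at 0.5
    (useful for indifference-point calibration checks).
    """
    offer = config.initial_immediate
    trials: list[ChoiceTrial] = []
    for t in range(1, config.choices_per_block + 1):
        p = _choice_prob(offer, delay, params, rule, config)
        if deterministic:
            choice = int(p > 0.5)
        else:
            choice = int(rng.random() < p)
        trials.append(ChoiceTrial(
            participant_id=participant_id, condition=condition, run=run,
            block=block, trial=t,
            immediate=Option(offer, 0.0),
            delayed=Option(config.delayed_amount, delay),
            choice=choice))
        if t < config.choices_per_block:
            offer = next_offer(offer, choice, t, config)
    return trials


def simulate_participant_condition(participant_id: str, condition: str, params,
                                   rule: ChoiceRuleParams, rng: np.random.Generator,
                                   config: StaircaseConfig = StaircaseConfig(),
                                   deterministic: bool = False) -> list[ChoiceTrial]:
    """All runs of one condition for one participant; block order is a fresh
    random permutation of the delays in every run."""
    trials: list[ChoiceTrial] = []
    for run in range(1, config.runs_per_condition + 1):
        order = rng.permutation(len(config.delays_days))
        for b, idx in enumerate(order, start=1):
            trials.extend(simulate_block(
                config.delays_days[idx], params, rule, rng, config,
                participant_id=participant_id, condition=condition,
                run=run, block=b, deterministic=deterministic))
    return trials


def make_params(model_id: str, values: Mapping[str, float]):
    """Build SVModelParams/HeuristicParams from a flat name->value mapping."""
    if model_id in SV_MODELS:
        return SVModelParams(model_id, k=values["k"],
                             s=values.get("s") if model_id.endswith("_scaled") else None)
    if model_id in HEURISTIC_MODELS:
        return HeuristicParams(model_id, **{p: values[p] for p in MODEL_PARAMS[model_id]})
    raise ValueError(f"unknown model {model_id!r}")


def _trials_to_frame(trials: Sequence[ChoiceTrial]) -> pd.DataFrame:
    return pd.DataFrame({
        "participant_id": [t.participant_id for t in trials],
        "condition": [t.condition for t in trials],
        "run": [t.run for t in trials],
        "block": [t.block for t in trials],
        "trial": [t.trial for t in trials],
        "delay_days": [t.delayed.delay for t in trials],
        "amount_immediate": [t.immediate.amount for t in trials],
        "amount_delayed": [t.delayed.amount for t in trials],
        "choice": [t.choice for t in trials],
        "rt_s": [t.rt if t.rt is not None else np.nan for t in trials],
    })


def simulate_from_params(params_table: pd.DataFrame, model_id: str,
                         config: StaircaseConfig = StaircaseConfig(),
                         seed: int = 0) -> ChoiceDataset:
    """Simulate choices for explicitly specified participant parameters.

    ``params_table`` is long format: participant_id, condition, parameter,
    value — with one row per model parameter (including ``error``) per
    participant and condition.
    """
    rng_root = np.random.SeedSequence(seed)
    pids = list(dict.fromkeys(params_table["participant_id"].astype(str)))
    streams = {pid: np.random.default_rng(s)
               for pid, s in zip(pids, rng_root.spawn(len(pids)))}
    trials: list[ChoiceTrial] = []
    for pid in pids:
        sub_p = params_table[params_table["participant_id"].astype(str) == pid]
        for condition in dict.fromkeys(sub_p["condition"]):
            values = dict(zip(sub_p[sub_p["condition"] == condition]["parameter"],
                              sub_p[sub_p["condition"] == condition]["value"]))
            params = make_params(model_id, values)
            rule = ChoiceRuleParams(values.get("error", 0.0))
            trials.extend(simulate_participant_condition(
                pid, condition, params, rule, streams[pid], config))
    df = _trials_to_frame(trials)
    meta = {"generating_model": model_id, "seed": seed,
            "config": dataclasses.asdict(config), "source": "simulate_from_params"}
    return ChoiceDataset(df, meta)


def _truncnorm_draw(rng: np.random.Generator, mean: float, sd: float,
                    lo: float, hi: float) -> float:
    """Rejection-sampled truncated normal draw (supports degenerate sd = 0)."""
    if sd < 0:
        raise ValueError("population SD must be >= 0")
    if sd == 0:
        if not (lo < mean <= hi or lo <= mean < hi):
            raise ValueError(f"degenerate mean {mean} outside support ({lo}, {hi})")
        return mean
    for _ in range(10000):
        x = rng.normal(mean, sd)
        if lo < x < hi:
            return x
    raise ValueError(f"truncated-normal sampling failed for mean={mean}, sd={sd} "
                     f"on ({lo}, {hi}); nearly all mass outside the support")


def simulate_cohort(n_participants: int,
                    population: Mapping[str, Mapping[str, tuple[float, float]]],
                    model_id: str,
                    config: StaircaseConfig = StaircaseConfig(),
                    seed: int = 0) -> tuple[ChoiceDataset, pd.DataFrame]:
    """Simulate a cohort with participant parameters drawn from a population.

    ``population`` maps condition -> {parameter: (mean, sd)}; every model
    parameter plus ``error`` must be given.  Participant values are drawn
    from normal distributions truncated to each parameter's support
    (:data:`PARAM_SUPPORT`).  Returns the dataset and the true-parameter
    table (participant_id, condition, parameter, value).
    """
    if n_participants < 1:
        raise ValueError("n_participants must be >= 1")
    needed = set(MODEL_PARAMS[model_id]) | {"error"}
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    rows = []
    for i in range(1, n_participants + 1):
        pid = f"sim{i:03d}"
        for condition, spec in population.items():
            missing = needed - set(spec)
            if missing:
                raise ValueError(f"population spec for {condition!r} missing {sorted(missing)}")
            for pname in sorted(needed):
                mean, sd = spec[pname]
                lo, hi = PARAM_SUPPORT[pname]
                rows.append({"participant_id": pid, "condition": condition,
                             "parameter": pname,
                             "value": _truncnorm_draw(rng, mean, sd, lo, hi)})
    truth = pd.DataFrame(rows)
    dataset = simulate_from_params(truth, model_id, config,
                                   seed=int(np.random.SeedSequence(seed).generate_state(1)[0] % (2**31)))
    dataset.meta.update({"source": "simulate_cohort", "seed": seed,
                         "population": {c: {p: list(v) for p, v in s.items()}
                                        for c, s in population.items()}})
    return dataset, truth


# ---------------------------------------------------------------------------
# indifference points and quality control
# ---------------------------------------------------------------------------

def empirical_indifference_point(block: Sequence[ChoiceTrial] | pd.DataFrame,
                                 config: StaircaseConfig = StaircaseConfig()) -> float:
    """Titration estimate of the indifference point from one complete block.

    Defined as the immediate amount a hypothetical sixth trial would offer:
    the final offer adjusted once more by the final (1-unit) step in the
    direction of the final choice.
    """
    if isinstance(block, pd.DataFrame):
        block = block.sort_values("trial")
        offers = block["amount_immediate"].to_numpy(dtype=float)
        choices = block["choice"].to_numpy(dtype=int)
    else:
        block = sorted(block, key=lambda t: t.trial)
        offers = np.array([t.immediate.amount for t in block], dtype=float)
        choices = np.array([t.choice for t in block], dtype=int)
    if len(offers) != config.choices_per_block:
        raise ValueError(f"incomplete block: expected {config.choices_per_block} trials, "
                         f"got {len(offers)}")
    final_step = config.steps[-1]
    return float(offers[-1] + final_step if choices[-1] == 1 else offers[-1] - final_step)


def indifference_points(dataset: ChoiceDataset,
                        config: StaircaseConfig = StaircaseConfig()) -> pd.DataFrame:
    """Per participant/condition/run/delay titration indifference points."""
    rows = []
    for keys, block in dataset.trials.groupby(
            ["participant_id", "condition", "run", "block"]):
        rows.append({
            "participant_id": keys[0], "condition": keys[1], "run": keys[2],
            "delay_days": float(block["delay_days"].iloc[0]),
            "indifference_point": empirical_indifference_point(block, config)})
    return pd.DataFrame(rows).sort_values(
        ["participant_id", "condition", "delay_days", "run"]).reset_index(drop=True)


def qc_filter(dataset: ChoiceDataset, one_sided_threshold: float = 0.9,
              rt_limit_s: float = 12.0, rt_fraction: float = 0.5
              ) -> tuple[ChoiceDataset, pd.DataFrame]:
    """Exclude non-discounters and inattentive participants.

    A participant is excluded when, pooled over all their trials, they chose
    the same option in strictly more than 90% of trials (no systematic
    discounting), or — when reaction times are recorded — more than half of
    their trials exceed 12 s (loss of focus).  Returns the retained dataset
    and an exclusion report (participant_id, reason, value).
    """
    report_rows = []
    excluded = set()
    for pid, sub in dataset.trials.groupby("participant_id"):
        frac_delayed = sub["choice"].mean()
        frac_same = max(frac_delayed, 1.0 - frac_delayed)
        if frac_same > one_sided_threshold:
            excluded.add(pid)
            report_rows.append({"participant_id": pid, "reason": "one_sided_choices",
                                "value": frac_same})
            continue
        rts = sub["rt_s"].dropna()
        if len(rts) == len(sub) and len(rts) > 0:
            frac_slow = float((rts > rt_limit_s).mean())
            if frac_slow > rt_fraction:
                excluded.add(pid)
                report_rows.append({"participant_id": pid, "reason": "slow_reaction_times",
                                    "value": frac_slow})
    retained = dataset.trials[~dataset.trials["participant_id"].isin(excluded)]
    report = pd.DataFrame(report_rows, columns=["participant_id", "reason", "value"])
    return ChoiceDataset(retained.reset_index(drop=True), dict(dataset.meta)), report
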