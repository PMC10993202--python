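"""Shared fixtures: small synthetic cohorts and cached reduced-scale fits.

Fits are session-scoped because MCMC dominates suite runtime; every test
that only inspects a posterior shares the same cached fit.
"""

import pytest

from tempodisc import FitConfig, build_model, fit, simulate_cohort

POP_EXP = {"k": (0.05, 0.02), "error": (0.05, 0.02)}
POP_EXP_SCALED = {"k": (0.05, 0.02), "s": (1.0, 0.0), "error": (0.05, 0.0)}


@pytest.fixture(scope="session")
def small_exp_dataset():
    """Six exponential discounters, both conditions (720 trials)."""
    dataset, truth = simulate_cohort(
        6, {"food": POP_EXP, "money": POP_EXP}, "exp", seed=11)
    return dataset, truth


@pytest.fixture(scope="session")
def tiny_exp_fit(small_exp_dataset):
    """Short two-chain fit of the exp model to the food condition."""
    dataset, _ = small_exp_dataset
    model = build_model(dataset, "food", "exp")
    return model, fit(model, FitConfig(warmup=400, draws=200, chains=2, seed=21))


@pytest.fixture(scope="session")
def cohort_exp_scaled_fit():
    """Ten participants simulated from exponential discounting with scaling
    (population k 0.05 +/- 0.02, s = 1, lapse 0.05) fitted with the matching
    hierarchical model at the reduced-scale settings (2,000 warm-up, 500
    draws, 4 chains)."""
    dataset, truth = simulate_cohort(
        10, {"food": POP_EXP_SCALED}, "exp_scaled", seed=1)
    model = build_model(dataset, "food", "exp_scaled")
    samples = fit(model, FitConfig(warmup=2000, draws=500, chains=4, seed=3))
    return dataset, truth, model, samples
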