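"""Diagnostic figure: titration indifference points against fitted SV curves."""

from __future__ import annotations

import numpy as np

from .models import SVModelParams, subjective_value
from .task import ChoiceDataset, StaircaseConfig, indifference_points

__all__ = ["plot_discounting_fit"]


def plot_discounting_fit(dataset: ChoiceDataset, participant_id: str, condition: str,
                         params_list, labels=None,
                         config: StaircaseConfig = StaircaseConfig(), ax=None):
    """Plot one participant's indifference points with model SV curves.

    ``params_list`` holds one or more :class:`SVModelParams` (e.g. the
    posterior-mean one- and two-parameter exponential fits) evaluated over
    the task's delay range for a 40-unit delayed reward.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 3.5))
    ips = indifference_points(dataset, config)
    sub = ips[(ips["participant_id"] == participant_id) & (ips["condition"] == condition)]
    ax.scatter(sub["delay_days"], sub["indifference_point"],
               color="tab:orange", zorder=3, label="indifference points")
    delays = np.linspace(0, max(config.delays_days), 400)
    for i, params in enumerate(params_list):
        label = labels[i] if labels else params.model_id
        sv = subjective_value(params=params, amount=config.delayed_amount, delay=delays)
        ax.plot(delays, sv, label=label)
    ax.set_xlabel("delay (days)")
    ax.set_ylabel(f"SV of {config.delayed_amount:g} units")
    ax.set_title(f"{participant_id} / {condition}")
    ax.legend(fontsize=8)
    return ax
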