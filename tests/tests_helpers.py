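"""Helpers shared across test modules."""

import numpy as np
import pandas as pd

from micromod.events import SpikeTrainSet, TrialTable


def flat_spikes_and_trials(n_units=4, n_trials=40, rate=5.0, seed=0):
    """Homogeneous Poisson units: task statistics match baseline, no tuning."""
    rng = np.random.default_rng(seed)
    spacing, base = 1.5, 2.0
    onsets = base + np.arange(n_trials) * spacing
    total = onsets[-1] + spacing + base
    rows_u, rows_t = [], []
    for u in range(n_units):
        n_spk = rng.poisson(rate * total)
        rows_u.append(np.full(n_spk, u))
        rows_t.append(np.sort(rng.uniform(0, total, n_spk)))
    spikes = SpikeTrainSet(
        spikes=pd.DataFrame(
            {"unit_id": np.concatenate(rows_u), "spike_time_s": np.concatenate(rows_t)}
        ),
        units=pd.DataFrame({"unit_id": np.arange(n_units), "electrode": np.arange(n_units)}),
    )
    cats = ["person", "place", "animal", "object"] * (n_trials // 4)
    trials = TrialTable(
        trials=pd.DataFrame(
            {"trial": np.arange(n_trials), "onset_s": onsets, "category": cats, "correct": True}
        ),
        baseline_periods=[(0.0, base), (total - base, total)],
    )
    return spikes, trials
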