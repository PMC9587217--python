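"""Spike-event and trial containers for the categorization-task analyses."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SpikeTrainSet", "TrialTable", "CATEGORIES"]

#: Default image categories of the recognition task.
CATEGORIES = ("person", "place", "animal", "object")


@dataclass
class SpikeTrainSet:
    """Sorted spike events with unit-to-electrode mapping.

    ``spikes`` has columns ``unit_id`` and ``spike_time_s``; ``units``
    has one row per unit with columns ``unit_id``, ``electrode`` and
    (for synthetic data) ``module``.
    """

    spikes: pd.DataFrame
    units: pd.DataFrame

    def __post_init__(self) -> None:
        need = {"unit_id", "spike_time_s"}
        if not need.issubset(self.spikes.columns):
            raise ValueError(f"spikes table must have columns {need}")
        if "unit_id" not in self.units.columns:
            raise ValueError("units table must have a unit_id column")
        self.spikes = self.spikes.sort_values("spike_time_s").reset_index(drop=True)

    @property
    def unit_ids(self) -> np.ndarray:
        return self.units["unit_id"].to_numpy()

    def times_for(self, unit_id: int) -> np.ndarray:
        sel = self.spikes["unit_id"] == unit_id
        return self.spikes.loc[sel, "spike_time_s"].to_numpy()


@dataclass
class TrialTable:
    """Image-presentation trials plus task baseline periods.

    ``trials`` columns: ``trial``, ``onset_s``, ``category``,
    ``correct``.  ``baseline_periods`` are (start, stop) intervals in
    seconds flanking each block of image presentations; the rate
    transform draws its normalisation statistics only from these.
    """

    trials: pd.DataFrame
    baseline_periods: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        need = {"trial", "onset_s", "category", "correct"}
        if not need.issubset(self.trials.columns):
            raise ValueError(f"trial table must have columns {need}")
        onsets = self.trials["onset_s"].to_numpy()
        if np.any(np.diff(onsets) <= 0):
            raise ValueError("trial onsets must be strictly increasing")

    def correct_trials(self) -> pd.DataFrame:
        """Only trials answered correctly; all analyses are restricted to these."""
        return self.trials[self.trials["correct"].astype(bool)]

    @property
    def categories(self) -> list[str]:
        return sorted(self.trials["category"].unique())
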