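"""Trial x neuron firing-rate tables with task labels.

The :class:`RateDataset` is the common currency between the simulator, the
synthetic-fixture generator and the analysis toolkit: a matrix of
stimulus-period mean rates with per-trial labels (stimulus, category,
choice, correctness, validity) and per-neuron metadata (population,
initial preferred direction where known).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["RateDataset"]

_TRIAL_COLUMNS = ["theta_deg", "category", "choice", "correct", "valid"]


@dataclass
class RateDataset:
    """rates: (n_trials, n_neurons) stimulus-period mean rates (Hz or z-scored).
    trials: DataFrame with columns theta_deg, category, choice, correct, valid.
    neurons: DataFrame with at least a ``pref_deg`` column (NaN if unknown)
    and optionally ``population``."""

    rates: np.ndarray
    trials: pd.DataFrame
    neurons: pd.DataFrame

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=float)
        if self.rates.ndim != 2:
            raise ValueError("rates must be a 2-D trials x neurons array")
        if len(self.trials) != self.rates.shape[0]:
            raise ValueError("trial labels do not match the number of rate rows")
        if len(self.neurons) != self.rates.shape[1]:
            raise ValueError("neuron labels do not match the number of rate columns")
        missing = [c for c in _TRIAL_COLUMNS if c not in self.trials.columns]
        if missing:
            raise ValueError(f"trial table missing columns: {missing}")

    @property
    def n_trials(self) -> int:
        return self.rates.shape[0]

    @property
    def n_neurons(self) -> int:
        return self.rates.shape[1]

    def valid_subset(self) -> "RateDataset":
        mask = self.trials["valid"].to_numpy(dtype=bool)
        return RateDataset(self.rates[mask],
                           self.trials.loc[mask].reset_index(drop=True),
                           self.neurons)

    def zscored(self) -> "RateDataset":
        """Per-neuron z-scores across all trials (zero-variance neurons map to 0)."""
        mu = self.rates.mean(axis=0)
        sd = self.rates.std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
        return RateDataset((self.rates - mu) / sd, self.trials.copy(), self.neurons.copy())

    def tuning_curve(self, neuron: int, *, valid_only: bool = True) -> pd.Series:
        """Mean rate per stimulus direction (all valid trials)."""
        mask = self.trials["valid"].to_numpy(dtype=bool) if valid_only else \
            np.ones(self.n_trials, dtype=bool)
        df = pd.DataFrame({"theta": self.trials["theta_deg"][mask],
                           "rate": self.rates[mask, neuron]})
        return df.groupby("theta")["rate"].mean()

    # ---- persistence (plain CSV; columns r000... hold the rate matrix) ----

    def to_csv(self, path) -> None:
        path = Path(path)
        rate_cols = pd.DataFrame(
            self.rates, columns=[f"r{j:03d}" for j in range(self.n_neurons)])
        wide = pd.concat([self.trials.reset_index(drop=True), rate_cols], axis=1)
        wide.to_csv(path, index=False)
        self.neurons.to_csv(path.with_suffix(".neurons.csv"), index=False)

    @classmethod
    def from_csv(cls, path) -> "RateDataset":
        path = Path(path)
        wide = pd.read_csv(path)
        rate_cols = [c for c in wide.columns if c.startswith("r") and c[1:].isdigit()]
        rate_cols.sort()
        rates = wide[rate_cols].to_numpy(dtype=float)
        trials = wide[[c for c in wide.columns if c not in rate_cols]]
        npath = path.with_suffix(".neurons.csv")
        if npath.exists():
            neurons = pd.read_csv(npath)
        else:
            neurons = pd.DataFrame({"pref_deg": np.full(rates.shape[1], np.nan)})
        return cls(rates, trials, neurons)
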