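"""Binned multi-trial spike trains with unit metadata.

The container mirrors what a multi-area extracellular recording session
provides after binning: a binary (M trials x N bins x U units) spike array,
a stimulus label per trial, and a unit table (area, optional 3-D position).
Plain delimited-text serialization keeps sessions portable: a long-format
``spikes`` table (trial, unit, bin), a ``units`` table and a ``trials``
table.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["SpikeTrainSet", "write_session", "read_session"]


@dataclass
class SpikeTrainSet:
    """Binary spike counts per (trial, bin, unit) plus metadata.

    ``spikes`` has shape (M, N, U) with values in {0, 1}; ``units`` is a
    DataFrame indexed by unit id (columns at least ``area``; optionally
    ``x``/``y``/``z`` positions in micrometres) whose row order matches the
    last axis of ``spikes``; ``trial_stimulus`` labels each trial with its
    stimulus type.
    """

    spikes: np.ndarray
    trial_stimulus: np.ndarray
    units: pd.DataFrame
    bin_ms: float = 1.0

    def __post_init__(self):
        self.spikes = np.asarray(self.spikes)
        self.trial_stimulus = np.asarray(self.trial_stimulus)
        if self.spikes.ndim != 3:
            raise ValueError("spikes must have shape (trials, bins, units)")
        if not np.isin(self.spikes, (0, 1)).all():
            raise ValueError("spike counts must be binary per bin")
        if len(self.trial_stimulus) != self.spikes.shape[0]:
            raise ValueError("one stimulus label per trial required")
        if len(self.units) != self.spikes.shape[2]:
            raise ValueError("unit table must match the spike array")

    @property
    def n_trials(self) -> int:
        return self.spikes.shape[0]

    @property
    def n_bins(self) -> int:
        return self.spikes.shape[1]

    @property
    def n_units(self) -> int:
        return self.spikes.shape[2]

    @property
    def unit_ids(self) -> np.ndarray:
        return self.units.index.to_numpy()

    @property
    def stimulus_types(self) -> list:
        return sorted(set(self.trial_stimulus.tolist()))

    def mean_count_per_bin(self) -> np.ndarray:
        """Mean spike count per bin per unit (the CCG rate lambda)."""
        return self.spikes.mean(axis=(0, 1))

    def rates_hz(self, stimulus=None) -> pd.Series:
        """Mean firing rate in spikes/s, optionally for one stimulus type."""
        d = self if stimulus is None else self.select_trials(stimulus)
        return pd.Series(
            d.mean_count_per_bin() * 1000.0 / self.bin_ms, index=self.units.index
        )

    def select_trials(self, stimulus) -> "SpikeTrainSet":
        mask = self.trial_stimulus == stimulus
        if not mask.any():
            raise ValueError(f"no trials with stimulus {stimulus!r}")
        return replace(
            self, spikes=self.spikes[mask], trial_stimulus=self.trial_stimulus[mask]
        )

    def select_units(self, unit_ids) -> "SpikeTrainSet":
        pos = self.units.index.get_indexer(list(unit_ids))
        if (pos < 0).any():
            raise KeyError("unknown unit id(s)")
        return replace(
            self, spikes=self.spikes[:, :, pos], units=self.units.iloc[pos].copy()
        )

    def train(self, unit_id) -> np.ndarray:
        """(M, N) binary train of one unit."""
        return self.spikes[:, :, self.units.index.get_loc(unit_id)]


def write_session(data: SpikeTrainSet, outdir) -> None:
    """Write spikes/units/trials delimited tables under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    m, t, u = np.nonzero(data.spikes)
    pd.DataFrame(
        {"trial": m, "unit": data.unit_ids[u], "bin": t}
    ).to_csv(outdir / "spikes.csv", index=False)
    units = data.units.copy()
    units["rate_hz"] = data.rates_hz()
    units.rename_axis("unit").to_csv(outdir / "units.csv")
    pd.DataFrame(
        {
            "trial": np.arange(data.n_trials),
            "stimulus": data.trial_stimulus,
            "n_bins": data.n_bins,
            "bin_ms": data.bin_ms,
        }
    ).to_csv(outdir / "trials.csv", index=False)


def read_session(indir) -> SpikeTrainSet:
    indir = Path(indir)
    spikes_tab = pd.read_csv(indir / "spikes.csv")
    units = pd.read_csv(indir / "units.csv", index_col="unit")
    trials = pd.read_csv(indir / "trials.csv")
    n_trials = len(trials)
    n_bins = int(trials["n_bins"].iloc[0])
    bin_ms = float(trials["bin_ms"].iloc[0])
    unit_pos = {uid: i for i, uid in enumerate(units.index)}
    spikes = np.zeros((n_trials, n_bins, len(units)), dtype=np.uint8)
    spikes[
        spikes_tab["trial"].to_numpy(),
        spikes_tab["bin"].to_numpy(),
        [unit_pos[u] for u in spikes_tab["unit"]],
    ] = 1
    units = units.drop(columns=["rate_hz"], errors="ignore")
    return SpikeTrainSet(
        spikes=spikes,
        trial_stimulus=trials["stimulus"].to_numpy(),
        units=units,
        bin_ms=bin_ms,
    )
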