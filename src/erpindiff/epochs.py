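"""Epoched-EEG container.

Epochs are held densely as a (n_trials, n_channels, n_times) array of
microvolt amplitudes plus a per-trial metadata table, which is the natural
in-memory layout for filtering and smoothing.  The on-disk interchange format
is a long table (participant, trial, item, condition, assignment flag,
electrode, time in ms, amplitude in uV) with a JSON metadata sidecar.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

#: analysed scalp sites (centro-parietal grid used in the sentence-processing
#: ERP literature)
ELECTRODES_OF_INTEREST = [
    "FC1", "FC2", "C3", "Cz", "C4", "CP1", "CP2", "CP5", "CP6", "Pz", "P3", "P4",
]

#: the four experimental conditions of the grammaticality x markedness design
EXPERIMENTAL_CONDITIONS = ["GramMasc", "GramFem", "UngramMasc", "UngramFem"]

#: error type -> (grammatical condition, ungrammatical condition).
#: A masculine noun with a feminine adjective is a Feature Clash error; a
#: feminine noun with a masculine (default) adjective is a Default error.
ERROR_PAIRS = {
    "FeatureClash": ("GramMasc", "UngramMasc"),
    "Default": ("GramFem", "UngramFem"),
}

TRIAL_COLUMNS = ["participant_id", "trial_id", "item_id", "condition", "assignment_correct"]


@dataclass
class EpochTable:
    """Dense epoched EEG with trial metadata.

    Attributes
    ----------
    data : ndarray, shape (n_trials, n_channels, n_times)
        Amplitudes in microvolts.
    trials : DataFrame
        One row per trial with columns ``participant_id``, ``trial_id``,
        ``item_id``, ``condition``, ``assignment_correct``.
    channels : list of str
        Electrode labels, ordered as the channel axis of ``data``.
    times : ndarray
        Sample times in ms relative to the critical word.
    sampling_rate_hz : float
    epoch_window_ms : tuple of float
    reference_state : str
        Free-text record of the referencing applied (e.g. ``"as-recorded"``,
        ``"mastoid_average"``).
    """

    data: np.ndarray
    trials: pd.DataFrame
    channels: list[str]
    times: np.ndarray
    sampling_rate_hz: float
    epoch_window_ms: tuple[float, float] = (-200.0, 950.0)
    reference_state: str = "as-recorded"
    log: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (n_trials, n_channels, n_times)")
        n_trials, n_channels, n_times = self.data.shape
        if len(self.trials) != n_trials:
            raise ValueError("trials table length does not match data")
        if len(self.channels) != n_channels:
            raise ValueError("channel list does not match data")
        if len(self.times) != n_times:
            raise ValueError("time vector does not match data")
        if n_times > 1:
            steps = np.diff(self.times)
            if not np.allclose(steps, steps[0]):
                raise ValueError("time grid must be regular")
        missing = [c for c in TRIAL_COLUMNS if c not in self.trials.columns]
        if missing:
            raise ValueError(f"trials table missing columns: {missing}")
        self.trials = self.trials.reset_index(drop=True)

    # -- basic views ------------------------------------------------------

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def channel_index(self, name: str) -> int:
        try:
            return self.channels.index(name)
        except ValueError:
            raise KeyError(f"unknown electrode {name!r}; have {self.channels}") from None

    def copy(self) -> "EpochTable":
        return replace(
            self,
            data=self.data.copy(),
            trials=self.trials.copy(),
            channels=list(self.channels),
            times=self.times.copy(),
            log=dict(self.log),
        )

    def select_trials(self, mask: np.ndarray) -> "EpochTable":
        """Return a new table with the masked subset of trials, order kept."""
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return replace(
            self,
            data=self.data[idx],
            trials=self.trials.iloc[idx].reset_index(drop=True),
        )

    @property
    def meta(self) -> dict:
        return {
            "sampling_rate_hz": self.sampling_rate_hz,
            "epoch_window_ms": list(self.epoch_window_ms),
            "reference_state": self.reference_state,
        }

    # -- long-format interchange -----------------------------------------

    def to_long(self) -> pd.DataFrame:
        """Expand to the long interchange layout (one row per sample)."""
        n_trials, n_channels, n_times = self.data.shape
        base = self.trials.loc[
            np.repeat(np.arange(n_trials), n_channels * n_times), TRIAL_COLUMNS
        ].reset_index(drop=True)
        base["electrode"] = np.tile(np.repeat(self.channels, n_times), n_trials)
        base["time_ms"] = np.tile(self.times, n_trials * n_channels)
        base["amplitude_uv"] = self.data.reshape(-1)
        return base

    @classmethod
    def from_long(cls, frame: pd.DataFrame, meta: dict) -> "EpochTable":
        """Rebuild the dense container from the long layout.

        Trials, channels and times are ordered by first appearance so that a
        ``to_long`` round trip is the identity.
        """
        for col in ("electrode", "time_ms", "amplitude_uv"):
            if col not in frame.columns:
                raise ValueError(f"long table missing column {col!r}")
        trial_keys = frame[["participant_id", "trial_id"]].drop_duplicates()
        channels = list(pd.unique(frame["electrode"]))
        times = np.sort(pd.unique(frame["time_ms"]).astype(float))
        n_trials, n_channels, n_times = len(trial_keys), len(channels), len(times)
        if len(frame) != n_trials * n_channels * n_times:
            raise ValueError("long table is not a complete trial x electrode x time grid")
        t_code = frame[["participant_id", "trial_id"]].apply(tuple, axis=1).map(
            {tuple(row): i for i, row in enumerate(trial_keys.to_numpy())}
        )
        c_code = frame["electrode"].map({c: i for i, c in enumerate(channels)})
        s_code = np.searchsorted(times, frame["time_ms"].to_numpy(dtype=float))
        data = np.full((n_trials, n_channels, n_times), np.nan)
        data[t_code.to_numpy(), c_code.to_numpy(), s_code] = frame["amplitude_uv"].to_numpy()
        if np.isnan(data).any():
            raise ValueError("long table has duplicate or missing samples")
        trials = (
            frame.loc[:, TRIAL_COLUMNS]
            .drop_duplicates(subset=["participant_id", "trial_id"])
            .reset_index(drop=True)
        )
        window = tuple(meta.get("epoch_window_ms", (times[0], times[-1])))
        return cls(
            data=data,
            trials=trials,
            channels=channels,
            times=times,
            sampling_rate_hz=float(meta["sampling_rate_hz"]),
            epoch_window_ms=(float(window[0]), float(window[1])),
            reference_state=str(meta.get("reference_state", "as-recorded")),
        )

    def to_csv(self, path: str | Path) -> Path:
        """Write the long layout as gzipped CSV with a JSON metadata sidecar."""
        path = Path(path)
        self.to_long().to_csv(path, index=False, compression="gzip" if path.suffix == ".gz" else None)
        sidecar = path.with_suffix(path.suffix + ".meta.json")
        sidecar.write_text(json.dumps(self.meta, indent=2))
        return path

    @classmethod
    def read_csv(cls, path: str | Path) -> "EpochTable":
        path = Path(path)
        sidecar = path.with_suffix(path.suffix + ".meta.json")
        meta = json.loads(sidecar.read_text())
        frame = pd.read_csv(path)
        return cls.from_long(frame, meta)
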