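"""Deterministic signal conditioning of epoch tables.

Re-referencing to the mastoid average, a zero-phase 0.1-30 Hz order-2
(12 dB/octave) Butterworth band-pass, baseline correction over the
pre-stimulus interval, and the correct-gender-assignment trial filter.
Filtering is applied per epoch with 100 ms reflection padding; the zero-phase
forward-backward pass keeps latency measures unbiased by filter delay.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

from erpindiff.epochs import EpochTable

MASTOID_CHANNELS = ("M1", "M2")


@dataclass
class PreprocConfig:
    reference: str = "none"                      # "mastoid_average" | "none"
    band_hz: tuple[float, float] = (0.1, 30.0)
    filter_order: int = 2                        # 12 dB/octave per edge
    epoch_window_ms: tuple[float, float] = (-200.0, 950.0)
    baseline_window_ms: tuple[float, float] = (-200.0, 0.0)
    drop_incorrect_assignment: bool = True
    pad_ms: float = 100.0

    def validate(self, sampling_rate_hz: float | None = None) -> None:
        lo, hi = self.band_hz
        if not 0 < lo < hi:
            raise ValueError("band_hz must satisfy 0 < low < high")
        if sampling_rate_hz is not None and hi >= sampling_rate_hz / 2:
            raise ValueError("band high edge must be below Nyquist")
        b0, b1 = self.baseline_window_ms
        e0, e1 = self.epoch_window_ms
        if not (e0 <= b0 < b1 <= e1):
            raise ValueError("baseline window must lie inside the epoch window")
        if self.reference not in ("none", "mastoid_average"):
            raise ValueError(f"unknown reference {self.reference!r}")


def rereference(epochs: EpochTable, cfg: PreprocConfig) -> EpochTable:
    """Subtract the mastoid average from every channel at every sample."""
    if cfg.reference == "none":
        return epochs.copy()
    missing = [m for m in MASTOID_CHANNELS if m not in epochs.channels]
    if missing:
        raise ValueError(f"mastoid_average reference needs channels {missing}")
    out = epochs.copy()
    idx = [epochs.channel_index(m) for m in MASTOID_CHANNELS]
    ref = out.data[:, idx, :].mean(axis=1, keepdims=True)
    out.data = out.data - ref
    out.reference_state = "mastoid_average"
    return out


def bandpass(epochs: EpochTable, cfg: PreprocConfig) -> EpochTable:
    """Zero-phase Butterworth band-pass (order ``filter_order`` per edge)."""
    cfg.validate(epochs.sampling_rate_hz)
    sos = signal.butter(
        cfg.filter_order, cfg.band_hz, btype="bandpass", fs=epochs.sampling_rate_hz, output="sos"
    )
    n_times = epochs.data.shape[-1]
    padlen = min(int(round(cfg.pad_ms * epochs.sampling_rate_hz / 1000.0)), n_times - 1)
    out = epochs.copy()
    flat = out.data.reshape(-1, n_times)
    out.data = signal.sosfiltfilt(sos, flat, axis=-1, padtype="odd", padlen=padlen).reshape(out.data.shape)
    return out


def baseline_correct(epochs: EpochTable, cfg: PreprocConfig) -> EpochTable:
    """Subtract the per-trial, per-electrode mean over the baseline window."""
    b0, b1 = cfg.baseline_window_ms
    mask = (epochs.times >= b0) & (epochs.times <= b1)
    if not mask.any():
        raise ValueError("baseline window contains no samples")
    out = epochs.copy()
    out.data = out.data - out.data[:, :, mask].mean(axis=-1, keepdims=True)
    return out


def filter_trials(epochs: EpochTable) -> tuple[EpochTable, dict]:
    """Keep only trials where the gender value was assigned correctly.

    Returns the filtered table and a log with retained/dropped counts per
    participant x condition; empty cells are recorded as warnings.
    """
    if "assignment_correct" not in epochs.trials.columns:
        raise ValueError("trials table has no assignment_correct column")
    flags = epochs.trials["assignment_correct"].astype(bool).to_numpy()
    out = epochs.select_trials(flags)
    before = epochs.trials.groupby(["participant_id", "condition"]).size()
    after = out.trials.groupby(["participant_id", "condition"]).size().reindex(before.index, fill_value=0)
    warnings = [
        f"participant {p} condition {c}: no correct-assignment trials left"
        for (p, c), n in after.items()
        if n == 0
    ]
    log = {
        "retained": int(flags.sum()),
        "dropped": int((~flags).sum()),
        "per_cell": {f"{p}/{c}": int(n) for (p, c), n in after.items()},
        "warnings": warnings,
    }
    return out, log


def preprocess(epochs: EpochTable, cfg: PreprocConfig) -> tuple[EpochTable, dict]:
    """Run the full conditioning chain; returns the table and a stage log."""
    cfg.validate(epochs.sampling_rate_hz)
    log: dict = {"stages": [], "params": {"band_hz": list(cfg.band_hz), "reference": cfg.reference}}
    out = rereference(epochs, cfg)
    log["stages"].append({"stage": "rereference", "n_trials": out.n_trials})
    out = bandpass(out, cfg)
    log["stages"].append({"stage": "bandpass", "n_trials": out.n_trials})
    out = baseline_correct(out, cfg)
    log["stages"].append({"stage": "baseline_correct", "n_trials": out.n_trials})
    if cfg.drop_incorrect_assignment:
        out, flog = filter_trials(out)
        log["stages"].append({"stage": "filter_trials", "n_trials": out.n_trials, **flog})
    out.log = log
    return out, log
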