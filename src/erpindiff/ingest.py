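"""Readers and converters for real-data reproduction.

Epochs come in either as the package's long CSV interchange format or as
standard epoched EEG files through MNE (FIF epoch files directly;
BrainVision/EDF recordings segmented around marker events).  Amplitudes are
normalized to microvolts and times to milliseconds.  Questionnaire tables
come in as one CSV row per participant x language x modality.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from erpindiff.epochs import EpochTable
from erpindiff.scores import MODALITIES


def to_mne(epochs: EpochTable):
    """Convert to an :class:`mne.EpochsArray` (volts, seconds)."""
    import mne

    info = mne.create_info(epochs.channels, sfreq=epochs.sampling_rate_hz, ch_types="eeg")
    events = np.column_stack(
        [
            np.arange(epochs.n_trials) * epochs.data.shape[-1],
            np.zeros(epochs.n_trials, dtype=int),
            pd.factorize(epochs.trials["condition"])[0] + 1,
        ]
    )
    event_id = {c: i + 1 for i, c in enumerate(pd.factorize(epochs.trials["condition"])[1])}
    out = mne.EpochsArray(
        epochs.data * 1e-6,
        info,
        events=events,
        event_id=event_id,
        tmin=epochs.times[0] / 1000.0,
        verbose="error",
    )
    out.metadata = epochs.trials.copy()
    return out


def from_mne(mne_epochs, reference_state: str = "as-recorded") -> EpochTable:
    """Convert an MNE epochs object to an :class:`EpochTable` (uV, ms)."""
    data = mne_epochs.get_data(copy=True) * 1e6
    times = mne_epochs.times * 1000.0
    meta = mne_epochs.metadata
    n = data.shape[0]
    if meta is not None and {"participant_id", "trial_id", "item_id", "condition"} <= set(meta.columns):
        trials = meta.reset_index(drop=True).copy()
        if "assignment_correct" not in trials:
            trials["assignment_correct"] = True
    else:
        inv = {v: k for k, v in mne_epochs.event_id.items()}
        trials = pd.DataFrame(
            {
                "participant_id": "unknown",
                "trial_id": [f"T{i + 1:04d}" for i in range(n)],
                "item_id": [f"I{i + 1:04d}" for i in range(n)],
                "condition": [inv[e] for e in mne_epochs.events[:, 2]],
                "assignment_correct": True,
            }
        )
    return EpochTable(
        data=data,
        trials=trials,
        channels=list(mne_epochs.ch_names),
        times=times,
        sampling_rate_hz=float(mne_epochs.info["sfreq"]),
        epoch_window_ms=(float(times[0]), float(times[-1])),
        reference_state=reference_state,
    )


def read_epochs(path: str | Path, known_electrodes: list[str] | None = None) -> EpochTable:
    """Read epochs from long CSV (+ JSON sidecar) or an MNE-readable file.

    ``known_electrodes``, when given, is used to validate channel labels;
    unknown labels raise with the offending names listed.
    """
    path = Path(path)
    if path.suffix in (".csv", ".gz") or path.name.endswith(".csv.gz"):
        table = EpochTable.read_csv(path)
    elif path.name.endswith(("-epo.fif", "-epo.fif.gz", ".fif")):
        import mne

        table = from_mne(mne.read_epochs(path, preload=True, verbose="error"))
    else:
        raise ValueError(f"unsupported epoch format: {path.name}")
    if known_electrodes is not None:
        unknown = [c for c in table.channels if c not in known_electrodes]
        if unknown:
            raise ValueError(f"unknown electrode labels: {unknown}")
    return table


def read_raw_segmented(
    path: str | Path,
    epoch_window_ms: tuple[float, float] = (-200.0, 950.0),
    event_id: dict | None = None,
) -> EpochTable:
    """Segment a continuous BrainVision (.vhdr) or EDF recording into epochs
    around its annotation markers."""
    import mne

    raw = mne.io.read_raw(str(path), preload=True, verbose="error")
    events, found = mne.events_from_annotations(raw, verbose="error")
    epochs = mne.Epochs(
        raw,
        events,
        event_id=event_id or found,
        tmin=epoch_window_ms[0] / 1000.0,
        tmax=epoch_window_ms[1] / 1000.0,
        baseline=None,
        preload=True,
        verbose="error",
    )
    return from_mne(epochs)


def resample(epochs: EpochTable, target_hz: float) -> EpochTable:
    """Polyphase resampling along time (e.g. 1000 Hz -> 250 Hz)."""
    from fractions import Fraction

    frac = Fraction(target_hz / epochs.sampling_rate_hz).limit_denominator(1000)
    data = signal.resample_poly(epochs.data, frac.numerator, frac.denominator, axis=-1)
    out = epochs.copy()
    out.data = data
    n = data.shape[-1]
    out.times = epochs.times[0] + 1000.0 / target_hz * np.arange(n)
    out.sampling_rate_hz = float(target_hz)
    return out


def read_questionnaire(path: str | Path) -> pd.DataFrame:
    """Read a long questionnaire CSV into the wide cohort layout.

    Expected columns: participant_id, language, modality, hours, rating,
    plus per-participant age, aoa, years_of_use, instruction, lextale.
    """
    frame = pd.read_csv(path)
    required = {"participant_id", "language", "modality", "hours", "rating"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"questionnaire CSV missing columns: {sorted(missing)}")
    frame["language"] = frame["language"].str.lower()
    frame["modality"] = frame["modality"].str.lower()
    bad = set(frame["modality"]) - {m.lower() for m in MODALITIES}
    if bad:
        raise ValueError(f"unknown modalities: {sorted(bad)}")
    wide = frame.pivot_table(
        index="participant_id", columns=["language", "modality"], values=["hours", "rating"]
    )
    wide.columns = [f"{v}_{lang}_{mod}" for v, lang, mod in wide.columns]
    per_part = frame.drop_duplicates("participant_id").set_index("participant_id")
    for col in ("age", "instruction", "lextale"):
        wide[col] = per_part[col]
    for lang in ("spanish", "english"):
        wide[f"aoa_{lang}"] = per_part.get(f"aoa_{lang}", 0.0)
        wide[f"you_{lang}"] = per_part.get(f"you_{lang}", per_part["age"])
    return wide.reset_index()
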