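"""Synthetic cohort and epoched-EEG generator.

The generator emulates the study design downstream stages expect: 39
heritage-bilingual participants, a 2x2 Grammaticality x Markedness
grammaticality-judgment task with 40 trials per condition drawn from one of
three stimulus lists, and 12 centro-parietal electrodes of interest.

Generative model for a single trial at electrode ``e`` and time ``t``::

    amplitude(t) = sum_c s_c(condition) * gain_e * A_c(participant, error)
                   * g_c(t)  +  u_item  +  eps(t)

where ``g_c`` is a unit Gaussian bump (centre and width per component),
``s_c`` switches the N400 and P600 components on for ungrammatical trials
only, and the participant-level amplitude is linear in the covariates::

    A_c(p, error) = base_amp_c(error) + sum_k beta[c, error, k] * x_k(p)
                    + participant deviation

``u_item`` is a per-item offset (Normal, item sd) and ``eps`` stationary
AR(1) noise, independent across trials and electrodes.  With all noise sds at
zero the waveform equals the analytic template exactly, which the extraction
tests rely on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from erpindiff.design import StimulusDesign, build_lists
from erpindiff.epochs import ELECTRODES_OF_INTEREST, EpochTable

ERROR_TYPES = ("Default", "FeatureClash")
#: ungrammatical condition -> error type
CONDITION_ERROR = {"UngramMasc": "FeatureClash", "UngramFem": "Default"}

#: relative component gain per electrode; centro-parietal sites carry the
#: largest signal, mirroring the central-posterior scalp distribution of the
#: P600 and the (here centro-parietal) N400.
DEFAULT_TOPOGRAPHY = {
    "Cz": 1.0, "CP1": 1.0, "CP2": 1.0, "Pz": 1.0,
    "C3": 0.9, "C4": 0.9, "P3": 0.9, "P4": 0.9,
    "FC1": 0.8, "FC2": 0.8, "CP5": 0.8, "CP6": 0.8,
}

_STREAMS = {"design": 0, "cohort": 1, "items": 2, "epochs": 3, "assignment": 4}


def stream_rng(seed: int, stage: str) -> np.random.Generator:
    """Deterministic per-stage random stream derived from the single run seed."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(_STREAMS[stage],)))


@dataclass
class ComponentTemplate:
    """Gaussian component template; ``base_amp_uv`` is signed per error type
    (negative for the N400), so polarity is carried by the sign."""

    center_ms: float
    width_ms: float
    base_amp_uv: dict[str, float]

    def curve(self, times_ms: np.ndarray) -> np.ndarray:
        return np.exp(-((times_ms - self.center_ms) ** 2) / (2.0 * self.width_ms**2))


@dataclass
class NoiseModel:
    trial_sd: float = 8.0        # stationary sd of the AR(1) noise, uV
    item_sd: float = 1.0         # per-item constant offset, uV
    participant_sd: float = 0.8  # per participant x component x error amplitude, uV
    ar1: float = 0.95            # AR(1) coefficient at the working sampling rate


def default_templates() -> dict[str, ComponentTemplate]:
    # Larger base effects for Feature Clash than Default errors (markedness).
    return {
        "N400": ComponentTemplate(420.0, 80.0, {"Default": -1.8, "FeatureClash": -2.4}),
        "P600": ComponentTemplate(650.0, 150.0, {"Default": 2.2, "FeatureClash": 2.8}),
    }


def default_effect_map() -> dict[tuple[str, str, str], float]:
    """Covariate -> component-amplitude effects, uV per raw covariate unit.

    The defaults reproduce the qualitative individual-differences pattern the
    pipeline is built to detect: proficiency raises the P600 for both error
    types; Spanish exposure share deepens the N400 for Default errors only;
    formal instruction deepens the N400 and shrinks the P600 for Feature
    Clash errors.
    """
    return {
        ("P600", "Default", "lextale"): 0.10,
        ("P600", "FeatureClash", "lextale"): 0.10,
        ("N400", "Default", "ratio_exposure"): -4.0,
        ("N400", "FeatureClash", "instruction"): -1.5,
        ("P600", "FeatureClash", "instruction"): -1.5,
    }


@dataclass
class CohortConfig:
    """Cohort- and recording-level parameters of the generator."""

    n_participants: int = 39
    electrodes: list[str] = field(default_factory=lambda: list(ELECTRODES_OF_INTEREST))
    trials_per_condition: int = 40
    sampling_rate_hz: float = 250.0
    epoch_window_ms: tuple[float, float] = (-200.0, 950.0)
    templates: dict[str, ComponentTemplate] = field(default_factory=default_templates)
    effect_map: dict[tuple[str, str, str], float] = field(default_factory=default_effect_map)
    latency_effect_map: dict[tuple[str, str, str], float] = field(default_factory=dict)
    noise: NoiseModel = field(default_factory=NoiseModel)
    topography: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_TOPOGRAPHY))
    assignment_error_rate: float = 0.1
    n_instructed: int = 18      # participants with formal instruction (of 39)
    mean_spanish_share: float = 0.32
    sd_spanish_share: float = 0.23
    lextale_mean: float = 64.7
    lextale_sd: float = 8.91
    age_mean: float = 20.0
    age_sd: float = 1.55
    aoa_english_mean: float = 3.7
    aoa_english_sd: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be at least 1")
        if not self.electrodes:
            raise ValueError("electrodes must be nonempty")
        if self.trials_per_condition < 1:
            raise ValueError("trials_per_condition must be at least 1")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        lo, hi = self.epoch_window_ms
        if lo >= hi:
            raise ValueError("epoch_window_ms must be an increasing interval")
        for name, tpl in self.templates.items():
            if tpl.width_ms <= 0:
                raise ValueError(f"templates[{name}].width_ms must be positive")
            if not (lo <= tpl.center_ms <= hi):
                raise ValueError(f"templates[{name}].center_ms outside epoch_window_ms")
        if not 0.0 <= self.assignment_error_rate < 1.0:
            raise ValueError("assignment_error_rate must lie in [0, 1)")
        if not 0.0 <= abs(self.noise.ar1) < 1.0:
            raise ValueError("noise.ar1 must lie in (-1, 1)")
        for sd in ("trial_sd", "item_sd", "participant_sd"):
            if getattr(self.noise, sd) < 0:
                raise ValueError(f"noise.{sd} must be non-negative")
        missing = [e for e in self.electrodes if e not in self.topography]
        if missing:
            raise ValueError(f"topography missing electrodes: {missing}")

    def times_ms(self) -> np.ndarray:
        lo, hi = self.epoch_window_ms
        dt = 1000.0 / self.sampling_rate_hz
        n = int(np.floor((hi - lo) / dt)) + 1
        return lo + dt * np.arange(n)


@dataclass
class ParticipantProfile:
    """Questionnaire record of one synthetic participant.

    ``hours`` and ``ratings`` are {language: {modality: value}} nested dicts;
    ages of acquisition and years of use are per language (the same AoA is
    used for all four modalities).
    """

    participant_id: str
    hours: dict[str, dict[str, float]]
    ratings: dict[str, dict[str, float]]
    age: float
    aoa: dict[str, float]
    years_of_use: dict[str, float]
    instruction: bool
    lextale: float
    list_id: int = 1

    def to_row(self) -> dict:
        row = {
            "participant_id": self.participant_id,
            "age": self.age,
            "instruction": self.instruction,
            "lextale": self.lextale,
            "list_id": self.list_id,
        }
        for lang in ("spanish", "english"):
            row[f"aoa_{lang}"] = self.aoa[lang]
            row[f"you_{lang}"] = self.years_of_use[lang]
            for mod, v in self.hours[lang].items():
                row[f"hours_{lang}_{mod}"] = v
            for mod, v in self.ratings[lang].items():
                row[f"rating_{lang}_{mod}"] = v
        return row


def cohort_frame(profiles: list[ParticipantProfile]) -> pd.DataFrame:
    return pd.DataFrame([p.to_row() for p in profiles])


#: mean total daily hours per modality across both languages
_TOTAL_HOURS = {"reading": 2.5, "writing": 1.5, "speaking": 3.5, "listening": 4.5}


def _beta_params(mean: float, sd: float) -> tuple[float, float]:
    nu = mean * (1 - mean) / sd**2 - 1.0
    if nu <= 0:
        raise ValueError("sd_spanish_share too large for the given mean")
    return mean * nu, (1 - mean) * nu


def sample_cohort(cfg: CohortConfig, rng: np.random.Generator | None = None) -> list[ParticipantProfile]:
    """Draw a cohort of participant profiles from the configured distributions.

    The participant-level Spanish share of daily use follows a Beta law with
    the configured mean/sd (so the Ratio of Exposure and Use inherits that
    mean); modality totals get mild lognormal variation and per-modality
    jitter on the share.  Self-ratings track the share of use of each
    language, LexTALE and age are truncated normals, Spanish is acquired from
    birth and English early in childhood.
    """
    cfg.validate()
    rng = rng or stream_rng(cfg.seed, "cohort")
    n = cfg.n_participants
    if cfg.sd_spanish_share == 0:
        share = np.full(n, cfg.mean_spanish_share)
    else:
        a, b = _beta_params(cfg.mean_spanish_share, cfg.sd_spanish_share)
        share = rng.beta(a, b, size=n)
    age = np.clip(rng.normal(cfg.age_mean, cfg.age_sd, size=n), 18.0, 35.0)
    lextale = np.clip(rng.normal(cfg.lextale_mean, cfg.lextale_sd, size=n), 0.0, 100.0)
    aoa_en = np.clip(rng.normal(cfg.aoa_english_mean, cfg.aoa_english_sd, size=n), 0.0, 8.0)
    instructed = np.zeros(n, dtype=bool)
    instructed[: min(cfg.n_instructed, n)] = True
    rng.shuffle(instructed)
    profiles = []
    for i in range(n):
        hours = {"spanish": {}, "english": {}}
        ratings = {"spanish": {}, "english": {}}
        for mod, total_mean in _TOTAL_HOURS.items():
            total = total_mean * rng.lognormal(0.0, 0.25 if cfg.sd_spanish_share else 0.0)
            s_mod = np.clip(share[i] + (rng.normal(0.0, 0.05) if cfg.sd_spanish_share else 0.0), 0.0, 1.0)
            hours["spanish"][mod] = float(np.clip(total * s_mod, 0.0, 24.0))
            hours["english"][mod] = float(np.clip(total * (1.0 - s_mod), 0.0, 24.0))
            # ratings loosely track relative use, on the 1-7 scale
            ratings["spanish"][mod] = float(np.clip(np.round(3.5 + 3.0 * (share[i] - 0.5) + rng.normal(0, 0.7)), 1, 7))
            ratings["english"][mod] = float(np.clip(np.round(6.0 + rng.normal(0, 0.7)), 1, 7))
        profiles.append(
            ParticipantProfile(
                participant_id=f"P{i + 1:02d}",
                hours=hours,
                ratings=ratings,
                age=float(age[i]),
                aoa={"spanish": 0.0, "english": float(min(aoa_en[i], age[i]))},
                years_of_use={"spanish": float(age[i]), "english": float(age[i] - min(aoa_en[i], age[i]))},
                instruction=bool(instructed[i]),
                lextale=float(lextale[i]),
                list_id=(i % 3) + 1,
            )
        )
    return profiles


def _covariate_value(profile: ParticipantProfile, name: str, cfg: "CohortConfig") -> float:
    """Resolve an effect-map covariate for one participant.

    ``ratio_exposure`` is the share convention of the scores module applied to
    the profile's own hours, ``instruction`` is 0/1, anything else is looked
    up as a profile attribute.  Numeric covariates enter centered at their
    configured population mean, so ``base_amp_uv`` is the amplitude of the
    population-average participant while covariate *differences* still scale
    exactly by beta.
    """
    if name == "ratio_exposure":
        es = sum(profile.hours["spanish"].values())
        en = sum(profile.hours["english"].values())
        share = es / (es + en) if es + en > 0 else np.nan
        return share - cfg.mean_spanish_share
    if name == "instruction":
        return float(profile.instruction)
    if name == "lextale":
        return profile.lextale - cfg.lextale_mean
    return float(getattr(profile, name))


def component_amplitudes(profiles: list[ParticipantProfile], cfg: CohortConfig) -> pd.DataFrame:
    """Deterministic part of A_c per participant x component x error type."""
    rows = []
    for p in profiles:
        for comp, tpl in cfg.templates.items():
            for err in ERROR_TYPES:
                amp = tpl.base_amp_uv[err]
                center = tpl.center_ms
                for (c, e, cov), beta in cfg.effect_map.items():
                    if c == comp and e == err:
                        amp += beta * _covariate_value(p, cov, cfg)
                for (c, e, cov), beta in cfg.latency_effect_map.items():
                    if c == comp and e == err:
                        center += beta * _covariate_value(p, cov, cfg)
                rows.append(
                    {"participant_id": p.participant_id, "component": comp,
                     "error_type": err, "amplitude_uv": amp, "center_ms": center}
                )
    return pd.DataFrame(rows)


def _ar1_noise(rng: np.random.Generator, shape: tuple[int, ...], sd: float, rho: float) -> np.ndarray:
    """Stationary AR(1) noise along the last axis with marginal sd ``sd``."""
    if sd == 0:
        return np.zeros(shape)
    e = rng.standard_normal(shape)
    e[..., 0] *= sd
    if shape[-1] > 1:
        e[..., 1:] *= sd * np.sqrt(1.0 - rho**2)
    return signal.lfilter([1.0], [1.0, -rho], e, axis=-1)


def simulate_epochs(
    profiles: list[ParticipantProfile],
    designs: list[StimulusDesign] | None,
    cfg: CohortConfig,
) -> EpochTable:
    """Simulate the full epoched dataset for a cohort.

    Each participant contributes ``trials_per_condition`` trials in each of
    the four experimental conditions of their assigned list (fillers and
    unrelated items carry no EEG here).  Randomness is drawn from dedicated
    streams of ``cfg.seed``, so identical inputs give a byte-identical table.
    """
    cfg.validate()
    designs = designs if designs is not None else build_lists(cfg.seed)
    times = cfg.times_ms()
    lo, hi = cfg.epoch_window_ms
    for name, tpl in cfg.templates.items():
        if not (lo <= tpl.center_ms - tpl.width_ms and tpl.center_ms + tpl.width_ms <= hi):
            raise ValueError(f"component {name} extends outside the epoch window")

    item_rng = stream_rng(cfg.seed, "items")
    epoch_rng = stream_rng(cfg.seed, "epochs")
    assign_rng = stream_rng(cfg.seed, "assignment")

    # one offset per item id, shared by every participant seeing that item
    all_items = sorted(set().union(*(set(d.experimental()["item_id"]) for d in designs)))
    item_offsets = dict(zip(all_items, _ar1_noise(item_rng, (len(all_items), 1), cfg.noise.item_sd, 0.0)[:, 0]))

    amps = component_amplitudes(profiles, cfg)
    amp_lookup = {
        (r.participant_id, r.component, r.error_type): (r.amplitude_uv, r.center_ms)
        for r in amps.itertuples()
    }

    gains = np.array([cfg.topography[e] for e in cfg.electrodes])
    n_elec = len(cfg.electrodes)
    comp_names = list(cfg.templates)
    trial_frames = []
    for p in profiles:
        design = designs[(p.list_id - 1) % len(designs)]
        exp = design.experimental()
        if cfg.trials_per_condition * 4 != len(exp):
            exp = (
                exp.groupby("condition", group_keys=False)
                .head(cfg.trials_per_condition)
                .reset_index(drop=True)
            )
        trial_frames.append(
            pd.DataFrame(
                {
                    "participant_id": p.participant_id,
                    "trial_id": [f"{p.participant_id}_T{k + 1:03d}" for k in range(len(exp))],
                    "item_id": exp["item_id"].to_numpy(),
                    "condition": exp["condition"].to_numpy(),
                    "assignment_correct": True,
                }
            )
        )
    trials = pd.concat(trial_frames, ignore_index=True)
    n_trials = len(trials)

    data = np.zeros((n_trials, n_elec, len(times)))
    data += trials["item_id"].map(item_offsets).to_numpy()[:, None, None]
    pid = trials["participant_id"].to_numpy()
    err_of_trial = trials["condition"].map(CONDITION_ERROR)
    for p in profiles:
        # idiosyncratic component reactivity per error type (drawn per
        # participant in a fixed order, independent of the trial layout)
        dev = {
            (c, e): epoch_rng.normal(0.0, cfg.noise.participant_sd) if cfg.noise.participant_sd else 0.0
            for c in comp_names
            for e in ERROR_TYPES
        }
        for err in ERROR_TYPES:
            mask = (pid == p.participant_id) & (err_of_trial == err).to_numpy()
            if not mask.any():
                continue
            wave = np.zeros((n_elec, len(times)))
            for comp in comp_names:
                amp, center = amp_lookup[(p.participant_id, comp, err)]
                tpl = cfg.templates[comp]
                g = np.exp(-((times - center) ** 2) / (2.0 * tpl.width_ms**2))
                wave += (amp + dev[(comp, err)]) * gains[:, None] * g[None, :]
            data[mask] += wave
    data += _ar1_noise(epoch_rng, (n_trials, n_elec, len(times)), cfg.noise.trial_sd, cfg.noise.ar1)

    if cfg.assignment_error_rate > 0:
        trials["assignment_correct"] = assign_rng.random(n_trials) >= cfg.assignment_error_rate

    return EpochTable(
        data=data,
        trials=trials,
        channels=list(cfg.electrodes),
        times=times,
        sampling_rate_hz=cfg.sampling_rate_hz,
        epoch_window_ms=cfg.epoch_window_ms,
        reference_state="simulated-referenced",
    )
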