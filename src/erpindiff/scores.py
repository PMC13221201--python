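"""Language-history composite scores and predictor screening.

Implements the questionnaire composites used as individual-difference
predictors: the Exposure-and-Use score sum_j w_j * (H_j / K) over the four
modalities (reading, writing, speaking, listening), the derived Ratio of
Exposure and Use (Spanish share of the two languages' scores), and the
standard Dominance and Immersion composites kept for comparison.  Also
provides the pre-modelling screen: pairwise correlations among the numeric
predictors and regressions of each numeric predictor on the instruction
factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

MODALITIES = ["Reading", "Writing", "Speaking", "Listening"]


@dataclass
class ScoreConfig:
    K: float = 16.0                       # scaling constant (hours)
    weights: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    rating_max: float = 7.0
    ratio_convention: str = "share"       # "share" -> es/(es+en); "quotient" -> es/en

    def validate(self) -> None:
        if self.K <= 0:
            raise ValueError("K must be positive")
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")
        if self.ratio_convention not in ("share", "quotient"):
            raise ValueError(f"unknown ratio_convention {self.ratio_convention!r}")


def _as_hours(H) -> np.ndarray:
    H = np.asarray(H, dtype=float)
    if H.shape[-1] != 4:
        raise ValueError("expected four modality values (Reading, Writing, Speaking, Listening)")
    if (H < 0).any():
        raise ValueError("hours must be non-negative")
    if (H > 24).any():
        raise ValueError("hours per day cannot exceed 24")
    return H


def exposure_use_score(H, cfg: ScoreConfig | None = None) -> float | np.ndarray:
    """Exposure-and-Use composite: sum_j w_j * (H_j / K).

    ``H`` holds daily hours per modality (last axis of length 4).  Hours are
    deliberately not capped at K, so a score above 1 is possible when reported
    use exceeds 16 h/day.
    """
    cfg = cfg or ScoreConfig()
    cfg.validate()
    H = _as_hours(H)
    w = np.asarray(cfg.weights)
    out = (w * H / cfg.K).sum(axis=-1)
    return float(out) if out.ndim == 0 else out


def ratio_exposure(spanish_score, english_score, convention: str = "share"):
    """Ratio of Exposure and Use.

    Under the default ``share`` convention this is es/(es+en), bounded in
    [0, 1]; ``quotient`` gives the raw es/en quotient.  A participant with
    both scores zero has no defined ratio and gets NaN.
    """
    es = np.asarray(spanish_score, dtype=float)
    en = np.asarray(english_score, dtype=float)
    if (es < 0).any() or (en < 0).any():
        raise ValueError("exposure scores must be non-negative")
    with np.errstate(divide="ignore", invalid="ignore"):
        if convention == "share":
            out = np.where(es + en > 0, es / (es + en), np.nan)
        elif convention == "quotient":
            out = np.where(en > 0, es / en, np.nan)
        else:
            raise ValueError(f"unknown ratio convention {convention!r}")
    return float(out) if out.ndim == 0 else out


def dominance_score(P, H, cfg: ScoreConfig | None = None):
    """Dominance composite: sum_j w_j * (P_j / (2*7) + H_j / (2*K)).

    Half the weight goes to self-rated proficiency ``P`` (1-7), half to daily
    hours; equals the Exposure-and-Use score when every rating satisfies
    P_j / 7 = H_j / K.
    """
    cfg = cfg or ScoreConfig()
    cfg.validate()
    P = np.asarray(P, dtype=float)
    H = _as_hours(H)
    if (P < 1).any() or (P > cfg.rating_max).any():
        raise ValueError(f"self ratings must lie in [1, {cfg.rating_max}]")
    w = np.asarray(cfg.weights)
    out = (w * (0.5 * P / cfg.rating_max + 0.5 * H / cfg.K)).sum(axis=-1)
    return float(out) if out.ndim == 0 else out


def immersion_score(age, AoA, YoU, cfg: ScoreConfig | None = None):
    """Immersion composite: 0.5 * sum_j w_j * ((Age - AoA_j)/Age + YoU/Age).

    ``AoA`` is the per-modality age of acquisition, ``YoU`` the years of use
    of the language; both are bounded by ``age``.  In [0, 1], with 1 for a
    lifelong user of every modality.
    """
    cfg = cfg or ScoreConfig()
    cfg.validate()
    age = np.asarray(age, dtype=float)
    if (age <= 0).any():
        raise ValueError("age must be positive")
    AoA = np.asarray(AoA, dtype=float)
    YoU = np.asarray(YoU, dtype=float)
    if (AoA < 0).any() or (AoA > age[..., None] if AoA.ndim > age.ndim else (AoA > age)).any():
        raise ValueError("AoA must lie in [0, age]")
    if (YoU < 0).any() or (YoU > age).any():
        raise ValueError("years of use must lie in [0, age]")
    w = np.asarray(cfg.weights)
    age_e = age[..., None] if AoA.ndim > age.ndim else age
    out = 0.5 * (w * ((age_e - AoA) / age_e + (YoU / age)[..., None] * np.ones(4))).sum(axis=-1)
    return float(out) if out.ndim == 0 else out


def sum_code(values: pd.Series) -> pd.Series:
    """Two-level sum coding: first level alphabetically -> +1, other -> -1."""
    levels = sorted(values.dropna().unique())
    if len(levels) != 2:
        raise ValueError(f"sum coding needs exactly two levels, got {levels}")
    return values.map({levels[0]: 1.0, levels[1]: -1.0})


def score_table(cohort: pd.DataFrame, cfg: ScoreConfig | None = None) -> pd.DataFrame:
    """Compute the full per-participant score table from a cohort frame.

    ``cohort`` needs ``hours_{spanish|english}_{modality}`` and
    ``rating_{spanish|english}_{modality}`` columns plus ``age``,
    ``aoa_{spanish|english}`` (scalar per language; applied to all
    modalities), ``you_{spanish|english}``, ``instruction`` and ``lextale``.
    Numeric predictors also get mean-centered ``_C`` variants computed over
    the analysis sample, and instruction a +-1 sum-coded column
    (``instructed`` mapped to +1).
    """
    cfg = cfg or ScoreConfig()
    cfg.validate()
    out = pd.DataFrame({"participant_id": cohort["participant_id"]})
    hours = {}
    for lang in ("spanish", "english"):
        H = cohort[[f"hours_{lang}_{m.lower()}" for m in MODALITIES]].to_numpy()
        P = cohort[[f"rating_{lang}_{m.lower()}" for m in MODALITIES]].to_numpy()
        hours[lang] = H
        out[f"exposure_use_{lang}"] = exposure_use_score(H, cfg)
        out[f"dominance_{lang}"] = dominance_score(P, H, cfg)
        AoA = np.repeat(cohort[[f"aoa_{lang}"]].to_numpy(), 4, axis=1)
        out[f"immersion_{lang}"] = immersion_score(
            cohort["age"].to_numpy(), AoA, cohort[f"you_{lang}"].to_numpy(), cfg
        )
    out["ratio_exposure"] = ratio_exposure(
        out["exposure_use_spanish"], out["exposure_use_english"], cfg.ratio_convention
    )
    out["ratio_dominance"] = ratio_exposure(
        out["dominance_spanish"], out["dominance_english"], cfg.ratio_convention
    )
    out["lextale"] = cohort["lextale"].astype(float)
    out["instruction"] = np.where(cohort["instruction"].astype(bool), "instructed", "uninstructed")
    out["Instruction_sum"] = sum_code(out["instruction"])
    # centered predictors, names following the analysis formula
    out["LexTale_O_C"] = out["lextale"] - out["lextale"].mean()
    out["Ratio_Exp_Spanish_C"] = out["ratio_exposure"] - out["ratio_exposure"].mean()
    return out


@dataclass
class ScreenReport:
    correlations: pd.DataFrame
    instruction_tests: pd.DataFrame
    constant_columns: list[str] = field(default_factory=list)

    @property
    def any_flagged(self) -> bool:
        return bool(self.correlations["flag"].any() or self.instruction_tests["flag"].any())


def screen_predictors(
    table: pd.DataFrame,
    numeric: tuple[str, ...] = ("lextale", "ratio_exposure"),
    instruction: str = "instruction",
    alpha: float = 0.05,
) -> ScreenReport:
    """Pre-modelling collinearity screen.

    Pairwise Pearson correlations among the numeric predictors and a
    regression (two-sample t-test) of each numeric predictor on the
    instruction factor; any p below ``alpha`` is flagged.  Constant columns
    cannot be correlated and are reported rather than raised.
    """
    if len(table) < 3:
        raise ValueError("screening needs at least 3 participants")
    constant = [c for c in numeric if table[c].nunique() <= 1]
    rows = []
    for i, a in enumerate(numeric):
        for b in numeric[i + 1 :]:
            if a in constant or b in constant:
                rows.append({"a": a, "b": b, "r": np.nan, "p": np.nan, "flag": True})
                continue
            r, p = stats.pearsonr(table[a], table[b])
            rows.append({"a": a, "b": b, "r": r, "p": p, "flag": p < alpha})
    corr = pd.DataFrame(rows, columns=["a", "b", "r", "p", "flag"])
    irows = []
    groups = table.groupby(instruction)
    for c in numeric:
        if c in constant or len(groups) < 2:
            irows.append({"predictor": c, "t": np.nan, "p": np.nan, "flag": c in constant})
            continue
        samples = [g[c].to_numpy() for _, g in groups]
        t, p = stats.ttest_ind(*samples)
        irows.append({"predictor": c, "t": t, "p": p, "flag": p < alpha})
    itests = pd.DataFrame(irows, columns=["predictor", "t", "p", "flag"])
    return ScreenReport(correlations=corr, instruction_tests=itests, constant_columns=constant)
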