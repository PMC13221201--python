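"""End-to-end run orchestration: simulate -> score -> preprocess -> extract -> model.

A run is fully described by a :class:`RunConfig`; all randomness flows from
its single seed through named substreams, so a manifest (config + seed) is
sufficient to re-execute a bit-identical run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import erpindiff
from erpindiff import design as design_mod
from erpindiff.design import build_lists
from erpindiff.gam import SmoothConfig, extract_all
from erpindiff.models import RESPONSES, fit_all_models
from erpindiff.preprocess import PreprocConfig, preprocess
from erpindiff.scores import ScoreConfig, score_table, screen_predictors
from erpindiff.simulate import CohortConfig, cohort_frame, sample_cohort, simulate_epochs


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "runs/default"
    cohort: CohortConfig = field(default_factory=CohortConfig)
    score: ScoreConfig = field(default_factory=ScoreConfig)
    preproc: PreprocConfig = field(default_factory=PreprocConfig)
    smooth: SmoothConfig = field(default_factory=SmoothConfig)
    responses: tuple[str, ...] = RESPONSES
    dataset_variant: str = "correct_only"   # "correct_only" | "all_trials"
    save_epochs: bool = False

    def validate(self) -> None:
        if self.dataset_variant not in ("correct_only", "all_trials"):
            raise ValueError(f"unknown dataset_variant {self.dataset_variant!r}")
        self.cohort.validate()
        self.score.validate()
        self.preproc.validate(self.cohort.sampling_rate_hz)
        self.smooth.validate()

    # -- (de)serialization -----------------------------------------------

    def to_dict(self) -> dict:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, dict):
                return {(k if isinstance(k, str) else "|".join(map(str, k))): enc(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [enc(v) for v in obj]
            if isinstance(obj, np.generic):
                return obj.item()
            return obj

        return enc(dataclasses.asdict(self))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        from erpindiff.simulate import ComponentTemplate, NoiseModel

        kwargs = dict(raw)
        if "cohort" in kwargs:
            c = dict(kwargs["cohort"])
            if "templates" in c:
                c["templates"] = {
                    name: ComponentTemplate(**tpl) for name, tpl in c["templates"].items()
                }
            if "noise" in c:
                c["noise"] = NoiseModel(**c["noise"])
            for key in ("effect_map", "latency_effect_map"):
                if key in c:
                    c[key] = {tuple(k.split("|")): v for k, v in c[key].items()}
            if "epoch_window_ms" in c:
                c["epoch_window_ms"] = tuple(c["epoch_window_ms"])
            kwargs["cohort"] = CohortConfig(**c)
        for key, klass in (("score", ScoreConfig), ("preproc", PreprocConfig), ("smooth", SmoothConfig)):
            if key in kwargs:
                sub = dict(kwargs[key])
                for tup_field in ("band_hz", "epoch_window_ms", "baseline_window_ms", "weights",
                                  "lambda_grid", "item_lambda_grid"):
                    if tup_field in sub and isinstance(sub[tup_field], list):
                        sub[tup_field] = tuple(sub[tup_field])
                if "windows" in sub:
                    sub["windows"] = {k: tuple(v) for k, v in sub["windows"].items()}
                kwargs[key] = klass(**sub)
        if "responses" in kwargs:
            kwargs["responses"] = tuple(kwargs["responses"])
        return cls(**kwargs)

    def config_hash(self) -> str:
        """Hash of the scientific configuration (output location excluded)."""
        payload = self.to_dict()
        payload.pop("out_dir", None)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def run(config: RunConfig) -> Path:
    """Execute the full pipeline; returns the run directory.

    Writes stage outputs (design, cohort, scores, indices, model tables) and
    a manifest recording the config hash, package versions, per-stage row
    counts and warnings.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "versions": {
            "erpindiff": erpindiff.__version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "stages": {},
        "warnings": [],
    }
    cfg = dataclasses.replace(config.cohort, seed=config.seed)

    stage = "simulate"
    try:
        designs = build_lists(config.seed)
        pd.concat([d.sentences.assign(list_id=d.list_id) for d in designs]).to_csv(
            out / "stimulus_design.csv", index=False
        )
        profiles = sample_cohort(cfg)
        cohort = cohort_frame(profiles)
        cohort.to_csv(out / "cohort.csv", index=False)
        epochs = simulate_epochs(profiles, designs, cfg)
        if config.save_epochs:
            epochs.to_csv(out / "epochs.csv.gz")
        manifest["stages"][stage] = {
            "n_participants": len(profiles),
            "n_trials": epochs.n_trials,
            "n_sentences_total": design_mod.total_unique_sentences(designs),
        }

        stage = "score"
        scores = score_table(cohort, config.score)
        scores.to_csv(out / "scores.csv", index=False)
        screen = screen_predictors(scores)
        screen.correlations.to_csv(out / "predictor_screen_correlations.csv", index=False)
        screen.instruction_tests.to_csv(out / "predictor_screen_instruction.csv", index=False)
        manifest["stages"][stage] = {
            "n_participants": len(scores),
            "screen_flagged": bool(screen.any_flagged),
        }

        stage = "preprocess"
        pcfg = dataclasses.replace(
            config.preproc,
            drop_incorrect_assignment=(config.dataset_variant == "correct_only"),
        )
        clean, plog = preprocess(epochs, pcfg)
        (out / "preprocess_log.json").write_text(json.dumps(plog, indent=2))
        manifest["stages"][stage] = {
            "n_trials_in": epochs.n_trials,
            "n_trials_out": clean.n_trials,
            "dataset_variant": config.dataset_variant,
        }
        manifest["warnings"] += [
            w for s in plog["stages"] for w in s.get("warnings", [])
        ]

        stage = "extract"
        indices, report = extract_all(clean, config.smooth)
        indices.to_csv(out / "component_indices.csv", index=False)
        manifest["stages"][stage] = {
            "n_indices": len(indices),
            "n_cells_fitted": report["n_fitted"],
            "n_cells_skipped": len(report["skipped_cells"]),
        }
        manifest["warnings"] += report["skipped_cells"]

        stage = "model"
        fits = fit_all_models(indices, scores, responses=config.responses)
        summary_rows = []
        for response, entry in fits.items():
            fit = entry["fit"]
            fit.table.assign(response=response).to_csv(out / f"model_{response}.csv", index=False)
            entry["posthoc"].assign(response=response).to_csv(
                out / f"posthoc_{response}.csv", index=False
            )
            summary_rows.append(
                {
                    "response": response,
                    "random_structure": fit.random_structure,
                    "ladder_position": fit.ladder_position,
                    "max_vif": float(fit.vifs.max()),
                    "n_obs": fit.n_obs,
                }
            )
            (out / f"model_{response}.json").write_text(
                json.dumps(
                    {
                        "response": response,
                        "random_structure": fit.random_structure,
                        "vifs": fit.vifs.to_dict(),
                        "terms": fit.table.to_dict(orient="records"),
                        "error_sum_coding": {"Default": 1, "FeatureClash": -1},
                        "instruction_sum_coding": {"instructed": 1, "uninstructed": -1},
                    },
                    indent=2,
                )
            )
        pd.DataFrame(summary_rows).to_csv(out / "model_summary.csv", index=False)
        manifest["stages"][stage] = {"responses": list(fits)}
    except Exception as err:
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {err}") from err

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return out
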