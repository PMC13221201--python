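import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from erpindiff.models import (
    ModelSpec,
    bonferroni,
    build_model_frame,
    fit_lmm,
    posthoc,
    vif,
)


def make_scores(n, rng=None, seed=0):
    rng = rng or np.random.default_rng(seed)
    sc = pd.DataFrame(
        {
            "participant_id": [f"P{i:02d}" for i in range(1, n + 1)],
            "lextale": rng.normal(65, 9, n),
            "ratio_exposure": rng.uniform(0.05, 0.75, n),
            "instruction": ["instructed", "uninstructed"] * (n // 2) + ["instructed"] * (n % 2),
        }
    )
    sc["Instruction_sum"] = sc["instruction"].map({"instructed": 1.0, "uninstructed": -1.0})
    sc["LexTale_O_C"] = sc["lextale"] - sc["lextale"].mean()
    sc["Ratio_Exp_Spanish_C"] = sc["ratio_exposure"] - sc["ratio_exposure"].mean()
    return sc


def make_indices(scores, component="N400", measure_fn=None, electrodes=("Cz", "Pz", "C3"), rng=None):
    rng = rng or np.random.default_rng(1)
    rows = []
    for _, s in scores.iterrows():
        for err, es in (("Default", 1.0), ("FeatureClash", -1.0)):
            for e in electrodes:
                y = measure_fn(s, es, rng) if measure_fn else rng.normal()
                rows.append(
                    {
                        "participant_id": s.participant_id,
                        "error_type": err,
                        "electrode": e,
                        "component": component,
                        "mpl_ms": 400.0,
                        "nmp": y,
                        "boundary_flag": False,
                        "flat_flag": False,
                    }
                )
    return pd.DataFrame(rows)


class TestExactRecovery:
    def test_noiseless_table_recovers_coefficients_exactly(self):
        scores = make_scores(6)
        indices = make_indices(scores, measure_fn=lambda s, es, rng: 1.0 + 0.5 * es)
        spec = ModelSpec("N400_NMP")
        fit = fit_lmm(build_model_frame(indices, scores, spec), spec)
        t = fit.table.set_index("term")
        assert t.loc["Intercept", "estimate"] == pytest.approx(1.0, abs=1e-8)
        assert t.loc["Error_sum", "estimate"] == pytest.approx(0.5, abs=1e-8)
        others = t.drop(["Intercept", "Error_sum"])["estimate"]
        assert others.abs().max() < 1e-8

    def test_noiseless_posthoc_error_contrast(self):
        scores = make_scores(6)
        indices = make_indices(scores, measure_fn=lambda s, es, rng: 1.0 + 0.5 * es)
        spec = ModelSpec("N400_NMP")
        data = build_model_frame(indices, scores, spec)
        fit = fit_lmm(data, spec)
        ph = posthoc(fit, data, spec)
        contrast = ph[ph.comparison == "error_contrast"].iloc[0]
        assert contrast["estimate"] == pytest.approx(1.0, abs=1e-8)  # Default - FeatureClash


class TestVif:
    def test_orthogonal_predictors_have_unit_vif(self):
        X = pd.DataFrame({"a": [1.0, 1, -1, -1], "b": [1.0, -1, 1, -1]})
        assert vif(X).max() == pytest.approx(1.0, abs=1e-9)

    def test_duplicated_predictor_is_unbounded(self):
        x = np.random.default_rng(0).normal(size=50)
        out = vif(pd.DataFrame({"x": x, "x2": x}))
        assert np.isinf(out).all()

    def test_correlation_point_six_gives_closed_form(self):
        """Sample correlation exactly .6 -> VIF = 1/(1-.36) = 1.5625."""
        rng = np.random.default_rng(3)
        n = 200
        x = rng.normal(size=n)
        z = rng.normal(size=n)
        x = (x - x.mean()) / x.std()
        z = z - z.mean()
        z -= x * (x @ z) / (x @ x)  # orthogonalize
        z /= z.std()
        y = 0.6 * x + np.sqrt(1 - 0.36) * z
        out = vif(pd.DataFrame({"x": x, "y": y}))
        assert out["x"] == pytest.approx(1.5625, abs=1e-9)


def test_bonferroni_definition():
    assert bonferroni(0.03, 2) == pytest.approx(0.06)
    assert bonferroni(0.7, 2) == pytest.approx(1.0)


@pytest.fixture(scope="module")
def noisy_fit():
    scores = make_scores(12)
    rng = np.random.default_rng(42)
    dev = {s: (rng.normal(0, 0.5), rng.normal(0, 0.3)) for s in scores.participant_id}

    def fn(s, es, r):
        b0, b1 = dev[s.participant_id]
        return -2 + 0.4 * es + 0.03 * (s.lextale - 65) + b0 + b1 * es + r.normal(0, 0.4)

    indices = make_indices(scores, measure_fn=fn, rng=rng)
    spec = ModelSpec("N400_NMP")
    data = build_model_frame(indices, scores, spec)
    return fit_lmm(data, spec), data, spec


class TestReparameterization:
    def test_relevelled_refit_is_a_reparameterization(self, noisy_fit):
        """Dummy vs sum coding of Error Type spans the same model: fitted
        values agree and the REML criteria differ by exactly the Jacobian of
        the coding map (|det A| = 2^-4 over the four Error columns)."""
        import warnings

        from erpindiff.models import LADDER, _ladder_model

        fit, data, spec = noisy_fit
        rung = LADDER[fit.ladder_position]
        d = data.copy()
        d["Error_dummy"] = (d["Error_sum"] != 1.0).astype(float)
        results = []
        for formula in (
            "Error_sum * (LexTale_O_C + Ratio_Exp_Spanish_C + Instruction_sum)",
            "Error_dummy * (LexTale_O_C + Ratio_Exp_Spanish_C + Instruction_sum)",
        ):
            model, free = _ladder_model(d, formula, rung)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                results.append(model.fit(reml=spec.reml, free=free, method="powell", maxiter=2000))
        sum_fit, dummy_fit = results
        np.testing.assert_allclose(
            np.asarray(dummy_fit.fittedvalues), np.asarray(sum_fit.fittedvalues), atol=1e-3
        )
        assert dummy_fit.llf - sum_fit.llf == pytest.approx(4 * np.log(2.0), abs=1e-3)

    def test_simple_effects_average_to_main_effect(self, noisy_fit):
        """The two simple LexTALE slopes bracket twice the interaction: their
        half-difference equals the Error x LexTALE coefficient."""
        fit, data, spec = noisy_fit
        ph = posthoc(fit, data, spec)
        s = ph[(ph.comparison == "simple_effect") & (ph.predictor == "LexTale_O_C")].set_index("error_type")
        inter = fit.term("Error_sum:LexTale_O_C")["estimate"]
        half_diff = (s.loc["Default", "estimate"] - s.loc["FeatureClash", "estimate"]) / 2.0
        assert half_diff == pytest.approx(inter, abs=5e-3)

    def test_ci_is_wald(self, noisy_fit):
        fit, _, _ = noisy_fit
        t = fit.table
        np.testing.assert_allclose(t["ci_low"], t["estimate"] - 1.96 * t["se"], atol=1e-10)
        np.testing.assert_allclose(t["ci_high"], t["estimate"] + 1.96 * t["se"], atol=1e-10)


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="R not available")
def test_matches_lme4_reference_fit(tmp_path):
    """Independent cross-check: the maximal-structure REML fit must agree
    with lme4's (1 + Error | participant) + (1 | participant:electrode)
    estimates and standard errors."""
    scores = make_scores(12)
    rng = np.random.default_rng(42)
    dev = {s: (rng.normal(0, 0.5), rng.normal(0, 0.3)) for s in scores.participant_id}

    def fn(s, es, r):
        b0, b1 = dev[s.participant_id]
        return -2 + 0.4 * es + 0.03 * (s.lextale - 65) + b0 + b1 * es + r.normal(0, 0.4)

    indices = make_indices(scores, measure_fn=fn, electrodes=("Cz", "Pz", "C3", "C4"), rng=rng)
    spec = ModelSpec("N400_NMP")
    data = build_model_frame(indices, scores, spec)
    fit = fit_lmm(data, spec)
    if fit.ladder_position != 0:
        pytest.skip("maximal structure did not converge on this draw")
    data.to_csv(tmp_path / "d.csv", index=False)
    script = f"""
    suppressMessages(library(lme4))
    d <- read.csv("{tmp_path}/d.csv")
    m <- lmer(y ~ Error_sum*(LexTale_O_C+Ratio_Exp_Spanish_C+Instruction_sum)
              + (1+Error_sum|participant_id) + (1|participant_id:electrode),
              data=d, REML=TRUE)
    write.csv(summary(m)$coefficients, "{tmp_path}/r.csv")
    """
    (tmp_path / "s.R").write_text(script)
    proc = subprocess.run(["Rscript", str(tmp_path / "s.R")], capture_output=True, text=True)
    assert proc.returncode == 0, proc.stderr
    ref = pd.read_csv(tmp_path / "r.csv", index_col=0)
    ours = fit.table.set_index("term")
    name_map = {"(Intercept)": "Intercept"}
    for rname, row in ref.iterrows():
        term = name_map.get(rname, rname.replace(".", ":"))
        assert ours.loc[term, "estimate"] == pytest.approx(row["Estimate"], abs=2e-3)
        assert ours.loc[term, "se"] == pytest.approx(row["Std. Error"], rel=0.02)


def test_requires_both_error_types():
    scores = make_scores(4)
    indices = make_indices(scores)
    indices = indices[indices.error_type == "Default"]
    spec = ModelSpec("N400_NMP")
    with pytest.raises(ValueError, match="error type"):
        fit_lmm(build_model_frame(indices, scores, spec), spec)


def test_drop_flagged_rows_switch():
    scores = make_scores(6)
    indices = make_indices(scores)
    indices.loc[indices.index[:6], "boundary_flag"] = True
    spec_keep = ModelSpec("N400_NMP", drop_flagged=False)
    spec_drop = ModelSpec("N400_NMP", drop_flagged=True)
    assert len(build_model_frame(indices, scores, spec_drop)) == len(
        build_model_frame(indices, scores, spec_keep)
    ) - 6


def test_invalid_response_rejected():
    with pytest.raises(ValueError):
        ModelSpec("N500_NMP").validate()
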