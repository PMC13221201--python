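"""Individual-differences mixed-effects regressions.

Each extracted index (MPL or NMP of one component) is regressed on Error
Type crossed with the three experience predictors,

    y ~ Error_sum * (LexTale_O_C + Ratio_Exp_Spanish_C + Instruction_sum)

with sum-coded factors (Default and "instructed" mapped to +1), mean-centered
numeric predictors, and by-participant random effects fitted by REML through
statsmodels' MixedLM.  A convergence ladder starts from the maximal feasible
structure (correlated intercept + Error slope by participant plus a
participant-by-electrode variance component) and simplifies until a fit
converges.  Degrees of freedom use a containment-style between-within rule;
95% CIs are Wald (+-1.96 SE).  Post hocs re-fit the model relevelled on
Error Type to obtain simple effects, Bonferroni-adjusted within each
predictor's family.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.formula.api as smf
from statsmodels.regression.mixed_linear_model import MixedLMParams

FIXED_FORMULA = "Error_sum * (LexTale_O_C + Ratio_Exp_Spanish_C + Instruction_sum)"
COVARIATES = ("LexTale_O_C", "Ratio_Exp_Spanish_C", "Instruction_sum")
RESPONSES = ("N400_MPL", "N400_NMP", "P600_MPL", "P600_NMP")

#: random-effect structures tried in order; the first converged fit is kept.
LADDER = (
    ("corr_slope", True),
    ("corr_slope", False),
    ("uncorr_slope", True),
    ("uncorr_slope", False),
    ("intercept", True),
    ("intercept", False),
)


@dataclass
class ModelSpec:
    response: str = "N400_NMP"          # component_measure
    alpha: float = 0.05
    drop_flagged: bool = False          # drop boundary/flat-flagged indices
    reml: bool = True

    def validate(self) -> None:
        if self.response not in RESPONSES:
            raise ValueError(f"response must be one of {RESPONSES}")

    @property
    def component(self) -> str:
        return self.response.split("_")[0]

    @property
    def measure(self) -> str:
        return "mpl_ms" if self.response.endswith("MPL") else "nmp"


@dataclass
class FitResult:
    response: str
    table: pd.DataFrame                 # term, estimate, se, ci_low, ci_high, t, df, p
    random_structure: str
    ladder_position: int
    converged: bool
    vifs: pd.Series
    loglike: float
    n_obs: int
    n_participants: int
    result: object = field(repr=False, default=None)

    def term(self, name: str) -> pd.Series:
        return self.table.set_index("term").loc[name]


def build_model_frame(
    indices: pd.DataFrame, scores: pd.DataFrame, spec: ModelSpec
) -> pd.DataFrame:
    """Join component indices to the score table for one response.

    Sum-codes Error Type (Default -> +1, FeatureClash -> -1, first level
    alphabetically positive) and re-centers the numeric predictors on the
    participants actually present in the analysis sample.
    """
    spec.validate()
    sub = indices[indices["component"] == spec.component].copy()
    if spec.drop_flagged:
        sub = sub[~(sub["boundary_flag"] | sub["flat_flag"])]
    data = sub.merge(scores, on="participant_id", how="inner")
    data["y"] = data[spec.measure]
    data["Error_sum"] = data["error_type"].map({"Default": 1.0, "FeatureClash": -1.0})
    if data["Error_sum"].isna().any():
        raise ValueError("error_type must be Default or FeatureClash")
    for col in ("LexTale_O_C", "Ratio_Exp_Spanish_C"):
        per_part = data.groupby("participant_id")[col].first()
        data[col] = data[col] - per_part.mean()
    return data.reset_index(drop=True)


def _ladder_model(data: pd.DataFrame, fixed: str, rung: tuple[str, bool]):
    slope, with_electrode = rung
    vc = {"electrode": "0 + C(electrode)"} if with_electrode else None
    re_formula = {"corr_slope": "1 + Error_sum", "uncorr_slope": "1 + Error_sum", "intercept": "1"}[slope]
    model = smf.mixedlm(
        f"y ~ {fixed}",
        data,
        groups=data["participant_id"],
        re_formula=re_formula,
        vc_formula=vc,
    )
    free = None
    if slope == "uncorr_slope":
        k_fe = model.exog.shape[1]
        free = MixedLMParams.from_components(
            fe_params=np.ones(k_fe),
            cov_re=np.eye(2),
            vcomp=np.ones(model.k_vc) if model.k_vc else None,
        )
    return model, free


class _ExactFixedFit:
    """Adapter giving an OLS result the MixedLM accessor surface.

    Used when the response is an exact linear function of the fixed effects
    (zero residual variance), where the mixed-model likelihood is degenerate
    but the fixed-effect estimates are the plain least-squares solution.
    """

    def __init__(self, res):
        self.fe_params = res.params
        self.bse_fe = res.bse
        self.llf = res.llf
        self.model = res.model
        self.converged = True


def _degenerate_fit(data: pd.DataFrame, fixed: str):
    res = smf.ols(f"y ~ {fixed}", data).fit()
    tss = float(res.centered_tss) if np.isfinite(res.centered_tss) else 1.0
    if res.ssr <= 1e-10 * max(tss, 1.0):
        return _ExactFixedFit(res)
    return None


def _fit_ladder(data: pd.DataFrame, fixed: str, reml: bool):
    exact = _degenerate_fit(data, fixed)
    if exact is not None:
        return exact, "none (zero residual variance; exact fixed-effect fit)", len(LADDER)
    last_err = None
    for pos, rung in enumerate(LADDER):
        model, free = _ladder_model(data, fixed, rung)
        # optimizer fallback within a rung, as lme4 users switch optimizers
        # before simplifying the structure
        for method in ("lbfgs", "powell"):
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    result = model.fit(reml=reml, free=free, method=method, maxiter=500)
                ok = (
                    bool(getattr(result, "converged", False))
                    and np.isfinite(result.fe_params).all()
                    and np.isfinite(result.bse_fe).all()
                )
            except (np.linalg.LinAlgError, ValueError, RuntimeError) as err:
                ok, result = False, None
                last_err = err
            if ok:
                label = f"participant: {rung[0]}" + (
                    ", participant x electrode: intercept" if rung[1] else ""
                )
                return result, label, pos
    # terminal fallback: no random structure supportable by the data
    res = smf.ols(f"y ~ {fixed}", data).fit()
    if np.isfinite(res.params).all() and np.isfinite(res.bse).all():
        return _ExactFixedFit(res), "none (fixed effects only; no random structure converged)", len(LADDER)
    raise RuntimeError(
        f"no random-effect structure converged (last attempted {LADDER[-1]}; last error: {last_err})"
    )


def _between_within_df(data: pd.DataFrame, exog: pd.DataFrame) -> pd.Series:
    """Containment-style denominator df per fixed-effect term.

    Columns constant within participants, and any term involving one (here
    every covariate main effect and interaction, plus the participant-
    randomized Error slope), are tested against participant-level df
    ``n_participants - p_between``; purely within-participant terms get the
    residual df.
    """
    groups = data["participant_id"]
    n_groups = groups.nunique()
    n_obs = len(data)
    between_cols = [
        c for c in exog.columns if exog.groupby(groups.to_numpy())[c].nunique().le(1).all()
    ]
    p_between = len(between_cols)
    df_between = max(n_groups - p_between, 1)
    df_within = max(n_obs - n_groups - (exog.shape[1] - p_between), 1)
    out = {}
    for c in exog.columns:
        involves_between = c in between_cols or any(b in c for b in between_cols if b != "Intercept")
        randomized = "Error_sum" in c
        out[c] = float(df_between if (involves_between or randomized) else df_within)
    return pd.Series(out)


def _term_table(result, dfs: pd.Series, alpha: float) -> pd.DataFrame:
    rows = []
    for term in result.fe_params.index:
        est = float(result.fe_params[term])
        se = float(result.bse_fe[term])
        df = float(dfs.get(term, np.inf))
        t = est / se if se > 0 else np.nan
        p = 2.0 * sps.t.sf(abs(t), df) if np.isfinite(t) else np.nan
        rows.append(
            {
                "term": term,
                "estimate": est,
                "se": se,
                "ci_low": est - 1.96 * se,
                "ci_high": est + 1.96 * se,
                "t": t,
                "df": df,
                "p": p,
                "significant": bool(p < alpha) if np.isfinite(p) else False,
            }
        )
    return pd.DataFrame(rows)


def vif(X: pd.DataFrame) -> pd.Series:
    """Variance inflation factor 1/(1-R^2) per predictor column.

    Each column is regressed on the others plus an intercept; exact
    collinearity yields ``inf`` rather than an error.
    """
    X = X.astype(float)
    out = {}
    for col in X.columns:
        others = X.drop(columns=[col])
        A = np.column_stack([np.ones(len(X)), others.to_numpy()])
        y = X[col].to_numpy()
        beta, *_ = np.linalg.lstsq(A, y, rcond=None)
        resid = y - A @ beta
        tss = ((y - y.mean()) ** 2).sum()
        r2 = 1.0 - resid @ resid / tss if tss > 0 else 1.0
        out[col] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out, name="vif")


def fit_lmm(data: pd.DataFrame, spec: ModelSpec) -> FitResult:
    """Fit the individual-differences model for one response.

    ``data`` is a frame from :func:`build_model_frame` (columns ``y``,
    ``Error_sum``, the centered covariates, ``participant_id``,
    ``electrode``).
    """
    spec.validate()
    if data["participant_id"].nunique() < 2:
        raise ValueError("need at least 2 participants")
    if data["Error_sum"].nunique() < 2:
        raise ValueError("both error types must be present")
    result, label, pos = _fit_ladder(data, FIXED_FORMULA, spec.reml)
    exog = pd.DataFrame(result.model.exog, columns=result.model.exog_names)
    dfs = _between_within_df(data, exog)
    table = _term_table(result, dfs, spec.alpha)
    main_effects = data[["Error_sum", *COVARIATES]]
    return FitResult(
        response=spec.response,
        table=table,
        random_structure=label,
        ladder_position=pos,
        converged=True,
        vifs=vif(main_effects),
        loglike=float(result.llf),
        n_obs=len(data),
        n_participants=int(data["participant_id"].nunique()),
        result=result,
    )


def posthoc(fit: FitResult, data: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    """Simple effects within each error type plus error-type contrasts.

    Each error type in turn is made the reference level of a dummy-coded
    refit (same random structure as the main fit), whose covariate main
    effects are the simple slopes within that error type.  The instruction
    entry is reported as the instructed-minus-uninstructed group difference
    (twice the sum-coded coefficient).  p-values are Bonferroni-adjusted
    within each predictor's family of two comparisons.
    """
    degenerate = fit.ladder_position >= len(LADDER)
    rung = None if degenerate else LADDER[fit.ladder_position]
    rows = []
    for level, sign in (("Default", 1.0), ("FeatureClash", -1.0)):
        d = data.copy()
        # 0 at the reference level, 1 at the other: main effects = simple effects at `level`
        d["Error_dummy"] = (d["Error_sum"] != sign).astype(float)
        relevel_formula = "Error_dummy * (LexTale_O_C + Ratio_Exp_Spanish_C + Instruction_sum)"
        if degenerate:
            res = _ExactFixedFit(smf.ols(f"y ~ {relevel_formula}", d).fit())
        else:
            model, free = _ladder_model(d, relevel_formula, rung)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = model.fit(reml=spec.reml, free=free, method="lbfgs", maxiter=200)
        exog = pd.DataFrame(res.model.exog, columns=res.model.exog_names)
        dfs = _between_within_df(d, exog)
        for cov in COVARIATES:
            scale = 2.0 if cov == "Instruction_sum" else 1.0
            est = scale * float(res.fe_params[cov])
            se = scale * float(res.bse_fe[cov])
            t = est / se if se > 0 else np.nan
            p = 2.0 * sps.t.sf(abs(t), float(dfs[cov]))
            rows.append(
                {
                    "comparison": "simple_effect",
                    "predictor": cov,
                    "error_type": level,
                    "estimate": est,
                    "se": se,
                    "t": t,
                    "p": p,
                }
            )
    # pairwise error-type contrast (Default - FeatureClash) from the main fit
    err = fit.term("Error_sum")
    rows.append(
        {
            "comparison": "error_contrast",
            "predictor": "Error_sum",
            "error_type": "Default-FeatureClash",
            "estimate": 2.0 * err["estimate"],
            "se": 2.0 * err["se"],
            "t": err["t"],
            "p": err["p"],
        }
    )
    out = pd.DataFrame(rows)
    fam = out.groupby(["comparison", "predictor"])["p"].transform("size")
    out["p_bonferroni"] = np.minimum(out["p"] * fam, 1.0)
    return out


def bonferroni(p, family_size: int):
    """Bonferroni adjustment: p * m capped at 1."""
    return np.minimum(np.asarray(p, dtype=float) * family_size, 1.0)


def fit_all_models(
    indices: pd.DataFrame,
    scores: pd.DataFrame,
    responses: tuple[str, ...] = RESPONSES,
    drop_flagged: bool = False,
    with_posthoc: bool | tuple[str, ...] = True,
) -> dict[str, dict]:
    """Fit the component-measure models and (optionally) their post hocs.

    ``with_posthoc`` may be a tuple of response names to restrict the
    (relatively expensive) relevelled refits to the models that need them.
    """
    out = {}
    for response in responses:
        spec = ModelSpec(response=response, drop_flagged=drop_flagged)
        data = build_model_frame(indices, scores, spec)
        fit = fit_lmm(data, spec)
        entry = {"spec": spec, "data": data, "fit": fit}
        wants = with_posthoc if isinstance(with_posthoc, bool) else response in with_posthoc
        if wants:
            entry["posthoc"] = posthoc(fit, data, spec)
        out[response] = entry
    return out
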