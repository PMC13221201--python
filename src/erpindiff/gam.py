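"""GAM-style difference smoothing and component-index extraction.

For one participant x error type x electrode cell the model is

    amplitude_{trial}(t) = f0(t) + u_trial * f1(t) + b_item(trial) + eps

with ``u = 1`` for ungrammatical and ``0`` for grammatical trials, so ``f1``
is the smoothed ungrammatical-minus-grammatical difference wave.  ``f0`` and
``f1`` are cubic B-spline expansions with a second-difference penalty sharing
one smoothing parameter; the item intercept ``b_item`` is absorbed as an
extra ridge-penalized coefficient block, which is exactly the random-effects-
as-penalties view of a GAM.  Everything is solved by penalized least squares
on the normal equations, making the smoother checkable against a dense
generalized-ridge oracle.

Smoothing parameters are chosen by GCV on a log-spaced grid (a fixed lambda
is available for oracle tests).  The pointwise standard error of ``f1`` comes
from the usual smoother sandwich

    se(t)^2 = sigma^2 * b(t)^T (X'X+P)^-1 X'X (X'X+P)^-1 b(t)

restricted to the ``f1`` coefficient block.

From the fitted difference smooth two indices are read off inside a
component's search window: the Modeled Peak Latency (MPL), the latency of the
windowed extremum of ``f1`` (minimum for the N400, maximum for the P600),
and the Normalized Magnitude Peak (NMP), the signed extremum height divided
by 1.96 times its pointwise standard error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from scipy.linalg import cho_factor, cho_solve

from erpindiff.epochs import ELECTRODES_OF_INTEREST, ERROR_PAIRS, EpochTable

COMPONENT_EXTREMUM = {"N400": "min", "P600": "max"}


class CellFitError(RuntimeError):
    """Raised when a cell has too few trials for a stable fit."""


@dataclass
class SmoothConfig:
    n_basis: int = 20
    time_grid_step_ms: float = 1.0
    lambda_selection: str = "GCV"            # "GCV" | "fixed"
    lambda_grid: tuple[float, ...] = tuple(np.logspace(-2.0, 6.0, 9))
    item_lambda_grid: tuple[float, ...] = tuple(np.logspace(0.0, 3.0, 4))
    lambda_fixed: float = 1.0
    item_lambda_fixed: float = 1.0
    include_item_effect: bool = True
    windows: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"N400": (200.0, 550.0), "P600": (400.0, 950.0)}
    )
    electrodes: list[str] = field(default_factory=lambda: list(ELECTRODES_OF_INTEREST))
    flat_eps_uv: float = 1e-6
    min_trials_per_side: int = 2

    def validate(self) -> None:
        if self.n_basis < 8:
            raise ValueError("n_basis must be at least 8")
        if not self.electrodes:
            raise ValueError("electrodes must be nonempty")
        if self.lambda_selection not in ("GCV", "fixed"):
            raise ValueError(f"unknown lambda_selection {self.lambda_selection!r}")
        for name, (w0, w1) in self.windows.items():
            if w0 >= w1:
                raise ValueError(f"window {name} must be an increasing interval")

    def lambda_pairs(self) -> list[tuple[float, float]]:
        if self.lambda_selection == "fixed":
            return [(float(self.lambda_fixed), float(self.item_lambda_fixed))]
        items = self.item_lambda_grid if self.include_item_effect else (1.0,)
        return [(float(ls), float(li)) for ls in self.lambda_grid for li in items]


@dataclass
class DifferenceSmooth:
    """Fitted difference curve with pointwise SE on a dense time grid."""

    participant_id: str
    error_type: str
    electrode: str
    grid: np.ndarray
    f1: np.ndarray
    se: np.ndarray
    lambda_used: float
    item_lambda_used: float
    edf: float
    sigma2: float
    n_gram: int
    n_ungram: int


@dataclass
class ComponentIndex:
    participant_id: str
    error_type: str
    electrode: str
    component: str
    mpl_ms: float
    nmp: float
    boundary_flag: bool
    flat_flag: bool


def bspline_basis(x01: np.ndarray, n_basis: int) -> np.ndarray:
    """Clamped cubic B-spline basis on [0, 1] evaluated at ``x01``."""
    k = 3
    interior = np.linspace(0.0, 1.0, n_basis - k + 1)[1:-1]
    knots = np.concatenate([np.zeros(k + 1), interior, np.ones(k + 1)])
    B = BSpline(knots, np.eye(n_basis), k, extrapolate=False)(np.clip(x01, 0.0, 1.0))
    return np.nan_to_num(B)


def second_diff_penalty(n_basis: int) -> np.ndarray:
    D = np.diff(np.eye(n_basis), n=2, axis=0)
    return D.T @ D


def _canonical_order(u: np.ndarray) -> np.ndarray:
    """Stable trial order: grammatical trials first, then ungrammatical."""
    return np.argsort(u, kind="stable")


class CellStructure:
    """Design-dependent quantities of one cell layout, shared across cells.

    Everything except the response enters here: the basis, the penalty, the
    blocks of X'X and, per smoothing-parameter pair, the effective degrees of
    freedom and the sandwich variance profile of ``f1`` on the dense grid.
    Caching these makes extracting 39 x 2 x 12 cells (and Monte-Carlo
    replicates of them) cheap, because balanced designs share one layout.
    """

    def __init__(self, times: np.ndarray, u: np.ndarray, item_codes: np.ndarray, cfg: SmoothConfig):
        self.cfg = cfg
        self.times = np.asarray(times, dtype=float)
        self.u = np.asarray(u, dtype=bool)
        self.item_codes = np.asarray(item_codes)
        self.n_trials = len(self.u)
        self.n_times = len(self.times)
        self.n_items = int(self.item_codes.max()) + 1 if self.cfg.include_item_effect else 0
        K = cfg.n_basis
        t0, t1 = self.times[0], self.times[-1]
        self.span = (t0, t1)
        x01 = (self.times - t0) / (t1 - t0)
        self.B = bspline_basis(x01, K)
        self.grid = np.arange(t0, t1 + cfg.time_grid_step_ms / 2, cfg.time_grid_step_ms)
        self.B_grid = bspline_basis((self.grid - t0) / (t1 - t0), K)
        self.S = second_diff_penalty(K)
        G = self.B.T @ self.B
        g0 = self.B.sum(axis=0)
        n_u = int(self.u.sum())
        p = 2 * K + self.n_items
        XtX = np.zeros((p, p))
        XtX[:K, :K] = self.n_trials * G
        XtX[:K, K : 2 * K] = n_u * G
        XtX[K : 2 * K, :K] = n_u * G
        XtX[K : 2 * K, K : 2 * K] = n_u * G
        if self.n_items:
            m = np.bincount(self.item_codes, minlength=self.n_items).astype(float)
            m_u = np.bincount(self.item_codes[self.u], minlength=self.n_items).astype(float)
            XtX[:K, 2 * K :] = g0[:, None] * m[None, :]
            XtX[2 * K :, :K] = XtX[:K, 2 * K :].T
            XtX[K : 2 * K, 2 * K :] = g0[:, None] * m_u[None, :]
            XtX[2 * K :, K : 2 * K] = XtX[K : 2 * K, 2 * K :].T
            XtX[2 * K :, 2 * K :] = np.diag(m * self.n_times)
        self.XtX = XtX
        self.K = K
        self.n = self.n_trials * self.n_times
        self._edf: dict[tuple[float, float], float] = {}
        self._var_unit: dict[tuple[float, float], np.ndarray] = {}

    def key(self) -> tuple:
        return (self.n_times, int(self.u.sum()), self.n_trials, self.n_items)

    def penalty(self, lam_s: float, lam_i: float) -> np.ndarray:
        K, p = self.K, self.XtX.shape[0]
        P = np.zeros((p, p))
        P[:K, :K] = lam_s * self.S
        P[K : 2 * K, K : 2 * K] = lam_s * self.S
        if self.n_items:
            P[2 * K :, 2 * K :] = lam_i * np.eye(self.n_items)
        return P

    def _factor(self, lam_s: float, lam_i: float):
        return cho_factor(self.XtX + self.penalty(lam_s, lam_i), lower=True)

    def edf(self, lam_s: float, lam_i: float, factor=None) -> float:
        key = (lam_s, lam_i)
        if key not in self._edf:
            c = factor if factor is not None else self._factor(lam_s, lam_i)
            self._edf[key] = float(np.trace(cho_solve(c, self.XtX)))
        return self._edf[key]

    def var_unit(self, lam_s: float, lam_i: float, factor=None) -> np.ndarray:
        """Unit-variance sandwich profile of f1 on the grid (multiply by sigma^2)."""
        key = (lam_s, lam_i)
        if key not in self._var_unit:
            c = factor if factor is not None else self._factor(lam_s, lam_i)
            V1 = cho_solve(c, self.XtX)
            V2 = cho_solve(c, V1.T)  # (X'X+P)^-1 X'X (X'X+P)^-1
            K = self.K
            M = V2[K : 2 * K, K : 2 * K]
            v = np.einsum("gk,kl,gl->g", self.B_grid, M, self.B_grid)
            self._var_unit[key] = np.maximum(v, 0.0)
        return self._var_unit[key]

    def cross_products(self, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """X'y and y'y for a stack of cells ``Y`` (n_trials, n_cells, n_times)."""
        n_trials, n_cells, _ = Y.shape
        z0 = self.B.T @ Y.sum(axis=0).T                      # (K, n_cells)
        z1 = self.B.T @ Y[self.u].sum(axis=0).T
        blocks = [z0, z1]
        if self.n_items:
            per_trial = Y.sum(axis=-1)                       # (n_trials, n_cells)
            z_items = np.zeros((self.n_items, n_cells))
            np.add.at(z_items, self.item_codes, per_trial)
            blocks.append(z_items)
        Z = np.concatenate(blocks, axis=0)
        yty = np.einsum("tcs,tcs->c", Y, Y)
        return Z, yty

    def fit_cells(self, Y: np.ndarray) -> list[dict]:
        """Penalized LS fit of every cell in ``Y``; GCV-selected smoothing.

        Returns one dict per cell with the f1 curve, pointwise SE, selected
        smoothing parameters, edf and the residual variance estimate.
        """
        Z, yty = self.cross_products(Y)
        n_cells = Z.shape[1]
        pairs = self.cfg.lambda_pairs()
        rss_all = np.empty((len(pairs), n_cells))
        beta_all = []
        edf_all = np.empty(len(pairs))
        for i, (ls, li) in enumerate(pairs):
            c = self._factor(ls, li)
            beta = cho_solve(c, Z)
            W = self.XtX @ beta
            rss = yty - 2.0 * np.einsum("pc,pc->c", beta, Z) + np.einsum("pc,pc->c", beta, W)
            rss_all[i] = np.maximum(rss, 0.0)
            beta_all.append(beta)
            edf_all[i] = self.edf(ls, li, factor=c)
        if len(pairs) == 1:
            chosen = np.zeros(n_cells, dtype=int)
        else:
            gcv = self.n * rss_all / (self.n - edf_all[:, None]) ** 2
            chosen = np.argmin(gcv, axis=0)
        out = []
        K = self.K
        for j in range(n_cells):
            i = chosen[j]
            ls, li = pairs[i]
            beta = beta_all[i][:, j]
            edf = edf_all[i]
            sigma2 = rss_all[i, j] / max(self.n - edf, 1.0)
            f1 = self.B_grid @ beta[K : 2 * K]
            se = np.sqrt(sigma2 * self.var_unit(ls, li))
            out.append(
                {
                    "f1": f1,
                    "se": se,
                    "lambda_used": ls,
                    "item_lambda_used": li,
                    "edf": edf,
                    "sigma2": sigma2,
                }
            )
        return out


class StructureCache:
    """Reuses :class:`CellStructure` objects across cells with one layout.

    Safe to share across calls (e.g. Monte-Carlo replicates) that use the
    same :class:`SmoothConfig`.
    """

    def __init__(self, cfg: SmoothConfig):
        self.cfg = cfg
        self._structures: dict[tuple, CellStructure] = {}

    def get(self, times: np.ndarray, u: np.ndarray, item_codes: np.ndarray) -> CellStructure:
        key = (
            len(times),
            float(times[0]),
            float(times[-1]),
            u.tobytes(),
            item_codes.tobytes(),
        )
        if key not in self._structures:
            self._structures[key] = CellStructure(times, u, item_codes, self.cfg)
        return self._structures[key]


def _prepare_cell(times, amplitudes, is_ungrammatical, item_ids, cfg):
    u = np.asarray(is_ungrammatical, dtype=bool)
    Y = np.asarray(amplitudes, dtype=float)
    if Y.ndim == 2:
        Y = Y[:, None, :]
    n_u = int(u.sum())
    n_g = len(u) - n_u
    if n_g < cfg.min_trials_per_side or n_u < cfg.min_trials_per_side:
        raise CellFitError(
            f"need at least {cfg.min_trials_per_side} trials per side, got {n_g} grammatical / {n_u} ungrammatical"
        )
    order = _canonical_order(u)
    u = u[order]
    Y = Y[order]
    if cfg.include_item_effect:
        items = pd.factorize(np.asarray(item_ids)[order])[0]
    else:
        items = np.zeros(len(u), dtype=int)
    return Y, u, items


def fit_difference_smooth(
    times: np.ndarray,
    amplitudes: np.ndarray,
    is_ungrammatical: np.ndarray,
    item_ids,
    cfg: SmoothConfig,
    *,
    participant_id: str = "",
    error_type: str = "",
    electrode: str = "",
    cache: StructureCache | None = None,
) -> DifferenceSmooth:
    """Fit the difference smooth for a single cell.

    ``amplitudes`` is (n_trials, n_times) for one electrode; ``item_ids``
    labels the sentence items so trial-level variability can be absorbed by
    the ridge-penalized item block.
    """
    cfg.validate()
    Y, u, items = _prepare_cell(times, amplitudes, is_ungrammatical, item_ids, cfg)
    structure = (cache or StructureCache(cfg)).get(np.asarray(times, float), u, items)
    res = structure.fit_cells(Y)[0]
    return DifferenceSmooth(
        participant_id=participant_id,
        error_type=error_type,
        electrode=electrode,
        grid=structure.grid,
        n_gram=int((~u).sum()),
        n_ungram=int(u.sum()),
        **res,
    )


def extract_index(smooth: DifferenceSmooth, component: str, cfg: SmoothConfig) -> ComponentIndex:
    """Windowed-extremum MPL and NMP for one component.

    The N400 takes the windowed minimum of ``f1``, the P600 the maximum;
    NMP = f1(MPL) / (1.96 * se(MPL)).  Ties break to the earliest latency.
    A peak on a window edge sets ``boundary_flag``; a difference curve whose
    windowed magnitude stays below ``flat_eps_uv`` sets ``flat_flag`` with
    NMP 0.
    """
    w0, w1 = cfg.windows[component]
    mask = (smooth.grid >= w0) & (smooth.grid <= w1)
    if not mask.any():
        raise ValueError(f"smooth grid does not cover the {component} window")
    grid = smooth.grid[mask]
    f = smooth.f1[mask]
    se = smooth.se[mask]
    flat = bool(np.max(np.abs(f)) < cfg.flat_eps_uv)
    idx = int(np.argmin(f) if COMPONENT_EXTREMUM[component] == "min" else np.argmax(f))
    peak = f[idx]
    with np.errstate(divide="ignore", invalid="ignore"):
        nmp = 0.0 if flat else float(peak / (1.96 * se[idx]))
    return ComponentIndex(
        participant_id=smooth.participant_id,
        error_type=smooth.error_type,
        electrode=smooth.electrode,
        component=component,
        mpl_ms=float(grid[idx]),
        nmp=nmp,
        boundary_flag=bool(idx == 0 or idx == len(grid) - 1),
        flat_flag=flat,
    )


def extract_all(
    epochs: EpochTable,
    cfg: SmoothConfig,
    cache: StructureCache | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Fit and extract every participant x error type x electrode x component.

    Cells whose grammatical or ungrammatical side is missing are skipped and
    reported; the returned frame has one row per extracted index.
    """
    cfg.validate()
    cache = cache or StructureCache(cfg)
    electrodes = [e for e in cfg.electrodes if e in epochs.channels]
    if not electrodes:
        raise ValueError("none of the configured electrodes are present in the epochs")
    elec_idx = np.array([epochs.channel_index(e) for e in electrodes])
    rows = []
    report = {"skipped_cells": [], "n_fitted": 0}
    conditions = epochs.trials["condition"].to_numpy()
    for pid, ptrials in epochs.trials.groupby("participant_id", sort=True):
        for error_type, (gram, ungram) in ERROR_PAIRS.items():
            sel = ptrials.index[ptrials["condition"].isin([gram, ungram])].to_numpy()
            if len(sel) == 0:
                report["skipped_cells"].append(f"{pid}/{error_type}: no trials")
                continue
            u = conditions[sel] == ungram
            try:
                Y, u_c, items = _prepare_cell(
                    epochs.times,
                    epochs.data[sel][:, elec_idx, :],
                    u,
                    epochs.trials["item_id"].to_numpy()[sel],
                    cfg,
                )
            except CellFitError as err:
                report["skipped_cells"].append(f"{pid}/{error_type}: {err}")
                continue
            structure = cache.get(epochs.times, u_c, items)
            for e_name, res in zip(electrodes, structure.fit_cells(Y)):
                smooth = DifferenceSmooth(
                    participant_id=str(pid),
                    error_type=error_type,
                    electrode=e_name,
                    grid=structure.grid,
                    n_gram=int((~u_c).sum()),
                    n_ungram=int(u_c.sum()),
                    **res,
                )
                report["n_fitted"] += 1
                for component in cfg.windows:
                    rows.append(extract_index(smooth, component, cfg).__dict__)
    table = pd.DataFrame(
        rows,
        columns=[
            "participant_id", "error_type", "electrode", "component",
            "mpl_ms", "nmp", "boundary_flag", "flat_flag",
        ],
    )
    if report["skipped_cells"]:
        warnings.warn(f"{len(report['skipped_cells'])} cells skipped during extraction")
    return table, report


def plot_extraction(smooth: DifferenceSmooth, cfg: SmoothConfig, path) -> None:
    """Diagnostic figure: difference smooth, confidence band, search windows
    and the MPL of each component."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, len(cfg.windows), figsize=(5 * len(cfg.windows), 3.2), sharey=True)
    axes = np.atleast_1d(axes)
    for ax, component in zip(axes, cfg.windows):
        idx = extract_index(smooth, component, cfg)
        ax.axvspan(*cfg.windows[component], color="red", alpha=0.12, label="search window")
        ax.plot(smooth.grid, smooth.f1, color="black", lw=1.2, label="difference smooth")
        ax.fill_between(
            smooth.grid,
            smooth.f1 - 1.96 * smooth.se,
            smooth.f1 + 1.96 * smooth.se,
            color="purple",
            alpha=0.25,
            label="1.96 SE band",
        )
        ax.axvline(idx.mpl_ms, ls=(0, (8, 4)), color="blue", label=f"MPL {idx.mpl_ms:.0f} ms")
        ax.axhline(0.0, color="grey", lw=0.6)
        ax.set_title(f"{smooth.participant_id} {smooth.error_type} {smooth.electrode} {component} (NMP {idx.nmp:.2f})")
        ax.set_xlabel("time (ms)")
        ax.legend(fontsize=7)
    axes[0].set_ylabel("amplitude (uV)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
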