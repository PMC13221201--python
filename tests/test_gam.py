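import numpy as np
import pandas as pd
import pytest

from erpindiff.gam import (
    CellFitError,
    ComponentIndex,
    DifferenceSmooth,
    SmoothConfig,
    StructureCache,
    bspline_basis,
    extract_all,
    extract_index,
    fit_difference_smooth,
    second_diff_penalty,
)
from erpindiff.simulate import sample_cohort, simulate_epochs
from tests.conftest import noiseless_config


def dense_ridge_oracle(times, Y, u, lam, n_basis):
    """Brute-force generalized ridge: beta = (X'X + lam D'D)^-1 X'y with the
    full design matrix assembled densely."""
    n_trials, n_times = Y.shape
    x01 = (times - times[0]) / (times[-1] - times[0])
    B = bspline_basis(x01, n_basis)
    X = np.zeros((n_trials * n_times, 2 * n_basis))
    for i in range(n_trials):
        X[i * n_times : (i + 1) * n_times, :n_basis] = B
        if u[i]:
            X[i * n_times : (i + 1) * n_times, n_basis:] = B
    S = second_diff_penalty(n_basis)
    P = np.zeros((2 * n_basis, 2 * n_basis))
    P[:n_basis, :n_basis] = lam * S
    P[n_basis:, n_basis:] = lam * S
    return np.linalg.solve(X.T @ X + P, X.T @ Y.reshape(-1))


def random_instance(rng, n_times=30, n_trials=10):
    times = np.linspace(-200.0, 950.0, n_times)
    while True:
        u = rng.random(n_trials) < 0.5
        if 2 <= u.sum() <= n_trials - 2:
            break
    Y = rng.normal(size=(n_trials, n_times))
    lam = 10.0 ** rng.uniform(-1.0, 3.0)
    return times, Y, u, lam


def test_fixed_lambda_fit_matches_dense_ridge_oracle():
    """20 random small instances; the structured solver must agree with the
    dense generalized-ridge solution to 1e-8."""
    rng = np.random.default_rng(314)
    n_basis = 12
    for _ in range(20):
        times, Y, u, lam = random_instance(rng)
        cfg = SmoothConfig(
            lambda_selection="fixed", lambda_fixed=lam, include_item_effect=False, n_basis=n_basis
        )
        sm = fit_difference_smooth(times, Y, u, np.arange(len(u)), cfg)
        beta = dense_ridge_oracle(times, Y, u, lam, n_basis)
        Bg = bspline_basis((sm.grid - times[0]) / (times[-1] - times[0]), n_basis)
        np.testing.assert_allclose(sm.f1, Bg @ beta[n_basis:], atol=1e-8)


def test_identical_trials_give_zero_difference(noiseless_epochs):
    """Grammatical and ungrammatical trials drawn from one template must
    yield an (essentially) zero difference curve."""
    epochs, _ = noiseless_epochs
    tr = epochs.trials
    sel = ((tr.participant_id == "P01") & (tr.condition == "GramFem")).to_numpy()
    Y = epochs.data[sel][:, 0, :]
    u = np.arange(Y.shape[0]) % 2 == 0  # split identical trials arbitrarily
    sm = fit_difference_smooth(epochs.times, Y, u, tr.item_id[sel].to_numpy(), SmoothConfig())
    assert np.abs(sm.f1).max() < 1e-8


def test_noiseless_bump_recovery(noiseless_epochs):
    epochs, cfg = noiseless_epochs
    tr = epochs.trials
    sel = (tr.participant_id == "P01") & tr.condition.isin(["GramFem", "UngramFem"])
    u = (tr.condition[sel] == "UngramFem").to_numpy()
    sm = fit_difference_smooth(
        epochs.times, epochs.data[sel.to_numpy()][:, 0, :], u, tr.item_id[sel].to_numpy(), SmoothConfig()
    )
    tpl = cfg.templates["N400"]
    expected = tpl.base_amp_uv["Default"] * np.exp(
        -((sm.grid - tpl.center_ms) ** 2) / (2 * tpl.width_ms**2)
    ) + cfg.templates["P600"].base_amp_uv["Default"] * np.exp(
        -((sm.grid - 650.0) ** 2) / (2 * 150.0**2)
    )
    assert np.abs(sm.f1 - expected).max() < 0.05


class TestExtractIndex:
    grid = np.arange(-200.0, 949.0, 1.0)
    se = np.full_like(grid, 0.5)
    cfg = SmoothConfig()

    def smooth_with(self, f1):
        return DifferenceSmooth("p", "Default", "Cz", self.grid, f1, self.se, 1.0, 1.0, 5.0, 1.0, 10, 10)

    def test_gaussian_bump_closed_form(self):
        f1 = -3.0 * np.exp(-((self.grid - 420.0) ** 2) / (2 * 80.0**2))
        idx = extract_index(self.smooth_with(f1), "N400", self.cfg)
        assert idx.mpl_ms == 420.0
        assert idx.nmp == pytest.approx(-3.0 / (1.96 * 0.5), abs=1e-12)
        assert not idx.boundary_flag and not idx.flat_flag

    def test_flat_curve_flags(self):
        idx = extract_index(self.smooth_with(np.zeros_like(self.grid)), "N400", self.cfg)
        assert idx.nmp == 0.0 and idx.flat_flag

    def test_bump_outside_window_hits_boundary(self):
        f1 = -3.0 * np.exp(-((self.grid - 100.0) ** 2) / (2 * 80.0**2))
        idx = extract_index(self.smooth_with(f1), "N400", self.cfg)
        assert idx.mpl_ms == 200.0 and idx.boundary_flag

    def test_p600_takes_windowed_maximum(self):
        f1 = 2.0 * np.exp(-((self.grid - 650.0) ** 2) / (2 * 150.0**2))
        idx = extract_index(self.smooth_with(f1), "P600", self.cfg)
        assert idx.mpl_ms == 650.0
        assert idx.nmp == pytest.approx(2.0 / (1.96 * 0.5), abs=1e-12)


def analytic_difference(cfg, grid, error_type="Default"):
    """Noiseless injected difference curve (sum of the component bumps)."""
    out = np.zeros_like(grid)
    for tpl in cfg.templates.values():
        out = out + tpl.base_amp_uv[error_type] * np.exp(
            -((grid - tpl.center_ms) ** 2) / (2 * tpl.width_ms**2)
        )
    return out


def test_mpl_recovery_within_grid_step(noiseless_epochs):
    """On noiseless data the MPL lands within one grid step of the analytic
    difference curve's windowed extremum (the overlapping P600 tail shifts
    the composite minimum away from the N400 bump centre, so the reference
    is the composite curve, not the template centre)."""
    epochs, gen_cfg = noiseless_epochs
    cfg = SmoothConfig(electrodes=["Cz", "Pz"])
    indices, _ = extract_all(epochs, cfg)
    grid = np.arange(epochs.times[0], epochs.times[-1] + 0.5, cfg.time_grid_step_ms)
    f = analytic_difference(gen_cfg, grid)
    for component, pick in (("N400", np.argmin), ("P600", np.argmax)):
        w0, w1 = cfg.windows[component]
        mask = (grid >= w0) & (grid <= w1)
        expected = grid[mask][pick(f[mask])]
        rows = indices[indices.component == component]
        assert (rows.mpl_ms - expected).abs().max() <= cfg.time_grid_step_ms


def test_nmp_scale_invariance(noisy_small_epochs):
    """Multiplying a cell's amplitudes by a > 0 rescales f1 and se together
    and leaves the NMP unchanged (GCV is scale-free)."""
    epochs, _ = noisy_small_epochs
    tr = epochs.trials
    sel = ((tr.participant_id == "P01") & tr.condition.isin(["GramMasc", "UngramMasc"])).to_numpy()
    u = (tr.condition[sel] == "UngramMasc").to_numpy()
    items = tr.item_id[sel].to_numpy()
    cfg = SmoothConfig()
    a = 3.7
    sm1 = fit_difference_smooth(epochs.times, epochs.data[sel][:, 2, :], u, items, cfg)
    sm2 = fit_difference_smooth(epochs.times, a * epochs.data[sel][:, 2, :], u, items, cfg)
    np.testing.assert_allclose(sm2.f1, a * sm1.f1, rtol=1e-9, atol=1e-9)
    idx1 = extract_index(sm1, "N400", cfg)
    idx2 = extract_index(sm2, "N400", cfg)
    assert idx2.nmp == pytest.approx(idx1.nmp, abs=1e-6)
    assert idx2.mpl_ms == idx1.mpl_ms


def test_nmp_magnitude_monotone_in_injected_amplitude():
    """With noise held fixed, a larger injected difference never shrinks the
    windowed |NMP|."""
    rng = np.random.default_rng(99)
    times = np.arange(-200.0, 949.0, 4.0)
    n_trials = 24
    noise = rng.normal(0.0, 3.0, size=(n_trials, len(times)))
    u = np.arange(n_trials) % 2 == 1
    bump = np.exp(-((times - 420.0) ** 2) / (2 * 80.0**2))
    cfg = SmoothConfig()
    nmps = []
    for amp in (0.5, 1.5, 3.0, 6.0):
        Y = noise + np.where(u, -amp, 0.0)[:, None] * bump[None, :]
        sm = fit_difference_smooth(times, Y, u, np.arange(n_trials), cfg)
        nmps.append(abs(extract_index(sm, "N400", cfg).nmp))
    assert all(b >= a - 1e-9 for a, b in zip(nmps, nmps[1:]))


def test_extract_all_row_count_and_determinism(noiseless_epochs):
    epochs, _ = noiseless_epochs
    cfg = SmoothConfig(electrodes=["Cz", "Pz", "C3"])
    indices, report = extract_all(epochs, cfg)
    # participants x error types x electrodes x components
    assert len(indices) == 2 * 2 * 3 * 2
    assert report["skipped_cells"] == []
    again, _ = extract_all(epochs, cfg)
    pd.testing.assert_frame_equal(indices, again)


def test_full_design_yields_1872_indices():
    """39 participants x 2 error types x 12 electrodes x 2 components."""
    cfg = noiseless_config(n_participants=39, trials_per_condition=4, seed=21)
    epochs = simulate_epochs(sample_cohort(cfg), None, cfg)
    indices, _ = extract_all(epochs, SmoothConfig())
    assert len(indices) == 39 * 2 * 12 * 2 == 1872


def test_missing_ungrammatical_side_is_skipped_and_logged(noiseless_epochs):
    epochs, _ = noiseless_epochs
    keep = ~(
        (epochs.trials.participant_id == "P01")
        & (epochs.trials.condition == "UngramFem")
    ).to_numpy()
    reduced = epochs.select_trials(keep)
    cfg = SmoothConfig(electrodes=["Cz"])
    with pytest.warns(UserWarning):
        indices, report = extract_all(reduced, cfg)
    assert any("P01/Default" in s for s in report["skipped_cells"])
    assert not ((indices.participant_id == "P01") & (indices.error_type == "Default")).any()


def test_too_few_trials_raise_cell_fit_error():
    times = np.linspace(-200, 948, 50)
    Y = np.zeros((3, 50))
    with pytest.raises(CellFitError):
        fit_difference_smooth(times, Y, np.array([True, False, False]), np.arange(3), SmoothConfig())


def test_structure_cache_reuse_gives_identical_results(noisy_small_epochs):
    epochs, _ = noisy_small_epochs
    cfg = SmoothConfig(electrodes=["Cz", "Pz"])
    cache = StructureCache(cfg)
    first, _ = extract_all(epochs, cfg, cache)
    second, _ = extract_all(epochs, cfg, cache)
    pd.testing.assert_frame_equal(first, second)


def test_plot_extraction_writes_figure(tmp_path, noiseless_epochs):
    epochs, _ = noiseless_epochs
    tr = epochs.trials
    sel = (tr.participant_id == "P01") & tr.condition.isin(["GramFem", "UngramFem"])
    u = (tr.condition[sel] == "UngramFem").to_numpy()
    sm = fit_difference_smooth(
        epochs.times, epochs.data[sel.to_numpy()][:, 0, :], u, tr.item_id[sel].to_numpy(), SmoothConfig()
    )
    from erpindiff.gam import plot_extraction

    out = tmp_path / "cell.png"
    plot_extraction(sm, SmoothConfig(), out)
    assert out.stat().st_size > 0
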