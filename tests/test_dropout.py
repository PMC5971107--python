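"""Dropout hazards, observation probabilities, weights, u-MAR screen."""

import numpy as np
import pandas as pd
import pytest

from mortalcohort import simulate as sim
from mortalcohort.data import PanelData
from mortalcohort.dropout import fit_dropout, observation_prob, weights
from mortalcohort.dropout import test_umar as umar_screen

from conftest import toy_panel


def saturated_two_visit(n_per_cell=40, seed=0):
    """Binary Y1, binary sex, J=2: hazards are empirical cell frequencies."""
    rng = np.random.default_rng(seed)
    rows = []
    p_obs = {(0, 0): 0.8, (0, 1): 0.5, (1, 0): 0.6, (1, 1): 0.3}
    for y1 in (0, 1):
        for x in (0, 1):
            for _ in range(n_per_cell):
                r2 = int(rng.random() < p_obs[(y1, x)])
                rows.append((y1, x, r2))
    y1, x, r2 = map(np.array, zip(*rows))
    Y = np.column_stack([y1.astype(float), np.where(r2 == 1, 1.0, np.nan)])
    R = np.column_stack([np.ones_like(r2), r2])
    d = PanelData(Y=Y, R=R, D=np.full(len(rows), 2),
                  covariates=pd.DataFrame({"sex": x.astype(float)}),
                  z_cols=["sex"])
    return d, y1, x, r2


def test_saturated_fit_matches_empirical_frequencies():
    d, y1, x, r2 = saturated_two_visit()
    # interaction column makes the model saturated over the 4 cells
    d.covariates["y1x"] = (y1 * x).astype(float)
    d.x_cols = ["sex", "y1x"]
    fit = fit_dropout(d, variant="u")
    pi = observation_prob(fit, d)
    for yv in (0, 1):
        for xv in (0, 1):
            cell = (y1 == yv) & (x == xv)
            emp = r2[cell].mean()
            assert pi[cell, 1] == pytest.approx(emp, abs=1e-6)


def test_no_dropout_errors_without_degenerate_flag():
    d = toy_panel(np.ones((30, 3)), np.ones((30, 3), dtype=int), [3] * 30)
    with pytest.raises(ValueError, match="no non-events"):
        fit_dropout(d, variant="u")
    fit = fit_dropout(d, variant="u", allow_degenerate=True)
    assert np.allclose(observation_prob(fit, d), 1.0)


def test_cumulative_product_arithmetic():
    """Hand-set hazards 0.8 then 0.5 give pi_3 = 0.4."""
    d = toy_panel(np.ones((10, 3)), np.ones((10, 3), dtype=int), [3] * 10)
    fit = fit_dropout(d, variant="u", allow_degenerate=True)
    from scipy.special import logit

    for k, p in ((2, 0.8), (3, 0.5)):
        fit.models[k].degenerate = ""
        fit.models[k].coef = np.array([logit(p)] + [0.0] * (len(fit.models[k].coef) - 1))
    pi = observation_prob(fit, d)
    assert pi[0, 0] == pytest.approx(1.0)
    assert pi[0, 1] == pytest.approx(0.8)
    assert pi[0, 2] == pytest.approx(0.4)


def test_weight_flooring():
    d = toy_panel(np.ones((10, 2)), np.ones((10, 2), dtype=int), [2] * 10)
    fit = fit_dropout(d, variant="u", allow_degenerate=True)
    from scipy.special import logit

    fit.models[2].degenerate = ""
    fit.models[2].coef = np.array([logit(0.001)] + [0.0] * (len(fit.models[2].coef) - 1))
    ws = weights(fit, d, floor=0.01)
    assert ws.w[0, 1] == pytest.approx(100.0)
    assert ws.n_floored == 10
    exact = weights(fit, d, floor=0.0)
    assert exact.w[0, 1] == pytest.approx(1000.0, rel=1e-6)
    assert np.all(ws.w[np.isfinite(ws.w)] >= 1.0)


def test_u_variant_ignores_future_information(dag1_data_small):
    """pi for the u variant never uses visits beyond k: altering D (and the
    post-dropout future) of other subjects' records leaves each subject's
    own fitted probability unchanged when the fit is re-used."""
    d = dag1_data_small
    fit = fit_dropout(d, variant="u")
    pi1 = observation_prob(fit, d)
    perturbed = d.copy()
    # move death times of dropped-out subjects later (future info only)
    dropped = perturbed.last_observed < perturbed.D
    perturbed.D[dropped] = perturbed.n_visits
    pi2 = observation_prob(fit, perturbed)
    obs = d.observed
    assert np.allclose(pi1[obs], pi2[obs], equal_nan=True)


def test_f_strat_reduces_to_f_cov_for_shared_slopes(dag1_data_small):
    """With every stratum forced to fall back, the stratified fit evaluates
    the D-as-covariate models exactly."""
    d = dag1_data_small
    strat = fit_dropout(d, variant="f_strat", stratum_min=10**9)
    cov = fit_dropout(d, variant="f_cov")
    pi_s = observation_prob(strat, d)
    pi_c = observation_prob(cov, d)
    obs = d.observed
    assert np.allclose(pi_s[obs], pi_c[obs], equal_nan=True)
    assert len(strat.fallbacks) > 0


def test_horvitz_thompson_balance(spec5):
    """Correctly specified weights rebalance observed cells to the alive
    population: sum_i R_ij w_ij / (# alive at j) ~ 1."""
    d = sim.generate(sim.dag1_config(n_subjects=100_000), seed=55)
    fit = fit_dropout(d, variant="u")
    ws = weights(fit, d, floor=0.0)
    for j in range(1, 6):
        alive = d.D >= j
        obs = d.observed[:, j - 1]
        ratio = np.nansum(ws.w[obs, j - 1]) / alive.sum()
        assert abs(ratio - 1.0) < 0.02


class TestUmarScreen:
    def test_power_under_death_driven_dropout(self):
        d = sim.generate(sim.dfirst_config(n_subjects=2000), seed=3)
        tab = umar_screen(d)
        assert (tab["p_value"] < 0.05).any()

    def test_type_i_error_under_u_mar(self):
        hits, total = 0, 0
        for rep in range(60):
            d = sim.generate(sim.dag1_config(n_subjects=1200), seed=1000 + rep)
            tab = umar_screen(d)
            hits += int((tab["p_value"] < 0.05).sum())
            total += len(tab)
        rate = hits / total
        assert 0.01 < rate < 0.11

    def test_degenerate_death_distribution(self):
        d = toy_panel(np.ones((40, 3)), np.ones((40, 3), dtype=int), [3] * 40)
        d.R[::3, 2] = 0
        d.Y[::3, 2] = np.nan
        with pytest.raises(ValueError, match="one level"):
            umar_screen(d)


def test_dag1_hazard_recovers_true_coefficients(spec5):
    """M-estimation consistency: u-variant hazard coefficients approach the
    generating dropout coefficients."""
    cfg = sim.dag1_config(n_subjects=30_000)
    d = sim.generate(cfg, seed=21)
    import statsmodels.api as sm

    fit = fit_dropout(d, variant="u")
    for k in (2, 3):
        est = fit.models[k].coef  # const, y_{k-1}, sex
        true = np.array([cfg.drop_intercept[k - 2], cfg.drop_lag, cfg.drop_sex])
        # sampling error scale from an independent refit of the same model
        at_risk = (d.R[:, k - 2] == 1) & (d.D >= k)
        X = np.column_stack([np.ones(d.n_subjects), d.Y[:, k - 2],
                             d.covariates["sex"].to_numpy(float)])
        ref = sm.Logit(d.R[at_risk, k - 1], X[at_risk]).fit(disp=0)
        assert np.allclose(est, np.asarray(ref.params), atol=1e-6)
        assert np.all(np.abs(est - true) < 4.5 * np.asarray(ref.bse))
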