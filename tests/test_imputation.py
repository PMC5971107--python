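"""Sequential imputation: fits, MI draws, deterministic fill, Rubin's rules."""

import numpy as np
import pytest

from mortalcohort import simulate as sim
from mortalcohort.design import visit_sex_design
from mortalcohort.estimators import solve_iee
from mortalcohort.imputation import (
    estimate_li,
    estimate_mi,
    fit_sequential,
    li_impute,
    mi_impute,
    rubin_combine,
)
from mortalcohort.results import EstimateResult

from conftest import toy_panel


def test_fit_recovers_generating_coefficients():
    cfg = sim.dag1_config(n_subjects=10_000, no_dropout=True)
    d = sim.generate(cfg, seed=14)
    fit = fit_sequential(d, stratify="none")
    for j in (2, 4):
        m = fit.models[(j, None)]           # const, y_{j-1}, sex
        true = np.array([cfg.y_intercept[j - 2], cfg.y_lag, cfg.y_sex])
        assert np.allclose(m.coef, true, atol=0.1)
        assert m.sigma2 == pytest.approx(cfg.y_sd**2, rel=0.1)


def test_degenerate_residual_variance_flagged():
    Y = np.tile(np.array([[1.0], [2.0], [3.0], [4.0], [5.0]]), (1, 2))
    d = toy_panel(Y, np.ones((5, 2), dtype=int), [2] * 5, sex=[0, 1, 0, 1, 0])
    with pytest.raises(ValueError, match="degenerate residual variance"):
        fit_sequential(d)


def test_thin_stratum_falls_back(dag1_data_small):
    fit = fit_sequential(dag1_data_small, stratify="stratum", stratum_min=10**6)
    assert len(fit.fallbacks) > 0
    # fallback chains still complete every alive cell
    imp = li_impute(dag1_data_small, fit)
    assert np.all(np.isfinite(imp.panel.Y[imp.panel.alive]))


def test_li_single_cell_arithmetic():
    """One subject, J=2, Y1=2 observed, fit (rho, phi, psi) = (1, .5, 0):
    imputed Y2 = 1 + 0.5 * 2 = 2."""
    d = toy_panel([[2.0, np.nan], [1.0, 1.8], [3.0, 2.4], [0.0, 1.1], [2.5, 2.0]],
                  [[1, 0], [1, 1], [1, 1], [1, 1], [1, 1]], [2] * 5,
                  sex=[0, 1, 0, 1, 0])
    fit = fit_sequential(d)
    m = fit.models[(2, None)]
    m.coef = np.array([1.0, 0.5, 0.0])
    imp = li_impute(d, fit)
    assert imp.panel.Y[0, 1] == pytest.approx(2.0)


def test_li_chained_fill_matches_hand_composition():
    """J=3 fill equals composing the two conditional means."""
    rng = np.random.default_rng(0)
    n = 200
    sex = rng.integers(0, 2, size=n).astype(float)
    y1 = rng.normal(size=n)
    y2 = 0.5 + 0.8 * y1 - 0.3 * sex + rng.normal(scale=0.5, size=n)
    y3 = -0.2 + 0.6 * y2 + 0.2 * sex + rng.normal(scale=0.5, size=n)
    R = np.ones((n, 3), dtype=int)
    R[:40, 1:] = 0   # first 40 subjects observed at visit 1 only
    Y = np.column_stack([y1, y2, y3])
    d = toy_panel(np.where(R == 1, Y, np.nan), R, [3] * n, sex=sex)
    fit = fit_sequential(d)
    imp = li_impute(d, fit)
    c2 = fit.models[(2, None)].coef
    c3 = fit.models[(3, None)].coef
    for i in range(5):
        f2 = c2[0] + c2[1] * y1[i] + c2[2] * sex[i]
        f3 = c3[0] + c3[1] * f2 + c3[2] * sex[i]
        assert imp.panel.Y[i, 1] == pytest.approx(f2, abs=1e-10)
        assert imp.panel.Y[i, 2] == pytest.approx(f3, abs=1e-10)


def test_imputation_preserves_observed_and_deletes_post_death():
    d = sim.generate(sim.dag2_config(n_subjects=600), seed=9)
    fit = fit_sequential(d, stratify="covariate")
    imps = mi_impute(d, fit, M=3, seed=1)
    for imp in imps:
        obs = d.observed
        assert np.allclose(imp.panel.Y[obs], d.Y[obs])          # unchanged
        assert np.all(np.isnan(imp.panel.Y[~d.alive]))          # no post-death
        assert np.all(np.isfinite(imp.panel.Y[d.alive]))        # all filled


def test_mi_deterministic_given_seed():
    d = sim.generate(sim.dag1_config(n_subjects=300), seed=4)
    fit = fit_sequential(d)
    a = mi_impute(d, fit, M=4, seed=99)
    b = mi_impute(d, fit, M=4, seed=99)
    for ia, ib in zip(a, b):
        assert np.array_equal(ia.panel.Y, ib.panel.Y, equal_nan=True)


def test_mi_noop_without_missingness(spec5):
    d = sim.generate(sim.dag1_config(n_subjects=250, no_dropout=True), seed=5)
    fit = fit_sequential(d)
    for imp in mi_impute(d, fit, M=3, seed=0):
        assert np.allclose(imp.panel.Y[d.alive], d.Y[d.alive])
    res = estimate_mi(d, spec5, M=3, seed=0)
    assert np.allclose(res.params, solve_iee(d, spec5).params, atol=1e-12)


def test_mi_requires_at_least_two_imputations():
    d = sim.generate(sim.dag1_config(n_subjects=200), seed=5)
    with pytest.raises(ValueError, match="at least 2"):
        mi_impute(d, fit_sequential(d), M=1)


class TestRubin:
    def _res(self, beta, W):
        return EstimateResult("MI", np.atleast_1d(float(beta)), ["b"],
                              vcov=np.array([[float(W)]]))

    def test_identical_inputs_give_within_only(self):
        pooled = rubin_combine([self._res(1.5, 2.0)] * 4)
        assert pooled.params[0] == pytest.approx(1.5)
        assert pooled.vcov[0, 0] == pytest.approx(2.0)

    def test_two_point_arithmetic(self):
        pooled = rubin_combine([self._res(0.0, 1.0), self._res(2.0, 1.0)])
        # W = 1, B = 2, T = 1 + (1 + 1/2) * 2 = 4
        assert pooled.params[0] == pytest.approx(1.0)
        assert pooled.vcov[0, 0] == pytest.approx(4.0)

    def test_mismatched_layouts_rejected(self):
        a = self._res(0.0, 1.0)
        b = EstimateResult("MI", np.zeros(1), ["other"], vcov=np.eye(1))
        with pytest.raises(ValueError, match="layout"):
            rubin_combine([a, b])


def test_mi_confidence_interval_coverage(spec5, dag1_truth):
    """Normal-theory CIs from Rubin's rules cover the truth at close to the
    nominal rate for the consistent f-variant imputation under dag1."""
    from scipy import stats

    z = stats.norm.ppf(0.975)
    cfg = sim.dag1_config()
    hits = np.zeros(spec5.n_params)
    n_reps = 150
    for rep in range(n_reps):
        d = sim.generate(cfg, seed=20_000 + rep)
        res = estimate_mi(d, spec5, stratify="covariate", M=10, seed=rep)
        lo = res.params - z * res.bse
        hi = res.params + z * res.bse
        hits += (dag1_truth.beta_true >= lo) & (dag1_truth.beta_true <= hi)
    coverage = hits / n_reps
    assert np.all(coverage > 0.89) and np.all(coverage <= 1.0)


def test_li_estimate_has_no_default_vcov(dag1_data_small, spec5):
    res = estimate_li(dag1_data_small, spec5)
    assert res.vcov is None
    assert np.all(np.isnan(res.bse))
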