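"""IEE / weighted estimating equation solver and IPW pipelines."""

import numpy as np
import pytest

from mortalcohort import simulate as sim
from mortalcohort.data import PanelData
from mortalcohort.design import MeanModelSpec, visit_sex_design
from mortalcohort.estimators import estimate_cc, estimate_ipw, solve_iee

from conftest import toy_panel


def intercept_spec():
    return MeanModelSpec(lambda j, Z: np.ones((len(Z), 1)), ["const"])


def test_single_visit_intercept_is_sample_mean():
    y = np.array([[1.0], [2.0], [4.0]])
    d = toy_panel(y, np.ones((3, 1), dtype=int), [1, 1, 1])
    res = solve_iee(d, intercept_spec())
    assert res.params[0] == pytest.approx(y.mean())


def test_complete_data_equals_stacked_ols(spec5):
    d = sim.generate(sim.dag1_config(n_subjects=400, no_dropout=True,
                                     surv_intercept=(50.0,) * 4), seed=2)
    res = solve_iee(d, spec5)
    X = spec5.design_tensor(d).reshape(-1, spec5.n_params)
    beta_ols = np.linalg.lstsq(X, d.Y.ravel(), rcond=None)[0]
    assert np.allclose(res.params, beta_ols, atol=1e-10)


def test_hand_weighted_normal_equations_oracle():
    """4-subject toy with hand-set weights matches a brute-force weighted
    normal-equations solve."""
    Y = np.array([[1.0, 2.0], [2.0, np.nan], [3.0, 1.0], [0.5, np.nan]])
    R = np.array([[1, 1], [1, 0], [1, 1], [1, 0]])
    D = np.array([2, 2, 2, 1])
    d = toy_panel(Y, R, D, sex=[0, 1, 0, 1])
    w = np.array([[1.0, 2.0], [3.0, np.nan], [1.5, 1.0], [2.0, np.nan]])

    spec = MeanModelSpec(
        lambda j, Z: np.column_stack([np.ones(len(Z)), np.full(len(Z), float(j == 1))]),
        ["const", "visit1"],
    )
    res = solve_iee(d, spec, weights=w)

    # brute force: accumulate A and b cell by cell
    A = np.zeros((2, 2))
    b = np.zeros(2)
    for i in range(4):
        for j in range(2):
            if R[i, j] == 1 and j + 1 <= D[i]:
                z = np.array([1.0, 1.0 if j == 0 else 0.0])
                A += w[i, j] * np.outer(z, z)
                b += w[i, j] * z * Y[i, j]
    assert np.allclose(res.params, np.linalg.solve(A, b), atol=1e-12)


def test_rank_deficiency_names_columns():
    d = toy_panel(np.ones((5, 2)), np.ones((5, 2), dtype=int), [2] * 5)
    spec = MeanModelSpec(
        lambda j, Z: np.column_stack([np.ones(len(Z)), np.ones(len(Z))]),
        ["const", "dup"],
    )
    with pytest.raises(ValueError, match="rank deficient"):
        solve_iee(d, spec)


def test_intercept_equivariance(spec5, dag1_data_small):
    """Adding c to every outcome shifts only the intercept by c."""
    res0 = solve_iee(dag1_data_small, spec5)
    shifted = dag1_data_small.copy()
    shifted.Y = shifted.Y + 10.0
    res1 = solve_iee(shifted, spec5)
    delta = res1.params - res0.params
    assert delta[0] == pytest.approx(10.0, abs=1e-8)
    assert np.allclose(delta[1:], 0.0, atol=1e-8)


def test_cc_equals_iee_without_missingness(spec5):
    d = sim.generate(sim.dag1_config(n_subjects=300, no_dropout=True,
                                     surv_intercept=(50.0,) * 4), seed=6)
    assert np.allclose(estimate_cc(d, spec5).params, solve_iee(d, spec5).params)


def test_single_complete_subject_intercept_mean():
    d = toy_panel([[2.0, 4.0, 6.0]], [[1, 1, 1]], [3])
    res = estimate_cc(d, intercept_spec())
    assert res.params[0] == pytest.approx(4.0)


def test_ipw_reduces_to_iee_without_dropout(spec5):
    d = sim.generate(sim.dag1_config(n_subjects=500, no_dropout=True), seed=3)
    base = solve_iee(d, spec5)
    for variant in ("u", "p", "f_cov", "f_strat"):
        res = estimate_ipw(d, spec5, variant=variant)
        assert np.allclose(res.params, base.params, atol=1e-10), variant
        assert res.diagnostics["weight_max"] == pytest.approx(1.0)


def test_cc_biased_ipw_not(spec5, dag1_truth):
    """Outcome-dependent dropout and death make the complete-case estimate
    drift from the survivor means while IPW stays close (single large N)."""
    d = sim.generate(sim.dag1_config(n_subjects=40_000), seed=44)
    cc = estimate_cc(d, spec5)
    ipw = estimate_ipw(d, spec5, variant="u")
    err_cc = np.abs(cc.params - dag1_truth.beta_true)
    err_ipw = np.abs(ipw.params - dag1_truth.beta_true)
    assert err_cc[0] > 5 * err_ipw[0]
    assert err_cc[0] > 0.2


def test_sandwich_close_to_cluster_bootstrap(spec5):
    from mortalcohort.study import bootstrap_se

    d = sim.generate(sim.dag1_config(n_subjects=2000), seed=12)
    res = solve_iee(d, spec5)
    boot = bootstrap_se(d, spec5, "iee", B=300, seed=1)
    rel = np.abs(res.bse - boot["se"].to_numpy()) / boot["se"].to_numpy()
    assert np.all(rel < 0.15)
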