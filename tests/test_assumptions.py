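"""Exact finite-distribution checks of the identifying assumptions."""

import numpy as np
import pytest

from mortalcohort import simulate as sim
from mortalcohort.assumptions import (
    CONDITIONS,
    check,
    discretize_mechanism,
    factorized_joint,
    fmar_not_pmar_joint,
    independence_joint,
    pmar_not_fmar_joint,
    random_joint,
    verify_theorem1,
)

TOL = 1e-10


def test_full_independence_satisfies_everything():
    dist = independence_joint()
    for c in CONDITIONS:
        assert check(dist, c) <= TOL, c


def test_unknown_condition_rejected():
    with pytest.raises(ValueError, match="unknown condition"):
        check(independence_joint(), "not-a-condition")


def test_relabelling_outcomes_preserves_violations():
    rng = np.random.default_rng(3)
    dist = random_joint(rng)
    relabelled = dist.relabel_y(lambda v: 3.0 * v + 7.0)
    for c in CONDITIONS:
        assert check(dist, c) == pytest.approx(check(relabelled, c), abs=1e-12)


def test_direct_outcome_to_response_edge_breaks_ddtic():
    """Dropout depending on the current outcome violates mortal-cohort
    dDTIC."""
    rng = np.random.default_rng(5)
    base = factorized_joint(rng, J=2)
    # rebuild with R_2 depending on Y_2: shift mass between patterns
    configs, probs = [], []
    for (x, d, k, ys), p in zip(base.configs, base.probs):
        if d == 2 and ys[1] > 0:
            # make high Y_2 subjects more likely observed
            configs.append((x, d, 2, ys)); probs.append(p * (0.9 if k == 2 else 0.5))
            configs.append((x, d, 1, ys)); probs.append(p * (0.1 if k == 2 else 0.5))
        else:
            configs.append((x, d, k, ys)); probs.append(p)
    from mortalcohort.assumptions import DiscreteJoint

    raw = {}
    for c, p in zip(configs, probs):
        raw[c] = raw.get(c, 0.0) + p
    tampered = DiscreteJoint(2, list(raw), np.array(list(raw.values())) / sum(raw.values()))
    assert check(tampered, "ddtic") > 1e-3


def test_u_mar_implies_f_mar_on_tested_distributions():
    rng = np.random.default_rng(11)
    dists = [factorized_joint(rng) for _ in range(25)] + [independence_joint()]
    for dist in dists:
        if check(dist, "u_mar") <= TOL:
            assert check(dist, "f_mar") <= TOL
            assert check(dist, "p_mar") <= TOL


def test_pmar_and_fmar_do_not_imply_each_other():
    a = pmar_not_fmar_joint()
    assert check(a, "p_mar") <= TOL
    assert check(a, "f_mar") > 0.05
    b = fmar_not_pmar_joint()
    assert check(b, "f_mar") <= TOL
    assert check(b, "p_mar") > 0.05


class TestDiscretizedMechanisms:
    def test_dag1_satisfies_u_mar_exactly(self):
        cfg = sim.dag1_config(n_visits=3, y_intercept=(1.0, 1.0),
                              surv_intercept=(-0.6, -1.2),
                              drop_intercept=(-1.0, -1.0))
        dist = discretize_mechanism(cfg)
        assert check(dist, "u_mar") <= TOL
        assert check(dist, "ddtic") <= TOL
        assert check(dist, "miss_indep_death") <= TOL
        # dag1 allows death to track unobserved outcomes
        assert check(dist, "indep_death") > 1e-3

    def test_dag2_satisfies_ddtic_and_indep_death_but_not_u_mar(self):
        cfg = sim.dag2_config(n_visits=3, y_intercept=(1.0, 1.0),
                              surv_intercept=(-0.6, -1.2),
                              drop_intercept=(-1.0, -1.0))
        dist = discretize_mechanism(cfg)
        assert check(dist, "ddtic") <= TOL
        assert check(dist, "indep_death") <= TOL
        assert check(dist, "miss_indep_death") > 1e-3
        assert check(dist, "u_mar") > 1e-3
        assert check(dist, "f_mar") > 1e-3

    def test_dfirst_satisfies_f_mar_but_not_u_mar(self):
        # y_death = 0 keeps the outcome grids of the death strata aligned so
        # the u-MAR instances are non-vacuous on the discrete grid
        cfg = sim.dfirst_config(n_visits=3, y_intercept=(1.0, 1.0),
                                death_intercept=(-1.5, -1.0),
                                drop_intercept=(-0.5, -0.5), y_death=0.0,
                                surv_intercept=())
        dist = discretize_mechanism(cfg)
        assert check(dist, "f_mar") <= TOL
        assert check(dist, "u_mar") > 1e-3

    def test_degenerate_config_all_conditions_hold(self):
        cfg = sim.dag1_config(n_visits=3, y_intercept=(1.0, 1.0),
                              surv_intercept=(50.0, 50.0), no_dropout=True,
                              drop_intercept=(0.0, 0.0))
        dist = discretize_mechanism(cfg)
        for c in CONDITIONS:
            assert check(dist, c) <= TOL, c


def test_theorem1_forward_direction_sample():
    """Laws built to satisfy dDTIC + missingness-independent death satisfy
    u-MAR (small sample here; the full 200-draw sweep runs in the acceptance
    suite)."""
    rng = np.random.default_rng(2024)
    for _ in range(20):
        dist = factorized_joint(rng)
        rep = verify_theorem1(dist)
        assert rep["ddtic"] <= TOL and rep["miss_indep_death"] <= TOL
        assert rep["u_mar"] <= TOL
        assert rep["consistent"]
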