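"""Exact verification of the identifying assumptions on finite joint laws.

The missing-at-random variants and death-independence conditions used by the
estimators are conditional-independence statements about the joint law of
(X, Y_1..Y_D, D, R_1..R_J).  On a finite discrete joint distribution each one
can be checked *exactly* by enumerating every instance of its defining
conditional equality and returning the maximum absolute difference between
the two sides.  A value below ``1e-10`` counts as "holds" for
double-precision tables.

Supported conditions (quantifier ranges exactly as defined):

* ``u_mar``  -- P(R_k=1 | R_{k-1}=1, Ybar_j, D=j, X) = P(R_k=1 | R_{k-1}=1,
  Ybar_{k-1}, D>=k, X) for all k <= j.
* ``p_mar``  -- same with both sides conditioning on D >= j.
* ``f_mar``  -- same with both sides conditioning on D = j.
* ``ddtic`` -- mortal-cohort discrete-time independent censoring:
  f(Y_j | Ybar_{j-1}, Rbar_j, X, D>=j) = f(Y_j | Ybar_{j-1}, X, D>=j).
* ``indep_death`` -- P(D>=j | D>=j-1, R_k=1, R_{k+1}=0, Ybar_{j-1}, X)
  does not depend on Y_{k+1}..Y_{j-1}.
* ``miss_indep_death`` -- P(D>=j | D>=j-1, Ybar_{j-1}, Rbar_{j-1}, X) does
  not depend on the missingness history, for all j >= 3 (for J <= 3 the
  printed quantifier and an all-j version coincide in what they constrain
  beyond trivially-satisfied instances).

The equivalence "u-MAR holds iff mortal-cohort dDTIC and
missingness-independent death both hold" can be brute-force verified over
families of constructed and unconstrained random distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
from scipy.special import expit

__all__ = [
    "DiscreteJoint",
    "CONDITIONS",
    "check",
    "verify_theorem1",
    "discretize_mechanism",
    "random_joint",
    "factorized_joint",
    "independence_joint",
    "pmar_not_fmar_joint",
    "fmar_not_pmar_joint",
]

CONDITIONS = ("u_mar", "p_mar", "f_mar", "ddtic", "indep_death", "miss_indep_death")

_PTOL = 1e-14   # conditioning events with mass below this are vacuous


@dataclass
class DiscreteJoint:
    """A finite joint law over (X, D, last-observed-visit, Y_1..Y_D).

    Each support point ("configuration") is a tuple ``(x, d, k, ys)`` with
    ``x`` the covariate value, ``d`` the last visit alive, ``k`` the last
    observed visit (monotone response with R_1 = 1 means the response pattern
    is summarised by k, 1 <= k <= d), and ``ys`` the outcome values at visits
    1..d (outcomes are undefined after death).
    """

    J: int
    configs: list
    probs: np.ndarray
    skipped: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        if len(self.configs) == 0:
            raise ValueError("empty support")
        if np.any(self.probs < -1e-15):
            raise ValueError("negative probabilities")
        tot = self.probs.sum()
        if abs(tot - 1.0) > 1e-9:
            raise ValueError(f"probabilities sum to {tot}, not 1")
        for (x, d, k, ys) in self.configs:
            if not (1 <= d <= self.J and 1 <= k <= d and len(ys) == d):
                raise ValueError(f"inconsistent configuration {(x, d, k, ys)}")

    def items(self):
        for cfg, p in zip(self.configs, self.probs):
            if p > 0.0:
                yield cfg, p

    def relabel_y(self, mapping) -> "DiscreteJoint":
        """Apply an injective relabelling to every outcome value."""
        new = [(x, d, k, tuple(mapping(v) for v in ys))
               for (x, d, k, ys) in self.configs]
        return DiscreteJoint(self.J, new, self.probs.copy())


class _Gap:
    """Accumulates P(event | fine group) vs P(event | coarse group)."""

    def __init__(self):
        self.num_l, self.den_l = {}, {}
        self.num_r, self.den_r = {}, {}
        self.proj = {}

    def add(self, kl, kr, p, hit):
        self.den_l[kl] = self.den_l.get(kl, 0.0) + p
        self.den_r[kr] = self.den_r.get(kr, 0.0) + p
        if hit:
            self.num_l[kl] = self.num_l.get(kl, 0.0) + p
            self.num_r[kr] = self.num_r.get(kr, 0.0) + p
        self.proj[kl] = kr

    def max_gap(self):
        worst = 0.0
        for kl, dl in self.den_l.items():
            if dl <= _PTOL:
                continue
            kr = self.proj[kl]
            dr = self.den_r[kr]
            pl = self.num_l.get(kl, 0.0) / dl
            pr = self.num_r.get(kr, 0.0) / dr
            worst = max(worst, abs(pl - pr))
        return worst


def _check_mar(dist: DiscreteJoint, flavor: str) -> float:
    """Shared engine for the three MAR variants (they differ only in the
    death-conditioning of each side)."""
    J = dist.J
    worst = 0.0
    for j in range(2, J + 1):
        for k in range(2, j + 1):
            gap = _Gap()
            for (x, d, kk, ys), p in dist.items():
                if kk < k - 1:
                    continue  # R_{k-1} = 1 fails
                if flavor == "u":
                    in_l, in_r = d == j, d >= k
                elif flavor == "p":
                    in_l = in_r = d >= j
                else:  # f
                    in_l = in_r = d == j
                hit = kk >= k
                kl = (x, ys[:j]) if in_l else None
                kr = (x, ys[: k - 1]) if in_r else None
                if flavor == "u":
                    # sides condition on different events: accumulate each
                    if in_l:
                        gap.den_l[kl] = gap.den_l.get(kl, 0.0) + p
                        if hit:
                            gap.num_l[kl] = gap.num_l.get(kl, 0.0) + p
                        gap.proj[kl] = (x, ys[: k - 1])
                    if in_r:
                        gap.den_r[kr] = gap.den_r.get(kr, 0.0) + p
                        if hit:
                            gap.num_r[kr] = gap.num_r.get(kr, 0.0) + p
                else:
                    if in_l:
                        gap.add(kl, kr, p, hit)
            worst = max(worst, gap.max_gap())
    return worst


def _check_ddtic(dist: DiscreteJoint) -> float:
    J = dist.J
    worst = 0.0
    for j in range(2, J + 1):
        # joint over (group, pattern, y_j) among survivors at j
        num_l, den_l, num_r, den_r = {}, {}, {}, {}
        for (x, d, kk, ys), p in dist.items():
            if d < j:
                continue
            m = min(kk, j)                      # response pattern through j
            base = (x, ys[: j - 1])
            y = ys[j - 1]
            den_l[(base, m)] = den_l.get((base, m), 0.0) + p
            den_r[base] = den_r.get(base, 0.0) + p
            num_l[(base, m, y)] = num_l.get((base, m, y), 0.0) + p
            num_r[(base, y)] = num_r.get((base, y), 0.0) + p
        for (base, m, y), pj in num_l.items():
            dl = den_l[(base, m)]
            if dl <= _PTOL:
                continue
            worst = max(worst, abs(pj / dl - num_r.get((base, y), 0.0) / den_r[base]))
        # also catch y-values absent from a pattern but present marginally
        for (base, m), dl in den_l.items():
            if dl <= _PTOL:
                continue
            for (base_r, y), pr in num_r.items():
                if base_r != base:
                    continue
                pl = num_l.get((base, m, y), 0.0) / dl
                worst = max(worst, abs(pl - pr / den_r[base]))
    return worst


def _check_indep_death(dist: DiscreteJoint) -> float:
    J = dist.J
    worst = 0.0
    for k in range(1, J):
        for j in range(k + 2, J + 1):
            gap = _Gap()
            for (x, d, kk, ys), p in dist.items():
                if kk != k or d < j - 1:
                    continue  # needs R_k=1, R_{k+1}=0 and survival to j-1
                gap.add((x, ys[: j - 1]), (x, ys[:k]), p, d >= j)
            worst = max(worst, gap.max_gap())
    return worst


def _check_miss_indep_death(dist: DiscreteJoint) -> float:
    J = dist.J
    worst = 0.0
    for j in range(3, J + 1):
        gap = _Gap()
        for (x, d, kk, ys), p in dist.items():
            if d < j - 1:
                continue
            m = min(kk, j - 1)                  # missingness history through j-1
            gap.add((x, ys[: j - 1], m), (x, ys[: j - 1]), p, d >= j)
        worst = max(worst, gap.max_gap())
    return worst


_CHECKERS = {
    "u_mar": lambda d: _check_mar(d, "u"),
    "p_mar": lambda d: _check_mar(d, "p"),
    "f_mar": lambda d: _check_mar(d, "f"),
    "ddtic": _check_ddtic,
    "indep_death": _check_indep_death,
    "miss_indep_death": _check_miss_indep_death,
}


def check(dist: DiscreteJoint, condition: str) -> float:
    """Maximum absolute violation of the condition over the whole support.

    Zero (up to 1e-10) means the condition holds exactly; conditioning events
    of probability zero are vacuous and skipped.
    """
    try:
        fn = _CHECKERS[condition]
    except KeyError:
        raise ValueError(f"unknown condition {condition!r}; one of {CONDITIONS}") from None
    return fn(dist)


def verify_theorem1(dist: DiscreteJoint, tol: float = 1e-10) -> dict:
    """Evaluate both sides of the equivalence: u-MAR holds iff mortal-cohort
    dDTIC and missingness-independent death both hold."""
    v_u = check(dist, "u_mar")
    v_d = check(dist, "ddtic")
    v_m = check(dist, "miss_indep_death")
    lhs = (v_d <= tol) and (v_m <= tol)
    rhs = v_u <= tol
    return {
        "u_mar": v_u,
        "ddtic": v_d,
        "miss_indep_death": v_m,
        "consistent": lhs == rhs,
    }


# ---------------------------------------------------------------------------
# constructors
# ---------------------------------------------------------------------------

def _merge(raw: dict, J: int, meta=None) -> DiscreteJoint:
    configs = list(raw.keys())
    probs = np.array([raw[c] for c in configs])
    probs = probs / probs.sum()
    return DiscreteJoint(J, configs, probs, meta=meta or {})


def random_joint(rng, J: int = 3, x_levels=(0.0, 1.0), y_levels=(-1.0, 1.0),
                 concentration: float = 1.0) -> DiscreteJoint:
    """Dirichlet-random probabilities over the full structural support."""
    raw = {}
    for x in x_levels:
        for d in range(1, J + 1):
            for k in range(1, d + 1):
                for ys in product(y_levels, repeat=d):
                    raw[(x, d, k, ys)] = rng.gamma(concentration)
    return _merge(raw, J)


def factorized_joint(rng, J: int = 3, x_levels=(0.0, 1.0), y_levels=(-1.0, 1.0)) -> DiscreteJoint:
    """Random law generated in temporal order with death depending on the
    full outcome history (not on missingness) and dropout depending on the
    observed history (not on the current outcome or death time).

    By construction this satisfies mortal-cohort dDTIC and
    missingness-independent death -- the forward hypothesis of the u-MAR
    equivalence -- with otherwise arbitrary random conditional tables.
    """
    p_x = rng.dirichlet(np.ones(len(x_levels)))
    ny = len(y_levels)

    def table(*key):
        # memoised random conditionals, keyed by (kind, x, history...)
        if key not in table.memo:
            table.memo[key] = rng.dirichlet(np.ones(ny))
        return table.memo[key]
    table.memo = {}

    def bern(*key):
        if key not in bern.memo:
            bern.memo[key] = rng.uniform(0.05, 0.95)
        return bern.memo[key]
    bern.memo = {}

    raw = {}
    # state: (prob, ys, k_obs, alive_through) expanded visit by visit
    for xi, x in enumerate(x_levels):
        stack = [(p_x[xi] * w, (y,), 1)
                 for y, w in zip(y_levels, table("y", 1, x))]
        for j in range(2, J + 1):
            nxt = []
            for p, ys, k in stack:
                if p == 0.0:
                    continue
                p_surv = bern("surv", j, x, ys)         # any past-Y dependence
                # death before visit j: finalize with d = j - 1
                cfg = (x, j - 1, k, ys)
                raw[cfg] = raw.get(cfg, 0.0) + p * (1 - p_surv)
                p_alive = p * p_surv
                branches = []
                if k == j - 1:  # still under observation: dropout branch
                    p_obs = bern("drop", j, x, ys[: j - 1])
                    branches = [(p_alive * p_obs, j), (p_alive * (1 - p_obs), k)]
                else:
                    branches = [(p_alive, k)]
                for pb, kb in branches:
                    for y, w in zip(y_levels, table("y", j, x, ys)):
                        nxt.append((pb * w, ys + (y,), kb))
            stack = nxt
        for p, ys, k in stack:
            cfg = (x, J, k, ys)
            raw[cfg] = raw.get(cfg, 0.0) + p
    return _merge(raw, J)


def independence_joint(J: int = 3, x_levels=(0.0, 1.0), y_levels=(-1.0, 1.0)) -> DiscreteJoint:
    """R independent of (Y, D) given X: every condition holds trivially."""
    raw = {}
    for xi, x in enumerate(x_levels):
        px = 1.0 / len(x_levels)
        p_obs = 0.6 + 0.2 * xi / max(len(x_levels) - 1, 1)
        p_die = 0.2
        for d in range(1, J + 1):
            pd = p_die * (1 - p_die) ** (d - 1) if d < J else (1 - p_die) ** (J - 1)
            for k in range(1, d + 1):
                pk = ((p_obs ** (k - 1)) * (1 - p_obs)) if k < d else p_obs ** (d - 1)
                for ys in product(y_levels, repeat=d):
                    raw[(x, d, k, ys)] = px * pd * pk * (1 / len(y_levels)) ** d
    return _merge(raw, J)


def pmar_not_fmar_joint() -> DiscreteJoint:
    """A J=3 law where p-MAR holds exactly but f-MAR fails.

    Construction: dropout at visit 2 depends on Y_2 *within* the stratum
    D = 2 but the dependence cancels exactly in the pooled population of
    survivors (D >= 2), because the death-between-visits-2-and-3 probability
    is chosen so that w(y2) * [P(R2 | Y2=y2, D=2) - P(R2 | D=3)] is constant
    in y2.  Nothing depends on Y_3, so all remaining instances hold.
    """
    J = 3
    y_levels = (-1.0, 1.0)
    p_d1 = 0.1
    # P(D=2 | Y2, D>=2) and P(R2=1 | Y2, D=2), constants solving the pooling
    w = {1.0: 0.1, -1.0: 0.2}
    p2 = {1.0: 0.7, -1.0: 0.6}          # within D=2: depends on y2
    c3 = 0.5                            # within D=3: constant
    p_r3 = 0.5
    raw = {}
    for y1 in y_levels:
        base = 0.5 * 0.5  # P(y1) * P(y2 | y1) applied later
        # D = 1: only Y1 exists, k = 1
        raw[(0.0, 1, 1, (y1,))] = raw.get((0.0, 1, 1, (y1,)), 0.0) + 0.5 * p_d1
        for y2 in y_levels:
            p_base = 0.5 * (1 - p_d1) * 0.5    # y1, survive to 2, y2
            # stratum D = 2
            p_d2 = p_base * w[y2]
            raw[(0.0, 2, 2, (y1, y2))] = p_d2 * p2[y2]
            raw[(0.0, 2, 1, (y1, y2))] = p_d2 * (1 - p2[y2])
            # stratum D = 3
            p_d3 = p_base * (1 - w[y2])
            for y3 in y_levels:
                p_y = p_d3 * 0.5
                raw[(0.0, 3, 3, (y1, y2, y3))] = p_y * c3 * p_r3
                raw[(0.0, 3, 2, (y1, y2, y3))] = p_y * c3 * (1 - p_r3)
                raw[(0.0, 3, 1, (y1, y2, y3))] = p_y * (1 - c3)
    return _merge(raw, J)


def fmar_not_pmar_joint() -> DiscreteJoint:
    """A J=3 law where f-MAR holds exactly but p-MAR fails.

    Dropout at visit 2 depends only on the death time (not on outcomes), so
    f-MAR holds; death between visits 2 and 3 depends on Y_2, so pooling the
    D = 2 and D = 3 strata makes dropout associated with Y_2 among survivors
    at visit 2, violating p-MAR.
    """
    J = 3
    y_levels = (-1.0, 1.0)
    p_d1 = 0.1
    w = {1.0: 0.3, -1.0: 0.6}           # P(D=2 | Y2, D>=2): depends on y2
    p2 = {2: 0.8, 3: 0.4}               # P(R2=1 | D=l): depends on l only
    p_r3 = 0.5
    raw = {}
    for y1 in y_levels:
        raw[(0.0, 1, 1, (y1,))] = raw.get((0.0, 1, 1, (y1,)), 0.0) + 0.5 * p_d1
        for y2 in y_levels:
            p_base = 0.5 * (1 - p_d1) * 0.5
            p_d2 = p_base * w[y2]
            raw[(0.0, 2, 2, (y1, y2))] = p_d2 * p2[2]
            raw[(0.0, 2, 1, (y1, y2))] = p_d2 * (1 - p2[2])
            p_d3 = p_base * (1 - w[y2])
            for y3 in y_levels:
                p_y = p_d3 * 0.5
                raw[(0.0, 3, 3, (y1, y2, y3))] = p_y * p2[3] * p_r3
                raw[(0.0, 3, 2, (y1, y2, y3))] = p_y * p2[3] * (1 - p_r3)
                raw[(0.0, 3, 1, (y1, y2, y3))] = p_y * (1 - p2[3])
    return _merge(raw, J)


# ---------------------------------------------------------------------------
# mechanism discretization
# ---------------------------------------------------------------------------

def discretize_mechanism(config, max_states: int = 20000) -> DiscreteJoint:
    """Exact joint law of a two-point discretization of a simulator config.

    Each normal outcome draw N(mu, sd^2) is replaced by the two-point law
    {mu - sd, mu + sd} with probability 1/2 each (matching the conditional
    mean and variance); the logistic survival/dropout structure is evaluated
    exactly on the grid, so the conditional-independence structure of the
    mechanism is preserved and the identifying assumptions can be checked
    exactly by enumeration.  Requires a small J (state space grows like
    4^J).
    """
    J = config.n_visits
    scenario = config.scenario
    raw = {}

    def y_pair(mu, sd):
        return ((mu - sd, 0.5), (mu + sd, 0.5))

    for x, px in ((0.0, 1 - config.p_sex), (1.0, config.p_sex)):
        if scenario in ("dag1", "dag2"):
            # state: (prob, ys, k_obs) for currently-alive subjects
            stack = [(px * w, (y,), 1)
                     for y, w in y_pair(config.y1_intercept + config.y1_sex * x,
                                        config.y1_sd)]
            for j in range(2, J + 1):
                nxt = []
                for p, ys, k in stack:
                    y_star = ys[k - 1]            # last observed outcome
                    driver = ys[j - 2] if scenario == "dag1" else y_star
                    p_surv = float(expit(config.surv_intercept[j - 2]
                                         + config.surv_lag * driver
                                         + config.surv_sex * x))
                    cfg = (x, j - 1, k, ys)
                    raw[cfg] = raw.get(cfg, 0.0) + p * (1 - p_surv)
                    p_alive = p * p_surv
                    if config.no_dropout:
                        branches = [(p_alive, j)] if k == j - 1 else [(p_alive, k)]
                    elif k == j - 1:
                        p_obs = float(expit(config.drop_intercept[j - 2]
                                            + config.drop_lag * ys[j - 2]
                                            + config.drop_sex * x))
                        branches = [(p_alive * p_obs, j),
                                    (p_alive * (1 - p_obs), k)]
                    else:
                        branches = [(p_alive, k)]
                    mu = (config.y_intercept[j - 2] + config.y_lag * ys[j - 2]
                          + config.y_sex * x)
                    for pb, kb in branches:
                        for y, w in y_pair(mu, config.y_sd):
                            nxt.append((pb * w, ys + (y,), kb))
                stack = nxt
                if len(stack) > max_states:
                    raise ValueError("state space overflow; reduce J or levels")
            for p, ys, k in stack:
                cfg = (x, J, k, ys)
                raw[cfg] = raw.get(cfg, 0.0) + p
        elif scenario == "dfirst":
            # death time first, then the outcome chain given D, then dropout
            surv_p = 1.0
            for d in range(1, J + 1):
                if d < J:
                    p_die = float(expit(config.death_intercept[d - 1]
                                        + config.death_sex * x))
                    pd = surv_p * p_die
                    surv_p *= 1 - p_die
                else:
                    pd = surv_p
                d_adj = config.y_death * (d - config.d_center)
                chains = [(pd * px * w, (y,))
                          for y, w in y_pair(config.y1_intercept
                                             + config.y1_sex * x + d_adj,
                                             config.y1_sd)]
                for j in range(2, d + 1):
                    chains = [
                        (p * w, ys + (y,))
                        for p, ys in chains
                        for y, w in y_pair(config.y_intercept[j - 2]
                                           + config.y_lag * ys[j - 1 - 1]
                                           + config.y_sex * x + d_adj,
                                           config.y_sd)
                    ]
                for p, ys in chains:
                    # dropout pattern given (ys, d)
                    pk = {1: 1.0}
                    probs_k = {}
                    run = 1.0
                    for j in range(2, d + 1):
                        if config.no_dropout:
                            p_obs = 1.0
                        else:
                            p_obs = float(expit(config.drop_intercept[j - 2]
                                                + config.drop_lag * ys[j - 2]
                                                + config.drop_sex * x
                                                + config.drop_death
                                                * (d - config.d_center)))
                        probs_k[j - 1] = run * (1 - p_obs)
                        run *= p_obs
                    probs_k[d] = run
                    for k, pk_ in probs_k.items():
                        if pk_ == 0.0:
                            continue
                        cfg = (x, d, k, ys)
                        raw[cfg] = raw.get(cfg, 0.0) + p * pk_
                if len(raw) > max_states:
                    raise ValueError("state space overflow; reduce J or levels")
        else:
            raise ValueError(f"unknown scenario {scenario!r}")
    return _merge(raw, J)
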