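"""Discrete-time dropout-hazard models and inverse-probability weights.

Monotone dropout is modelled through per-visit logistic hazards for remaining
under observation, ``P(R_k = 1 | R_{k-1} = 1, history, X, ...)``, fitted
among subjects at risk.  Three missing-at-random variants differ only in how
the hazards condition on survival:

* ``u``  -- survivors at the current visit k (``D >= k``); death time D is
  never used, so survival needs to be known only up to dropout.
* ``p``  -- survivors at the *target* visit j (``D >= j``); one hazard model
  per (k, j) pair, refitted for every target visit.
* ``f_strat`` / ``f_cov`` -- fully conditional on the death time: hazards
  within each death stratum ``D = l``, or with D entered as a categorical
  covariate.  Both require survival status known to the end of the study.

The cumulative product of fitted hazards along a subject's observed run gives
the observation probability, and its (floored) inverse the IPW weight.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy import stats

__all__ = [
    "DropoutHazardFit",
    "WeightSet",
    "fit_dropout",
    "observation_prob",
    "weights",
    "test_umar",
]

VARIANTS = ("u", "p", "f_strat", "f_cov")


# ---------------------------------------------------------------------------
# low-level logistic fit
# ---------------------------------------------------------------------------

@dataclass
class _Logit:
    """A fitted per-visit hazard component."""

    coef: np.ndarray
    names: list
    n_obs: int
    n_events: int
    llf: float = np.nan
    degenerate: str = ""  # "", "all-events" (hazard 1) or "no-events"

    def predict(self, X: np.ndarray) -> np.ndarray:
        if self.degenerate == "all-events":
            return np.ones(X.shape[0])
        return expit(X @ self.coef)


def _fit_logit(X, y, label, allow_degenerate=False):
    y = np.asarray(y, dtype=float)
    n, n_events = len(y), int(y.sum())
    if n_events == n:
        if allow_degenerate:
            return _Logit(np.zeros(X.shape[1]), [], n, n_events,
                          llf=0.0, degenerate="all-events")
        raise ValueError(f"{label}: no non-events (everyone remains observed)")
    if n_events == 0:
        raise ValueError(f"{label}: no events (nobody remains observed)")
    import statsmodels.api as sm

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(y, X).fit(disp=0, method="newton", maxiter=100)
        except Exception as exc:  # separation / singular information
            raise ValueError(f"{label}: logistic fit failed ({exc})") from exc
    params = np.asarray(fit.params, dtype=float)
    if not np.all(np.isfinite(params)) or np.any(np.abs(params) > 1e3):
        raise ValueError(f"{label}: separation (non-finite or exploding coefficients)")
    return _Logit(params, [], n, n_events, llf=float(fit.llf))


# ---------------------------------------------------------------------------
# regressor construction
# ---------------------------------------------------------------------------

def _history_matrix(data, k, history, aux_cols):
    """Regressors for the hazard at visit k: intercept, outcome history, X.

    Rows are returned for *all* subjects; caller masks to the at-risk set
    (whose history is guaranteed observed).
    """
    if aux_cols is None:
        aux_cols = data.x_cols
    cols = [np.ones(data.n_subjects)]
    names = ["const"]
    if history == "lag1":
        lags = [k - 1]
    elif history == "full":
        lags = list(range(1, k))
    else:
        raise ValueError(f"unknown history spec {history!r}")
    for lag in lags:
        cols.append(data.Y[:, lag - 1])
        names.append(f"y{lag}")
    for c in aux_cols:
        cols.append(data.covariates[c].to_numpy(dtype=float))
        names.append(c)
    return np.column_stack(cols), names


def _d_dummies(D, levels, ref):
    """Indicator columns for D = level, level in ``levels`` minus the reference."""
    cols = [(D == l).astype(float) for l in levels if l != ref]
    names = [f"D={l}" for l in levels if l != ref]
    if not cols:
        return np.empty((len(D), 0)), []
    return np.column_stack(cols), names


# ---------------------------------------------------------------------------
# public types
# ---------------------------------------------------------------------------

@dataclass
class DropoutHazardFit:
    variant: str
    history: str
    aux_cols: list
    models: dict            # keyed by k (u, f_cov), (k, j) (p), (k, l) (f_strat)
    d_levels: list = field(default_factory=list)   # dummy levels for cov models
    fallbacks: list = field(default_factory=list)  # (k, l) strata sent to f_cov
    n_visits: int = 0

    def coefficient_table(self) -> pd.DataFrame:
        """Tidy (variant, k, j_or_l, term, estimate) table of all hazards."""
        rows = []
        for key, m in self.models.items():
            k, extra = (key, "") if np.isscalar(key) else (key[0], key[1])
            for name, est in zip(m.names, m.coef):
                rows.append({"variant": self.variant, "k": k, "j_or_l": extra,
                             "term": name, "estimate": est})
        return pd.DataFrame(rows)


@dataclass
class WeightSet:
    """Inverse-probability weights on observed cells; NaN elsewhere."""

    w: np.ndarray
    floor: float
    n_floored: int
    pi: np.ndarray = None


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def fit_dropout(
    data,
    variant: str = "u",
    history: str = "lag1",
    aux_cols=None,
    allow_degenerate: bool = False,
    stratum_min: int = 30,
) -> DropoutHazardFit:
    """Fit the per-visit dropout hazard models for a MAR variant.

    Small death strata (fewer than ``stratum_min`` at-risk subjects) under
    ``f_strat`` fall back to the D-as-covariate model for that visit, with
    the (k, l) pair recorded in ``fallbacks``.
    """
    if variant not in VARIANTS:
        raise ValueError(f"variant must be one of {VARIANTS}")
    J = data.n_visits
    R, D = data.R, data.D
    models, fallbacks = {}, []
    d_levels = sorted(np.unique(D))
    aux = list(aux_cols) if aux_cols is not None else list(data.x_cols)

    def fit_at(k, mask, label, with_d=False):
        X, names = _history_matrix(data, k, history, aux)
        if with_d:
            lv = sorted(np.unique(D[mask]))
            dd, dn = _d_dummies(D, lv, ref=max(lv))
            X = np.column_stack([X, dd])
            names = names + dn
        m = _fit_logit(X[mask], R[mask, k - 1], label, allow_degenerate)
        m.names = names
        return m

    if variant == "u":
        for k in range(2, J + 1):
            at_risk = (R[:, k - 2] == 1) & (D >= k)
            models[k] = fit_at(k, at_risk, f"u-hazard at visit {k}")
    elif variant == "p":
        for j in range(2, J + 1):
            for k in range(2, j + 1):
                at_risk = (R[:, k - 2] == 1) & (D >= j)
                models[(k, j)] = fit_at(
                    k, at_risk, f"p-hazard at visit {k} targeting visit {j}"
                )
    elif variant == "f_cov":
        for k in range(2, J + 1):
            at_risk = (R[:, k - 2] == 1) & (D >= k)
            models[k] = fit_at(k, at_risk, f"f-hazard at visit {k} (D as covariate)",
                               with_d=True)
    else:  # f_strat
        cov_models = {}
        for k in range(2, J + 1):
            at_risk = (R[:, k - 2] == 1) & (D >= k)
            cov_models[k] = fit_at(
                k, at_risk, f"f-hazard at visit {k} (D as covariate)", with_d=True
            )
        for l in d_levels:
            for k in range(2, l + 1):
                at_risk = (R[:, k - 2] == 1) & (D == l)
                n_risk = int(at_risk.sum())
                if n_risk == 0:
                    raise ValueError(f"empty death stratum D={l} at visit {k}")
                if n_risk < stratum_min:
                    fallbacks.append((k, l))
                    continue
                try:
                    models[(k, l)] = fit_at(
                        k, at_risk, f"f-hazard at visit {k} in stratum D={l}"
                    )
                except ValueError:
                    fallbacks.append((k, l))
        models["_cov"] = cov_models

    return DropoutHazardFit(
        variant=variant,
        history=history,
        aux_cols=aux,
        models=models,
        d_levels=d_levels,
        fallbacks=fallbacks,
        n_visits=J,
    )


# ---------------------------------------------------------------------------
# observation probabilities and weights
# ---------------------------------------------------------------------------

def _eval_cov_model(model, data, k, history, aux, D_value):
    """Evaluate a D-as-covariate hazard model forcing D to ``D_value``."""
    X, _ = _history_matrix(data, k, history, aux)
    n_base = X.shape[1]
    n_extra = len(model.coef) - n_base
    if n_extra:
        # reconstruct dummy columns at the forced D value
        lv = [int(n.split("=")[1]) for n in model.names[n_base:]]
        dd = np.column_stack([(np.full(data.n_subjects, D_value) == l).astype(float)
                              for l in lv])
        X = np.column_stack([X, dd])
    return model.predict(X)


def _hazard_matrix(fit: DropoutHazardFit, data, target_j=None) -> np.ndarray:
    """(N, J) fitted hazards h_{ik}; NaN where not evaluable/applicable."""
    N, J = data.n_subjects, data.n_visits
    H = np.full((N, J), np.nan)
    H[:, 0] = 1.0
    for k in range(2, J + 1):
        evaluable = (data.R[:, k - 2] == 1) & (data.D >= k)
        if fit.variant == "u":
            X, _ = _history_matrix(data, k, fit.history, fit.aux_cols)
            h = fit.models[k].predict(X)
        elif fit.variant == "p":
            if target_j is None or k > target_j:
                continue
            X, _ = _history_matrix(data, k, fit.history, fit.aux_cols)
            h = fit.models[(k, target_j)].predict(X)
            evaluable &= data.D >= target_j
        elif fit.variant == "f_cov":
            X, _ = _history_matrix(data, k, fit.history, fit.aux_cols)
            n_base = X.shape[1]
            m = fit.models[k]
            if len(m.coef) > n_base:
                lv = [int(n.split("=")[1]) for n in m.names[n_base:]]
                dd = np.column_stack([(data.D == l).astype(float) for l in lv])
                X = np.column_stack([X, dd])
            h = m.predict(X)
        else:  # f_strat: per-subject stratum model, fallback to cov at D=l
            h = np.full(N, np.nan)
            cov_models = fit.models["_cov"]
            for l in fit.d_levels:
                if l < k:
                    continue
                sel = evaluable & (data.D == l)
                if not sel.any():
                    continue
                if (k, l) in fit.models:
                    m = fit.models[(k, l)]
                    X, _ = _history_matrix(data, k, fit.history, fit.aux_cols)
                    h[sel] = m.predict(X[sel])
                else:
                    h[sel] = _eval_cov_model(
                        cov_models[k], data, k, fit.history, fit.aux_cols, l
                    )[sel]
        H[evaluable, k - 1] = np.asarray(h)[evaluable]
    return H


def observation_prob(fit: DropoutHazardFit, data, j: int = None):
    """Cumulative observation probabilities pi-hat.

    Returns the (N, J) matrix of ``pi_ij = prod_{k<=j} h_ik`` along each
    subject's observed run (NaN where the history needed by some factor is
    itself unobserved), or the single column for visit ``j`` if given.
    """
    J = data.n_visits
    if fit.variant == "p":
        N = data.n_subjects
        pi = np.full((N, J), np.nan)
        pi[:, 0] = 1.0
        for tj in range(2, J + 1):
            H = _hazard_matrix(fit, data, target_j=tj)
            col = np.ones(N)
            for k in range(2, tj + 1):
                col = col * H[:, k - 1]
            pi[:, tj - 1] = col
    else:
        H = _hazard_matrix(fit, data)
        pi = np.nancumprod(H, axis=1)
        # nancumprod treats NaN as 1; restore NaN once a factor is missing
        broken = np.isnan(H).cumsum(axis=1) > 0
        pi[broken] = np.nan
        pi[:, 0] = 1.0
    if j is not None:
        alive = data.D >= j
        return pi[alive, j - 1]
    return pi


def weights(fit: DropoutHazardFit, data, floor: float = 0.01) -> WeightSet:
    """Inverse-probability weights ``1 / max(pi, floor)`` on observed cells."""
    pi = observation_prob(fit, data)
    obs = data.observed & data.alive
    w = np.full(pi.shape, np.nan)
    pio = pi[obs]
    if np.any(~np.isfinite(pio)):
        raise ValueError("observation probability undefined on some observed cells")
    floored = pio < floor
    w[obs] = 1.0 / np.maximum(pio, floor)
    return WeightSet(w=w, floor=floor, n_floored=int(floored.sum()), pi=pi)


# ---------------------------------------------------------------------------
# u-MAR screen
# ---------------------------------------------------------------------------

def test_umar(data, history: str = "lag1", aux_cols=None) -> pd.DataFrame:
    """Likelihood-ratio screen of the u-MAR assumption.

    For each visit k, the u-variant dropout hazard is augmented with
    categorical death-time terms; a small p-value for the D terms indicates
    that dropout is associated with the (future) time of death given the
    observed history, making u-MAR implausible.  Requires D known to the end
    of the study.
    """
    J = data.n_visits
    aux = list(aux_cols) if aux_cols is not None else list(data.x_cols)
    rows = []
    for k in range(2, J + 1):
        at_risk = (data.R[:, k - 2] == 1) & (data.D >= k)
        d_here = np.unique(data.D[at_risk])
        if len(d_here) < 2:
            # structurally so at k = J (D >= J forces D = J); no contrast
            continue
        X0, names0 = _history_matrix(data, k, history, aux)
        dd, dn = _d_dummies(data.D, sorted(d_here), ref=max(d_here))
        X1 = np.column_stack([X0, dd])
        y = data.R[:, k - 1]
        base = _fit_logit(X0[at_risk], y[at_risk], f"u-MAR screen base, visit {k}")
        aug = _fit_logit(X1[at_risk], y[at_risk], f"u-MAR screen augmented, visit {k}")
        lr = max(0.0, 2.0 * (aug.llf - base.llf))
        df = len(dn)
        rows.append({"visit": k, "lr_stat": lr, "df": df,
                     "p_value": float(stats.chi2.sf(lr, df))})
    if not rows:
        raise ValueError("D has one level among subjects at risk at every visit")
    return pd.DataFrame(rows)
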