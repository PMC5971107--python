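"""Monotone sequential imputation: proper multiple imputation, deterministic
linear-increments-style mean imputation, post-death deletion, Rubin's rules.

The imputation model is a chain of per-visit normal linear regressions of
``Y_j`` on the outcome history and auxiliary covariates X,

    Y_j = rho_j + phi_j' Ybar_{j-1} + psi_j' X + eps_j,
    eps_j | history, alive ~ N(0, sigma_j^2),

optionally conditioned on the death time D, either as a categorical covariate
(``stratify="covariate"``) or by fitting a separate chain within each death
stratum ``D = l`` (``stratify="stratum"``).  For monotone missingness this
sequential scheme is equivalent to joint multivariate-normal imputation.

Proper MI draws (sigma_j^2, coefficients) from the standard non-informative
posterior (scaled inverse chi-square times conditional normal) before filling
each missing-while-alive cell, feeding imputed values forward along the
chain; the deterministic variant (``li_impute``) fills with fitted
conditional means, which is the infinite-imputation limit of MI.  Imputed
post-death cells are never produced: only cells with ``j <= D`` exist in the
output, which is what keeps the estimand partly conditional.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import PanelData
from .results import EstimateResult

__all__ = [
    "SeqImputationFit",
    "ImputedDataset",
    "fit_sequential",
    "mi_impute",
    "li_impute",
    "rubin_combine",
    "estimate_mi",
    "estimate_li",
]


@dataclass
class VisitRegression:
    visit: int
    stratum: object            # None or the death-stratum value l
    coef: np.ndarray
    names: list
    sigma2: float
    df: int
    xtx_inv: np.ndarray


@dataclass
class SeqImputationFit:
    stratify: str              # "none" | "covariate" | "stratum"
    history: str
    aux_cols: list
    models: dict               # (j, stratum) -> VisitRegression; stratum None
    cov_models: dict = field(default_factory=dict)  # fallback D-as-covariate fits
    d_levels: list = field(default_factory=list)
    fallbacks: list = field(default_factory=list)
    n_visits: int = 0


@dataclass
class ImputedDataset:
    """A completed dataset: every alive cell has a value, none after death."""

    panel: PanelData
    m: int
    provenance: dict = field(default_factory=dict)


def _lag_columns(j, history):
    if history == "lag1":
        return [j - 1]
    if history == "full":
        return list(range(1, j))
    raise ValueError(f"unknown history spec {history!r}")


def _regressors(Ymat, data, j, history, aux_cols, d_names=None, d_force=None):
    """Design for the visit-j outcome regression, built from matrix ``Ymat``
    (observed data when fitting, working completed data when predicting)."""
    n = Ymat.shape[0]
    cols, names = [np.ones(n)], ["const"]
    for lag in _lag_columns(j, history):
        cols.append(Ymat[:, lag - 1])
        names.append(f"y{lag}")
    for c in aux_cols:
        cols.append(data.covariates[c].to_numpy(dtype=float))
        names.append(c)
    if d_names:
        D = np.full(n, d_force) if d_force is not None else data.D
        for nm in d_names:
            l = int(nm.split("=")[1])
            cols.append((D == l).astype(float))
        names += list(d_names)
    return np.column_stack(cols), names


def _ols(X, y, label):
    n, p = X.shape
    if n <= p:
        raise ValueError(f"{label}: {n} observations for {p} regressors")
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < p:
        raise ValueError(f"{label}: singular regression design")
    resid = y - X @ coef
    df = n - p
    sigma2 = float(resid @ resid) / df
    scale = float(np.var(y)) if n > 1 else 1.0
    if sigma2 <= max(scale, 1.0) * 1e-12:
        raise ValueError(f"{label}: degenerate residual variance")
    return coef, sigma2, df, np.linalg.inv(X.T @ X)


def fit_sequential(
    data: PanelData,
    stratify: str = "none",
    history: str = "lag1",
    aux_cols=None,
    stratum_min: int = 30,
) -> SeqImputationFit:
    """Fit the per-visit imputation regressions on observed cells.

    ``stratify="stratum"`` fits a chain within each death stratum, falling
    back to the D-as-covariate fit for strata with fewer than ``stratum_min``
    observed cells (recorded in ``fallbacks``).
    """
    if stratify not in ("none", "covariate", "stratum"):
        raise ValueError("stratify must be 'none', 'covariate' or 'stratum'")
    J = data.n_visits
    aux = list(aux_cols) if aux_cols is not None else list(data.x_cols)
    d_levels = sorted(int(v) for v in np.unique(data.D))
    models, cov_models, fallbacks = {}, {}, []

    def d_names_for(mask):
        lv = sorted(int(v) for v in np.unique(data.D[mask]))
        ref = max(lv)
        return [f"D={l}" for l in lv if l != ref]

    for j in range(2, J + 1):
        obs_j = data.R[:, j - 1] == 1
        if stratify in ("covariate", "stratum"):
            dn = d_names_for(obs_j)
            X, names = _regressors(data.Y, data, j, history, aux, d_names=dn)
            coef, s2, df, xtx = _ols(X[obs_j], data.Y[obs_j, j - 1],
                                     f"imputation regression, visit {j} (D as covariate)")
            cov_models[j] = VisitRegression(j, "covariate", coef, names, s2, df, xtx)
        if stratify in ("none", "covariate"):
            if stratify == "none":
                X, names = _regressors(data.Y, data, j, history, aux)
                coef, s2, df, xtx = _ols(X[obs_j], data.Y[obs_j, j - 1],
                                         f"imputation regression, visit {j}")
                models[(j, None)] = VisitRegression(j, None, coef, names, s2, df, xtx)
            else:
                models[(j, None)] = cov_models[j]
        else:  # stratum
            for l in d_levels:
                if l < j:
                    continue
                sel = obs_j & (data.D == l)
                n_sel = int(sel.sum())
                if n_sel == 0:
                    raise ValueError(f"empty death stratum D={l} at visit {j}")
                if n_sel < stratum_min:
                    fallbacks.append((j, l))
                    continue
                try:
                    X, names = _regressors(data.Y, data, j, history, aux)
                    coef, s2, df, xtx = _ols(
                        X[sel], data.Y[sel, j - 1],
                        f"imputation regression, visit {j}, stratum D={l}")
                    models[(j, l)] = VisitRegression(j, l, coef, names, s2, df, xtx)
                except ValueError:
                    fallbacks.append((j, l))

    return SeqImputationFit(
        stratify=stratify, history=history, aux_cols=aux, models=models,
        cov_models=cov_models, d_levels=d_levels, fallbacks=fallbacks, n_visits=J,
    )


# ---------------------------------------------------------------------------
# filling
# ---------------------------------------------------------------------------

def _predict_visit(fit, data, W, j, model, noise_sd=None, rng=None, mask=None):
    """Fitted (or drawn) values of visit j for subjects in ``mask``."""
    dn = [n for n in model.names if n.startswith("D=")]
    X, _ = _regressors(W, data, j, fit.history, fit.aux_cols,
                       d_names=dn if dn else None)
    mu = X @ model.coef
    if noise_sd is not None:
        mu = mu + rng.normal(0.0, noise_sd, size=len(mu))
    return mu[mask] if mask is not None else mu


def _fill(fit, data, draws=None, rng=None):
    """One sequential pass; ``draws`` maps model key -> (coef, sigma2)."""
    W = np.where(data.observed, data.Y, np.nan)
    alive = data.alive
    for j in range(2, fit.n_visits + 1):
        need = alive[:, j - 1] & ~data.observed[:, j - 1]
        if not need.any():
            continue
        if fit.stratify == "stratum":
            for l in fit.d_levels:
                if l < j:
                    continue
                sel = need & (data.D == l)
                if not sel.any():
                    continue
                key = (j, l)
                if key in fit.models:
                    model, base = fit.models[key], fit.models[key]
                else:
                    model, base = fit.cov_models[j], fit.cov_models[j]
                    key = (j, "covariate")
                coef, s2 = draws[key] if draws else (base.coef, None)
                m = VisitRegression(j, model.stratum, coef, model.names,
                                    model.sigma2, model.df, model.xtx_inv)
                W[sel, j - 1] = _predict_visit(
                    fit, data, W, j, m,
                    noise_sd=np.sqrt(s2) if draws else None, rng=rng, mask=sel)
        else:
            base = fit.models[(j, None)]
            coef, s2 = draws[(j, None)] if draws else (base.coef, None)
            m = VisitRegression(j, base.stratum, coef, base.names,
                                base.sigma2, base.df, base.xtx_inv)
            W[need, j - 1] = _predict_visit(
                fit, data, W, j, m,
                noise_sd=np.sqrt(s2) if draws else None, rng=rng, mask=need)
    Y_out = np.where(alive, W, np.nan)
    assert np.all(np.isfinite(Y_out[alive])), "unfilled alive cell"
    panel = PanelData(
        Y=Y_out, R=alive.astype(np.int8), D=data.D.copy(),
        covariates=data.covariates.copy(), z_cols=list(data.z_cols),
        x_cols=list(data.x_cols), ids=data.ids.copy(),
    )
    return panel


def _posterior_draw(model: VisitRegression, rng):
    """Scaled-inverse-chi-square / conditional-normal posterior draw."""
    s2 = model.sigma2 * model.df / rng.chisquare(model.df)
    L = np.linalg.cholesky(model.xtx_inv * s2 + 1e-14 * np.eye(len(model.coef)))
    coef = model.coef + L @ rng.standard_normal(len(model.coef))
    return coef, s2


def _all_model_keys(fit):
    keys = list(fit.models.keys())
    if fit.stratify == "stratum":
        keys += [(j, "covariate") for j in fit.cov_models]
    return keys


def mi_impute(data: PanelData, fit: SeqImputationFit, M: int = 30, seed=None) -> list:
    """Proper multiple imputation: ``M`` completed datasets.

    Each imputation draws every component regression's (sigma^2, coef) from
    its posterior, then fills missing-while-alive cells sequentially for
    j = 2..J, feeding imputed values forward.  Default M = 30.
    """
    if M < 2:
        raise ValueError("M must be at least 2 for Rubin variance combination")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    out = []
    for m, child in enumerate(ss.spawn(M)):
        rng = np.random.default_rng(child)
        draws = {key: _posterior_draw(_lookup(fit, key), rng)
                 for key in _all_model_keys(fit)}
        panel = _fill(fit, data, draws=draws, rng=rng)
        out.append(ImputedDataset(panel=panel, m=m,
                                  provenance={"seed": seed, "stratify": fit.stratify}))
    return out


def _lookup(fit, key):
    if key in fit.models:
        return fit.models[key]
    j, tag = key
    return fit.cov_models[j]


def li_impute(data: PanelData, fit: SeqImputationFit) -> ImputedDataset:
    """Deterministic sequential conditional-mean fill (linear-increments
    style): the infinite-imputation limit of :func:`mi_impute`."""
    panel = _fill(fit, data, draws=None)
    return ImputedDataset(panel=panel, m=0, provenance={"stratify": fit.stratify})


# ---------------------------------------------------------------------------
# Rubin's rules and the pipelines
# ---------------------------------------------------------------------------

def rubin_combine(results: list) -> EstimateResult:
    """Combine per-imputation estimates: mean point estimate and variance
    ``W + (1 + 1/M) B`` (within + inflated between-imputation covariance)."""
    if len(results) < 2:
        raise ValueError("need at least 2 imputation results")
    names = results[0].param_names
    for r in results:
        if r.param_names != names:
            raise ValueError("mismatched parameter layouts across imputations")
        if r.vcov is None:
            raise ValueError("per-imputation vcov required for Rubin's rules")
    M = len(results)
    betas = np.stack([r.params for r in results])
    point = betas.mean(axis=0)
    W = np.mean([r.vcov for r in results], axis=0)
    dev = betas - point
    B = dev.T @ dev / (M - 1)
    T = W + (1 + 1 / M) * B
    return EstimateResult(
        method="MI", params=point, param_names=list(names), vcov=(T + T.T) / 2,
        diagnostics={"n_imputations": M,
                     "between_within_ratio": float(np.trace(B) / max(np.trace(W), 1e-300))},
    )


def estimate_mi(
    data: PanelData,
    spec,
    stratify: str = "none",
    history: str = "lag1",
    aux_cols=None,
    M: int = 30,
    seed=None,
    stratum_min: int = 30,
) -> EstimateResult:
    """MI pipeline: fit chain -> impute M times -> IEE per imputation ->
    Rubin's rules.  ``stratify='none'`` is the u-variant; ``'covariate'`` or
    ``'stratum'`` condition on the death time (f-variant)."""
    from .estimators import solve_iee

    fit = fit_sequential(data, stratify=stratify, history=history,
                         aux_cols=aux_cols, stratum_min=stratum_min)
    imps = mi_impute(data, fit, M=M, seed=seed)
    fits = [solve_iee(imp.panel, spec) for imp in imps]
    res = rubin_combine(fits)
    res.method = "MI_u" if stratify == "none" else "MI_f"
    res.diagnostics.update(stratify=stratify, stratum_fallbacks=list(fit.fallbacks))
    return res


def estimate_li(
    data: PanelData,
    spec,
    stratify: str = "none",
    history: str = "lag1",
    aux_cols=None,
    stratum_min: int = 30,
    keep_vcov: bool = False,
) -> EstimateResult:
    """Deterministic mean-imputation pipeline: fill -> IEE.

    The IEE sandwich ignores imputation uncertainty, so the default result
    carries no vcov; use the cluster bootstrap (study module) for standard
    errors, or pass ``keep_vcov=True`` to retain the naive sandwich.
    """
    from .estimators import solve_iee

    fit = fit_sequential(data, stratify=stratify, history=history,
                         aux_cols=aux_cols, stratum_min=stratum_min)
    imp = li_impute(data, fit)
    res = solve_iee(imp.panel, spec)
    res.method = "LI_u" if stratify == "none" else "LI_f"
    if not keep_vcov:
        res.vcov = None
    res.diagnostics.update(stratify=stratify, stratum_fallbacks=list(fit.fallbacks))
    return res
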