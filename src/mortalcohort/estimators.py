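"""Estimating-equation solvers: complete case, IEE and inverse-probability
weighting.

All of them solve the same linear estimating equation

    sum_i sum_j Z_ij I(D_i >= j) R_ij w_ij (Y_ij - beta' Z_ij) = 0

over observed survivor cells, which with an identity link and independence
working correlation is weighted least squares in closed form.  The sandwich
variance clusters at the subject level and treats the weights as fixed.
"""

from __future__ import annotations

import numpy as np

from .data import PanelData, complete_cases
from .design import MeanModelSpec
from .results import EstimateResult

__all__ = ["solve_iee", "estimate_cc", "estimate_ipw"]


def _stack_cells(data: PanelData, spec: MeanModelSpec, weights=None):
    """Stack observed alive cells into (X, y, w, subject index)."""
    obs = data.observed & data.alive
    design = spec.design_tensor(data)  # (N, J, p)
    idx_i, idx_j = np.nonzero(obs)
    X = design[idx_i, idx_j, :]
    y = data.Y[idx_i, idx_j]
    if weights is None:
        w = np.ones(len(y))
    else:
        wmat = weights.w if hasattr(weights, "w") else np.asarray(weights)
        w = wmat[idx_i, idx_j]
        if not np.all(np.isfinite(w)):
            raise ValueError("weights undefined on some observed cells")
    return X, y, w, idx_i


def _check_rank(X: np.ndarray, names) -> None:
    if X.shape[0] == 0:
        raise ValueError("no observed cells to fit on")
    # name collinear columns via QR with pivoting
    from scipy import linalg

    _, r, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = max(X.shape) * np.finfo(float).eps * (diag[0] if diag.size else 0.0)
    rank = int((diag > tol).sum())
    if rank < X.shape[1]:
        bad = [names[k] for k in piv[rank:]]
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")


def solve_iee(data: PanelData, spec: MeanModelSpec, weights=None) -> EstimateResult:
    """Weighted independence estimating equations, solved in closed form.

    ``weights`` is a :class:`~mortalcohort.dropout.WeightSet`, an (N, J)
    array, or ``None`` for unit weights (plain IEE).
    """
    X, y, w, subj = _stack_cells(data, spec, weights)
    _check_rank(X, spec.param_names)
    Xw = X * w[:, None]
    A = Xw.T @ X
    b = Xw.T @ y
    beta = np.linalg.solve(A, b)
    resid = y - X @ beta
    # subject-clustered sandwich
    scores = Xw * resid[:, None]
    # sum scores within subject
    order = np.argsort(subj, kind="stable")
    s_sorted = scores[order]
    subj_sorted = subj[order]
    boundaries = np.nonzero(np.diff(subj_sorted))[0] + 1
    per_subject = np.add.reduceat(s_sorted, np.r_[0, boundaries], axis=0)
    meat = per_subject.T @ per_subject
    Ainv = np.linalg.inv(A)
    vcov = Ainv @ meat @ Ainv
    vcov = (vcov + vcov.T) / 2
    diagnostics = {
        "n_cells": int(len(y)),
        "n_subjects_used": int(len(np.unique(subj))),
        "condition_number": float(np.linalg.cond(A)),
        "normal_eq_residual": float(np.max(np.abs(A @ beta - b))),
        "weight_min": float(w.min()),
        "weight_max": float(w.max()),
    }
    return EstimateResult(
        method="IEE" if weights is None else "IEE(weighted)",
        params=beta,
        param_names=spec.param_names,
        vcov=vcov,
        diagnostics=diagnostics,
    )


def estimate_cc(data: PanelData, spec: MeanModelSpec) -> EstimateResult:
    """Complete-case analysis: IEE on subjects observed at every visit."""
    res = solve_iee(complete_cases(data), spec, weights=None)
    res.method = "CC"
    return res


def estimate_ipw(
    data: PanelData,
    spec: MeanModelSpec,
    variant: str = "u",
    history: str = "lag1",
    aux_cols=None,
    floor: float = 0.01,
    stratum_min: int = 30,
) -> EstimateResult:
    """Inverse-probability-weighted IEE under a chosen MAR variant.

    ``variant`` is one of ``"u"``, ``"p"``, ``"f_strat"``, ``"f_cov"``: the
    discrete-time dropout hazards are modelled, respectively, among survivors
    at the current visit, among survivors at the target visit, within death
    strata, or with the death time D entered as a categorical covariate.
    """
    from . import dropout

    fit = dropout.fit_dropout(
        data,
        variant=variant,
        history=history,
        aux_cols=aux_cols,
        allow_degenerate=True,
        stratum_min=stratum_min,
    )
    wset = dropout.weights(fit, data, floor=floor)
    res = solve_iee(data, spec, weights=wset)
    res.method = f"IPW_{variant}"
    res.diagnostics.update(
        n_floored=wset.n_floored,
        stratum_fallbacks=list(fit.fallbacks),
        dropout_variant=variant,
    )
    return res
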