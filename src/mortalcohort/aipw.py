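"""Augmented inverse-probability-weighted estimating equations.

A subject's contribution to the AIPW estimating equations is

    Psi_i(beta) = (R_D / pi~_D) U_i(beta)
                + sum_{j=1}^{D-1} (R_j / pi~_j - R_{j+1} / pi~_{j+1}) H_ij(beta)

where ``U_i(beta) = sum_{m<=D} Z_m (Y_m - beta' Z_m)`` is the subject's full
(survivor) estimating-function contribution, ``pi~_j`` is a model for the
cumulative observation probability ``P(R_j = 1 | Ybar_{j-1}, X)``, and
``H_ij(beta)`` replaces the unobserved tail of ``U_i`` by recursive
conditional-mean (Paik) predictions chained from the history observed through
visit j.  ``H_D = U`` holds by construction, so the equations are unbiased if
*either* the dropout hazards or the mean-imputation chain is correctly
specified (double robustness); with both correct, AIPW is at least as
efficient as the corresponding IPW estimator.

Because the mean model is linear with an identity link, ``Psi(beta) = b - A
beta`` and the solution is a one-shot linear solve.  The ``f`` variant enters
the death time D as categorical indicators in both nuisance models; the ``u``
variant excludes D throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import dropout as dropout_mod
from .data import PanelData
from .imputation import SeqImputationFit, fit_sequential, _regressors, VisitRegression
from .results import EstimateResult

__all__ = [
    "AipwComponents",
    "fit_paik",
    "fit_pi_tilde",
    "build_components",
    "solve_aipw",
    "estimate_aipw",
]


def fit_paik(data: PanelData, include_D: bool = False, history: str = "lag1",
             aux_cols=None) -> SeqImputationFit:
    """Recursive mean-prediction (Paik) model: per-visit OLS of Y_j on the
    observed history and X, optionally with D as categorical covariate.

    Shares machinery with the sequential imputation fit; its deterministic
    one-step predictions coincide with the linear-increments fill.
    """
    return fit_sequential(
        data,
        stratify="covariate" if include_D else "none",
        history=history,
        aux_cols=aux_cols,
    )


def fit_pi_tilde(data: PanelData, include_D: bool = False, history: str = "lag1",
                 aux_cols=None):
    """Cumulative observation probabilities ``pi~_j(Ybar_{j-1}, X)``.

    Per-visit logistic hazards of R_k on the lagged outcome history and X
    among subjects still under observation, multiplied cumulatively; each
    factor at k conditions on the history through k-1 only, so ``pi~_j`` is a
    function of ``Ybar_{j-1}`` as the augmentation requires.

    Returns ``(hazard_fit, pi_tilde)`` with ``pi_tilde`` an (N, J) matrix
    (NaN beyond each subject's evaluable run; ``pi~_1 = 1``).
    """
    fit = dropout_mod.fit_dropout(
        data,
        variant="f_cov" if include_D else "u",
        history=history,
        aux_cols=aux_cols,
        allow_degenerate=True,
    )
    pi = dropout_mod.observation_prob(fit, data)
    return fit, pi


@dataclass
class AipwComponents:
    pi_tilde: np.ndarray          # (N, J), floored
    completed: list               # completed[j-1] = (N, J) Ytilde^(j), j = 1..J
    paik_fit: SeqImputationFit
    hazard_fit: object
    floor: float
    n_floored: int
    diagnostics: dict = field(default_factory=dict)


def _paik_completed(data: PanelData, fit: SeqImputationFit) -> list:
    """Ytilde^(j) for every prefix length j: actual outcomes through visit j,
    chained mean predictions beyond."""
    J = data.n_visits
    Yobs = np.where(data.observed, data.Y, np.nan)
    out = []
    for j in range(1, J + 1):
        W = Yobs.copy()
        for m in range(j + 1, J + 1):
            key = (m, None)
            model = fit.models.get(key) or fit.cov_models.get(m)
            dn = [n for n in model.names if n.startswith("D=")]
            X, _ = _regressors(W, data, m, fit.history, fit.aux_cols,
                               d_names=dn if dn else None)
            W[:, m - 1] = X @ model.coef
        out.append(W)
    return out


def build_components(
    data: PanelData,
    variant: str = "u",
    history: str = "lag1",
    dropout_aux_cols=None,
    paik_aux_cols=None,
    floor: float = 0.01,
) -> AipwComponents:
    """Fit both nuisance models and assemble the augmentation inputs.

    ``dropout_aux_cols`` / ``paik_aux_cols`` control the covariates of each
    nuisance model separately (deliberately omitting one is the standard way
    to study double robustness)."""
    if variant not in ("u", "f"):
        raise ValueError("variant must be 'u' or 'f'")
    include_D = variant == "f"
    hz_fit, pi = fit_pi_tilde(data, include_D=include_D, history=history,
                              aux_cols=dropout_aux_cols)
    paik = fit_paik(data, include_D=include_D, history=history,
                    aux_cols=paik_aux_cols)
    completed = _paik_completed(data, paik)
    defined = np.isfinite(pi)
    n_floored = int((pi[defined] < floor).sum())
    pi_f = np.where(defined, np.maximum(pi, floor), np.nan)
    qs = np.nanquantile(pi_f, [0.0, 0.25, 0.5, 0.75, 1.0])
    return AipwComponents(
        pi_tilde=pi_f, completed=completed, paik_fit=paik, hazard_fit=hz_fit,
        floor=floor, n_floored=n_floored,
        diagnostics={"pi_tilde_quantiles": qs.tolist()},
    )


def solve_aipw(
    data: PanelData,
    spec,
    components: AipwComponents,
    augment: bool = True,
) -> EstimateResult:
    """Assemble and solve the AIPW estimating equations in one linear solve.

    ``augment=False`` zeroes the H terms, leaving the pure per-subject IPW
    estimating equation weighted by ``R_D / pi~_D`` (a diagnostic reduction,
    not an estimator to use in practice)."""
    N, J = data.n_subjects, data.n_visits
    ZT = spec.design_tensor(data)                       # (N, J, p)
    alive = data.alive
    ZTm = ZT * alive[:, :, None]
    R = data.R
    D = data.D
    pi = components.pi_tilde
    k_last = data.last_observed

    # H_D = U identity: the completed record at prefix D equals the observed
    # record for every fully observed subject.
    full = k_last == D
    for i in np.nonzero(full)[0][: min(N, 200)]:
        d = D[i]
        comp = components.completed[d - 1][i, :d]
        assert np.allclose(comp, data.Y[i, :d], equal_nan=False), \
            "H_D != U for a fully observed subject"

    # per-subject coefficient on U and on each H_j
    wU = np.zeros(N)
    pi_at_D = pi[np.arange(N), D - 1]
    wU[full] = 1.0 / pi_at_D[full]
    if not np.all(np.isfinite(wU[full])):
        raise ValueError("pi~ undefined at D for a fully observed subject")

    Yobs0 = np.where(data.observed & alive, data.Y, 0.0)
    SU = np.einsum("njp,nj->np", ZTm, Yobs0)            # sum_m z_m Y_m (observed)
    bvec = wU[:, None] * SU                             # (N, p) per-subject b
    coefA = wU.copy()

    if augment:
        for j in range(1, J):
            cj = np.zeros(N)
            m1 = (R[:, j - 1] == 1) & (D >= j + 1)      # j <= D-1 and R_j = 1
            if not m1.any():
                continue
            term1 = 1.0 / pi[m1, j - 1]
            nxt = R[m1, j] == 1
            term2 = np.zeros(m1.sum())
            term2[nxt] = 1.0 / pi[m1, j][nxt]
            cj[m1] = term1 - term2
            Yc = np.where(alive, components.completed[j - 1], 0.0)
            Yc = np.where(m1[:, None], Yc, 0.0)
            if not np.all(np.isfinite(Yc)):
                raise ValueError(f"Paik completion undefined at prefix {j}")
            Sj = np.einsum("njp,nj->np", ZTm, Yc)
            bvec += cj[:, None] * Sj
            coefA += cj

    A = np.einsum("n,njp,njq->pq", coefA, ZTm, ZTm)
    b = bvec.sum(axis=0)
    cond = np.linalg.cond(A)
    if not np.isfinite(cond) or cond > 1e12:
        raise ValueError(f"singular AIPW system (condition number {cond:.3g})")
    beta = np.linalg.solve(A, b)

    # sandwich: psi_i = bvec_i - coefA_i * (G_i beta)
    zbeta = np.einsum("njp,p->nj", ZTm, beta)
    Gb = np.einsum("njp,nj->np", ZTm, zbeta)
    psi = bvec - coefA[:, None] * Gb
    meat = psi.T @ psi
    Ainv = np.linalg.inv(A)
    vcov = Ainv @ meat @ Ainv.T
    vcov = (vcov + vcov.T) / 2

    return EstimateResult(
        method="AIPW",
        params=beta,
        param_names=spec.param_names,
        vcov=vcov,
        diagnostics={
            "condition_number": float(cond),
            "n_floored": components.n_floored,
            "augmented": augment,
            **components.diagnostics,
        },
    )


def estimate_aipw(
    data: PanelData,
    spec,
    variant: str = "u",
    history: str = "lag1",
    dropout_aux_cols=None,
    paik_aux_cols=None,
    floor: float = 0.01,
) -> EstimateResult:
    """Doubly robust AIPW estimator (``variant`` 'u' excludes D from both
    nuisance models, 'f' enters D as categorical indicators in both)."""
    comp = build_components(
        data, variant=variant, history=history,
        dropout_aux_cols=dropout_aux_cols, paik_aux_cols=paik_aux_cols,
        floor=floor,
    )
    res = solve_aipw(data, spec, comp, augment=True)
    res.method = f"AIPW_{variant}"
    return res
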