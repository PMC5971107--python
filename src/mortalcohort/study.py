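"""Replicate simulation harness: bias, standardized bias, empirical SE.

``run_study`` generates independent datasets under a mechanism, applies a
set of estimation methods to each, and summarises, per method and parameter,

* bias x100                 = 100 (mean estimate - truth)
* standardized bias (s-bias) = 100 (mean estimate - truth) / empirical SD
* empirical SE x100          = 100 SD of the estimates across replicates

An absolute standardized bias of roughly 40% is the conventional flag for a
practically significant bias.  Replicate-level failures (separation,
singularity) are excluded with a logged count rather than aborting the study.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import partial

import numpy as np
import pandas as pd

from .aipw import estimate_aipw
from .estimators import estimate_cc, estimate_ipw, solve_iee
from .imputation import estimate_li, estimate_mi
from .simulate import SimConfig, SimTruth, generate

__all__ = ["StudyResult", "run_study", "bootstrap_se", "resolve_method", "METHOD_NAMES"]

METHOD_NAMES = (
    "cc", "iee", "ipw_u", "ipw_p", "ipw_f", "ipw_f_strat",
    "aipw_u", "aipw_f", "mi_u", "mi_f", "mi_f_strat", "li_u", "li_f",
)


def resolve_method(name: str, M: int = 30, **options):
    """Map a method label to a callable ``(data, spec, seed) -> EstimateResult``."""
    def no_seed(fn):
        return lambda data, spec, seed: fn(data, spec, **options)

    table = {
        "cc": no_seed(estimate_cc),
        "iee": no_seed(solve_iee),
        "ipw_u": no_seed(partial(estimate_ipw, variant="u")),
        "ipw_p": no_seed(partial(estimate_ipw, variant="p")),
        "ipw_f": no_seed(partial(estimate_ipw, variant="f_cov")),
        "ipw_f_strat": no_seed(partial(estimate_ipw, variant="f_strat")),
        "aipw_u": no_seed(partial(estimate_aipw, variant="u")),
        "aipw_f": no_seed(partial(estimate_aipw, variant="f")),
        "li_u": no_seed(partial(estimate_li, stratify="none")),
        "li_f": no_seed(partial(estimate_li, stratify="covariate")),
        "mi_u": lambda data, spec, seed: estimate_mi(
            data, spec, stratify="none", M=M, seed=seed, **options),
        "mi_f": lambda data, spec, seed: estimate_mi(
            data, spec, stratify="covariate", M=M, seed=seed, **options),
        "mi_f_strat": lambda data, spec, seed: estimate_mi(
            data, spec, stratify="stratum", M=M, seed=seed, **options),
    }
    try:
        return table[name]
    except KeyError:
        raise ValueError(f"unknown method {name!r}; known: {METHOD_NAMES}") from None


@dataclass
class StudyResult:
    table: pd.DataFrame               # method, parameter, bias100, sbias, se100...
    estimates: dict                   # method -> (n_ok, p) array
    failures: dict                    # method -> count
    truth: SimTruth
    meta: dict = field(default_factory=dict)

    def sbias(self, method: str) -> pd.Series:
        sub = self.table[self.table["method"] == method]
        return sub.set_index("parameter")["sbias"]

    def se100(self, method: str) -> pd.Series:
        sub = self.table[self.table["method"] == method]
        return sub.set_index("parameter")["se100"]


def summarize(estimates: np.ndarray, truth: SimTruth, method: str) -> pd.DataFrame:
    """Table-2-style summary of one method's replicate estimates."""
    mean = estimates.mean(axis=0)
    sd = estimates.std(axis=0, ddof=1)
    if np.any(sd <= 0):
        raise ValueError("degenerate empirical SD; cannot standardize bias")
    bias = mean - truth.beta_true
    return pd.DataFrame({
        "method": method,
        "parameter": truth.param_names,
        "bias100": 100 * bias,
        "sbias": 100 * bias / sd,
        "se100": 100 * sd,
        "n_reps": estimates.shape[0],
    })


def run_study(
    config: SimConfig,
    spec,
    methods,
    n_reps: int = 300,
    seed=None,
    truth: SimTruth = None,
    n_mc_truth: int = 1_000_000,
) -> StudyResult:
    """Run the replicate study.

    ``methods`` is a list of method names (see ``METHOD_NAMES``) and/or
    ``(label, callable)`` pairs with signature ``(data, spec, seed)``.
    ``truth`` defaults to the Monte-Carlo oracle for ``config``.
    """
    from .simulate import true_params

    ss = np.random.SeedSequence(seed)
    truth_seed, *rep_seeds = ss.spawn(n_reps + 1)
    if truth is None:
        truth = true_params(config, spec, n_mc=n_mc_truth, seed=truth_seed)

    runners = []
    for m in methods:
        if isinstance(m, str):
            runners.append((m, resolve_method(m)))
        else:
            runners.append(m)

    collected = {label: [] for label, _ in runners}
    failures = {label: 0 for label, _ in runners}
    for rep, rep_ss in enumerate(rep_seeds):
        data_seed, method_seed = rep_ss.spawn(2)
        data = generate(config, seed=data_seed)
        for k, (label, fn) in enumerate(runners):
            try:
                res = fn(data, spec, np.random.SeedSequence(
                    entropy=method_seed.entropy, spawn_key=method_seed.spawn_key + (k,)))
                collected[label].append(res.params)
            except (ValueError, np.linalg.LinAlgError):
                failures[label] += 1

    frames, estimates = [], {}
    for label, _ in runners:
        if not collected[label]:
            raise ValueError(f"method {label!r} failed on every replicate")
        est = np.vstack(collected[label])
        estimates[label] = est
        frames.append(summarize(est, truth, label))

    return StudyResult(
        table=pd.concat(frames, ignore_index=True),
        estimates=estimates,
        failures=failures,
        truth=truth,
        meta={"n_reps": n_reps, "config": config.to_dict(), "seed": seed},
    )


def bootstrap_se(data, spec, method, B: int = 200, seed=None, max_fail: float = 0.1):
    """Cluster (subject-level) bootstrap standard errors.

    Resamples subjects with replacement and refits the entire pipeline --
    dropout/imputation models included -- returning the SD of the estimates
    and percentile confidence intervals.
    """
    if B < 2:
        raise ValueError("B must be at least 2")
    fn = resolve_method(method) if isinstance(method, str) else method
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    draws, n_fail = [], 0
    for b in range(B):
        idx = rng.integers(0, data.n_subjects, size=data.n_subjects)
        child = np.random.SeedSequence(entropy=ss.entropy, spawn_key=(1, b))
        try:
            res = fn(data.subset(idx), spec, child)
            draws.append(res.params)
        except (ValueError, np.linalg.LinAlgError):
            n_fail += 1
    if n_fail > max_fail * B:
        raise ValueError(f"excessive bootstrap failures: {n_fail}/{B}")
    draws = np.vstack(draws)
    se = draws.std(axis=0, ddof=1)
    ci = np.percentile(draws, [2.5, 97.5], axis=0)
    return pd.DataFrame({
        "parameter": spec.param_names,
        "se": se,
        "ci_lower": ci[0],
        "ci_upper": ci[1],
    })
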