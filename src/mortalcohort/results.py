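"""Results container shared by every estimator."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["EstimateResult"]


@dataclass
class EstimateResult:
    """Point estimates, optional covariance matrix and method metadata.

    ``vcov`` is a subject-clustered sandwich covariance where available and
    ``None`` where the estimator's default variance requires a bootstrap
    (e.g. deterministic linear-increments imputation).
    """

    method: str
    params: np.ndarray
    param_names: list
    vcov: np.ndarray = None
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self):
        self.params = np.asarray(self.params, dtype=float)
        if self.vcov is not None:
            self.vcov = np.asarray(self.vcov, dtype=float)
            if self.vcov.shape != (len(self.params),) * 2:
                raise ValueError("vcov shape does not match params")
            if not np.allclose(self.vcov, self.vcov.T, atol=1e-8):
                raise ValueError("vcov must be symmetric")

    @property
    def bse(self) -> np.ndarray:
        if self.vcov is None:
            return np.full(len(self.params), np.nan)
        return np.sqrt(np.clip(np.diag(self.vcov), 0.0, None))

    def params_series(self) -> pd.Series:
        return pd.Series(self.params, index=self.param_names, name=self.method)

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        from scipy import stats

        z = stats.norm.ppf(1 - alpha / 2)
        se = self.bse
        return pd.DataFrame(
            {"lower": self.params - z * se, "upper": self.params + z * se},
            index=self.param_names,
        )

    def summary(self) -> str:
        from scipy import stats

        se = self.bse
        with np.errstate(divide="ignore", invalid="ignore"):
            zval = self.params / se
            pval = 2 * stats.norm.sf(np.abs(zval))
        tab = pd.DataFrame(
            {
                "coef": self.params,
                "std err": se,
                "z": zval,
                "P>|z|": pval,
            },
            index=self.param_names,
        )
        lines = [
            f"Partly conditional mean model -- method: {self.method}",
            tab.to_string(float_format=lambda v: f"{v: .4f}"),
        ]
        keys = ("n_cells", "weight_min", "weight_max", "n_floored", "n_imputations")
        diag = {k: self.diagnostics[k] for k in keys if k in self.diagnostics}
        if diag:
            lines.append("diagnostics: " + ", ".join(f"{k}={v}" for k, v in diag.items()))
        return "\n".join(lines)
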