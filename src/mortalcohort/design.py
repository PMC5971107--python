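"""Mean-model design for the partly conditional estimand.

The estimand is the parameter vector beta of a linear model for the mean
outcome among survivors, ``E(Y_j | Z, D >= j) = beta' Z_j``, where ``Z_j`` is
a visit-specific design vector built from the baseline covariates.  The
default design is a saturated visit/sex specification: intercept, indicators
for visits 1..J-1 (visit J is the reference), a sex main effect, and
visit-by-sex interactions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["MeanModelSpec", "visit_sex_design"]


class MeanModelSpec:
    """Maps (visit j, baseline covariates Z) to a design vector.

    Parameters
    ----------
    builder : callable ``(j: int, Z: DataFrame) -> (N, p) array``
        Returns the design rows of every subject at visit ``j``.  Must be
        linear-model ready (the mean is ``beta' Z_j``, linear in beta).
    param_names : list of str
    """

    def __init__(self, builder, param_names):
        self.builder = builder
        self.param_names = list(param_names)

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    def design_at(self, j: int, Z: pd.DataFrame) -> np.ndarray:
        out = np.asarray(self.builder(j, Z), dtype=float)
        if out.shape != (len(Z), self.n_params):
            raise ValueError(
                f"design builder returned shape {out.shape}, "
                f"expected {(len(Z), self.n_params)}"
            )
        return out

    def design_tensor(self, data) -> np.ndarray:
        """(N, J, p) stack of design rows for every subject and visit."""
        Z = data.Z()
        return np.stack(
            [self.design_at(j, Z) for j in range(1, data.n_visits + 1)], axis=1
        )


def visit_sex_design(n_visits: int = 5, sex_col: str = "sex") -> MeanModelSpec:
    """The default analysis design: visit indicators and sex interactions.

    Columns: ``const``, ``I(j=1) .. I(j=J-1)``, ``sex``, and
    ``I(j=1)*sex .. I(j=J-1)*sex`` -- visit J is the reference category, so
    the visit coefficients are survivor mean contrasts against the final
    visit, separately for each sex.
    """
    J = n_visits
    names = (
        ["const"]
        + [f"visit{j}" for j in range(1, J)]
        + [sex_col]
        + [f"visit{j}:{sex_col}" for j in range(1, J)]
    )

    def builder(j, Z):
        n = len(Z)
        sex = Z[sex_col].to_numpy(dtype=float)
        cols = [np.ones(n)]
        for v in range(1, J):
            cols.append(np.full(n, 1.0 if v == j else 0.0))
        cols.append(sex)
        for v in range(1, J):
            cols.append(sex if v == j else np.zeros(n))
        return np.column_stack(cols)

    return MeanModelSpec(builder, names)
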