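"""Model-level interface: a partly conditional mean model bound to a panel.

``PartlyConditionalMean`` pairs a :class:`~mortalcohort.data.PanelData` with
a :class:`~mortalcohort.design.MeanModelSpec` and dispatches ``fit`` to any
of the registered estimation methods, returning an
:class:`~mortalcohort.results.EstimateResult`.
"""

from __future__ import annotations

import numpy as np

from .data import PanelData, monotonize as _monotonize, read_panel_csv, validate
from .design import MeanModelSpec, visit_sex_design
from .results import EstimateResult
from .study import METHOD_NAMES, resolve_method

__all__ = ["PartlyConditionalMean"]


class PartlyConditionalMean:
    """A linear model for E(Y_j | Z, D >= j), the survivor mean at visit j.

    Parameters
    ----------
    data : PanelData
        Monotone mortal-cohort panel (``monotonize=True`` forces the
        pattern).
    spec : MeanModelSpec, optional
        Defaults to the saturated visit/sex design when the analysis
        covariates contain a ``sex`` column.

    Examples
    --------
    >>> model = PartlyConditionalMean(data)
    >>> res = model.fit(method="aipw_f")
    >>> print(res.summary())
    """

    def __init__(self, data: PanelData, spec: MeanModelSpec = None,
                 monotonize: bool = False):
        if monotonize:
            data = _monotonize(data)
        problems = validate(data)
        if problems:
            rules = sorted({v.rule for v in problems})
            raise ValueError(f"invalid panel data ({len(problems)} violations: {rules})")
        if spec is None:
            if "sex" not in data.z_cols:
                raise ValueError(
                    "no default design without a 'sex' analysis covariate; "
                    "pass a MeanModelSpec"
                )
            spec = visit_sex_design(data.n_visits)
        self.data = data
        self.spec = spec

    @classmethod
    def from_csv(cls, path, z_cols, x_cols=None, spec=None,
                 monotonize: bool = False) -> "PartlyConditionalMean":
        data = read_panel_csv(path, z_cols=z_cols, x_cols=x_cols,
                              monotonize_flag=monotonize)
        return cls(data, spec=spec)

    @property
    def methods(self) -> tuple:
        return METHOD_NAMES

    def fit(self, method: str = "iee", seed=None, **options) -> EstimateResult:
        """Fit by any registered method (``model.methods`` lists them).

        ``seed`` feeds the imputation draws of the MI methods; ``options``
        are forwarded to the estimator (e.g. ``floor``, ``history``,
        ``aux_cols``, ``M``).
        """
        runner = resolve_method(method, **options)
        return runner(self.data, self.spec, seed)

    def bootstrap_se(self, method: str = "iee", B: int = 200, seed=None):
        from .study import bootstrap_se

        return bootstrap_se(self.data, self.spec, method, B=B, seed=seed)
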