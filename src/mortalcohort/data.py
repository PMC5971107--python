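"""Data model for mortal-cohort longitudinal data.

A *mortal cohort* is a panel of N subjects with J scheduled visits in which a
subject may miss visits (dropout, monotone) and may die during follow-up.  The
central bookkeeping distinguishes two different kinds of "no outcome value":

* **missing while alive** -- visit ``j <= D_i`` but the outcome was not
  observed (``R[i, j] = 0``).  These cells have a well-defined, unknown value
  and are the target of weighting/imputation.
* **undefined, post death** -- visit ``j > D_i``.  The outcome does not exist;
  these cells must never enter an estimating equation or an imputation model.

``D_i`` is the last scheduled visit at which subject ``i`` is alive
(1-indexed); ``D_i = J`` means alive at study end, and "dies between visits j
and j+1" is encoded as ``D = j``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PanelData",
    "Violation",
    "validate",
    "monotonize",
    "complete_cases",
    "read_panel_csv",
    "write_panel_csv",
    "panel_from_long",
    "panel_to_long",
]


@dataclass(frozen=True)
class Violation:
    """A single invariant violation: which subject, visit and rule."""

    subject: int
    visit: int
    rule: str
    message: str = ""


@dataclass
class PanelData:
    """Outcomes, response indicators, survival and baseline covariates.

    Parameters
    ----------
    Y : (N, J) float array
        Outcome matrix; ``nan`` wherever the outcome is unobserved or
        undefined.  Column ``j-1`` holds visit ``j`` (visits are 1-indexed).
    R : (N, J) integer array of 0/1
        Response indicators; ``R[i, j-1] = 1`` iff ``Y`` is observed.
    D : (N,) integer array
        Last visit alive, values in ``1..J``.
    covariates : DataFrame with N rows
        Fully observed baseline covariates (analysis + auxiliary).
    z_cols, x_cols : list of str
        Names of the analysis covariates Z and the auxiliary covariates X;
        ``x_cols`` must be a superset of ``z_cols``.
    """

    Y: np.ndarray
    R: np.ndarray
    D: np.ndarray
    covariates: pd.DataFrame
    z_cols: list = field(default_factory=list)
    x_cols: list = None
    ids: np.ndarray = None

    def __post_init__(self):
        self.Y = np.asarray(self.Y, dtype=float)
        self.R = np.asarray(self.R, dtype=np.int8)
        self.D = np.asarray(self.D, dtype=np.int64)
        if self.Y.ndim != 2 or self.R.shape != self.Y.shape:
            raise ValueError("Y and R must be matching N x J matrices")
        if self.D.shape != (self.Y.shape[0],):
            raise ValueError("D must be a length-N vector")
        if self.x_cols is None:
            self.x_cols = list(self.covariates.columns)
        missing = set(self.z_cols) - set(self.x_cols)
        if missing:
            raise ValueError(f"x_cols must contain z_cols; missing {sorted(missing)}")
        unknown = set(self.x_cols) - set(self.covariates.columns)
        if unknown:
            raise ValueError(f"covariate columns not present: {sorted(unknown)}")
        if self.covariates.isna().any().any():
            raise ValueError("baseline covariates must be fully observed")
        if len(self.covariates) != self.n_subjects:
            raise ValueError("covariates must have one row per subject")
        if self.ids is None:
            self.ids = np.arange(self.n_subjects)
        else:
            self.ids = np.asarray(self.ids)

    # -- basic geometry -------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return self.Y.shape[0]

    @property
    def n_visits(self) -> int:
        return self.Y.shape[1]

    @property
    def visits(self) -> np.ndarray:
        """1-indexed visit labels."""
        return np.arange(1, self.n_visits + 1)

    # -- masks -----------------------------------------------------------
    @property
    def alive(self) -> np.ndarray:
        """(N, J) boolean; True where visit j <= D_i."""
        return self.visits[None, :] <= self.D[:, None]

    @property
    def observed(self) -> np.ndarray:
        """(N, J) boolean; True where the outcome is observed."""
        return self.R.astype(bool)

    @property
    def last_observed(self) -> np.ndarray:
        """(N,) last visit with R = 1 (monotone data), in ``1..J``."""
        return self.R.astype(np.int64).sum(axis=1)

    def observed_history(self) -> np.ndarray:
        """The observed-or-undefined outcome process Y*.

        ``Y*_j = Y_j`` when observed, ``nan`` otherwise -- the record a data
        analyst actually sees.
        """
        out = np.where(self.observed, self.Y, np.nan)
        return out

    def Z(self) -> pd.DataFrame:
        return self.covariates[self.z_cols]

    def X(self) -> pd.DataFrame:
        return self.covariates[self.x_cols]

    def subset(self, idx) -> "PanelData":
        """Row-subset (or resample, for the cluster bootstrap) by position."""
        idx = np.asarray(idx)
        return PanelData(
            Y=self.Y[idx].copy(),
            R=self.R[idx].copy(),
            D=self.D[idx].copy(),
            covariates=self.covariates.iloc[idx].reset_index(drop=True),
            z_cols=list(self.z_cols),
            x_cols=list(self.x_cols),
            ids=self.ids[idx].copy(),
        )

    def copy(self) -> "PanelData":
        return self.subset(np.arange(self.n_subjects))


# ---------------------------------------------------------------------------
# validation, monotonization, complete cases
# ---------------------------------------------------------------------------

def validate(data: PanelData) -> list:
    """Check the PanelData invariants; return a list of violations.

    An empty list means the data are valid: every subject observed at
    baseline, monotone response, no observation after death, and outcome
    values present exactly where ``R = 1``.
    """
    out = []
    N, J = data.Y.shape
    if np.any((data.D < 1) | (data.D > J)):
        for i in np.nonzero((data.D < 1) | (data.D > J))[0]:
            out.append(Violation(int(i), 0, "death index", f"D={data.D[i]} outside 1..{J}"))
    R = data.R
    for i in range(N):
        if R[i, 0] != 1:
            out.append(Violation(i, 1, "baseline response", "R_1 must be 1"))
        dropped = False
        for j in range(1, J):
            if R[i, j - 1] == 0:
                dropped = True
            if dropped and R[i, j] == 1:
                out.append(Violation(i, j + 1, "non-monotone", "R=1 after a missing visit"))
                dropped = False  # report each resumption once
        for j in range(J):
            if R[i, j] == 1 and j + 1 > data.D[i]:
                out.append(Violation(i, j + 1, "post-death observation", "R=1 with j > D"))
            if R[i, j] == 1 and not np.isfinite(data.Y[i, j]):
                out.append(Violation(i, j + 1, "missing observed value", "R=1 but Y is nan"))
            if R[i, j] == 0 and np.isfinite(data.Y[i, j]):
                out.append(Violation(i, j + 1, "stray value", "R=0 but Y has a value"))
    return out


def monotonize(data: PanelData) -> PanelData:
    """Force a monotone missingness pattern.

    Every outcome after a subject's first missing visit is set unobserved
    (``R <- 0`` and the value dropped); ``D`` is unchanged.  Idempotent.
    """
    R = data.R.copy()
    Y = data.Y.copy()
    # cumulative product along visits: 1 until the first 0, then 0
    keep = np.cumprod(R, axis=1).astype(bool)
    Y[~keep] = np.nan
    return PanelData(
        Y=Y,
        R=keep.astype(np.int8),
        D=data.D.copy(),
        covariates=data.covariates.copy(),
        z_cols=list(data.z_cols),
        x_cols=list(data.x_cols),
        ids=data.ids.copy(),
    )


def complete_cases(data: PanelData) -> PanelData:
    """Retain exactly the subjects observed at every visit."""
    full = data.R.all(axis=1)
    if not full.any():
        raise ValueError("no complete cases: every subject has a missing visit")
    return data.subset(np.nonzero(full)[0])


# ---------------------------------------------------------------------------
# long-format interchange
# ---------------------------------------------------------------------------

def panel_to_long(data: PanelData) -> pd.DataFrame:
    """One row per (subject, visit); post-death rows present with empty y."""
    N, J = data.Y.shape
    rows = {
        "id": np.repeat(data.ids, J),
        "visit": np.tile(np.arange(1, J + 1), N),
        "y": data.Y.ravel(),
        "r": data.R.ravel().astype(int),
        "d": np.repeat(data.D, J),
    }
    df = pd.DataFrame(rows)
    cov = data.covariates.iloc[np.repeat(np.arange(N), J)].reset_index(drop=True)
    return pd.concat([df, cov], axis=1)


def panel_from_long(df: pd.DataFrame, z_cols, x_cols=None,
                    monotonize_flag: bool = False) -> PanelData:
    """Build a PanelData from the long schema (id, visit, y, r, d, covariates).

    Raises ``ValueError`` listing the offending subjects when the data violate
    an invariant and ``monotonize_flag`` is off.
    """
    required = {"id", "visit", "y", "r", "d"}
    if not required <= set(df.columns):
        raise ValueError(f"long CSV must have columns {sorted(required)}")
    df = df.sort_values(["id", "visit"], kind="stable")
    ids = df["id"].unique()
    J = int(df["visit"].max())
    N = len(ids)
    counts = df.groupby("id", sort=False).size()
    if not (counts == J).all():
        bad = counts[counts != J].index.tolist()
        raise ValueError(f"subjects without one row per visit 1..{J}: {bad[:10]}")
    Y = df["y"].to_numpy(dtype=float).reshape(N, J)
    R = df["r"].to_numpy(dtype=int).reshape(N, J)
    D = df["d"].to_numpy(dtype=np.int64).reshape(N, J)[:, 0]
    if x_cols is None:
        x_cols = [c for c in df.columns if c not in required]
    cov = df.loc[df["visit"] == 1, list(dict.fromkeys(x_cols))].reset_index(drop=True)
    Y = np.where(R == 1, Y, np.nan)
    data = PanelData(Y=Y, R=R, D=D, covariates=cov, z_cols=list(z_cols),
                     x_cols=list(dict.fromkeys(x_cols)), ids=ids)
    if monotonize_flag:
        data = monotonize(data)
    problems = validate(data)
    if problems:
        subjects = sorted({v.subject for v in problems})
        raise ValueError(
            f"invalid panel: {len(problems)} violations "
            f"(first rules: {[v.rule for v in problems[:5]]}; subjects {subjects[:10]})"
        )
    return data


def write_panel_csv(data: PanelData, path) -> None:
    df = panel_to_long(data)
    df.to_csv(path, index=False, float_format="%.17g")


def read_panel_csv(path, z_cols, x_cols=None, monotonize_flag: bool = False) -> PanelData:
    df = pd.read_csv(path)
    return panel_from_long(df, z_cols=z_cols, x_cols=x_cols,
                           monotonize_flag=monotonize_flag)
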