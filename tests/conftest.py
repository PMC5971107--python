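import numpy as np
import pandas as pd
import pytest

from mortalcohort import simulate as sim
from mortalcohort.data import PanelData
from mortalcohort.design import visit_sex_design


@pytest.fixture(scope="session")
def spec5():
    return visit_sex_design(5)


@pytest.fixture(scope="session")
def dag1_data_small():
    """One N=2000 dag1 panel shared by read-only tests."""
    return sim.generate(sim.dag1_config(n_subjects=2000), seed=101)


@pytest.fixture(scope="session")
def dag1_truth(spec5):
    """Monte-Carlo truth for the default dag1 mechanism (shared)."""
    return sim.true_params(sim.dag1_config(), spec5, n_mc=1_500_000, seed=77)


def toy_panel(Y, R, D, sex=None, **kw):
    """Small hand-built panel; sex defaults to zeros."""
    Y = np.asarray(Y, dtype=float)
    n = Y.shape[0]
    cov = pd.DataFrame({"sex": np.zeros(n) if sex is None else np.asarray(sex, float)})
    return PanelData(Y=np.where(np.asarray(R) == 1, Y, np.nan), R=np.asarray(R),
                     D=np.asarray(D), covariates=cov, z_cols=["sex"], **kw)
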