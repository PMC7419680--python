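import numpy as np
import pandas as pd
import pytest

from tnbcstrat.cohort import SimulationConfig, simulate_cohort
from tnbcstrat.matrix import ExpressionMatrix


def make_matrix(values, genes=None, samples=None) -> ExpressionMatrix:
    arr = np.asarray(values, dtype=float)
    genes = genes or [f"G{i:03d}" for i in range(arr.shape[0])]
    samples = samples or [f"S{i:03d}" for i in range(arr.shape[1])]
    return ExpressionMatrix(pd.DataFrame(arr, index=genes, columns=samples))


@pytest.fixture(scope="session")
def default_cohort():
    """One mid-size ground-truth cohort shared across module tests."""
    cfg = SimulationConfig(n_samples=200, seed=11)
    matrix, truth, sets, ref = simulate_cohort(cfg)
    return {"cfg": cfg, "matrix": matrix, "truth": truth, "sets": sets, "ref": ref}
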