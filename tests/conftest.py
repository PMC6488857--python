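import numpy as np
import pandas as pd
import pytest

from lncnet.array_io import ExpressionMatrix
from lncnet.synthetic_data import SimConfig, generate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """One seeded default dataset shared across tests (read-only)."""
    return generate_dataset(SimConfig(seed=7))


@pytest.fixture()
def toy_matrix():
    """3-probe x 4-sample linear-scale matrix with 2 vs 2 groups."""
    values = pd.DataFrame(
        [[4.0, 8.0, 16.0, 32.0], [2.0, 2.0, 2.0, 2.0], [10.0, 12.0, 5.0, 6.0]],
        index=["P1", "P2", "P3"],
        columns=["c1", "c2", "t1", "t2"],
    )
    groups = {"c1": "control", "c2": "control", "t1": "treated", "t2": "treated"}
    return ExpressionMatrix(values=values, groups=groups, scale="linear")


def make_matrix(values, n_control, n_treated, scale="log2", prefix="P"):
    """Build an ExpressionMatrix from a 2-D array with balanced-ish groups."""
    values = np.asarray(values, dtype=float)
    samples = [f"c{i}" for i in range(n_control)] + [f"t{i}" for i in range(n_treated)]
    groups = {s: ("control" if s.startswith("c") else "treated") for s in samples}
    df = pd.DataFrame(values, index=[f"{prefix}{i}" for i in range(values.shape[0])], columns=samples)
    return ExpressionMatrix(values=df, groups=groups, scale=scale)
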