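import numpy as np
import pandas as pd
import pytest

from hkmlearn.binarizer import BinarizedDataset, binarize
from hkmlearn.formula_core import HKMConstraints
from hkmlearn.simplifier import build_catalog
from hkmlearn.synthetic import default_planted_spec, generate_planted


@pytest.fixture(scope="session")
def catalog():
    """Default-constraints simplification catalog (cached at module level too)."""
    return build_catalog(HKMConstraints())


@pytest.fixture(scope="session")
def planted_noiseless():
    """Noise-free planted-rule dataset, no missing cells: (a AND b) OR c."""
    spec = default_planted_spec(seed=11, n_obs=600, noise=0.0, missing_rate=0.0)
    df = generate_planted(spec)
    return spec, binarize(df, "y", k=2)


def random_bool_dataset(seed: int, n_rows: int = 80, n_atoms: int = 10):
    """Random Boolean atoms with a noisily planted 3-atom rule as target."""
    rng = np.random.default_rng(seed)
    X = rng.random((n_rows, n_atoms)) < rng.uniform(0.2, 0.8, size=n_atoms)
    y = (X[:, 0] & X[:, 1 % n_atoms]) | X[:, 2 % n_atoms]
    y = y ^ (rng.random(n_rows) < 0.15)
    if y.all() or not y.any():  # keep both classes
        y[0] = ~y[0]
    df = pd.DataFrame({f"a{j}": X[:, j].astype(int) for j in range(n_atoms)})
    df["y"] = y.astype(int)
    return binarize(df, "y")
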