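import numpy as np
import pandas as pd
import pytest

from qsarforge.dataio import DescriptorTable, QsarDataset, load_fixture
from qsarforge.linear_model import paper_model
from qsarforge.synthetic import SyntheticSpec, generate_dataset


@pytest.fixture(scope="session")
def table4():
    return load_fixture("table4")


@pytest.fixture(scope="session")
def table5():
    return load_fixture("table5")


@pytest.fixture(scope="session")
def table10():
    return load_fixture("table10")


@pytest.fixture(scope="session")
def published_model():
    return paper_model()


@pytest.fixture()
def small_dataset():
    """Tiny clean dataset: 8 compounds, 3 descriptors, exact linear activity."""
    rng = np.random.default_rng(42)
    X = rng.standard_normal((8, 3))
    y = 4.0 + X @ np.array([1.0, -0.5, 2.0])
    ids = [str(i) for i in range(1, 9)]
    table = DescriptorTable(pd.DataFrame(X, index=ids, columns=["a", "b", "c"]))
    return QsarDataset(table, pd.Series(y, index=ids, name="pIC50"))


@pytest.fixture()
def noisy_dataset():
    ds, truth = generate_dataset(
        SyntheticSpec(n_compounds=40, n_descriptors=10, n_informative=3, seed=7)
    )
    return ds, truth
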