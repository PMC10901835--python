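import numpy as np
import pandas as pd
import pytest

from tempro.io import ExpressionMatrix
from tempro.simulate import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A small coupled dataset shared by read-only tests."""
    return simulate_dataset(SimConfig(n_genes=400, protein_fraction=0.3, seed=7))


@pytest.fixture(scope="session")
def criterion_dataset():
    """The recovery-test configuration: 2000 genes, 200 planted responders."""
    return simulate_dataset(SimConfig(n_genes=2000, protein_fraction=0.3, seed=1))


@pytest.fixture
def toy_counts():
    """3 genes x 2 samples of hand-checkable counts."""
    return ExpressionMatrix(
        pd.DataFrame(
            [[10.0, 20.0], [30.0, 40.0], [60.0, 140.0]],
            index=pd.Index(["g1", "g2", "g3"], name="feature_id"),
            columns=["s1", "s2"],
        ),
        "mrna",
    )


@pytest.fixture
def protein_matrix():
    """6 proteins x 4 samples exercising every QC filter branch."""
    rng = np.random.default_rng(3)
    vals = pd.DataFrame(
        rng.lognormal(8, 0.3, size=(6, 4)),
        index=pd.Index([f"p{i}" for i in range(6)], name="feature_id"),
        columns=[f"s{i}" for i in range(4)],
    )
    vals.iloc[3, :3] = np.nan        # 75% missing -> excluded
    vals.iloc[4, 0] = np.nan         # 25% missing -> excluded at the 20% bound
    annot = pd.DataFrame(
        {
            "unique_razor_peptides": [5, 1, 4, 6, 3, 2],
            "id_score": [12.0, 11.0, 4.9, 15.0, 9.0, 5.0],
        },
        index=vals.index,
    )
    return ExpressionMatrix(vals, "protein", annot)
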