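import numpy as np
import pandas as pd
import pytest

from drugsig import ExpressionMatrix, GeneratorConfig, SensitivityTable, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A small planted-signal panel shared by read-only tests."""
    cfg = GeneratorConfig(
        n_train=30, n_blind=15, n_genes=150,
        causal_genes=[(0, 1.5), (1, 0.6)], dominant_index=0,
        noise_sd=0.2, seed=7,
    )
    return generate_dataset(cfg)


@pytest.fixture
def tiny_expression():
    """3 genes x 2 samples, hand-checkable."""
    values = pd.DataFrame(
        [[5.5, 6.25], [8.0, 7.5], [10.0, 9.0]],
        index=pd.Index(["PTGR1", "GAPDH", "TP53"], name="gene"),
        columns=["CELL1", "CELL2"],
    )
    return ExpressionMatrix(values)


@pytest.fixture
def tiny_sensitivity():
    table = pd.DataFrame(
        {
            "ic50_molar": [1e-7, 3.2e-6, 14.3e-9],
            "tumor_type": ["ovarian", "lung", "colon"],
            "lineage": ["solid", "solid", "solid"],
        },
        index=pd.Index(["CELL1", "CELL2", "CELL3"], name="name"),
    )
    return SensitivityTable(table)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
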