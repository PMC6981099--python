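import numpy as np
import pandas as pd
import pytest

from cernascreen import (
    ExpressionDataset,
    PipelineConfig,
    SyntheticConfig,
    generate_dataset,
)


@pytest.fixture(scope="session")
def default_bundle():
    """Default synthetic bundle: 200/20/50 features, 8 vs 8, 5 planted triplets."""
    return generate_dataset(SyntheticConfig(seed=0))


@pytest.fixture(scope="session")
def null_bundle():
    """No planted triplets, no planted DE: pure-noise negative control."""
    return generate_dataset(
        SyntheticConfig(seed=100, n_planted_triplets=0, fraction_de=0.0)
    )


@pytest.fixture(scope="session")
def small_bundle():
    """Scaled-down bundle for fast end-to-end runs."""
    return generate_dataset(
        SyntheticConfig(seed=11, n_mrna=40, n_mirna=8, n_lncrna=15,
                        n_planted_triplets=3, n_decoy_interactions=40,
                        n_random_terms=10)
    )


@pytest.fixture
def tiny_dataset():
    """Hand-built 4-feature x 8-sample dataset."""
    rng = np.random.default_rng(1)
    vals = rng.uniform(1.0, 50.0, size=(4, 8))
    norm = pd.DataFrame(vals, index=["mRNA_A", "mRNA_B", "miR_x", "lnc_L"],
                        columns=[f"s{i}" for i in range(8)])
    counts = pd.DataFrame((vals * 10).astype(np.int64), index=norm.index,
                          columns=norm.columns)
    return ExpressionDataset(
        normalized=norm,
        feature_class=pd.Series(["mRNA", "mRNA", "miRNA", "lncRNA"],
                                index=norm.index),
        condition=pd.Series(["disease"] * 4 + ["normal"] * 4,
                            index=norm.columns),
        counts=counts,
    )


@pytest.fixture
def fast_config():
    return PipelineConfig(n_permutations=1000, seed=0, n_baseline_draws=10)
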