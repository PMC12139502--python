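import numpy as np
import pandas as pd
import pytest

from cardatlas import GeneratorConfig, QuantMatrix, generate_atlas, make_design


@pytest.fixture(scope="session")
def default_atlas():
    """The study-condition atlas: 2000 genes, marker_fold 4, noise_cv 0.1, seed 42."""
    return generate_atlas(GeneratorConfig(seed=42))


@pytest.fixture(scope="session")
def tight_coupling_atlas():
    """Recovery scenario for the intercept procedure: tight protein-RNA coupling
    and no dropout, so the planted +-3 log2 offsets are the only discordance."""
    return generate_atlas(
        GeneratorConfig(seed=42, rna_coupling=0.99, baseline_log_sd=1.0, detection_quantile=0.0)
    )


def toy_matrix(values, samples, groups, scale="FOT", features=None):
    values = np.asarray(values, dtype=float)
    features = features or [f"g{i}" for i in range(values.shape[0])]
    df = pd.DataFrame(values, index=pd.Index(features, name="feature"), columns=samples)
    design = make_design(samples, groups)
    return QuantMatrix(df, scale, design)


@pytest.fixture
def four_celltype_matrix():
    """One sample per cell-type, convenient for hand-arithmetic rule checks."""

    def _make(rows, features=None, scale="FOT"):
        return toy_matrix(
            rows, samples=["CM_1", "CF_1", "EC_1", "IM_1"],
            groups=["CM", "CF", "EC", "IM"], scale=scale, features=features,
        )

    return _make
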