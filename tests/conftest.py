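import numpy as np
import pandas as pd
import pytest

from svrdeconv import (
    DeconvolutionConfig,
    SyntheticPanelSpec,
    generate_synthetic_panel,
)


@pytest.fixture(scope="session")
def default_panel():
    """The default synthetic 25-type panel: (signature, reference, labels, hierarchy)."""
    return generate_synthetic_panel(SyntheticPanelSpec(seed=0))


@pytest.fixture(scope="session")
def small_panel():
    """A fast 5-type panel for plumbing tests."""
    spec = SyntheticPanelSpec(
        n_cell_types=5, markers_per_type=8, shared_marker_fraction=0.25, seed=7
    )
    return generate_synthetic_panel(spec)


@pytest.fixture(scope="session")
def sim_config():
    """Engine config for simulated mixtures (already on the signature's scale)."""
    return DeconvolutionConfig(quantile_normalize_input=False)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture()
def toy_expression():
    """A tiny 4-gene, 3-sample linear-scale table."""
    from svrdeconv import ExpressionMatrix

    data = pd.DataFrame(
        {
            "s1": [1.0, 5.0, 3.0, 7.0],
            "s2": [2.0, 6.0, 4.0, 8.0],
            "s3": [0.5, 4.0, 2.0, 6.0],
        },
        index=pd.Index(["g1", "g2", "g3", "g4"], name="gene"),
    )
    return ExpressionMatrix(data, scale="linear")
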