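import numpy as np
import pandas as pd
import pytest

from gmsubtype import (
    BCCP,
    HumanSimConfig,
    MouseSimConfig,
    OrthologMap,
    derive_signature,
    simulate_cohort,
    simulate_mouse,
    zscore_genes,
)


@pytest.fixture(scope="session")
def mouse_default():
    """Default mouse experiment: 5000 genes, 3 x 6 samples, effect 2.0 SD."""
    return simulate_mouse(MouseSimConfig(seed=11))


@pytest.fixture(scope="session")
def mouse_signature(mouse_default):
    expr, labels, _ = mouse_default
    sig, venn = derive_signature(expr, labels)
    return sig, venn


@pytest.fixture(scope="session")
def fitted_model(mouse_default, mouse_signature):
    expr, labels, _ = mouse_default
    sig, _ = mouse_signature
    return BCCP(zscore_genes(expr), labels, sig).fit()


@pytest.fixture(scope="session")
def ortholog_map_default(mouse_default):
    """Identity-style mouse -> synthetic-human symbol map for all mouse genes."""
    expr, _, _ = mouse_default
    return OrthologMap(
        pd.DataFrame({"a": expr.gene_ids, "b": ["H" + g.upper() for g in expr.gene_ids]})
    )


@pytest.fixture(scope="session")
def cohort_default(mouse_default):
    """Default human cohort tied to the true overlap genes (human symbols)."""
    _, _, truth = mouse_default
    sig_h = sorted("H" + g.upper() for g in truth.overlap)
    return simulate_cohort(HumanSimConfig(seed=21), sig_h)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
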