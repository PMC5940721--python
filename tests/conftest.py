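import warnings

import numpy as np
import pandas as pd
import pytest

from dioxmark.panel import MATRICES, default_panel
from dioxmark.simulate import BlockSpec, generate_dataset, study_blockspec


def make_blockspec(
    blocks: dict[str, list[str]],
    rho_within: float = 0.9,
    rho_between: float = 0.1,
    log_iqr_factor: float = 2.0,
    detect_target: float = 1.0,
) -> BlockSpec:
    """Uniform-marginal block spec over the given congener partition."""
    ids = [c for members in blocks.values() for c in members]
    cols = list(MATRICES)
    return BlockSpec(
        blocks=blocks,
        rho_within=rho_within,
        rho_between=rho_between,
        log_median=pd.DataFrame(0.0, index=ids, columns=cols),
        log_iqr_factor=pd.DataFrame(log_iqr_factor, index=ids, columns=cols),
        detect_target=pd.DataFrame(detect_target, index=ids, columns=cols),
    )


def quiet_generate(panel, n, spec, seed, **kw):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return generate_dataset(panel, n, spec, seed, **kw)


TWO_BLOCK_IDS = {
    "a": ["PCB105", "PCB118", "PCB123", "PCB126"],
    "b": ["PCB156", "PCB157", "PCB167", "PCB169"],
}


@pytest.fixture
def two_block_dataset():
    """41-subject cohort with two planted 4-congener blocks, no censoring."""
    ids = [c for v in TWO_BLOCK_IDS.values() for c in v]
    panel = default_panel().subset(ids)
    spec = make_blockspec(TWO_BLOCK_IDS)
    return quiet_generate(panel, 41, spec, seed=20240101)


@pytest.fixture(scope="session")
def study_dataset():
    """Full 29-congener study-like cohort with empirical LOD placement."""
    return quiet_generate(
        default_panel(), 41, study_blockspec(), seed=7, lod_placement="empirical"
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
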