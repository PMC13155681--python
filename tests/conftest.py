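"""Shared fixtures: small synthetic screens and a tiny trained global model."""

from __future__ import annotations

import numpy as np
import pytest

from pairdose.encoders import CellEncoderConfig, DoseEmbedderConfig, DrugEncoderConfig
from pairdose.global_model import GlobalModelConfig, train_global
from pairdose.synthetic import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """6 drugs x 3 cells x 5x5 grids, default noise."""
    return generate_dataset(SyntheticConfig(n_drugs=6, n_cells=3, seed=42))


@pytest.fixture(scope="session")
def tiny_model(small_dataset):
    """A briefly trained small global model (shared; treat as read-only)."""
    ds = small_dataset
    return train_global(
        ds.combo,
        GlobalModelConfig(epochs=8, patience=8, seed=0),
        ds.drugs,
        ds.cells,
        drug_cfg=DrugEncoderConfig(embedding_dim=16, conv_filters=(16, 32)),
        cell_cfg=CellEncoderConfig(hidden=(32, 16), embedding_dim=8),
        dose_cfg=DoseEmbedderConfig(n_frequencies=8),
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
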