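"""Ready-made experiment configurations.

``synthetic_benchmark_config`` is the package's standard end-to-end study:
a 12-drug x 6-cell-line screen with full 5 x 5 dose-response matrices and
measurement noise sigma = 0.05 on the growth-fraction scale, evaluated under
the matrix-completion (S1) split. The encoder widths are kept lean — the
synthetic screen has far fewer drugs and cell lines than a production
screen, and smaller embeddings both regularize and keep a full
cross-validated run cheap on one CPU. ``smoke_config`` is a minutes-scale
configuration for pipeline checks.
"""

from __future__ import annotations

from .encoders import CellEncoderConfig, DoseEmbedderConfig, DrugEncoderConfig
from .evaluation import ExperimentConfig
from .global_model import GlobalModelConfig
from .local_model import LocalGCNConfig
from .synthetic import SyntheticConfig

__all__ = ["synthetic_benchmark_config", "smoke_config"]


def synthetic_benchmark_config(
    seed: int,
    scenario: str = "S1",
    variants: tuple[str, ...] = ("full", "global_only", "local_only"),
) -> ExperimentConfig:
    """Standard synthetic benchmark: 12 drugs, 6 cell lines, 5x5 grids."""
    return ExperimentConfig(
        scenario=scenario,
        n_folds=5,
        folds_to_run=1,
        fraction=0.2,
        seed=seed,
        variants=variants,
        synthetic=SyntheticConfig(n_drugs=12, n_cells=6, n_doses=5, noise_sd=0.05),
        global_cfg=GlobalModelConfig(epochs=40, patience=8),
        local_cfg=LocalGCNConfig(epochs=150, hidden=16),
        drug_cfg=DrugEncoderConfig(embedding_dim=16, conv_filters=(16, 32)),
        cell_cfg=CellEncoderConfig(hidden=(32, 16), embedding_dim=8),
        dose_cfg=DoseEmbedderConfig(n_frequencies=8),
    )


def smoke_config(seed: int = 0) -> ExperimentConfig:
    """Small, fast pipeline check: 6 drugs, 3 cell lines, one fold."""
    return ExperimentConfig(
        scenario="S1",
        n_folds=5,
        folds_to_run=1,
        seed=seed,
        variants=("full", "global_only", "local_only"),
        synthetic=SyntheticConfig(n_drugs=6, n_cells=3),
        global_cfg=GlobalModelConfig(epochs=15, patience=5),
        local_cfg=LocalGCNConfig(epochs=100, hidden=16),
        drug_cfg=DrugEncoderConfig(embedding_dim=16, conv_filters=(16, 32)),
        cell_cfg=CellEncoderConfig(hidden=(32, 16), embedding_dim=8),
        dose_cfg=DoseEmbedderConfig(n_frequencies=8),
    )
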