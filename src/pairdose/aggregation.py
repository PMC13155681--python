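"""Aggregation of the global and local predictions.

A small learnable MLP fuses the two base predictions into the final synergy
value. Beyond the two raw predictions, the default input also carries the
local-availability flag and log(1 + k) (k = number of retrieved neighbors),
so one network can modulate how much it trusts the local path. Whatever the
mode, a query whose local path is unavailable receives the global
prediction bit-exactly — the method degenerates to the global model in
data-scarce settings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io_types import ValidationError
from .nn import MLP, Adam, Tensor

logger = logging.getLogger(__name__)

__all__ = [
    "PredictionPair",
    "AggregatorConfig",
    "Aggregator",
    "aggregate_predictions",
    "train_aggregator",
]


@dataclass(frozen=True)
class PredictionPair:
    """(global, local) predictions for one query."""

    global_pred: float
    local_pred: float | None
    local_available: bool
    local_source: str = ""
    k: int = 0

    def __post_init__(self):
        if self.local_available != (self.local_pred is not None):
            raise ValidationError("local_pred must be present iff local_available")


@dataclass(frozen=True)
class AggregatorConfig:
    mode: str = "learned-mlp"  # learned-mlp | fixed-average | global-only
    hidden: tuple[int, ...] = (16, 16)
    extra_inputs: bool = True  # availability flag and log(1+k) as inputs
    learning_rate: float = 1e-2
    epochs: int = 400
    seed: int = 0

    def __post_init__(self):
        if self.mode not in ("learned-mlp", "fixed-average", "global-only"):
            raise ValidationError(f"unknown aggregator mode {self.mode!r}")


class Aggregator:
    """Trained (or fixed) fusion of global and local predictions."""

    def __init__(self, cfg: AggregatorConfig, mlp: MLP | None = None):
        self.cfg = cfg
        self.mlp = mlp

    def _features(self, pairs: Sequence[PredictionPair]) -> np.ndarray:
        rows = []
        for p in pairs:
            row = [p.global_pred, p.local_pred if p.local_available else 0.0]
            if self.cfg.extra_inputs:
                row += [float(p.local_available), np.log1p(p.k)]
            rows.append(row)
        return np.asarray(rows, dtype=np.float64)

    def predict(self, pair: PredictionPair) -> float:
        if not pair.local_available or self.cfg.mode == "global-only":
            return pair.global_pred  # exact degeneration to the global model
        if self.cfg.mode == "fixed-average":
            return (pair.global_pred + pair.local_pred) / 2.0
        if self.mlp is None:  # untrained learned aggregator: identity on global
            return pair.global_pred
        return float(self.mlp(Tensor(self._features([pair]))).data[0, 0])

    def predict_many(self, pairs: Sequence[PredictionPair]) -> np.ndarray:
        return np.array([self.predict(p) for p in pairs])


def aggregate_predictions(
    pair: PredictionPair, model: Aggregator, cfg: AggregatorConfig | None = None
) -> float:
    if cfg is not None and cfg is not model.cfg:
        model = Aggregator(cfg, model.mlp)
    return model.predict(pair)


def train_aggregator(
    pairs: Sequence[PredictionPair],
    responses: Sequence[float],
    cfg: AggregatorConfig,
) -> Aggregator:
    """Fit the fusion MLP by MSE on (prediction pair, true response) data.

    Training pairs should come from data held out from global-model training
    (out-of-fold predictions), so the aggregator sees honestly calibrated
    inputs. If no pair has an available local prediction there is nothing to
    learn and the identity-on-global aggregator is returned with a warning.
    """
    if cfg.mode in ("fixed-average", "global-only"):
        return Aggregator(cfg)
    usable = [(p, y) for p, y in zip(pairs, responses) if p.local_available]
    if not usable:
        logger.warning(
            "no training pair has an available local prediction; "
            "returning the identity-on-global aggregator"
        )
        return Aggregator(cfg)
    agg = Aggregator(cfg)
    x = agg._features([p for p, _ in usable])
    y = np.array([t for _, t in usable], dtype=np.float64)
    rng = np.random.default_rng(cfg.seed)
    mlp = MLP([x.shape[1], *cfg.hidden, 1], rng)
    opt = Adam(mlp.params(), lr=cfg.learning_rate)
    xt = Tensor(x)
    yt = Tensor(y[:, None])
    for _ in range(cfg.epochs):
        loss = (mlp(xt) - yt).square().mean()
        opt.zero_grad()
        loss.backward()
        opt.step()
    agg.mlp = mlp
    return agg
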