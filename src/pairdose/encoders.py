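"""Feature encoders for drugs, doses and cell lines.

Three subnetworks produce the joint representation of one combination
measurement:

* **Drug encoder** — a character-level 1-D CNN over the SMILES string: token
  embedding, stacked convolutions with ReLU, masked global max-pooling and a
  linear projection. One encoder is shared by both drugs of a pair.
* **Dose embedder** — a fixed (non-learnable) sinusoidal feature map: a dose
  ``d`` becomes ``[sin(2*pi*f1*d), cos(2*pi*f1*d), ..., sin(2*pi*fc*d),
  cos(2*pi*fc*d)]`` with frequencies log-spaced between ``f_min`` and
  ``f_max``. By default the raw concentration is first mapped into [0, 1]
  by a log-min-max transform over the training dose range, so micromolar
  magnitudes do not alias the high-frequency components.
* **Cell-line encoder** — a three-layer ReLU MLP over the expression vector
  (the screening convention keeps the 78 highest-variance genes, but the
  length is data-driven).

The joint feature of a sample is the fixed-order concatenation
``[drug1, drug2, dose1, dose2, cell]``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .io_types import ValidationError
from .nn import MLP, Conv1d, Embedding, Linear, Tensor

__all__ = [
    "SmilesVocabulary",
    "tokenize_smiles",
    "DoseEmbedderConfig",
    "embed_dose",
    "DrugEncoderConfig",
    "DrugEncoder",
    "CellEncoderConfig",
    "CellEncoder",
    "build_joint_feature",
]

PAD = 0
UNK = 1


@dataclass(frozen=True)
class SmilesVocabulary:
    """Character → index map with reserved PAD (0) and UNK (1) slots."""

    symbols: tuple[str, ...]
    max_length: int = 128

    def __post_init__(self):
        if len(set(self.symbols)) != len(self.symbols):
            raise ValidationError("duplicate symbols in vocabulary")
        if self.max_length < 1:
            raise ValidationError("max_length must be positive")

    @classmethod
    def from_smiles(cls, smiles: Iterable[str], max_length: int = 128) -> "SmilesVocabulary":
        chars = sorted({ch for s in smiles for ch in s})
        return cls(tuple(chars), max_length)

    @property
    def index(self) -> dict[str, int]:
        return {ch: i + 2 for i, ch in enumerate(self.symbols)}

    @property
    def size(self) -> int:
        return len(self.symbols) + 2

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({"symbols": list(self.symbols), "max_length": self.max_length})
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "SmilesVocabulary":
        d = json.loads(Path(path).read_text())
        return cls(tuple(d["symbols"]), int(d["max_length"]))


def tokenize_smiles(smiles: str, vocab: SmilesVocabulary) -> np.ndarray:
    """Character indices, right-padded with PAD and truncated at max_length."""
    if not smiles:
        raise ValidationError("empty SMILES string")
    index = vocab.index
    ids = [index.get(ch, UNK) for ch in smiles[: vocab.max_length]]
    out = np.full(vocab.max_length, PAD, dtype=np.int64)
    out[: len(ids)] = ids
    return out


# ---------------------------------------------------------------------------
# Dose embedding


@dataclass(frozen=True)
class DoseEmbedderConfig:
    """Sinusoidal dose feature map.

    ``n_frequencies`` sine/cosine pairs with frequencies log-spaced on
    [f_min, f_max]; output dimension is ``2 * n_frequencies``. The defaults
    (16 frequencies on [0.1, 50]) let the slowest wave span a unit dose range
    while the fastest resolves ~1% dose differences. ``transform`` maps the
    raw concentration to the embedded value: ``log-min-max`` (default)
    rescales log-dose into [0, 1] using ``dose_min``/``dose_max`` fitted from
    the training doses; ``identity`` embeds the raw value. ``raw`` disables
    the sinusoidal map entirely and returns the 1-D transformed dose (the
    ablation that replaces the embedding with raw normalized dose values).
    """

    n_frequencies: int = 16
    f_min: float = 0.1
    f_max: float = 50.0
    transform: str = "log-min-max"
    dose_min: float | None = None
    dose_max: float | None = None
    mode: str = "sinusoidal"

    def __post_init__(self):
        if self.n_frequencies < 1:
            raise ValidationError("n_frequencies must be positive")
        if not (0 < self.f_min < self.f_max):
            raise ValidationError("need 0 < f_min < f_max")
        if self.transform not in ("identity", "log-min-max"):
            raise ValidationError(f"unknown transform {self.transform!r}")
        if self.mode not in ("sinusoidal", "raw"):
            raise ValidationError(f"unknown mode {self.mode!r}")

    @property
    def frequencies(self) -> np.ndarray:
        return np.geomspace(self.f_min, self.f_max, self.n_frequencies)

    @property
    def output_dim(self) -> int:
        return 1 if self.mode == "raw" else 2 * self.n_frequencies

    def fit(self, doses: Sequence[float]) -> "DoseEmbedderConfig":
        """Record the training dose range used by the log-min-max transform."""
        d = np.asarray(doses, dtype=np.float64)
        if (d <= 0).any():
            raise ValidationError("doses must be positive to fit a log range")
        lo, hi = float(d.min()), float(d.max())
        if lo == hi:
            hi = lo * 10.0  # degenerate single-dose range: one decade
        return replace(self, dose_min=lo, dose_max=hi)

    def transform_dose(self, dose) -> np.ndarray:
        d = np.asarray(dose, dtype=np.float64)
        if self.transform == "identity":
            if not np.all(np.isfinite(d)):
                raise ValidationError("dose must be finite")
            return d
        if np.any(d <= 0):
            raise ValidationError("dose must be positive under the log transform")
        if self.dose_min is None or self.dose_max is None:
            raise ValidationError(
                "log-min-max transform requires a fitted dose range; call .fit()"
            )
        lo, hi = np.log(self.dose_min), np.log(self.dose_max)
        return np.clip((np.log(d) - lo) / (hi - lo), 0.0, 1.0)


def embed_dose(dose, cfg: DoseEmbedderConfig) -> np.ndarray:
    """Sinusoidal embedding of one dose (or an array of doses).

    Scalar input yields a vector of length ``cfg.output_dim``; an array of
    shape (n,) yields (n, output_dim). In sinusoidal mode the pairs are
    interleaved as [sin f1, cos f1, ..., sin fc, cos fc].
    """
    d = cfg.transform_dose(dose)
    scalar = d.ndim == 0
    d = np.atleast_1d(d)
    if cfg.mode == "raw":
        out = d[:, None]
    else:
        phase = 2.0 * np.pi * d[:, None] * cfg.frequencies[None, :]
        out = np.empty((d.shape[0], 2 * cfg.n_frequencies))
        out[:, 0::2] = np.sin(phase)
        out[:, 1::2] = np.cos(phase)
    return out[0] if scalar else out


# ---------------------------------------------------------------------------
# Drug encoder (1D-CNN over SMILES characters)


@dataclass(frozen=True)
class DrugEncoderConfig:
    char_dim: int = 16
    conv_filters: tuple[int, ...] = (32, 64)
    kernel_sizes: tuple[int, ...] = (5, 5)
    embedding_dim: int = 64
    max_length: int = 128

    def __post_init__(self):
        if len(self.conv_filters) != len(self.kernel_sizes):
            raise ValidationError("conv_filters and kernel_sizes must align")
        if min((self.char_dim, self.embedding_dim, *self.conv_filters)) < 1:
            raise ValidationError("all encoder sizes must be positive")


class DrugEncoder:
    """Character CNN: embedding → conv+ReLU stack → masked max-pool → linear.

    The PAD embedding row is pinned to zero and pooling is masked to the real
    token span, so the output does not depend on how much trailing padding a
    tokenized string carries.
    """

    def __init__(self, cfg: DrugEncoderConfig, vocab: SmilesVocabulary, rng: np.random.Generator):
        self.cfg = cfg
        self.vocab = vocab
        self.embedding = Embedding(vocab.size, cfg.char_dim, rng, pad_index=PAD)
        self.convs = []
        n_in = cfg.char_dim
        for f, k in zip(cfg.conv_filters, cfg.kernel_sizes):
            self.convs.append(Conv1d(n_in, f, k, rng))
            n_in = f
        self.project = Linear(n_in, cfg.embedding_dim, rng)

    def forward(self, tokens: np.ndarray) -> Tensor:
        """Encode a (batch, length) int array to a (batch, embedding_dim) Tensor."""
        tokens = np.atleast_2d(np.asarray(tokens))
        x = self.embedding(tokens)
        for conv in self.convs:
            x = conv(x).relu()
        real = tokens != PAD
        # rows with no real token fall back to pooling everywhere (zero inputs)
        empty = ~real.any(axis=1)
        mask = real | empty[:, None]
        penalty = Tensor(np.where(mask, 0.0, -1e30)[:, :, None])
        pooled = (x + penalty).max(axis=1)
        return self.project(pooled)

    def encode(self, tokens: np.ndarray) -> np.ndarray:
        """Inference-mode encoding; 1-D token input yields a 1-D vector."""
        single = np.asarray(tokens).ndim == 1
        out = self.forward(tokens).data
        return out[0] if single else out

    def params(self) -> list[Tensor]:
        return (
            self.embedding.params()
            + [p for c in self.convs for p in c.params()]
            + self.project.params()
        )

    def pin_pad_row(self) -> None:
        self.embedding.pin_pad_row()


def encode_drug(tokens: np.ndarray, encoder: DrugEncoder) -> np.ndarray:
    return encoder.encode(tokens)


# ---------------------------------------------------------------------------
# Cell-line encoder


@dataclass(frozen=True)
class CellEncoderConfig:
    """Exactly three affine layers (widths hidden1 → hidden2 → output)."""

    hidden: tuple[int, int] = (128, 64)
    embedding_dim: int = 32
    final_activation: str = "relu"

    def __post_init__(self):
        if len(self.hidden) != 2:
            raise ValidationError("cell encoder is fixed at three affine layers")
        if min((*self.hidden, self.embedding_dim)) < 1:
            raise ValidationError("widths must be positive")


class CellEncoder:
    def __init__(self, cfg: CellEncoderConfig, n_genes: int, rng: np.random.Generator):
        self.cfg = cfg
        self.n_genes = n_genes
        self.mlp = MLP(
            [n_genes, *cfg.hidden, cfg.embedding_dim], rng,
            final_activation=cfg.final_activation,
        )

    def forward(self, profiles: np.ndarray | Tensor) -> Tensor:
        x = profiles if isinstance(profiles, Tensor) else Tensor(np.atleast_2d(profiles))
        if x.shape[-1] != self.n_genes:
            raise ValidationError(
                f"profile length {x.shape[-1]} != encoder input {self.n_genes}"
            )
        return self.mlp(x)

    def encode(self, profile: np.ndarray) -> np.ndarray:
        single = np.asarray(profile).ndim == 1
        out = self.forward(profile).data
        return out[0] if single else out

    def params(self) -> list[Tensor]:
        return self.mlp.params()


def encode_cell_line(profile: np.ndarray, encoder: CellEncoder) -> np.ndarray:
    return encoder.encode(profile)


def build_joint_feature(
    d1: np.ndarray, d2: np.ndarray, r1: np.ndarray, r2: np.ndarray, cell: np.ndarray
) -> np.ndarray:
    """Concatenate the five embeddings in fixed order [d1, d2, r1, r2, cell]."""
    parts = [np.asarray(p, dtype=np.float64) for p in (d1, d2, r1, r2, cell)]
    for p in parts:
        if not np.all(np.isfinite(p)):
            raise ValidationError("non-finite embedding entry")
    return np.concatenate(parts, axis=-1)
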