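"""The global synergy predictor.

One network trained end-to-end on every available combination measurement:
the two drug embeddings (shared CNN), the two dose embeddings (shared
sinusoidal map) and the cell-line embedding are concatenated and fed to an
MLP head that regresses the response. Training minimizes the mean squared
error between the head's output and the measured response, with Adam, an
optional pair-swap augmentation (synergy is symmetric in the two drugs), and
early stopping on a held-out slice of the training data.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .encoders import (
    CellEncoder,
    CellEncoderConfig,
    DoseEmbedderConfig,
    DrugEncoder,
    DrugEncoderConfig,
    SmilesVocabulary,
    build_joint_feature,
    embed_dose,
    tokenize_smiles,
)
from .io_types import CellLineProfile, ComboSample, DrugRecord, ValidationError
from .nn import MLP, Adam, Tensor, concatenate

__all__ = ["GlobalModelConfig", "TrainedGlobalModel", "train_global", "predict_global"]


@dataclass(frozen=True)
class GlobalModelConfig:
    head_hidden: tuple[int, ...] = (128, 64)
    learning_rate: float = 1e-3
    batch_size: int = 256
    epochs: int = 300
    patience: int = 20
    val_fraction: float = 0.1
    pair_swap_augment: bool = True
    seed: int = 0

    def __post_init__(self):
        if not (1e-5 <= self.learning_rate <= 1e-1):
            raise ValidationError(
                f"global learning rate {self.learning_rate} outside [1e-5, 1e-1]"
            )
        if min(self.batch_size, self.epochs, self.patience) < 1:
            raise ValidationError("batch size, epochs and patience must be positive")


class TrainedGlobalModel:
    """Frozen encoders + head, with id-indexed drug/cell libraries attached."""

    def __init__(
        self,
        vocab: SmilesVocabulary,
        drug_encoder: DrugEncoder,
        cell_encoder: CellEncoder,
        dose_cfg: DoseEmbedderConfig,
        head: MLP,
        drug_tokens: dict[str, np.ndarray],
        cell_profiles: dict[str, np.ndarray],
        training_log: list[dict] | None = None,
    ):
        self.vocab = vocab
        self.drug_encoder = drug_encoder
        self.cell_encoder = cell_encoder
        self.dose_cfg = dose_cfg
        self.head = head
        self.drug_tokens = drug_tokens
        self.cell_profiles = cell_profiles
        self.training_log = training_log or []
        self._drug_ids = list(drug_tokens)
        self._cell_ids = list(cell_profiles)
        self._drug_index = {d: i for i, d in enumerate(self._drug_ids)}
        self._cell_index = {c: i for i, c in enumerate(self._cell_ids)}
        self._token_matrix = np.stack([drug_tokens[d] for d in self._drug_ids])
        self._profile_matrix = np.stack([cell_profiles[c] for c in self._cell_ids])
        self._frozen: tuple[np.ndarray, np.ndarray] | None = None

    # -- lookup helpers ------------------------------------------------------
    def _indices(self, samples: Sequence[ComboSample]) -> tuple[np.ndarray, ...]:
        try:
            i1 = np.array([self._drug_index[s.drug1_id] for s in samples])
        except KeyError as exc:
            raise LookupError(f"unknown drug_id {exc.args[0]!r}") from exc
        try:
            i2 = np.array([self._drug_index[s.drug2_id] for s in samples])
        except KeyError as exc:
            raise LookupError(f"unknown drug_id {exc.args[0]!r}") from exc
        try:
            ic = np.array([self._cell_index[s.cell_id] for s in samples])
        except KeyError as exc:
            raise LookupError(f"unknown cell_id {exc.args[0]!r}") from exc
        return i1, i2, ic

    def _forward(self, samples: Sequence[ComboSample]) -> Tensor:
        i1, i2, ic = self._indices(samples)
        drug_emb = self.drug_encoder.forward(self._token_matrix)
        cell_emb = self.cell_encoder.forward(self._profile_matrix)
        r1 = embed_dose(np.array([s.dose1 for s in samples]), self.dose_cfg)
        r2 = embed_dose(np.array([s.dose2 for s in samples]), self.dose_cfg)
        joint = concatenate(
            [
                drug_emb.take_rows(i1),
                drug_emb.take_rows(i2),
                Tensor(r1),
                Tensor(r2),
                cell_emb.take_rows(ic),
            ],
            axis=-1,
        )
        return self.head(joint).reshape(len(samples))

    def predict(self, samples: Sequence[ComboSample]) -> np.ndarray:
        """Response predictions for a batch of samples (no gradients kept)."""
        if not samples:
            return np.empty(0)
        return self._forward(samples).data.copy()

    def joint_features(self, samples: Sequence[ComboSample]) -> np.ndarray:
        """Frozen-encoder joint feature matrix (used by the local model).

        Drug and cell embeddings are cached on first use; call
        :meth:`invalidate_cache` after mutating encoder weights by hand.
        """
        if self._frozen is None:
            self._frozen = (
                self.drug_encoder.forward(self._token_matrix).data,
                self.cell_encoder.forward(self._profile_matrix).data,
            )
        drug_emb, cell_emb = self._frozen
        i1, i2, ic = self._indices(samples)
        r1 = embed_dose(np.array([s.dose1 for s in samples]), self.dose_cfg)
        r2 = embed_dose(np.array([s.dose2 for s in samples]), self.dose_cfg)
        return build_joint_feature(drug_emb[i1], drug_emb[i2], r1, r2, cell_emb[ic])

    def invalidate_cache(self) -> None:
        self._frozen = None

    def params(self) -> list[Tensor]:
        return self.drug_encoder.params() + self.cell_encoder.params() + self.head.params()

    # -- persistence ---------------------------------------------------------
    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.savez(
            directory / "weights.npz",
            **{f"p{i}": p.data for i, p in enumerate(self.params())},
        )
        self.vocab.to_json(directory / "vocab.json")
        meta = {
            "dose_cfg": asdict(self.dose_cfg),
            "drug_cfg": asdict(self.drug_encoder.cfg),
            "cell_cfg": asdict(self.cell_encoder.cfg),
            "n_genes": self.cell_encoder.n_genes,
            "head_sizes": [l.W.shape[0] for l in self.head.layers] + [1],
            "drug_ids": self._drug_ids,
            "cell_ids": self._cell_ids,
        }
        (directory / "model.json").write_text(json.dumps(meta))
        np.savez(directory / "tokens.npz", tokens=self._token_matrix)
        np.savez(directory / "profiles.npz", profiles=self._profile_matrix)
        if self.training_log:
            import pandas as pd

            pd.DataFrame(self.training_log).to_csv(
                directory / "training_log.csv", index=False
            )

    @classmethod
    def load(cls, directory: str | Path) -> "TrainedGlobalModel":
        directory = Path(directory)
        meta = json.loads((directory / "model.json").read_text())
        vocab = SmilesVocabulary.from_json(directory / "vocab.json")
        rng = np.random.default_rng(0)
        drug_encoder = DrugEncoder(DrugEncoderConfig(**meta["drug_cfg"]), vocab, rng)
        cell_encoder = CellEncoder(
            CellEncoderConfig(
                hidden=tuple(meta["cell_cfg"]["hidden"]),
                embedding_dim=meta["cell_cfg"]["embedding_dim"],
                final_activation=meta["cell_cfg"]["final_activation"],
            ),
            meta["n_genes"],
            rng,
        )
        dose_cfg = DoseEmbedderConfig(**meta["dose_cfg"])
        head = MLP(meta["head_sizes"], rng)
        tokens = np.load(directory / "tokens.npz")["tokens"]
        profiles = np.load(directory / "profiles.npz")["profiles"]
        model = cls(
            vocab, drug_encoder, cell_encoder, dose_cfg, head,
            {d: tokens[i] for i, d in enumerate(meta["drug_ids"])},
            {c: profiles[i] for i, c in enumerate(meta["cell_ids"])},
        )
        weights = np.load(directory / "weights.npz")
        for i, p in enumerate(model.params()):
            p.data[...] = weights[f"p{i}"]
        return model


def _build_model(
    drugs: Sequence[DrugRecord],
    cells: dict[str, CellLineProfile],
    dose_cfg: DoseEmbedderConfig,
    drug_cfg: DrugEncoderConfig,
    cell_cfg: CellEncoderConfig,
    head_hidden: tuple[int, ...],
    rng: np.random.Generator,
) -> TrainedGlobalModel:
    longest = max(len(d.smiles) for d in drugs)
    vocab = SmilesVocabulary.from_smiles(
        (d.smiles for d in drugs), max_length=min(drug_cfg.max_length, longest)
    )
    drug_encoder = DrugEncoder(drug_cfg, vocab, rng)
    n_genes = len(next(iter(cells.values())).expression)
    cell_encoder = CellEncoder(cell_cfg, n_genes, rng)
    feat_dim = (
        2 * drug_cfg.embedding_dim + 2 * dose_cfg.output_dim + cell_cfg.embedding_dim
    )
    head = MLP([feat_dim, *head_hidden, 1], rng)
    return TrainedGlobalModel(
        vocab, drug_encoder, cell_encoder, dose_cfg, head,
        {d.drug_id: tokenize_smiles(d.smiles, vocab) for d in drugs},
        {c: p.as_array() for c, p in cells.items()},
    )


def train_global(
    train: Sequence[ComboSample],
    cfg: GlobalModelConfig,
    drugs: Sequence[DrugRecord],
    cells: dict[str, CellLineProfile],
    dose_cfg: DoseEmbedderConfig | None = None,
    drug_cfg: DrugEncoderConfig | None = None,
    cell_cfg: CellEncoderConfig | None = None,
) -> TrainedGlobalModel:
    """Train encoders and head jointly by MSE on the training samples.

    A 10% (``val_fraction``) random slice of the training data is held out
    for early stopping; the weights from the best validation epoch are kept.
    Fully reproducible from ``cfg.seed``.
    """
    if not train:
        raise ValidationError("empty training set")
    dose_cfg = dose_cfg or DoseEmbedderConfig()
    drug_cfg = drug_cfg or DrugEncoderConfig()
    cell_cfg = cell_cfg or CellEncoderConfig()
    if dose_cfg.transform == "log-min-max" and dose_cfg.dose_min is None:
        all_doses = [s.dose1 for s in train] + [s.dose2 for s in train]
        dose_cfg = dose_cfg.fit(all_doses)

    rng = np.random.default_rng(cfg.seed)
    model = _build_model(drugs, cells, dose_cfg, drug_cfg, cell_cfg, cfg.head_hidden, rng)

    order = rng.permutation(len(train))
    n_val = int(round(cfg.val_fraction * len(train)))
    val = [train[i] for i in order[:n_val]]
    fit = [train[i] for i in order[n_val:]] or list(train)
    if cfg.pair_swap_augment:
        fit = fit + [s.swapped() for s in fit]
    y_fit = np.array([s.response for s in fit])
    y_val = np.array([s.response for s in val])

    params = model.params()
    opt = Adam(params, lr=cfg.learning_rate)
    best_val = np.inf
    best_state = [p.data.copy() for p in params]
    bad_epochs = 0
    log: list[dict] = []
    for epoch in range(cfg.epochs):
        perm = rng.permutation(len(fit))
        epoch_loss = 0.0
        for start in range(0, len(fit), cfg.batch_size):
            idx = perm[start : start + cfg.batch_size]
            batch = [fit[i] for i in idx]
            pred = model._forward(batch)
            loss = (pred - Tensor(y_fit[idx])).square().mean()
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}; "
                    "lower the learning rate or check the response scale"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            model.drug_encoder.pin_pad_row()
            epoch_loss += float(loss.data) * len(idx)
        epoch_loss /= len(fit)
        if val:
            val_loss = float(np.mean((model.predict(val) - y_val) ** 2))
        else:
            val_loss = epoch_loss
        log.append({"epoch": epoch, "train_mse": epoch_loss, "val_mse": val_loss})
        if val_loss < best_val - 1e-12:
            best_val = val_loss
            best_state = [p.data.copy() for p in params]
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs >= cfg.patience:
                break
    for p, s in zip(params, best_state):
        p.data[...] = s
    model.training_log = log
    return model


def predict_global(sample: ComboSample, model: TrainedGlobalModel) -> float:
    """Predicted response for one sample (drug/cell ids must be known)."""
    return float(model.predict([sample])[0])
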