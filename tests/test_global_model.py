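"""Global model: forward oracle, MSE loss semantics, training behaviour."""

import numpy as np
import pytest

from pairdose.encoders import (
    CellEncoderConfig,
    DoseEmbedderConfig,
    DrugEncoderConfig,
    embed_dose,
)
from pairdose.global_model import GlobalModelConfig, predict_global, train_global
from pairdose.io_types import CellLineProfile, ComboSample, DrugRecord, ValidationError
from pairdose.synthetic import SyntheticConfig, generate_dataset

TINY_DRUGS = [DrugRecord("A", "CCO"), DrugRecord("B", "CC(=O)O"), DrugRecord("C", "c1ccccc1")]
TINY_CELLS = {
    "c1": CellLineProfile("c1", (0.1, -0.3, 0.5, 0.2, -0.1)),
    "c2": CellLineProfile("c2", (1.0, 0.4, -0.5, 0.0, 0.3)),
}


def tiny_samples(responses):
    doses = [0.01, 0.1, 1.0]
    out = []
    i = 0
    for d1, d2 in (("A", "B"), ("A", "C"), ("B", "C")):
        for c in TINY_CELLS:
            out.append(
                ComboSample(d1, d2, doses[i % 3], doses[(i + 1) % 3], c, responses[i % len(responses)])
            )
            i += 1
    return out


def tiny_cfgs():
    return dict(
        dose_cfg=DoseEmbedderConfig(n_frequencies=2),
        drug_cfg=DrugEncoderConfig(char_dim=3, conv_filters=(4,), kernel_sizes=(3,), embedding_dim=4),
        cell_cfg=CellEncoderConfig(hidden=(6, 5), embedding_dim=3),
    )


class TestPredict:
    def test_deterministic(self, tiny_model, small_dataset):
        s = small_dataset.combo[0]
        assert predict_global(s, tiny_model) == predict_global(s, tiny_model)

    def test_zero_head_returns_bias(self):
        train = tiny_samples([1.0, 2.0])
        model = train_global(train, GlobalModelConfig(epochs=1), TINY_DRUGS, TINY_CELLS, **tiny_cfgs())
        for layer in model.head.layers:
            layer.W.data[...] = 0.0
            layer.b.data[...] = 0.0
        model.head.layers[-1].b.data[...] = 4.25
        preds = model.predict(train)
        assert np.allclose(preds, 4.25)

    def test_unknown_ids_raise(self):
        train = tiny_samples([1.0])
        model = train_global(train, GlobalModelConfig(epochs=1), TINY_DRUGS, TINY_CELLS, **tiny_cfgs())
        with pytest.raises(LookupError, match="ZZZ"):
            model.predict([ComboSample("ZZZ", "B", 1.0, 1.0, "c1", 0.0)])
        with pytest.raises(LookupError, match="nope"):
            model.predict([ComboSample("A", "B", 1.0, 1.0, "nope", 0.0)])

    def test_matches_explicit_forward_oracle(self):
        """Head prediction equals a straight-line numpy recomputation."""
        train = tiny_samples([0.5, -0.5])
        model = train_global(train, GlobalModelConfig(epochs=2), TINY_DRUGS, TINY_CELLS, **tiny_cfgs())
        s = train[0]
        d1 = model.drug_encoder.encode(model.drug_tokens[s.drug1_id])
        d2 = model.drug_encoder.encode(model.drug_tokens[s.drug2_id])
        r1 = embed_dose(s.dose1, model.dose_cfg)
        r2 = embed_dose(s.dose2, model.dose_cfg)
        c = model.cell_encoder.encode(model.cell_profiles[s.cell_id])
        h = np.concatenate([d1, d2, r1, r2, c])
        for layer in model.head.layers[:-1]:
            h = np.maximum(h @ layer.W.data + layer.b.data, 0.0)
        expected = (h @ model.head.layers[-1].W.data + model.head.layers[-1].b.data).item()
        assert abs(predict_global(s, model) - expected) < 1e-8


class TestTraining:
    def test_empty_training_set_rejected(self):
        with pytest.raises(ValidationError):
            train_global([], GlobalModelConfig(), TINY_DRUGS, TINY_CELLS)

    def test_learning_rate_bounds(self):
        with pytest.raises(ValidationError):
            GlobalModelConfig(learning_rate=0.5)
        with pytest.raises(ValidationError):
            GlobalModelConfig(learning_rate=1e-6)

    def test_constant_response_converges_to_constant(self):
        train = tiny_samples([3.0])
        model = train_global(
            train,
            GlobalModelConfig(epochs=300, patience=300, learning_rate=1e-2, val_fraction=0.0),
            TINY_DRUGS, TINY_CELLS, **tiny_cfgs(),
        )
        assert np.allclose(model.predict(train), 3.0, atol=0.05)

    def test_same_seed_identical_training_logs(self):
        ds = generate_dataset(SyntheticConfig(n_drugs=4, n_cells=2, seed=3))
        kw = dict(
            drug_cfg=DrugEncoderConfig(embedding_dim=8, conv_filters=(8,), kernel_sizes=(3,)),
            cell_cfg=CellEncoderConfig(hidden=(8, 8), embedding_dim=4),
            dose_cfg=DoseEmbedderConfig(n_frequencies=4),
        )
        m1 = train_global(ds.combo, GlobalModelConfig(epochs=4, seed=9), ds.drugs, ds.cells, **kw)
        m2 = train_global(ds.combo, GlobalModelConfig(epochs=4, seed=9), ds.drugs, ds.cells, **kw)
        assert m1.training_log == m2.training_log
        assert np.array_equal(m1.predict(ds.combo[:10]), m2.predict(ds.combo[:10]))

    def test_trainer_loss_equals_independent_mse(self):
        """The logged epoch loss is a sample-weighted mean of batch MSEs; check
        the underlying residual computation on a fixed model."""
        train = tiny_samples([0.2, 0.8, -0.4])
        model = train_global(train, GlobalModelConfig(epochs=3), TINY_DRUGS, TINY_CELLS, **tiny_cfgs())
        preds = model.predict(train)
        y = np.array([s.response for s in train])
        independent = float(np.mean((preds - y) ** 2))
        batch = model._forward(train)
        from pairdose.nn import Tensor

        loss = float(((batch - Tensor(y)).square().mean()).data)
        assert abs(loss - independent) < 1e-6

    def test_pair_swap_augmentation_improves_symmetry(self):
        ds = generate_dataset(SyntheticConfig(n_drugs=5, n_cells=2, seed=6))
        kw = dict(
            drug_cfg=DrugEncoderConfig(embedding_dim=8, conv_filters=(8,), kernel_sizes=(3,)),
            cell_cfg=CellEncoderConfig(hidden=(8, 8), embedding_dim=4),
            dose_cfg=DoseEmbedderConfig(n_frequencies=4),
        )
        gaps = {}
        for aug in (True, False):
            diffs = []
            for seed in (0, 1, 2):
                m = train_global(
                    ds.combo,
                    GlobalModelConfig(epochs=10, seed=seed, pair_swap_augment=aug),
                    ds.drugs, ds.cells, **kw,
                )
                test = ds.combo[::7]
                a = m.predict(test)
                b = m.predict([s.swapped() for s in test])
                diffs.append(float(np.mean(np.abs(a - b))))
            gaps[aug] = np.mean(diffs)
        assert gaps[True] < gaps[False]

    def test_save_load_round_trip(self, tmp_path):
        train = tiny_samples([0.3, 0.9])
        model = train_global(train, GlobalModelConfig(epochs=2), TINY_DRUGS, TINY_CELLS, **tiny_cfgs())
        model.save(tmp_path / "m")
        from pairdose.global_model import TrainedGlobalModel

        back = TrainedGlobalModel.load(tmp_path / "m")
        assert np.allclose(back.predict(train), model.predict(train), atol=1e-12)


class TestMemorization:
    def test_overfits_ten_samples(self):
        """With enough capacity the trainer can memorize a small table."""
        rng = np.random.default_rng(0)
        ds = generate_dataset(SyntheticConfig(n_drugs=4, n_cells=2, seed=8))
        train = [ds.combo[i] for i in rng.choice(len(ds.combo), 10, replace=False)]
        y = np.array([s.response for s in train])
        model = train_global(
            train,
            GlobalModelConfig(
                epochs=2000, patience=2000, learning_rate=3e-3,
                val_fraction=0.0, pair_swap_augment=False, seed=0,
            ),
            ds.drugs, ds.cells,
            drug_cfg=DrugEncoderConfig(embedding_dim=8, conv_filters=(8,), kernel_sizes=(3,)),
            cell_cfg=CellEncoderConfig(hidden=(16, 8), embedding_dim=4),
            dose_cfg=DoseEmbedderConfig(n_frequencies=4),
        )
        mse = float(np.mean((model.predict(train) - y) ** 2))
        assert mse < 0.01 * float(np.var(y))
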