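"""Scenario-based evaluation: splits, cross-validation, PCC, ablations.

Three evaluation regimes mirror how a combination screen is used:

* **S1 (matrix completion)** — a random subset of the cells of every
  dose-response matrix is held out; monotherapy rows stay available.
* **S2 (new combination, monotherapy known)** — whole matrices of held-out
  drug pairs are predicted across all cell lines; monotherapy data for the
  drugs remain in the training set, so the local model can fall back to
  Bliss pseudo-curves.
* **S3 (new combination, no monotherapy)** — as S2 but with all monotherapy
  data removed; the local model can only retrieve by feature similarity.

Three additional transfer modes hold out whole (pair, cell) triplets, whole
drugs, or whole cell lines. Folds partition the unit set (samples for S1,
pairs for S2/S3, triplets/drugs/cells for the transfer modes); the metric is
the Pearson correlation between predicted and observed responses, averaged
over folds.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .aggregation import AggregatorConfig, PredictionPair, train_aggregator
from .encoders import CellEncoderConfig, DoseEmbedderConfig, DrugEncoderConfig
from .global_model import GlobalModelConfig, TrainedGlobalModel, train_global
from .io_types import ComboSample, MonoSample, ValidationError, canonical_pair_key
from .local_model import LocalGCNConfig, LocalPrediction, predict_local_batch
from .synthetic import SyntheticConfig, SyntheticDataset, generate_dataset

__all__ = [
    "pearson_cc",
    "ScenarioSplit",
    "make_scenario_split",
    "ExperimentConfig",
    "EvaluationReport",
    "run_experiment",
    "ABLATION_VARIANTS",
]

ABLATION_VARIANTS = (
    "full",
    "global_only",
    "local_only",
    "no_dose_embedding",
    "local_mlp",
    "fixed_aggregation",
)

SCENARIOS = ("S1", "S2", "S3", "new-combo", "new-drug", "new-cell")


def pearson_cc(predicted: Sequence[float], observed: Sequence[float]) -> float:
    """Pearson product-moment correlation between two equal-length sequences."""
    x = np.asarray(predicted, dtype=np.float64)
    y = np.asarray(observed, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValidationError("pearson_cc needs two equal-length 1-D sequences (n >= 2)")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt((xc**2).sum())
    sy = np.sqrt((yc**2).sum())
    if sx == 0 or sy == 0:
        raise ValidationError("correlation undefined for a constant sequence")
    return float((xc * yc).sum() / (sx * sy))


@dataclass(frozen=True)
class ScenarioSplit:
    scenario: str
    fold: int
    train_idx: tuple[int, ...]
    test_idx: tuple[int, ...]
    include_monotherapy: bool


def _partition(units: list, n_folds: int, rng: np.random.Generator) -> list[list]:
    if len(units) < n_folds:
        raise ValidationError(
            f"cannot make {n_folds} folds from {len(units)} unit(s)"
        )
    order = rng.permutation(len(units))
    return [[units[i] for i in order[f::n_folds]] for f in range(n_folds)]


def make_scenario_split(
    combos: Sequence[ComboSample],
    scenario: str,
    n_folds: int = 5,
    fraction: float = 0.2,
    seed: int = 0,
) -> list[ScenarioSplit]:
    """Seeded fold assignments for one scenario.

    For S1, ``fraction`` sets the held-out share of each matrix per fold
    (the folds jointly partition every matrix). For the unit-based scenarios
    the units themselves are partitioned across folds.
    """
    if scenario not in SCENARIOS:
        raise ValidationError(f"unknown scenario {scenario!r}; one of {SCENARIOS}")
    if not combos:
        raise ValidationError("empty dataset")
    if n_folds < 2:
        raise ValidationError("fold count must be >= 2")
    rng = np.random.default_rng(seed)
    idx_all = np.arange(len(combos))
    include_mono = scenario != "S3"

    if scenario == "S1":
        by_matrix: dict = {}
        for i, s in enumerate(combos):
            key = canonical_pair_key(s)
            by_matrix.setdefault((key.drug_lo, key.drug_hi, key.cell_id), []).append(i)
        fold_test: list[list[int]] = [[] for _ in range(n_folds)]
        for key in sorted(by_matrix):
            rows = np.array(by_matrix[key])
            rows = rows[rng.permutation(len(rows))]
            per_fold = max(1, int(round(fraction * len(rows))))
            for f in range(n_folds):
                fold_test[f].extend(rows[f * per_fold : (f + 1) * per_fold].tolist())
        splits = []
        for f in range(n_folds):
            test = np.array(sorted(fold_test[f]), dtype=int)
            train = np.setdiff1d(idx_all, test)
            splits.append(
                ScenarioSplit(scenario, f, tuple(train), tuple(test), include_mono)
            )
        return splits

    if scenario in ("S2", "S3"):
        def unit(s: ComboSample):
            k = canonical_pair_key(s)
            return (k.drug_lo, k.drug_hi)
    elif scenario == "new-combo":
        def unit(s: ComboSample):
            k = canonical_pair_key(s)
            return (k.drug_lo, k.drug_hi, k.cell_id)
    elif scenario == "new-cell":
        def unit(s: ComboSample):
            return s.cell_id
    else:  # new-drug: handled below (a sample touches two drug units)
        unit = None

    if scenario == "new-drug":
        drug_units = sorted({d for s in combos for d in (s.drug1_id, s.drug2_id)})
        folds = _partition(drug_units, n_folds, rng)
        splits = []
        for f, held in enumerate(folds):
            held_set = set(held)
            test = [
                i for i, s in enumerate(combos)
                if s.drug1_id in held_set or s.drug2_id in held_set
            ]
            train = [
                i for i, s in enumerate(combos)
                if s.drug1_id not in held_set and s.drug2_id not in held_set
            ]
            splits.append(
                ScenarioSplit(scenario, f, tuple(train), tuple(test), include_mono)
            )
        return splits

    units = sorted({unit(s) for s in combos})
    folds = _partition(units, n_folds, rng)
    splits = []
    for f, held in enumerate(folds):
        held_set = set(held)
        test = [i for i, s in enumerate(combos) if unit(s) in held_set]
        train = [i for i, s in enumerate(combos) if unit(s) not in held_set]
        splits.append(
            ScenarioSplit(scenario, f, tuple(train), tuple(test), include_mono)
        )
    return splits


# ---------------------------------------------------------------------------
# Experiment harness


@dataclass(frozen=True)
class ExperimentConfig:
    scenario: str = "S1"
    n_folds: int = 5
    folds_to_run: int | None = None  # evaluate only the first m folds
    fraction: float = 0.2
    seed: int = 0
    variants: tuple[str, ...] = ("full",)
    local_mode: str = "auto"
    local_use_gcn: bool = True
    inner_fraction: float = 0.1  # held out from global training for the aggregator
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    global_cfg: GlobalModelConfig = field(default_factory=GlobalModelConfig)
    local_cfg: LocalGCNConfig = field(default_factory=LocalGCNConfig)
    aggregator_cfg: AggregatorConfig = field(default_factory=AggregatorConfig)
    dose_cfg: DoseEmbedderConfig = field(default_factory=DoseEmbedderConfig)
    drug_cfg: DrugEncoderConfig = field(default_factory=DrugEncoderConfig)
    cell_cfg: CellEncoderConfig = field(default_factory=CellEncoderConfig)

    def __post_init__(self):
        for v in self.variants:
            if v not in ABLATION_VARIANTS:
                raise ValidationError(
                    f"unknown variant {v!r}; choose from {ABLATION_VARIANTS}"
                )


@dataclass
class EvaluationReport:
    scenario: str
    per_fold_pcc: dict[str, list[float]]  # variant -> per-fold PCC
    mean_pcc: dict[str, float]
    seeds: dict[str, int]
    config: dict
    local_availability: float  # fraction of test queries with a local prediction

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "scenario": self.scenario,
                "per_fold_pcc": self.per_fold_pcc,
                "mean_pcc": self.mean_pcc,
                "seeds": self.seeds,
                "local_availability": self.local_availability,
                "config": self.config,
            },
            indent=2,
            default=str,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload


def _fan_out_seeds(master: int) -> dict[str, int]:
    ss = np.random.SeedSequence(master)
    names = ("data", "split", "global", "local", "aggregator", "inner")
    children = ss.spawn(len(names))
    return {
        name: int(child.generate_state(1)[0] % (2**31 - 1))
        for name, child in zip(names, children)
    }


def _local_predictions(
    queries: Sequence[ComboSample],
    pool: Sequence[ComboSample],
    model: TrainedGlobalModel,
    cfg: ExperimentConfig,
    mono: Sequence[MonoSample] | None,
    seed: int,
    use_gcn: bool = True,
) -> list[LocalPrediction]:
    mono_scale = "percent" if cfg.synthetic.percent_scale else "fraction"
    needs_features = cfg.local_mode in ("auto", "feature")
    pool_features = model.joint_features(pool) if needs_features else None
    return predict_local_batch(
        queries,
        pool,
        model.joint_features,
        cfg.local_cfg,
        mode=cfg.local_mode,
        mono=mono,
        train_features=pool_features,
        mono_scale=mono_scale,
        use_gcn=use_gcn,
        seeds=[(seed + qi) % (2**31 - 1) for qi in range(len(queries))],
    )


def _pairs(globals_: np.ndarray, locals_: Sequence[LocalPrediction]) -> list[PredictionPair]:
    return [
        PredictionPair(
            float(g), lp.prediction if lp.available else None,
            lp.available, lp.source, lp.k,
        )
        for g, lp in zip(globals_, locals_)
    ]


def run_experiment(
    cfg: ExperimentConfig, dataset: SyntheticDataset | None = None
) -> EvaluationReport:
    """Cross-validated evaluation of the requested model variants.

    Per fold: the global model is trained on an inner slice of the training
    split; local predictions use the scenario-appropriate retrieval path;
    the aggregator is fitted on the held-out inner slice (out-of-fold for
    the global model); all variants are then scored on the fold's test set.
    """
    seeds = _fan_out_seeds(cfg.seed)
    if dataset is None:
        dataset = generate_dataset(replace(cfg.synthetic, seed=seeds["data"]))
    combos = dataset.combo
    splits = make_scenario_split(
        combos, cfg.scenario, cfg.n_folds, cfg.fraction, seeds["split"]
    )
    if cfg.folds_to_run is not None:
        splits = splits[: cfg.folds_to_run]

    # Variants that change the pipeline itself are run as sub-experiments on
    # the same dataset and seeds: raw-dose features, or MLP instead of GCN.
    sub_results: dict[str, EvaluationReport] = {}
    if "no_dose_embedding" in cfg.variants:
        sub_results["no_dose_embedding"] = run_experiment(
            replace(
                cfg, variants=("full",), dose_cfg=replace(cfg.dose_cfg, mode="raw")
            ),
            dataset=dataset,
        )
    if "local_mlp" in cfg.variants:
        sub_results["local_mlp"] = run_experiment(
            replace(cfg, variants=("full",), local_use_gcn=False), dataset=dataset
        )

    variants = tuple(v for v in cfg.variants if v not in sub_results)
    per_fold: dict[str, list[float]] = {v: [] for v in variants}
    n_local_avail = 0
    n_test = 0
    rng_inner = np.random.default_rng(seeds["inner"])

    for split in splits if variants else []:
        train = [combos[i] for i in split.train_idx]
        test = [combos[i] for i in split.test_idx]
        y_test = np.array([s.response for s in test])
        mono = dataset.mono if split.include_monotherapy else None

        order = rng_inner.permutation(len(train))
        n_inner_val = max(1, int(round(cfg.inner_fraction * len(train))))
        inner_val = [train[i] for i in order[:n_inner_val]]
        inner_train = [train[i] for i in order[n_inner_val:]]

        gcfg = replace(cfg.global_cfg, seed=seeds["global"] + split.fold)
        model = train_global(
            inner_train, gcfg, dataset.drugs, dataset.cells,
            dose_cfg=cfg.dose_cfg, drug_cfg=cfg.drug_cfg, cell_cfg=cfg.cell_cfg,
        )

        g_test = model.predict(test)
        l_test = _local_predictions(
            test, train, model, cfg, mono, seeds["local"] + 7919 * split.fold,
            use_gcn=cfg.local_use_gcn,
        )
        n_local_avail += sum(lp.available for lp in l_test)
        n_test += len(test)
        test_pairs = _pairs(g_test, l_test)

        agg = None
        if "full" in variants:
            g_val = model.predict(inner_val)
            l_val = _local_predictions(
                inner_val, inner_train, model, cfg, mono,
                seeds["local"] + 7919 * split.fold + 104729,
                use_gcn=cfg.local_use_gcn,
            )
            acfg = replace(cfg.aggregator_cfg, seed=seeds["aggregator"] + split.fold)
            agg = train_aggregator(
                _pairs(g_val, l_val), [s.response for s in inner_val], acfg
            )

        for v in variants:
            if v == "global_only":
                pred = g_test
            elif v == "local_only":
                pred = np.array(
                    [
                        lp.prediction if lp.available else float(g)
                        for g, lp in zip(g_test, l_test)
                    ]
                )
            elif v == "fixed_aggregation":
                fixed = train_aggregator(
                    [], [], replace(cfg.aggregator_cfg, mode="fixed-average")
                )
                pred = fixed.predict_many(test_pairs)
            else:  # full
                pred = agg.predict_many(test_pairs)
            per_fold[v].append(pearson_cc(pred, y_test))

    local_avail = n_local_avail / max(n_test, 1)
    for name, sub in sub_results.items():
        per_fold[name] = sub.per_fold_pcc["full"]
        if not variants:
            local_avail = sub.local_availability

    return EvaluationReport(
        scenario=cfg.scenario,
        per_fold_pcc=per_fold,
        mean_pcc={v: float(np.mean(p)) for v, p in per_fold.items()},
        seeds=seeds,
        config=_config_snapshot(cfg),
        local_availability=local_avail,
    )


def _config_snapshot(cfg: ExperimentConfig) -> dict:
    return json.loads(json.dumps(asdict(cfg), default=str))
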