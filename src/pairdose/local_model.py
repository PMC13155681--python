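"""The local, retrieval-augmented dose-response model.

For a query (drug1, drug2, dose1, dose2, cell), retrieve the training
measurements that share the query's unordered drug pair and cell line but
differ in doses; build a (k+1)-node graph over the retrieved points plus the
query, connecting each node to its nearest neighbors in (log dose1,
log dose2) space; and train a small semi-supervised graph convolutional
network per query, with an MSE loss on the labeled (retrieved) nodes only,
to predict the response at the unlabeled query node.

Two fallbacks cover queries with no same-pair measurements:

* **Bliss pseudo-curves** — when monotherapy curves for both drugs exist in
  the query's cell line, the combination surface is approximated by the
  product of single-drug growth fractions (Bliss independence) and the
  resulting grid enters the graph as pseudo-labeled nodes.
* **Feature similarity** — otherwise the K nearest training samples by
  cosine distance in joint-feature space are retrieved.

If even the fallbacks yield fewer than ``k_min`` neighbors, the local path
reports itself unavailable and the caller degenerates to the global model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .io_types import ComboSample, MonoSample, ValidationError, canonical_orientation, canonical_pair_key

logger = logging.getLogger(__name__)

__all__ = [
    "RetrievalResult",
    "SemiSupervisedGraph",
    "LocalGCNConfig",
    "LocalPrediction",
    "retrieve_matching_samples",
    "bliss_pseudo_curve",
    "retrieve_by_feature_similarity",
    "build_semisupervised_graph",
    "knn_dose_adjacency",
    "normalize_adjacency",
    "gcn_propagate",
    "gcn_forward",
    "train_local_predict",
    "train_local_mlp_predict",
    "predict_local",
    "predict_local_batch",
    "build_pair_index",
]

_DOSE_MATCH_RTOL = 1e-9


@dataclass(frozen=True)
class RetrievalResult:
    """Neighbors retrieved for one query, with their provenance."""

    samples: tuple[ComboSample, ...]
    source: str  # exact-match | bliss-pseudo | feature-similarity
    available: bool

    @property
    def k(self) -> int:
        return len(self.samples)

    @classmethod
    def of(cls, samples: Sequence[ComboSample], source: str, k_min: int) -> "RetrievalResult":
        samples = tuple(samples)
        return cls(samples, source, available=len(samples) >= k_min)


@dataclass
class SemiSupervisedGraph:
    """(k+1)-node graph; the query is the single unlabeled node (index -1)."""

    features: np.ndarray        # (n, F)
    adjacency: np.ndarray       # (n, n) binary, symmetric, unit diagonal
    labels: np.ndarray          # (n,), query entry is a placeholder 0.0
    labeled_mask: np.ndarray    # (n,) bool, exactly one False (the query)
    query_index: int

    def __post_init__(self):
        n = self.features.shape[0]
        if self.adjacency.shape != (n, n):
            raise ValidationError("adjacency shape mismatch")
        if not np.array_equal(self.adjacency, self.adjacency.T):
            raise ValidationError("adjacency must be symmetric")
        if not np.all(np.diag(self.adjacency) == 1):
            raise ValidationError("adjacency must have a unit diagonal")
        if self.labeled_mask.sum() != n - 1:
            raise ValidationError("exactly one node (the query) must be unlabeled")


@dataclass(frozen=True)
class LocalGCNConfig:
    n_layers: int = 2
    hidden: int = 32
    learning_rate: float = 1e-3
    epochs: int = 200
    k_min: int = 2
    knn: int = 4
    seed: int = 0
    feature_k: int = 20  # K for the feature-similarity fallback

    def __post_init__(self):
        if not (1e-6 <= self.learning_rate <= 1e-2):
            raise ValidationError(
                f"local learning rate {self.learning_rate} outside [1e-6, 1e-2]"
            )
        if self.knn < 1 or self.n_layers < 1 or self.k_min < 1 or self.feature_k < 1:
            raise ValidationError("knn, n_layers, k_min and feature_k must be >= 1")


@dataclass(frozen=True)
class LocalPrediction:
    """Typed outcome of the local path; ``prediction`` is None if unavailable."""

    available: bool
    prediction: float | None
    source: str
    k: int


# ---------------------------------------------------------------------------
# Retrieval


def build_pair_index(
    train: Sequence[ComboSample],
) -> dict[object, list[ComboSample]]:
    """Group training samples by canonical (pair, cell) key for fast retrieval."""
    index: dict[object, list[ComboSample]] = {}
    for s in train:
        index.setdefault(canonical_pair_key(s), []).append(s)
    return index


def retrieve_matching_samples(
    query: ComboSample,
    train: Sequence[ComboSample],
    k_min: int = 2,
    index: dict[object, list[ComboSample]] | None = None,
) -> RetrievalResult:
    """Training samples sharing the query's unordered pair and cell line.

    Matches are re-oriented so doses align with the query's drug order;
    samples at exactly the query's dose pair are excluded (that response is
    the unknown being predicted). Pass a prebuilt ``index`` (from
    :func:`build_pair_index`) to skip the linear scan.
    """
    qkey = canonical_pair_key(query)
    q = canonical_orientation(query)
    flip = query.drug1_id != q.drug1_id
    pool = index.get(qkey, []) if index is not None else train
    out: list[ComboSample] = []
    for s in pool:
        if canonical_pair_key(s) != qkey:
            continue
        c = canonical_orientation(s)
        if np.isclose(c.dose1, q.dose1, rtol=_DOSE_MATCH_RTOL) and np.isclose(
            c.dose2, q.dose2, rtol=_DOSE_MATCH_RTOL
        ):
            continue
        out.append(c.swapped() if flip else c)
    return RetrievalResult.of(out, "exact-match", k_min)


def bliss_pseudo_curve(
    mono1: Sequence[MonoSample],
    mono2: Sequence[MonoSample],
    cell_id: str,
    scale: str = "fraction",
) -> list[ComboSample]:
    """Bliss-independence pseudo-surface from two monotherapy curves.

    The combined growth fraction at (r1, r2) is the product g1(r1) * g2(r2)
    over the outer product of the two dose grids. Responses must be growth
    fractions in [0, 1]; with ``scale='percent'`` they are divided by 100
    first and clipped into [0, 1] (clipping is logged).
    """
    if not mono1 or not mono2:
        raise ValidationError("both monotherapy curves must be non-empty")
    for m in (*mono1, *mono2):
        if m.cell_id != cell_id:
            raise ValidationError(
                f"monotherapy sample for cell {m.cell_id!r} does not match {cell_id!r}"
            )
    if scale not in ("fraction", "percent"):
        raise ValidationError(f"unknown scale {scale!r}")

    def fractions(mono: Sequence[MonoSample]) -> np.ndarray:
        g = np.array([m.response for m in mono], dtype=np.float64)
        if scale == "percent":
            g = g / 100.0
            clipped = (g < 0) | (g > 1)
            if clipped.any():
                logger.warning(
                    "clipped %d monotherapy growth fraction(s) into [0, 1]",
                    int(clipped.sum()),
                )
                g = np.clip(g, 0.0, 1.0)
        if ((g < 0) | (g > 1)).any():
            raise ValidationError(
                "monotherapy responses must be growth fractions in [0, 1] "
                "(pass scale='percent' for percent-growth data)"
            )
        return g

    g1, g2 = fractions(mono1), fractions(mono2)
    d1 = mono1[0].drug_id
    d2 = mono2[0].drug_id
    return [
        ComboSample(d1, d2, a.dose, b.dose, cell_id, float(ga * gb))
        for a, ga in zip(mono1, g1)
        for b, gb in zip(mono2, g2)
    ]


def retrieve_bliss_pseudo(
    query: ComboSample,
    mono: Sequence[MonoSample],
    k_min: int = 2,
    scale: str = "fraction",
) -> RetrievalResult:
    """Bliss fallback: pseudo-labeled grid for the query's pair and cell."""
    m1 = [m for m in mono if m.drug_id == query.drug1_id and m.cell_id == query.cell_id]
    m2 = [m for m in mono if m.drug_id == query.drug2_id and m.cell_id == query.cell_id]
    if not m1 or not m2:
        return RetrievalResult.of((), "bliss-pseudo", k_min)
    pseudo = bliss_pseudo_curve(m1, m2, query.cell_id, scale=scale)
    pseudo = [
        s
        for s in pseudo
        if not (
            np.isclose(s.dose1, query.dose1, rtol=_DOSE_MATCH_RTOL)
            and np.isclose(s.dose2, query.dose2, rtol=_DOSE_MATCH_RTOL)
        )
    ]
    return RetrievalResult.of(pseudo, "bliss-pseudo", k_min)


def retrieve_by_feature_similarity(
    query_feature: np.ndarray,
    train_features: np.ndarray,
    train_samples: Sequence[ComboSample],
    k: int = 20,
    k_min: int = 2,
) -> RetrievalResult:
    """K training samples nearest in cosine distance to the query feature.

    Ties break toward the lower training index; K is capped at the pool size.
    """
    q = np.asarray(query_feature, dtype=np.float64)
    x = np.asarray(train_features, dtype=np.float64)
    qn = np.linalg.norm(q)
    xn = np.linalg.norm(x, axis=1)
    if qn == 0 or (xn == 0).any():
        raise ValidationError("zero-norm feature vector in cosine retrieval")
    dist = 1.0 - (x @ q) / (xn * qn)
    order = np.argsort(dist, kind="stable")[: min(k, len(train_samples))]
    return RetrievalResult.of(
        [train_samples[i] for i in order], "feature-similarity", k_min
    )


# ---------------------------------------------------------------------------
# Graph construction


def knn_dose_adjacency(log_doses: np.ndarray, knn: int = 4) -> np.ndarray:
    """Binary adjacency from k-nearest-neighbor selection in log-dose space.

    Each node selects its ``knn`` nearest other nodes (Euclidean distance in
    the (log dose1, log dose2) plane; ties toward the lower index); directed
    selections are symmetrized by union and a unit diagonal is added.
    """
    n = log_doses.shape[0]
    knn = min(knn, n - 1)
    adj = np.eye(n)
    if knn < 1:
        return adj
    diff = log_doses[:, None, :] - log_doses[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=-1))
    np.fill_diagonal(dist, np.inf)
    for i in range(n):
        nearest = np.argsort(dist[i], kind="stable")[:knn]
        adj[i, nearest] = 1.0
        adj[nearest, i] = 1.0
    return adj


def build_semisupervised_graph(
    query: ComboSample,
    retrieval: RetrievalResult,
    feature_fn: Callable[[Sequence[ComboSample]], np.ndarray],
    knn: int = 4,
) -> SemiSupervisedGraph | None:
    """Assemble the (k+1)-node graph; None signals "local path unavailable"."""
    if not retrieval.available:
        return None
    nodes = list(retrieval.samples) + [query]
    features = np.asarray(feature_fn(nodes), dtype=np.float64)
    log_doses = np.log(np.array([[s.dose1, s.dose2] for s in nodes]))
    adjacency = knn_dose_adjacency(log_doses, knn=knn)
    labels = np.array([s.response for s in retrieval.samples] + [0.0])
    mask = np.ones(len(nodes), dtype=bool)
    mask[-1] = False
    return SemiSupervisedGraph(features, adjacency, labels, mask, len(nodes) - 1)


def normalize_adjacency(adjacency: np.ndarray) -> np.ndarray:
    """Symmetric degree normalization D^(-1/2) A D^(-1/2)."""
    a = np.asarray(adjacency, dtype=np.float64)
    if not np.array_equal(a, a.T):
        raise ValidationError("adjacency must be symmetric")
    if not np.all(np.diag(a) == 1):
        raise ValidationError("adjacency must have a unit diagonal")
    d = a.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(d)
    return a * inv_sqrt[:, None] * inv_sqrt[None, :]


# ---------------------------------------------------------------------------
# GCN forward / training (hand-vectorized; this is the per-query hot loop)


def gcn_propagate(
    a_hat: np.ndarray,
    x: np.ndarray,
    layers: Sequence[tuple[np.ndarray, np.ndarray]],
    activation: str = "relu",
) -> np.ndarray:
    """Layered propagation H <- act(A_hat @ H @ W + b); returns the last H."""
    h = x
    for w, b in layers:
        h = a_hat @ h @ w + b
        if activation == "relu":
            h = np.maximum(h, 0.0)
        elif activation != "linear":
            raise ValidationError(f"unknown activation {activation!r}")
    return h


@dataclass
class GCNParams:
    conv: list[tuple[np.ndarray, np.ndarray]]
    out_w: np.ndarray
    out_b: float


def _init_gcn(n_features: int, cfg: LocalGCNConfig, rng: np.random.Generator) -> GCNParams:
    conv = []
    n_in = n_features
    for _ in range(cfg.n_layers):
        conv.append(
            (
                rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, cfg.hidden)),
                np.zeros(cfg.hidden),
            )
        )
        n_in = cfg.hidden
    return GCNParams(conv, rng.normal(0.0, np.sqrt(1.0 / n_in), size=n_in), 0.0)


def gcn_forward(graph: SemiSupervisedGraph, params: GCNParams) -> np.ndarray:
    """Per-node predictions: ReLU conv layers then a linear scalar head."""
    a_hat = normalize_adjacency(graph.adjacency)
    h = gcn_propagate(a_hat, graph.features, params.conv, activation="relu")
    return h @ params.out_w + params.out_b


def _train_semisupervised_batch(
    a_hat: np.ndarray | None,
    x: np.ndarray,
    labels: np.ndarray,
    mask: np.ndarray,
    cfg: LocalGCNConfig,
    seeds: Sequence[int],
) -> np.ndarray:
    """Train B independent per-query networks in one vectorized loop.

    ``x`` is (B, n, F), ``a_hat`` is (B, n, n) (or None to drop the graph
    coupling — the "local without GCN" ablation, a plain per-node MLP),
    ``labels``/``mask`` are (B, n). Each batch element carries its own
    weights, initialized from its own seed, so the result per element is
    identical to training that query alone. Returns per-node outputs (B, n).
    """
    bsz, n, n_feat = x.shape
    layer_sizes = [n_feat] + [cfg.hidden] * cfg.n_layers
    ws: list[np.ndarray] = []
    bs: list[np.ndarray] = []
    out_w = np.empty((bsz, cfg.hidden, 1))
    for li in range(cfg.n_layers):
        ws.append(np.empty((bsz, layer_sizes[li], cfg.hidden)))
        bs.append(np.zeros((bsz, 1, cfg.hidden)))
    for bi, seed in enumerate(seeds):
        p = _init_gcn(n_feat, cfg, np.random.default_rng(seed))
        for li, (w, _) in enumerate(p.conv):
            ws[li][bi] = w
        out_w[bi, :, 0] = p.out_w
    out_b = np.zeros((bsz, 1, 1))

    maskf = mask.astype(np.float64)
    n_lab = maskf.sum(axis=1, keepdims=True)
    # standardize labels per graph so the zero-initialized output starts at
    # the labeled mean; predictions are mapped back afterwards
    mu = (labels * maskf).sum(axis=1, keepdims=True) / n_lab
    sd = np.sqrt(((labels - mu) ** 2 * maskf).sum(axis=1, keepdims=True) / n_lab)
    sd = np.where(sd < 1e-12, 1.0, sd)
    t = (labels - mu) / sd
    m0 = a_hat @ x if a_hat is not None else x  # constant across epochs

    params = ws + bs + [out_w, out_b]
    adam_m = [np.zeros_like(p) for p in params]
    adam_v = [np.zeros_like(p) for p in params]
    b1, b2, eps = 0.9, 0.999, 1e-8

    y = np.zeros((bsz, n))
    for step in range(1, cfg.epochs + 1):
        # forward
        srcs = [m0]
        zs = []
        h = None
        for li in range(cfg.n_layers):
            src = srcs[li]
            z = src @ ws[li] + bs[li]
            zs.append(z)
            h = np.maximum(z, 0.0)
            if li + 1 < cfg.n_layers:
                srcs.append(a_hat @ h if a_hat is not None else h)
        y = (h @ out_w + out_b)[:, :, 0]
        # backward: MSE on labeled nodes
        dy = (2.0 * (y - t) * maskf / n_lab)[:, :, None]
        g_out_w = np.matmul(h.transpose(0, 2, 1), dy)
        g_out_b = dy.sum(axis=1, keepdims=True)
        dh = dy @ out_w.transpose(0, 2, 1)
        g_ws: list[np.ndarray] = [None] * cfg.n_layers  # type: ignore[list-item]
        g_bs: list[np.ndarray] = [None] * cfg.n_layers  # type: ignore[list-item]
        for li in range(cfg.n_layers - 1, -1, -1):
            dz = dh * (zs[li] > 0)
            g_ws[li] = np.matmul(srcs[li].transpose(0, 2, 1), dz)
            g_bs[li] = dz.sum(axis=1, keepdims=True)
            if li > 0:
                dh = dz @ ws[li].transpose(0, 2, 1)
                if a_hat is not None:
                    dh = a_hat @ dh  # a_hat is symmetric
        grads = g_ws + g_bs + [g_out_w, g_out_b]
        # Adam
        c1 = 1 - b1**step
        c2 = 1 - b2**step
        for i, g in enumerate(grads):
            adam_m[i] = b1 * adam_m[i] + (1 - b1) * g
            adam_v[i] = b2 * adam_v[i] + (1 - b2) * g**2
            params[i] -= cfg.learning_rate * (adam_m[i] / c1) / (
                np.sqrt(adam_v[i] / c2) + eps
            )
    # final forward, mapped back to the label scale
    h = None
    src = m0
    for li in range(cfg.n_layers):
        h = np.maximum(src @ ws[li] + bs[li], 0.0)
        if li + 1 < cfg.n_layers:
            src = a_hat @ h if a_hat is not None else h
    return (h @ out_w + out_b)[:, :, 0] * sd + mu


def _train_semisupervised(
    a_hat: np.ndarray | None,
    graph: SemiSupervisedGraph,
    cfg: LocalGCNConfig,
    seed: int,
) -> float:
    y = _train_semisupervised_batch(
        a_hat[None] if a_hat is not None else None,
        graph.features[None],
        graph.labels[None],
        graph.labeled_mask[None],
        cfg,
        [seed],
    )
    return float(y[0, graph.query_index])


def train_local_predict(
    graph: SemiSupervisedGraph | None, cfg: LocalGCNConfig, seed: int | None = None
) -> float | None:
    """Train the per-query semi-supervised GCN; None if the path is unavailable."""
    if graph is None:
        return None
    if int(graph.labeled_mask.sum()) < cfg.k_min:
        return None
    a_hat = normalize_adjacency(graph.adjacency)
    return _train_semisupervised(a_hat, graph, cfg, cfg.seed if seed is None else seed)


def train_local_mlp_predict(
    graph: SemiSupervisedGraph | None, cfg: LocalGCNConfig, seed: int | None = None
) -> float | None:
    """Ablation: same retrieval and features, but a plain MLP (no graph)."""
    if graph is None:
        return None
    if int(graph.labeled_mask.sum()) < cfg.k_min:
        return None
    return _train_semisupervised(None, graph, cfg, cfg.seed if seed is None else seed)


# ---------------------------------------------------------------------------
# High-level per-query drivers


def _retrieve_for_query(
    query: ComboSample,
    train: Sequence[ComboSample],
    feature_fn: Callable[[Sequence[ComboSample]], np.ndarray],
    cfg: LocalGCNConfig,
    mode: str,
    mono: Sequence[MonoSample] | None,
    train_features: np.ndarray | None,
    mono_scale: str,
    index: dict[object, list[ComboSample]] | None = None,
) -> RetrievalResult | None:
    retrieval: RetrievalResult | None = None
    if mode in ("exact", "auto"):
        retrieval = retrieve_matching_samples(query, train, k_min=cfg.k_min, index=index)
    if (retrieval is None or not retrieval.available) and mode in ("bliss", "auto"):
        if mono:
            r = retrieve_bliss_pseudo(query, mono, k_min=cfg.k_min, scale=mono_scale)
            if r.available or mode == "bliss":
                retrieval = r
        elif mode == "bliss":
            raise ValidationError("bliss mode requires a monotherapy table")
    if (retrieval is None or not retrieval.available) and mode in ("feature", "auto"):
        if train_features is None:
            raise ValidationError("feature retrieval requires precomputed train features")
        qf = feature_fn([query])[0]
        retrieval = retrieve_by_feature_similarity(
            qf, train_features, train, k=cfg.feature_k, k_min=cfg.k_min
        )
    return retrieval


def _rescale(pred: float, source: str, mono_scale: str) -> float:
    # Bliss pseudo-labels are growth fractions; map back to percent data.
    if source == "bliss-pseudo" and mono_scale == "percent":
        return pred * 100.0
    return pred


def predict_local(
    query: ComboSample,
    train: Sequence[ComboSample],
    feature_fn: Callable[[Sequence[ComboSample]], np.ndarray],
    cfg: LocalGCNConfig,
    mode: str = "auto",
    mono: Sequence[MonoSample] | None = None,
    train_features: np.ndarray | None = None,
    mono_scale: str = "fraction",
    use_gcn: bool = True,
    seed: int | None = None,
) -> LocalPrediction:
    """Run the local path for one query with the configured fallback policy.

    ``mode``: 'exact', 'bliss', 'feature', 'auto' (exact, then Bliss when
    monotherapy data exist, then feature similarity) or 'off'.
    """
    if mode == "off":
        return LocalPrediction(False, None, "off", 0)
    retrieval = _retrieve_for_query(
        query, train, feature_fn, cfg, mode, mono, train_features, mono_scale
    )
    if retrieval is None or not retrieval.available:
        source = retrieval.source if retrieval is not None else mode
        return LocalPrediction(False, None, source, retrieval.k if retrieval else 0)
    graph = build_semisupervised_graph(query, retrieval, feature_fn, knn=cfg.knn)
    trainer = train_local_predict if use_gcn else train_local_mlp_predict
    pred = trainer(graph, cfg, seed=seed)
    if pred is None:
        return LocalPrediction(False, None, retrieval.source, retrieval.k)
    return LocalPrediction(
        True, _rescale(pred, retrieval.source, mono_scale), retrieval.source, retrieval.k
    )


def predict_local_batch(
    queries: Sequence[ComboSample],
    train: Sequence[ComboSample],
    feature_fn: Callable[[Sequence[ComboSample]], np.ndarray],
    cfg: LocalGCNConfig,
    mode: str = "auto",
    mono: Sequence[MonoSample] | None = None,
    train_features: np.ndarray | None = None,
    mono_scale: str = "fraction",
    use_gcn: bool = True,
    seeds: Sequence[int] | None = None,
) -> list[LocalPrediction]:
    """Local predictions for many queries.

    Equivalent to calling :func:`predict_local` per query (same retrieval,
    same per-query networks and seeds), but queries whose graphs share a
    shape are trained together in one vectorized loop.
    """
    if seeds is None:
        seeds = list(range(len(queries)))
    if mode == "off":
        return [LocalPrediction(False, None, "off", 0) for _ in queries]
    index = build_pair_index(train) if mode in ("exact", "auto") else None
    results: list[LocalPrediction | None] = [None] * len(queries)
    groups: dict[tuple[int, int], list[tuple[int, SemiSupervisedGraph, RetrievalResult]]] = {}
    for qi, query in enumerate(queries):
        retrieval = _retrieve_for_query(
            query, train, feature_fn, cfg, mode, mono, train_features, mono_scale,
            index=index,
        )
        if retrieval is None or not retrieval.available:
            source = retrieval.source if retrieval is not None else mode
            results[qi] = LocalPrediction(
                False, None, source, retrieval.k if retrieval else 0
            )
            continue
        graph = build_semisupervised_graph(query, retrieval, feature_fn, knn=cfg.knn)
        groups.setdefault(graph.features.shape, []).append((qi, graph, retrieval))
    for shape, members in groups.items():
        a_hat = (
            np.stack([normalize_adjacency(g.adjacency) for _, g, _ in members])
            if use_gcn
            else None
        )
        x = np.stack([g.features for _, g, _ in members])
        labels = np.stack([g.labels for _, g, _ in members])
        mask = np.stack([g.labeled_mask for _, g, _ in members])
        y = _train_semisupervised_batch(
            a_hat, x, labels, mask, cfg, [seeds[qi] for qi, _, _ in members]
        )
        for row, (qi, g, retrieval) in enumerate(members):
            results[qi] = LocalPrediction(
                True,
                _rescale(float(y[row, g.query_index]), retrieval.source, mono_scale),
                retrieval.source,
                retrieval.k,
            )
    return results  # type: ignore[return-value]
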