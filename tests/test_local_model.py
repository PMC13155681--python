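"""Retrieval, Bliss pseudo-curves, graph construction, GCN, local training."""

import numpy as np
import pytest

from pairdose.io_types import ComboSample, MonoSample, ValidationError
from pairdose.local_model import (
    LocalGCNConfig,
    GCNParams,
    SemiSupervisedGraph,
    bliss_pseudo_curve,
    build_pair_index,
    build_semisupervised_graph,
    gcn_forward,
    gcn_propagate,
    knn_dose_adjacency,
    normalize_adjacency,
    predict_local,
    predict_local_batch,
    retrieve_by_feature_similarity,
    retrieve_bliss_pseudo,
    retrieve_matching_samples,
    train_local_predict,
)


def combo(d1, d2, r1, r2, cell="c", resp=0.0):
    return ComboSample(d1, d2, r1, r2, cell, resp)


def identity_features(samples):
    """Simple feature map for graph tests: (log dose1, log dose2, response)."""
    return np.array([[np.log(s.dose1), np.log(s.dose2), 0.0] for s in samples])


class TestExactRetrieval:
    def test_same_key_different_doses(self):
        q = combo("A", "B", 0.1, 0.2)
        train = [
            combo("A", "B", 0.3, 0.2), combo("A", "B", 0.1, 0.4),
            combo("B", "A", 0.5, 0.6),           # same pair, swapped storage
            combo("A", "C", 0.1, 0.2),           # other pair
            combo("A", "B", 0.1, 0.2, cell="z"), # other cell
        ]
        r = retrieve_matching_samples(q, train)
        assert r.k == 3 and r.available and r.source == "exact-match"

    def test_swapped_row_reoriented_to_query(self):
        q = combo("A", "B", 0.1, 0.2)
        train = [combo("B", "A", 0.7, 0.3, resp=5.0)]
        r = retrieve_matching_samples(q, train, k_min=1)
        s = r.samples[0]
        assert (s.drug1_id, s.dose1, s.drug2_id, s.dose2) == ("A", 0.3, "B", 0.7)

    def test_query_dose_pair_excluded(self):
        q = combo("A", "B", 0.1, 0.2)
        train = [combo("A", "B", 0.1, 0.2, resp=9.0), combo("B", "A", 0.2, 0.1, resp=9.0)]
        assert retrieve_matching_samples(q, train).k == 0

    def test_no_match_unavailable(self):
        r = retrieve_matching_samples(combo("A", "B", 1, 1), [combo("C", "D", 1, 1)])
        assert r.k == 0 and not r.available

    def test_index_equivalent_to_scan(self):
        rng = np.random.default_rng(0)
        train = [
            combo(f"D{rng.integers(4)}", f"D{rng.integers(4)}",
                  float(rng.uniform(0.1, 1)), float(rng.uniform(0.1, 1)),
                  cell=f"c{rng.integers(2)}")
            for _ in range(100)
        ]
        index = build_pair_index(train)
        for q in train[:20]:
            a = retrieve_matching_samples(q, train)
            b = retrieve_matching_samples(q, train, index=index)
            assert a == b


class TestBlissPseudo:
    def test_pointwise_product(self):
        m1 = [MonoSample("A", 0.1, "c", 0.5)]
        m2 = [MonoSample("B", 0.2, "c", 0.4)]
        out = bliss_pseudo_curve(m1, m2, "c")
        assert len(out) == 1 and abs(out[0].response - 0.2) < 1e-15

    def test_inactive_partner_is_identity(self):
        doses = [0.01, 0.1, 1.0]
        m1 = [MonoSample("A", d, "c", g) for d, g in zip(doses, (0.9, 0.5, 0.2))]
        m2 = [MonoSample("B", d, "c", 1.0) for d in doses]
        out = bliss_pseudo_curve(m1, m2, "c")
        for s in out:
            g1 = {0.01: 0.9, 0.1: 0.5, 1.0: 0.2}[s.dose1]
            assert abs(s.response - g1) < 1e-15

    def test_outer_product_oracle(self, rng):
        doses = np.geomspace(0.01, 1, 5)
        g1 = rng.uniform(0, 1, 5)
        g2 = rng.uniform(0, 1, 5)
        m1 = [MonoSample("A", d, "c", g) for d, g in zip(doses, g1)]
        m2 = [MonoSample("B", d, "c", g) for d, g in zip(doses, g2)]
        out = bliss_pseudo_curve(m1, m2, "c")
        assert len(out) == 25
        expected = np.outer(g1, g2)
        got = np.array([s.response for s in out]).reshape(5, 5)
        assert np.allclose(got, expected, atol=1e-15)

    def test_percent_scale_rescaled_before_multiplication(self):
        m1 = [MonoSample("A", 0.1, "c", 50.0)]
        m2 = [MonoSample("B", 0.2, "c", 40.0)]
        out = bliss_pseudo_curve(m1, m2, "c", scale="percent")
        assert abs(out[0].response - 0.2) < 1e-15

    def test_fraction_out_of_range_rejected(self):
        m1 = [MonoSample("A", 0.1, "c", 50.0)]  # looks like percent
        m2 = [MonoSample("B", 0.2, "c", 0.4)]
        with pytest.raises(ValidationError):
            bliss_pseudo_curve(m1, m2, "c")

    def test_retrieval_excludes_query_grid_point(self):
        doses = [0.1, 0.2]
        mono = [MonoSample("A", d, "c", 0.5) for d in doses] + [
            MonoSample("B", d, "c", 0.5) for d in doses
        ]
        q = combo("A", "B", 0.1, 0.2)
        r = retrieve_bliss_pseudo(q, mono)
        assert r.k == 3 and r.source == "bliss-pseudo"


class TestFeatureSimilarity:
    def test_collinear_vector_ranks_first(self, rng):
        q = np.array([1.0, 2.0, 3.0])
        pool = rng.normal(size=(5, 3))
        pool[3] = 2.5 * q
        samples = [combo("A", "B", 1, 1, resp=i) for i in range(5)]
        r = retrieve_by_feature_similarity(q, pool, samples, k=2)
        assert r.samples[0].response == 3

    def test_k_capped_at_pool(self, rng):
        pool = rng.normal(size=(30, 4))
        samples = [combo("A", "B", 1, 1, resp=i) for i in range(30)]
        assert retrieve_by_feature_similarity(rng.normal(size=4), pool, samples, k=100).k == 30

    def test_matches_brute_force_sort(self, rng):
        q = rng.normal(size=6)
        pool = rng.normal(size=(10, 6))
        samples = [combo("A", "B", 1, 1, resp=i) for i in range(10)]
        r = retrieve_by_feature_similarity(q, pool, samples, k=3)
        d = [1 - (p @ q) / (np.linalg.norm(p) * np.linalg.norm(q)) for p in pool]
        expected = np.argsort(d, kind="stable")[:3]
        assert [s.response for s in r.samples] == list(expected)

    def test_zero_norm_rejected(self):
        with pytest.raises(ValidationError):
            retrieve_by_feature_similarity(
                np.zeros(3), np.ones((2, 3)), [combo("A", "B", 1, 1)] * 2, k=1
            )


class TestGraphConstruction:
    def test_small_retrieval_caps_knn_to_complete_graph(self):
        q = combo("A", "B", 0.5, 0.5)
        train = [combo("A", "B", 0.1 * i, 0.1, resp=i) for i in (1, 2, 3)]
        r = retrieve_matching_samples(q, train)
        g = build_semisupervised_graph(q, r, identity_features, knn=4)
        assert np.all(g.adjacency == 1.0)  # complete incl. self-loops

    def test_adjacency_symmetric_unit_diagonal(self, rng):
        for _ in range(20):
            n = int(rng.integers(2, 12))
            pts = rng.uniform(-2, 2, size=(n, 2))
            a = knn_dose_adjacency(pts, knn=4)
            assert np.array_equal(a, a.T)
            assert np.all(np.diag(a) == 1)

    def test_matches_brute_force_knn_oracle(self, rng):
        """Union-symmetrized 4-NN via an explicit O(n^2) double loop."""
        for _ in range(200):
            n = int(rng.integers(2, 13))
            pts = rng.uniform(-3, 3, size=(n, 2))
            a = knn_dose_adjacency(pts, knn=4)
            expected = np.eye(n)
            for i in range(n):
                d = [(np.hypot(*(pts[i] - pts[j])), j) for j in range(n) if j != i]
                d.sort(key=lambda t: (t[0], t[1]))
                for _, j in d[: min(4, n - 1)]:
                    expected[i, j] = expected[j, i] = 1
            assert np.array_equal(a, expected)

    def test_unavailable_retrieval_returns_none(self):
        q = combo("A", "B", 1, 1)
        r = retrieve_matching_samples(q, [])
        assert build_semisupervised_graph(q, r, identity_features) is None

    def test_query_is_last_and_unlabeled(self):
        q = combo("A", "B", 0.5, 0.5, resp=99.0)
        train = [combo("A", "B", 0.1 * i, 0.1, resp=float(i)) for i in (1, 2, 3)]
        g = build_semisupervised_graph(q, retrieve_matching_samples(q, train), identity_features)
        assert g.query_index == 3
        assert not g.labeled_mask[3] and g.labeled_mask[:3].all()
        assert list(g.labels[:3]) == [1.0, 2.0, 3.0]


class TestNormalizeAdjacency:
    def test_identity_stays_identity(self):
        assert np.allclose(normalize_adjacency(np.eye(4)), np.eye(4))

    def test_two_node_complete(self):
        a = np.ones((2, 2))
        assert np.allclose(normalize_adjacency(a), 0.5)

    def test_matches_explicit_loop_oracle(self, rng):
        n = 6
        a = knn_dose_adjacency(rng.uniform(size=(n, 2)), knn=2)
        got = normalize_adjacency(a)
        deg = a.sum(axis=1)
        expected = np.zeros_like(a)
        for i in range(n):
            for j in range(n):
                expected[i, j] = a[i, j] / np.sqrt(deg[i] * deg[j])
        assert np.allclose(got, expected, atol=1e-12)
        assert np.allclose(got, got.T)
        assert np.all(got.sum(axis=1) <= 1 + 1e-12)


def toy_graph(rng, n=5, f=3):
    pts = rng.uniform(size=(n, 2))
    a = knn_dose_adjacency(pts, knn=2)
    x = rng.normal(size=(n, f))
    mask = np.ones(n, dtype=bool)
    mask[-1] = False
    return SemiSupervisedGraph(x, a, rng.normal(size=n), mask, n - 1)


class TestGCNForward:
    def test_zero_weights_zero_output(self, rng):
        g = toy_graph(rng)
        params = GCNParams(
            [(np.zeros((3, 4)), np.zeros(4))], np.zeros(4), 0.0
        )
        assert np.allclose(gcn_forward(g, params), 0.0)

    def test_identity_propagation_is_ahat_x(self, rng):
        """One linear layer with identity weights reduces to A_hat @ X."""
        a = np.array([[1, 1, 0], [1, 1, 1], [0, 1, 1]], dtype=float)
        x = rng.normal(size=(3, 3))
        a_hat = normalize_adjacency(a)
        out = gcn_propagate(a_hat, x, [(np.eye(3), np.zeros(3))], activation="linear")
        d = a.sum(axis=1)
        expected = np.zeros((3, 3))
        for i in range(3):
            for j in range(3):
                expected[i] += a[i, j] / np.sqrt(d[i] * d[j]) * x[j]
        assert np.allclose(out, expected, atol=1e-10)

    def test_permutation_equivariance(self, rng):
        g = toy_graph(rng, n=6)
        params = GCNParams(
            [(rng.normal(size=(3, 4)), rng.normal(size=4))],
            rng.normal(size=4), 0.3,
        )
        y = gcn_forward(g, params)
        perm = rng.permutation(6)
        g2 = SemiSupervisedGraph(
            g.features[perm], g.adjacency[np.ix_(perm, perm)],
            g.labels[perm], g.labeled_mask[perm],
            int(np.where(perm == g.query_index)[0][0]),
        )
        assert np.allclose(gcn_forward(g2, params), y[perm], atol=1e-12)

    def test_edge_addition_changes_output(self, rng):
        g = toy_graph(rng, n=6)
        params = GCNParams(
            [(rng.normal(size=(3, 4)), rng.normal(size=4))], rng.normal(size=4), 0.0
        )
        y1 = gcn_forward(g, params)
        a2 = g.adjacency.copy()
        # connect the two nodes currently farthest apart (guaranteed new edge)
        off = np.where(a2 == 0)
        if len(off[0]) == 0:
            pytest.skip("graph already complete")
        i, j = off[0][0], off[1][0]
        a2[i, j] = a2[j, i] = 1
        g2 = SemiSupervisedGraph(g.features, a2, g.labels, g.labeled_mask, g.query_index)
        assert not np.allclose(gcn_forward(g2, params), y1)


class TestLocalTraining:
    def test_constant_labels_recovered(self, rng):
        q = combo("A", "B", 0.3, 0.3)
        train = [
            combo("A", "B", float(r1), float(r2), resp=5.0)
            for r1 in np.geomspace(0.1, 1, 3)
            for r2 in np.geomspace(0.1, 1, 3)
        ]
        g = build_semisupervised_graph(
            q, retrieve_matching_samples(q, train), identity_features
        )
        pred = train_local_predict(g, LocalGCNConfig(epochs=400, hidden=8, learning_rate=1e-2))
        assert abs(pred - 5.0) < 0.1

    def test_k_below_k_min_unavailable(self):
        q = combo("A", "B", 0.5, 0.5)
        train = [combo("A", "B", 0.1, 0.1, resp=1.0)]
        r = retrieve_matching_samples(q, train, k_min=2)
        assert not r.available
        assert build_semisupervised_graph(q, r, identity_features) is None
        assert train_local_predict(None, LocalGCNConfig()) is None

    def test_interpolates_linear_label_field(self, rng):
        """Labels linear in (log r1, log r2) on a 5x5 grid minus its center."""
        doses = np.geomspace(0.01, 1.0, 5)

        def label(r1, r2):
            return 0.4 * np.log(r1) - 0.25 * np.log(r2)

        q = combo("A", "B", doses[2], doses[2])
        train = [
            combo("A", "B", float(r1), float(r2), resp=float(label(r1, r2)))
            for r1 in doses
            for r2 in doses
            if not (r1 == doses[2] and r2 == doses[2])
        ]

        def features(samples):
            return np.array(
                [[np.log(s.dose1), np.log(s.dose2), 1.0] for s in samples]
            )

        g = build_semisupervised_graph(q, retrieve_matching_samples(q, train), features)
        pred = train_local_predict(g, LocalGCNConfig(epochs=400, hidden=16, learning_rate=1e-2))
        labels = [s.response for s in train]
        rng_ = max(labels) - min(labels)
        assert abs(pred - label(doses[2], doses[2])) < 0.1 * rng_

    def test_batch_matches_single(self, small_dataset, tiny_model):
        ds = small_dataset
        cfg = LocalGCNConfig(epochs=50, hidden=8)
        queries = ds.combo[:6]
        singles = [
            predict_local(q, ds.combo, tiny_model.joint_features, cfg, mode="exact", seed=i)
            for i, q in enumerate(queries)
        ]
        batch = predict_local_batch(
            queries, ds.combo, tiny_model.joint_features, cfg, mode="exact",
            seeds=list(range(6)),
        )
        for a, b in zip(singles, batch):
            assert a.available == b.available
            assert a.prediction == pytest.approx(b.prediction, abs=1e-9)
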