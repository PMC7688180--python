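import networkx as nx
import numpy as np
import pandas as pd
import pytest

from conftest import make_annotations
from ppifunc.predictors import (
    combine,
    gba_predict,
    gba_weighted,
    knn_predict,
    label_matrix,
    naive_predict,
    ridge_fit_predict,
    similarity_transfer,
)
from ppifunc.simulate import SimConfig, gen_annotations, gen_ontology, simulate

T1, T2, T3 = "GO:0000011", "GO:0000012", "GO:0000013"


class TestNaive:
    def test_training_frequency(self):
        mapping = {f"P{i}": ({T1} if i < 4 else {T2}) for i in range(10)}
        pred = naive_predict(make_annotations(mapping), ["q1", "q2"], [T1, T2])
        assert pred.loc["q1", T1] == pytest.approx(0.4)
        assert pred.loc["q2", T2] == pytest.approx(0.6)

    def test_universal_term_scores_one(self):
        annots = make_annotations({"P1": {T1}, "P2": {T1}})
        pred = naive_predict(annots, ["q"], [T1])
        assert pred.loc["q", T1] == 1.0

    def test_all_rows_identical(self):
        annots = make_annotations({"P1": {T1}, "P2": {T2}})
        pred = naive_predict(annots, ["a", "b", "c"], [T1, T2])
        assert (pred.nunique(axis=0) == 1).all()

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            naive_predict(make_annotations({}), ["q"], [T1])


class TestGBA:
    def _toy(self):
        g = nx.Graph([("q", "P1"), ("q", "P2"), ("q", "P3")])
        annots = make_annotations({"P1": {T1}, "P2": {T1}, "P3": {T2}})
        return g, annots

    def test_two_of_three_neighbors(self):
        g, annots = self._toy()
        pred = gba_predict(g, annots, ["q"], [T1, T2])
        assert pred.loc["q", T1] == pytest.approx(2 / 3)
        assert pred.loc["q", T2] == pytest.approx(1 / 3)

    def test_no_training_neighbors_all_zero(self):
        g = nx.Graph([("q", "x")])
        annots = make_annotations({"P1": {T1}})
        pred = gba_predict(g, annots, ["q"], [T1])
        assert (pred.to_numpy() == 0).all()

    def test_unanimous_neighbors(self):
        g, _ = self._toy()
        annots = make_annotations({f"P{i}": {T1} for i in (1, 2, 3)})
        pred = gba_predict(g, annots, ["q"], [T1])
        assert pred.loc["q", T1] == 1.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_on_random_graphs(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 31))
        g = nx.gnp_random_graph(n, 0.3, seed=seed)
        g = nx.relabel_nodes(g, {i: f"N{i}" for i in g})
        nodes = sorted(g.nodes)
        split = len(nodes) * 2 // 3
        train_ids, test_ids = nodes[:split], nodes[split:]
        terms = [T1, T2, T3]
        annots = make_annotations(
            {p: {t for t in terms if rng.random() < 0.5} | {T1}
             for p in train_ids}
        )
        pred = gba_predict(g, annots, test_ids, terms)
        for p in test_ids:  # independent brute-force neighbor loop
            nbrs = [x for x in g.neighbors(p) if x in annots.annotations]
            for t in terms:
                if not nbrs:
                    expected = 0.0
                else:
                    expected = sum(t in annots[x] for x in nbrs) / len(nbrs)
                assert pred.loc[p, t] == pytest.approx(expected)

    def test_hierarchy_consistent_for_nested_terms(self):
        # closed annotation sets: T1 always accompanies T2 (parent-like)
        g = nx.Graph([("q", "P1"), ("q", "P2"), ("q", "P3")])
        annots = make_annotations(
            {"P1": {T1, T2}, "P2": {T1}, "P3": {T1, T2}}
        )
        pred = gba_predict(g, annots, ["q"], [T1, T2])
        assert pred.loc["q", T2] <= pred.loc["q", T1]


class TestWeightedGBA:
    def test_weighted_vote(self):
        g = nx.Graph()
        g.add_edge("q", "P1", weight=0.8)
        g.add_edge("q", "P2", weight=0.4)
        annots = make_annotations({"P1": {T1}, "P2": {T2}})
        pred = gba_weighted(g, annots, ["q"], [T1, T2])
        assert pred.loc["q", T1] == pytest.approx(0.8 / 1.2)

    def test_equal_weights_reduce_to_binary(self):
        g = nx.gnp_random_graph(15, 0.4, seed=3)
        g = nx.relabel_nodes(g, {i: f"N{i}" for i in g})
        nx.set_edge_attributes(g, 0.7, "weight")
        rng = np.random.default_rng(3)
        train = sorted(g.nodes)[:10]
        test = sorted(g.nodes)[10:]
        annots = make_annotations(
            {p: {t for t in (T1, T2) if rng.random() < 0.6} | {T3}
             for p in train}
        )
        unweighted = g.copy()
        nx.set_edge_attributes(unweighted, 1.0, "weight")
        a = gba_weighted(g, annots, test, [T1, T2, T3])
        b = gba_predict(unweighted, annots, test, [T1, T2, T3])
        assert np.allclose(a.to_numpy(), b.to_numpy())

    def test_single_neighbor_any_weight_is_one(self):
        g = nx.Graph()
        g.add_edge("q", "P1", weight=0.05)
        annots = make_annotations({"P1": {T1}})
        pred = gba_weighted(g, annots, ["q"], [T1])
        assert pred.loc["q", T1] == 1.0


class TestSimilarityTransfer:
    def test_max_identity_wins(self):
        annots = make_annotations({"P1": {T1}, "P2": {T1}})
        identity = {("q", "P1"): 0.9, ("q", "P2"): 0.7}
        pred = similarity_transfer(identity, annots, ["q"], [T1])
        assert pred.loc["q", T1] == pytest.approx(0.9)

    def test_no_annotated_hit_is_zero(self):
        annots = make_annotations({"P1": {T2}})
        pred = similarity_transfer({("q", "P1"): 0.9}, annots, ["q"], [T1, T2])
        assert pred.loc["q", T1] == 0.0

    def test_per_term_max(self):
        annots = make_annotations({"P1": {T1}, "P2": {T2}})
        identity = {("q", "P1"): 0.7, ("q", "P2"): 0.9}
        pred = similarity_transfer(identity, annots, ["q"], [T1, T2])
        assert pred.loc["q", T1] == pytest.approx(0.7)
        assert pred.loc["q", T2] == pytest.approx(0.9)

    def test_out_of_range_identity_rejected(self):
        annots = make_annotations({"P1": {T1}})
        with pytest.raises(ValueError):
            similarity_transfer({("q", "P1"): 1.2}, annots, ["q"], [T1])


class TestCombine:
    def _tables(self, a, b):
        idx, cols = ["p"], [T1]
        return (pd.DataFrame([[a]], index=idx, columns=cols),
                pd.DataFrame([[b]], index=idx, columns=cols))

    @pytest.mark.parametrize(
        "a,b,expected", [(0.5, 0.5, 0.75), (0.0, 0.3, 0.3), (1.0, 0.2, 1.0)]
    )
    def test_noisy_or_values(self, a, b, expected):
        p1, p2 = self._tables(a, b)
        assert combine(p1, p2).iloc[0, 0] == pytest.approx(expected)

    @pytest.mark.parametrize("seed", range(3))
    def test_commutative_and_monotone(self, seed):
        rng = np.random.default_rng(seed)
        A = pd.DataFrame(rng.random((4, 3)))
        B = pd.DataFrame(rng.random((4, 3)))
        assert np.allclose(combine(A, B), combine(B, A))
        bigger = combine(A.clip(upper=1.0) ** 0.5, B)  # raising A raises output
        assert (bigger.to_numpy() >= combine(A, B).to_numpy() - 1e-12).all()

    def test_index_mismatch_rejected(self):
        p1 = pd.DataFrame([[0.5]], index=["a"], columns=[T1])
        p2 = pd.DataFrame([[0.5]], index=["b"], columns=[T1])
        with pytest.raises(ValueError):
            combine(p1, p2)


class TestKNN:
    def _embeddings(self):
        tr = pd.DataFrame(
            [[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]], index=["P1", "P2", "P3"]
        )
        te = pd.DataFrame([[0.1, 0.0]], index=["q"])
        return tr, te

    def test_k1_copies_nearest_neighbor(self):
        tr, te = self._embeddings()
        annots = make_annotations({"P1": {T1}, "P2": {T2}, "P3": {T2}})
        pred = knn_predict(tr, annots, te, 1, [T1, T2])
        assert pred.loc["q", T1] == 1.0 and pred.loc["q", T2] == 0.0

    def test_k3_fraction(self):
        tr, te = self._embeddings()
        annots = make_annotations({"P1": {T1}, "P2": {T1}, "P3": {T2}})
        pred = knn_predict(tr, annots, te, 3, [T1, T2])
        assert pred.loc["q", T1] == pytest.approx(2 / 3)

    def test_exact_match_wins_with_k1(self):
        tr, _ = self._embeddings()
        te = pd.DataFrame([[0.0, 1.0]], index=["q"])
        annots = make_annotations({"P1": {T1}, "P2": {T1}, "P3": {T2}})
        pred = knn_predict(tr, annots, te, 1, [T1, T2])
        assert pred.loc["q", T2] == 1.0

    def test_distance_ties_break_by_row_order(self):
        tr = pd.DataFrame([[1.0], [-1.0]], index=["P1", "P2"])
        te = pd.DataFrame([[0.0]], index=["q"])  # equidistant
        annots = make_annotations({"P1": {T1}, "P2": {T2}})
        pred = knn_predict(tr, annots, te, 1, [T1, T2])
        assert pred.loc["q", T1] == 1.0

    def test_k_bounds_enforced(self):
        tr, te = self._embeddings()
        annots = make_annotations({"P1": {T1}, "P2": {T1}, "P3": {T1}})
        with pytest.raises(ValueError):
            knn_predict(tr, annots, te, 4, [T1])

    def test_matches_sklearn_neighbors(self):
        from sklearn.neighbors import NearestNeighbors

        rng = np.random.default_rng(11)
        tr = pd.DataFrame(rng.normal(size=(20, 4)),
                          index=[f"P{i}" for i in range(20)])
        te = pd.DataFrame(rng.normal(size=(6, 4)),
                          index=[f"q{i}" for i in range(6)])
        annots = make_annotations(
            {f"P{i}": ({T1} if i % 2 else {T2}) for i in range(20)}
        )
        pred = knn_predict(tr, annots, te, 5, [T1, T2])
        nn = NearestNeighbors(n_neighbors=5).fit(tr.to_numpy())
        _, idx = nn.kneighbors(te.to_numpy())
        for r, q in enumerate(te.index):
            frac = np.mean([i % 2 == 1 for i in idx[r]])
            assert pred.loc[q, T1] == pytest.approx(frac)


class TestRidge:
    def test_hand_computed_1d(self):
        X = np.array([[1.0], [-1.0]])
        Y = np.array([[1.0], [-1.0]])
        # (X^T X + I)^-1 X^T Y = 2/3 -> s(2/3)
        pred = ridge_fit_predict(X, Y, 1.0, np.array([[1.0]]), center=False)
        assert pred[0, 0] == pytest.approx(1 / (1 + np.exp(-2 / 3)), abs=1e-6)
        assert pred[0, 0] == pytest.approx(0.6608, abs=1e-4)

    def test_large_lambda_shrinks_to_half(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(10, 3))
        Y = np.where(rng.random((10, 2)) < 0.5, 1.0, -1.0)
        pred = ridge_fit_predict(X, Y, 1e9, X, center=False)
        assert np.allclose(pred, 0.5, atol=1e-6)

    def test_lambda_zero_interpolates_square_system(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(4, 4)) + 2 * np.eye(4)
        Y = np.where(rng.random((4, 3)) < 0.5, 1.0, -1.0)
        W = np.linalg.solve(X, Y)  # exact interpolation pre-sigmoid
        pred = ridge_fit_predict(X, Y, 0.0, X, center=False)
        assert np.allclose(pred, 1 / (1 + np.exp(-(X @ W))), atol=1e-8)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_augmented_least_squares(self, seed):
        # oracle: ridge == OLS on X stacked with sqrt(lambda) I
        rng = np.random.default_rng(seed)
        n, d, L, lam = 12, 5, 3, float(rng.uniform(0.1, 5))
        X = rng.normal(size=(n, d))
        Y = np.where(rng.random((n, L)) < 0.5, 1.0, -1.0)
        Xa = np.vstack([X, np.sqrt(lam) * np.eye(d)])
        Ya = np.vstack([Y, np.zeros((d, L))])
        W_oracle, *_ = np.linalg.lstsq(Xa, Ya, rcond=None)
        Xte = rng.normal(size=(4, d))
        pred = ridge_fit_predict(X, Y, lam, Xte, center=False)
        assert np.allclose(pred, 1 / (1 + np.exp(-(Xte @ W_oracle))), atol=1e-8)

    def test_negative_lambda_rejected(self):
        with pytest.raises(ValueError):
            ridge_fit_predict(np.eye(2), np.ones((2, 1)), -1.0, np.eye(2))

    def test_label_matrix_encoding(self):
        annots = make_annotations({"P1": {T1}, "P2": {T2}})
        Y = label_matrix(annots, ["P1", "P2"], [T1, T2])
        assert Y.tolist() == [[1.0, -1.0], [-1.0, 1.0]]


class TestPredictorInvariants:
    @pytest.mark.parametrize("seed", range(3))
    def test_outputs_in_unit_interval_and_hierarchy(self, seed):
        sim = simulate(SimConfig(seed=seed, n_proteins=40, n_terms=15))
        proteins = sorted(sim.annotations.proteins)
        train_ids, test_ids = proteins[:30], proteins[30:]
        train = sim.annotations.subset(train_ids)
        terms = sorted(train.terms)
        for fn in (
            lambda: naive_predict(train, test_ids, terms),
            lambda: gba_predict(sim.network, train, test_ids, terms),
        ):
            pred = fn()
            P = pred.to_numpy()
            assert ((P >= 0) & (P <= 1)).all()
            # propagation nesting implies P(child) <= P(parent)
            for child, parents in sim.ontology.parents.items():
                if child not in pred.columns:
                    continue
                for parent in parents:
                    if parent in pred.columns:
                        assert (
                            pred[child] <= pred[parent] + 1e-12
                        ).all()
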