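"""RCE/KNN classifier emulation: distances, learning rule, interpreters."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from soilmfc import (
    RCEConfig,
    Window,
    WindowedDataset,
    classify_dataset,
    classify_knn,
    classify_rbf,
    distance,
    model_from_json,
    model_to_json,
    train_knn,
    train_rbf,
)
from tests.conftest import make_cluster_dataset


def tiny_dataset(vectors, labels, w=None) -> WindowedDataset:
    w = w or len(vectors[0])
    wins = [Window(np.array(v, float), lab, f"{lab}-{i}", 0) for i, (v, lab) in enumerate(zip(vectors, labels))]
    return WindowedDataset(wins, w)


class TestDistance:
    def test_identical_vectors(self):
        assert distance([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_l1_example(self):
        assert distance([0.0, 0.0], [3.0, 4.0]) == 7.0

    def test_linf(self):
        assert distance([0.0, 0.0], [3.0, 4.0], RCEConfig(distance="Linf")) == 4.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            distance([1.0], [1.0, 2.0])

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.integers(0, 10_000))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(size=6), rng.normal(size=6)
        expected = sum(abs(x - y) for x, y in zip(a, b))
        assert distance(a, b) == pytest.approx(expected)

    def test_quantized_distance_is_integer(self):
        cfg = RCEConfig(quantize_8bit=True, quant_range=(0.0, 10.0))
        d = distance([0.0, 5.0], [10.0, 5.0], cfg)
        assert d == 255.0


class TestTrainRBF:
    def test_single_window_model(self):
        ds = tiny_dataset([[1.0, 2.0, 3.0]], ["A"])
        model = train_rbf(ds, RCEConfig(max_if=10.0, min_if=0.1))
        assert len(model.neurons) == 1
        assert model.neurons[0].aif == 10.0
        assert model.neurons[0].category == "A"

    def test_identical_vectors_conflicting_labels(self):
        """Both prototypes are committed, fields shrink to the floor, and a
        probe at that point is Uncertain (both fire at distance 0)."""
        ds = tiny_dataset([[1.0, 1.0], [1.0, 1.0]], ["A", "B"])
        cfg = RCEConfig(max_if=5.0, min_if=0.01)
        model = train_rbf(ds, cfg, shuffle_seed=0)
        assert len(model.neurons) == 2
        assert all(n.aif == 0.01 for n in model.neurons)
        result = classify_rbf(model, [1.0, 1.0], "dominant")
        assert result.confidence == "Uncertain"

    def test_separated_clusters_classify_training_set(self):
        ds = make_cluster_dataset(separation=100.0, spread=1.0, seed=1)
        model = train_rbf(ds, shuffle_seed=1)
        preds = classify_dataset(model, ds, interpreter="best_match")
        assert all(p.label == t for p, t in zip(preds, ds.labels()))

    def test_best_match_training_recall_is_total(self):
        """After convergence every training vector fires its own prototype at
        distance zero, so Best-Match recall on the training set is 100%."""
        ds = make_cluster_dataset(
            n_per_class=25, separation=12.0, spread=3.0,
            labels=("A", "B", "C"), seed=2,
        )
        model = train_rbf(ds, shuffle_seed=2)
        preds = classify_dataset(model, ds, interpreter="best_match")
        assert all(p.label == t for p, t in zip(preds, ds.labels()))

    def test_aif_never_exceeds_bounds(self):
        ds = make_cluster_dataset(n_per_class=20, separation=5.0, spread=2.0, seed=3)
        model = train_rbf(ds, shuffle_seed=3)
        aifs = model.aif_vector()
        assert np.all(aifs <= model.config.max_if)
        assert np.all(aifs >= model.config.min_if)

    def test_capacity_limit_enforced(self):
        ds = make_cluster_dataset(n_per_class=20, separation=200.0, seed=4)
        with pytest.raises(RuntimeError, match="capacity"):
            train_rbf(ds, RCEConfig(max_if=0.01, min_if=1e-5, max_neurons=10))

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            train_rbf(WindowedDataset([], 4))


class TestClassifyRBF:
    @pytest.fixture
    def abba_model(self):
        """Three neurons at distances 1, 2, 3 from the probe (0,0):
        categories A, A, B, all with fields wide enough to fire."""
        from soilmfc import Neuron, RCEModel

        neurons = [
            Neuron([1.0, 0.0], "A", 10.0, 1),
            Neuron([0.0, 2.0], "A", 10.0, 2),
            Neuron([3.0, 0.0], "B", 10.0, 3),
        ]
        return RCEModel(neurons, RCEConfig(max_if=10.0, min_if=0.001), "RBF", 2, ("A", "B"))

    def test_probe_at_lone_prototype_identified(self):
        ds = tiny_dataset([[2.0, 2.0]], ["A"])
        model = train_rbf(ds, RCEConfig(max_if=5.0, min_if=0.1))
        for interp in ("dominant", "best_match", "unanimous"):
            r = classify_rbf(model, [2.0, 2.0], interp)
            assert (r.label, r.confidence) == ("A", "Identified")
        r = classify_rbf(model, [2.0, 2.0], "min_consensus", min_consensus=1)
        assert (r.label, r.confidence) == ("A", "Identified")

    def test_far_probe_is_unknown(self):
        ds = tiny_dataset([[0.0, 0.0]], ["A"])
        model = train_rbf(ds, RCEConfig(max_if=1.0, min_if=0.1))
        r = classify_rbf(model, [100.0, 100.0], "dominant")
        assert r.label is None
        assert r.confidence == "Unknown"
        assert r.fired == []

    def test_interpreter_truth_table(self, abba_model):
        """Fired categories (A, A, B): Dominant -> A/Uncertain; Unanimous ->
        Unknown; Minimum Consensus m=3 -> Unknown; m=2 -> A; Best Match ->
        nearest neuron's category."""
        probe = [0.0, 0.0]
        dom = classify_rbf(abba_model, probe, "dominant")
        assert (dom.label, dom.confidence) == ("A", "Uncertain")
        assert len(dom.fired) == 3

        bm = classify_rbf(abba_model, probe, "best_match")
        assert bm.label == "A"  # neuron at distance 1

        un = classify_rbf(abba_model, probe, "unanimous")
        assert (un.label, un.confidence) == (None, "Unknown")

        mc3 = classify_rbf(abba_model, probe, "min_consensus", min_consensus=3)
        assert (mc3.label, mc3.confidence) == (None, "Unknown")
        mc2 = classify_rbf(abba_model, probe, "min_consensus", min_consensus=2)
        assert mc2.label == "A"

    def test_min_consensus_requires_quorum_argument(self, abba_model):
        with pytest.raises(ValueError):
            classify_rbf(abba_model, [0.0, 0.0], "min_consensus")

    def test_unknown_interpreter_rejected(self, abba_model):
        with pytest.raises(ValueError):
            classify_rbf(abba_model, [0.0, 0.0], "plurality")

    def test_fired_set_matches_brute_force(self):
        """The fired set equals an explicit scan comparing every neuron's
        distance with its field."""
        ds = make_cluster_dataset(n_per_class=40, separation=8.0, spread=3.0, seed=5)
        model = train_rbf(ds, shuffle_seed=5)
        assert len(model.neurons) <= 200
        rng = np.random.default_rng(6)
        for _ in range(20):
            x = rng.normal(4.0, 6.0, size=ds.w)
            result = classify_rbf(model, x, "dominant")
            expected = sorted(
                (j for j, n in enumerate(model.neurons)
                 if distance(x, n.prototype, model.config) < n.aif),
                key=lambda j: (distance(x, model.neurons[j].prototype, model.config), j),
            )
            assert [j for j, _ in result.fired] == expected

    def test_interpreter_hierarchy(self):
        """Unanimous's labelled outputs are a subset of Dominant's and agree;
        Minimum Consensus m=1 is identical to Dominant."""
        ds = make_cluster_dataset(n_per_class=30, separation=6.0, spread=3.0, seed=7)
        model = train_rbf(ds, shuffle_seed=7)
        probes = make_cluster_dataset(n_per_class=15, separation=6.0, spread=4.0, seed=8)
        for win in probes.windows:
            dom = classify_rbf(model, win.values, "dominant")
            un = classify_rbf(model, win.values, "unanimous")
            mc1 = classify_rbf(model, win.values, "min_consensus", min_consensus=1)
            if un.label is not None:
                assert un.label == dom.label
            assert (mc1.label, mc1.confidence) == (dom.label, dom.confidence)


class TestKNN:
    def test_one_neuron_per_training_window(self):
        ds = make_cluster_dataset(n_per_class=10, seed=9)
        model = train_knn(ds)
        assert len(model.neurons) == len(ds)

    def test_duplicates_preserved(self):
        ds = tiny_dataset([[1.0, 1.0], [1.0, 1.0]], ["A", "A"])
        assert len(train_knn(ds).neurons) == 2

    def test_k1_equals_best_match_over_knn_model(self):
        ds = make_cluster_dataset(n_per_class=25, separation=4.0, spread=3.0, seed=10)
        model = train_knn(ds)
        rng = np.random.default_rng(11)
        for _ in range(25):
            x = rng.normal(2.0, 4.0, size=ds.w)
            k1 = classify_knn(model, x, 1)
            d = [distance(x, n.prototype) for n in model.neurons]
            assert k1.label == model.neurons[int(np.argmin(d))].category

    def test_k1_matches_sklearn_oracle(self):
        sklearn = pytest.importorskip("sklearn.neighbors")
        ds = make_cluster_dataset(n_per_class=30, separation=3.0, spread=2.0, seed=12)
        model = train_knn(ds)
        clf = sklearn.KNeighborsClassifier(n_neighbors=1, metric="manhattan")
        clf.fit(ds.matrix(), ds.labels())
        probes = np.random.default_rng(13).normal(1.5, 3.0, size=(30, ds.w))
        ours = [classify_knn(model, x, 1).label for x in probes]
        theirs = clf.predict(probes)
        assert ours == list(theirs)

    def test_majority_vote_and_confidence(self):
        ds = tiny_dataset([[0.0], [1.0], [1.2]], ["A", "B", "B"], w=1)
        model = train_knn(ds)
        r = classify_knn(model, [0.9], 3)
        assert (r.label, r.confidence) == ("B", "Uncertain")
        r1 = classify_knn(model, [1.1], 2)
        assert (r1.label, r1.confidence) == ("B", "Identified")

    def test_never_unknown(self):
        ds = tiny_dataset([[0.0], [1.0]], ["A", "B"], w=1)
        model = train_knn(ds)
        r = classify_knn(model, [1000.0], 2)
        assert r.confidence in ("Identified", "Uncertain")
        assert r.label is not None

    def test_k_out_of_range_rejected(self):
        ds = tiny_dataset([[0.0], [1.0]], ["A", "B"], w=1)
        model = train_knn(ds)
        with pytest.raises(ValueError):
            classify_knn(model, [0.0], 3)
        with pytest.raises(ValueError):
            classify_knn(model, [0.0], 0)


class TestSerialization:
    @pytest.mark.parametrize("method", ["RBF", "KNN"])
    def test_round_trip_preserves_classifications(self, method):
        ds = make_cluster_dataset(n_per_class=20, separation=6.0, spread=2.0, seed=14)
        model = train_rbf(ds, shuffle_seed=14) if method == "RBF" else train_knn(ds)
        back = model_from_json(model_to_json(model))
        for orig, restored in zip(model.neurons, back.neurons):
            np.testing.assert_array_equal(orig.prototype, restored.prototype)
            assert orig.aif == restored.aif or (np.isinf(orig.aif) and np.isinf(restored.aif))
        probes = make_cluster_dataset(n_per_class=10, separation=6.0, spread=3.0, seed=15)
        for win in probes.windows:
            if method == "RBF":
                a = classify_rbf(model, win.values, "dominant")
                b = classify_rbf(back, win.values, "dominant")
            else:
                a = classify_knn(model, win.values, 3)
                b = classify_knn(back, win.values, 3)
            assert (a.label, a.confidence, a.fired) == (b.label, b.confidence, b.fired)
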