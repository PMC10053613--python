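"""Native k-NN against brute-force and scikit-learn oracles, confusion
metrics, the split protocol and the repeated-run experiment."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.neighbors import KNeighborsClassifier

from woafs import (
    ConfusionCounts,
    FeatureTable,
    KNNConfig,
    KNeighborsMajorityClassifier,
    MetricUndefinedWarning,
    SplitSpec,
    SyntheticSpec,
    WOAConfig,
    euclidean_distance,
    evaluate_classifier,
    generate_feature_table,
    knn_predict,
    make_classifier,
    metrics,
    run_experiment,
)
from woafs.classify import confusion_from_predictions, make_split

from _oracles import knn_oracle


def test_euclidean_distance():
    assert euclidean_distance([0, 0], [3, 4]) == pytest.approx(5.0)
    assert euclidean_distance([2], [5]) == pytest.approx(3.0)
    assert euclidean_distance([1.5, -2], [1.5, -2]) == 0.0
    with pytest.raises(ValueError):
        euclidean_distance([1, 2], [1, 2, 3])


def test_knn_predict_hand_examples():
    train = FeatureTable(
        np.array([[0.0], [1.0], [10.0], [11.0]]), np.array([1, 1, 2, 2]),
        ["f0"],
    )
    assert knn_predict(train, [0.5], KNNConfig(k=3)) == 1  # votes 2-1
    assert knn_predict(train, [10.4], KNNConfig(k=1)) == 2
    assert knn_predict(train, [11.0], KNNConfig(k=1)) == 2  # exact training point


def test_knn_matches_sklearn(rng):
    X = rng.normal(size=(40, 6))
    y = np.where(rng.random(40) < 0.5, 1, 2)
    Q = rng.normal(size=(30, 6))
    for k in (1, 3, 5, 7):
        ours = KNeighborsMajorityClassifier(k=k).fit(X, y).predict(Q)
        ref = KNeighborsClassifier(n_neighbors=k).fit(X, y).predict(Q)
        np.testing.assert_array_equal(ours, ref)


def test_knn_even_k_tie_break_distance_then_label():
    # two neighbours each side; class 2's neighbours are closer
    X = np.array([[0.0], [1.0], [3.1], [4.0]])
    y = np.array([1, 1, 2, 2])
    clf = KNeighborsMajorityClassifier(k=4).fit(X, y)
    assert clf.predict(np.array([[2.1]]))[0] == 2
    # perfectly symmetric tie falls to the lowest label
    X = np.array([[-1.0], [-2.0], [1.0], [2.0]])
    clf = KNeighborsMajorityClassifier(k=4).fit(X, y)
    assert clf.predict(np.array([[0.0]]))[0] == 1


def test_knn_proba_is_vote_fraction(rng):
    X = rng.normal(size=(25, 3))
    y = np.where(rng.random(25) < 0.5, 1, 2)
    clf = KNeighborsMajorityClassifier(k=5).fit(X, y)
    proba = clf.predict_proba(rng.normal(size=(10, 3)))
    assert np.allclose(proba.sum(axis=1), 1.0)
    assert set(np.round(np.unique(proba * 5)).astype(int)) <= {0, 1, 2, 3, 4, 5}


def test_knn_k_exceeding_train_rejected():
    X, y = np.zeros((3, 2)), np.array([1, 2, 1])
    with pytest.raises(ValueError, match="k=5"):
        KNeighborsMajorityClassifier(k=5).fit(X, y)
    with pytest.raises(ValueError):
        KNNConfig(k=0)


def test_metrics_hand_computations():
    m = metrics(ConfusionCounts(tp=99, fn=1, tn=98, fp=2))
    assert m.sensitivity == pytest.approx(0.99)
    assert m.specificity == pytest.approx(0.98)
    assert m.accuracy == pytest.approx(0.985)
    perfect = metrics(ConfusionCounts(tp=10, tn=10, fp=0, fn=0))
    assert (perfect.accuracy, perfect.sensitivity, perfect.specificity) == (1, 1, 1)


def test_undefined_metric_flagged_not_zero():
    with pytest.warns(MetricUndefinedWarning, match="sensitivity"):
        m = metrics(ConfusionCounts(tp=0, fn=0, tn=5, fp=5))
    assert np.isnan(m.sensitivity)
    assert m.specificity == pytest.approx(0.5)


@given(
    st.integers(1, 500), st.integers(1, 500), st.integers(0, 500), st.integers(0, 500)
)
@settings(derandomize=True, max_examples=100)
def test_metric_identity(tp, tn, fp, fn):
    c = ConfusionCounts(tp, tn, fp, fn)
    m = metrics(c)
    P, N = tp + fn, tn + fp
    assert m.accuracy == pytest.approx((m.sensitivity * P + m.specificity * N) / (P + N))


def test_stratified_split_preserves_proportions():
    y = np.array([1] * 70 + [2] * 30)
    (tr, te), = make_split(y, SplitSpec(test_size=0.2, seed=0))
    assert abs((y[tr] == 1).sum() - 56) <= 1
    assert abs((y[te] == 1).sum() - 14) <= 1
    assert len(tr) + len(te) == 100


@pytest.mark.parametrize("name", ["knn", "lda", "dt", "rf", "lr"])
def test_separable_table_perfect_for_every_classifier(name):
    spec = SyntheticSpec(
        n_samples=120, n_features=6, informative_idx=(0, 1), effect_size=10.0,
        redundancy_pairs=(), seed=31,
    )
    t = generate_feature_table(spec)
    counts, auc = evaluate_classifier(t, np.ones(6, dtype=int), name, SplitSpec(seed=2), seed=2)
    assert counts.fp == 0 and counts.fn == 0
    assert auc == pytest.approx(1.0)


def test_shuffled_labels_chance_level():
    spec = SyntheticSpec(
        n_samples=400, n_features=10, informative_idx=(0,), effect_size=0.0,
        redundancy_pairs=(), seed=13,
    )
    t = generate_feature_table(spec)
    counts, auc = evaluate_classifier(t, np.ones(10, dtype=int), "knn", SplitSpec(seed=1))
    acc = (counts.tp + counts.tn) / counts.total
    assert 0.3 < acc < 0.7
    assert 0.0 <= auc <= 1.0


def test_evaluate_classifier_matches_knn_oracle(standard_table):
    split = SplitSpec(seed=8)
    mask = np.ones(40, dtype=int)
    counts, _ = evaluate_classifier(standard_table, mask, "knn", split)
    (tr, te), = make_split(standard_table.y, split)
    preds = [
        knn_oracle(standard_table.X[tr], standard_table.y[tr], q, k=5)
        for q in standard_table.X[te]
    ]
    oracle_counts = confusion_from_predictions(standard_table.y[te], np.array(preds))
    assert counts == oracle_counts


def test_unknown_classifier_rejected():
    with pytest.raises(ValueError, match="unknown classifier"):
        make_classifier("svm")


def test_run_experiment_single_run_and_determinism(small_table):
    cfg = WOAConfig(n_agents=8, max_iter=8, seed=5)
    rep1 = run_experiment(small_table, cfg, "knn", n_runs=1)
    agg = rep1.aggregate()
    assert rep1.n_runs == 1
    assert agg["accuracy"][1] == 0.0  # single run: SD reported as 0
    assert agg["accuracy"][0] == rep1.per_run[0].accuracy

    rep2 = run_experiment(small_table, cfg, "knn", n_runs=3)
    rep3 = run_experiment(small_table, cfg, "knn", n_runs=3)
    assert rep2.to_dict() == rep3.to_dict()


def test_experiment_aggregate_recomputable(small_table):
    cfg = WOAConfig(n_agents=6, max_iter=6, seed=4)
    rep = run_experiment(small_table, cfg, "knn", n_runs=4)
    accs = [r.accuracy for r in rep.per_run]
    m, s = rep.aggregate()["accuracy"]
    assert m == pytest.approx(np.mean(accs))
    assert s == pytest.approx(np.std(accs, ddof=1))
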