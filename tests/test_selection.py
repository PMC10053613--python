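"""Binarization, the subset cost, mask evaluation and the full wrapper loop."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.base import clone
from sklearn.pipeline import Pipeline

from woafs import (
    FeatureTable,
    KNeighborsMajorityClassifier,
    SplitSpec,
    SyntheticSpec,
    WOAConfig,
    WOAFeatureSelector,
    binarize,
    evaluate_mask,
    fitness,
    generate_feature_table,
    select_features,
    sigmoid_transfer,
)
from woafs.classify import make_split

from _oracles import knn_error_oracle


def test_sigmoid_values():
    assert sigmoid_transfer(0.0) == pytest.approx(0.5)
    assert sigmoid_transfer(1.0) == pytest.approx(1 / (1 + np.exp(-1.0)), abs=1e-12)
    assert sigmoid_transfer(2.0) > sigmoid_transfer(1.0)  # strictly increasing


@given(st.floats(-30, 30))
@settings(derandomize=True, max_examples=100)
def test_sigmoid_symmetry(x):
    assert sigmoid_transfer(x) + sigmoid_transfer(-x) == pytest.approx(1.0, abs=1e-12)


def test_binarize_threshold_convention():
    # sigmoid(0.847...) ~ 0.7 >= 0.5 -> selected; 0.3 < 0.5 -> not
    pos = np.array([np.log(0.7 / 0.3), np.log(0.3 / 0.7)])
    np.testing.assert_array_equal(binarize(pos, np.array([0.5, 0.5])), [1, 0])
    # the boundary counts as selected
    pos = np.array([0.4, -1.2, 2.0])
    np.testing.assert_array_equal(binarize(pos, sigmoid_transfer(pos)), [1, 1, 1])
    with pytest.raises(ValueError):
        binarize(np.zeros(3), np.zeros(2))


def test_fitness_arithmetic():
    fb = fitness(0.2, 31, 68, weight_error=0.99)
    assert fb.cost == pytest.approx(0.99 * 0.2 + 0.01 * (31 / 68), abs=1e-12)
    # zero-error limit isolates the ratio term
    assert fitness(0.0, 1, 68).cost == pytest.approx(0.01 * (1 / 68), abs=1e-12)
    # worst case: weights sum to 1
    assert fitness(1.0, 68, 68).cost == pytest.approx(1.0, abs=1e-12)


def test_fitness_rejects_bad_inputs():
    with pytest.raises(ValueError):
        fitness(0.1, 0, 10)  # empty subset never scored
    with pytest.raises(ValueError):
        fitness(0.1, 3, 10, weight_error=0.8, weight_ratio=0.3)
    with pytest.raises(ValueError):
        fitness(1.2, 3, 10)


def test_evaluate_mask_matches_brute_force_knn():
    spec = SyntheticSpec(
        n_samples=1000, n_features=12, informative_idx=(0, 1, 2), effect_size=3.0,
        redundancy_pairs=(), seed=21,
    )
    t = generate_feature_table(spec)
    mask = np.zeros(12, dtype=int)
    mask[:3] = 1
    split = SplitSpec(seed=5)
    fb = evaluate_mask(mask, t, "knn", split)
    assert fb.error_rate < 0.05
    (tr, te), = make_split(t.y, split)
    err = knn_error_oracle(t.X[np.ix_(tr, [0, 1, 2])], t.y[tr],
                           t.X[np.ix_(te, [0, 1, 2])], t.y[te], k=5)
    assert fb.error_rate == pytest.approx(err, abs=1e-12)
    assert fb.cost == pytest.approx(0.99 * err + 0.01 * 3 / 12, abs=1e-12)


def test_evaluate_mask_noise_columns_near_chance_and_deterministic(standard_table):
    mask = np.zeros(40, dtype=int)
    mask[10:14] = 1  # pure-noise columns
    split = SplitSpec(seed=3)
    fb1 = evaluate_mask(mask, standard_table, "knn", split)
    fb2 = evaluate_mask(mask, standard_table, "knn", split)
    assert fb1 == fb2
    assert 0.25 < fb1.error_rate < 0.75


def test_select_single_feature_table_forced_mask():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(60, 1))
    y = np.where(rng.random(60) < 0.5, 1, 2)
    X[y == 1] += 2.0
    t = FeatureTable(X, y, ["f0"])
    for seed in (0, 5):
        res = select_features(t, WOAConfig(n_agents=4, max_iter=5, seed=seed))
        np.testing.assert_array_equal(res.best_mask, [1])


def test_degenerate_budget_single_agent_single_iteration(small_table):
    res = select_features(small_table, WOAConfig(n_agents=1, max_iter=1, seed=9))
    assert len(res.convergence) == 1
    assert res.convergence[0] == res.best_fitness
    assert res.evaluations == 1


def test_selection_beats_all_features_and_random_masks(standard_table):
    """The returned mask's cost must be no worse than the full mask and the
    best of 500 random masks scored on the identical split."""
    split = SplitSpec(seed=17)
    cfg = WOAConfig(n_agents=30, max_iter=60, seed=17)
    res = select_features(standard_table, cfg, "knn", split)
    assert all(a >= b for a, b in zip(res.convergence, res.convergence[1:]))
    assert len(res.convergence) == cfg.max_iter
    assert res.best_mask.sum() >= 1

    full = evaluate_mask(np.ones(40, dtype=int), standard_table, "knn", split)
    assert res.best_fitness <= full.cost + 1e-12

    rng = np.random.default_rng(99)
    best_random = np.inf
    for _ in range(500):
        m = (rng.random(40) < 0.5).astype(int)
        if m.sum() == 0:
            m[rng.integers(40)] = 1
        best_random = min(
            best_random, evaluate_mask(m, standard_table, "knn", split).cost
        )
    assert res.best_fitness <= best_random + 1e-12


def test_redundant_duplicate_column_dropped():
    """With a perfect duplicate of an informative column and any positive
    ratio weight, the optimum keeps only one copy."""
    rng = np.random.default_rng(12)
    n = 200
    y = np.where(rng.random(n) < 0.5, 1, 2)
    X = rng.normal(size=(n, 2))
    X[:, 0] += np.where(y == 1, 1.5, -1.5)
    X[:, 1] = X[:, 0]  # exact duplicate: any mask has identical k-NN error
    t = FeatureTable(X, y, ["f0", "f1"])
    hits = 0
    for seed in range(10):
        res = select_features(t, WOAConfig(n_agents=20, max_iter=40, seed=seed))
        if res.best_mask.sum() == 1:
            hits += 1
    assert hits >= 8


def test_selector_estimator_api(standard_table):
    sel = WOAFeatureSelector(n_agents=10, max_iter=10, random_state=0)
    assert clone(sel).get_params() == sel.get_params()
    sel.fit(standard_table.X, standard_table.y)
    support = sel.get_support()
    assert support.dtype == bool and support.shape == (40,)
    Xt = sel.transform(standard_table.X)
    assert Xt.shape == (300, int(support.sum()))
    assert sel.best_fitness_ == min(sel.convergence_)

    pipe = Pipeline(
        [
            ("select", WOAFeatureSelector(n_agents=8, max_iter=6, random_state=1)),
            ("clf", KNeighborsMajorityClassifier()),
        ]
    )
    pipe.fit(standard_table.X, standard_table.y)
    assert pipe.score(standard_table.X, standard_table.y) > 0.8


def test_selector_requires_two_classes(standard_table):
    sel = WOAFeatureSelector(max_iter=2)
    with pytest.raises(ValueError, match="two classes"):
        sel.fit(standard_table.X, np.ones(300))
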