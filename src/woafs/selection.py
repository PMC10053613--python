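"""Binary wrapper feature selection with the whale optimization algorithm.

A whale's continuous position is mapped through the s-shaped (sigmoid)
transfer function and thresholded against per-dimension uniform draws to
give a binary feature mask. Each mask is scored by the wrapper cost

    cost = rho * Err + (1 - rho) * |F| / |T|

where Err is the held-out error rate of the wrapper classifier trained on
the selected columns, |F| the number of selected features and |T| the
total. With the default rho = 0.99 classification error dominates and the
selection-ratio term acts as a small pressure toward compact subsets. The
cost is minimized by the continuous WOA of :mod:`woafs.woa`.

An all-zero mask is repaired by setting one uniformly random bit: the cost
is undefined at |F| = 0 and a classifier needs at least one feature. The
train/test split is drawn once per run (stratified 80/20 by default), so
identical masks within a run share one exact cached evaluation.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any

import numpy as np
from scipy.special import expit
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted, validate_data

from .classify import SplitSpec, confusion_from_predictions, make_classifier, make_split
from .io import FeatureTable
from .woa import WOAConfig, decay_a, woa_step

__all__ = [
    "FitnessBreakdown",
    "SelectionResult",
    "sigmoid_transfer",
    "binarize",
    "fitness",
    "evaluate_mask",
    "select_features",
    "WOAFeatureSelector",
]


def sigmoid_transfer(x):
    """S-shaped transfer 1/(1 + e^{-x}), mapping positions to (0, 1)."""
    return expit(x)


def binarize(position: np.ndarray, thresholds: np.ndarray) -> np.ndarray:
    """Threshold the transferred position against uniform draws.

    bit_i = 1 iff sigmoid(position_i) >= threshold_i (the boundary counts
    as selected).
    """
    position = np.asarray(position, dtype=float)
    thresholds = np.asarray(thresholds, dtype=float)
    if position.shape != thresholds.shape:
        raise ValueError("position and thresholds must have the same length")
    return (sigmoid_transfer(position) >= thresholds).astype(np.int8)


@dataclasses.dataclass(frozen=True)
class FitnessBreakdown:
    """Components of one wrapper-cost evaluation (lower cost is better)."""

    error_rate: float
    n_selected: int
    n_total: int
    cost: float


def fitness(
    error_rate: float,
    n_selected: int,
    n_total: int,
    weight_error: float = 0.99,
    weight_ratio: float | None = None,
) -> FitnessBreakdown:
    """Weighted sum of error rate and selection ratio (minimized).

    The two weights must sum to 1; by default the ratio weight is the
    complement of ``weight_error``.
    """
    if weight_ratio is None:
        weight_ratio = 1.0 - weight_error
    if abs(weight_error + weight_ratio - 1.0) > 1e-12:
        raise ValueError("weights must sum to 1")
    if not 0.0 <= error_rate <= 1.0:
        raise ValueError("error_rate must lie in [0, 1]")
    if n_selected < 1:
        raise ValueError("an empty feature subset is never scored (repair first)")
    if n_selected > n_total:
        raise ValueError("n_selected cannot exceed n_total")
    cost = weight_error * error_rate + weight_ratio * (n_selected / n_total)
    return FitnessBreakdown(error_rate, int(n_selected), int(n_total), float(cost))


def evaluate_mask(
    mask: np.ndarray,
    table: FeatureTable,
    classifier_spec: Any = "knn",
    split: SplitSpec = SplitSpec(),
    seed: int | None = None,
    weight_error: float = 0.99,
) -> FitnessBreakdown:
    """Score one feature mask by held-out wrapper error plus subset ratio.

    Trains the wrapper classifier on the training partition restricted to
    the selected columns and computes Err = 1 - accuracy on the held-out
    partition (averaged over folds when ``split.n_folds`` is set).
    """
    mask = np.asarray(mask).astype(bool)
    if mask.shape != (table.n_features,):
        raise ValueError("mask length must match the number of features")
    if mask.sum() == 0:
        raise ValueError("mask selects no features")
    sub = table.restrict(mask)
    errs = []
    for tr, te in make_split(sub.y, split):
        clf = make_classifier(classifier_spec, random_state=seed)
        clf.fit(sub.X[tr], sub.y[tr])
        c = confusion_from_predictions(sub.y[te], clf.predict(sub.X[te]))
        errs.append(1.0 - (c.tp + c.tn) / c.total)
    return fitness(float(np.mean(errs)), int(mask.sum()), table.n_features, weight_error)


@dataclasses.dataclass
class SelectionResult:
    """Outcome of one WOA feature-selection run."""

    best_mask: np.ndarray
    best_fitness: float
    convergence: list[float]
    evaluations: int
    seed: int | None
    position_extremes: tuple[float, float] | None = None

    def to_dict(self) -> dict:
        return {
            "best_mask": [int(b) for b in self.best_mask],
            "best_fitness": self.best_fitness,
            "convergence": list(self.convergence),
            "evaluations": self.evaluations,
            "seed": self.seed,
        }

    def save_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")

    def save_convergence_csv(self, path: str | Path) -> None:
        lines = ["iteration,best_fitness"]
        lines += [f"{t},{v!r}" for t, v in enumerate(self.convergence)]
        Path(path).write_text("\n".join(lines) + "\n")


def _repair_mask(mask: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    if mask.sum() == 0:
        mask = mask.copy()
        mask[int(rng.integers(len(mask)))] = 1
    return mask


def select_features(
    table: FeatureTable,
    cfg: WOAConfig = WOAConfig(),
    classifier_spec: Any = "knn",
    split: SplitSpec | None = None,
) -> SelectionResult:
    """Run the full binary-WOA wrapper loop on a feature table.

    Per iteration: binarize every agent's position (fresh per-dimension
    thresholds), repair empty masks, evaluate each mask (cached — the split
    is fixed for the run), update the elitist leader, record the best-so-far
    cost, then advance positions by one WOA step. The convergence curve has
    exactly ``cfg.max_iter`` entries and is monotone non-increasing.
    """
    if table.n_features < 1:
        raise ValueError("table has no features")
    rng = np.random.default_rng(cfg.seed)
    if split is None:
        split = SplitSpec(seed=int(rng.integers(2**31)))
    clf_seed = int(rng.integers(2**31))

    n_dim = table.n_features
    positions = rng.uniform(cfg.lb, cfg.ub, (cfg.n_agents, n_dim))
    cache: dict[bytes, FitnessBreakdown] = {}
    evaluations = 0
    best_fit = np.inf
    best_mask = np.zeros(n_dim, dtype=np.int8)
    leader_pos = positions[0].copy()
    convergence: list[float] = []
    pos_min, pos_max = float(positions.min()), float(positions.max())

    for t in range(cfg.max_iter):
        for i in range(cfg.n_agents):
            thresholds = rng.random(n_dim)
            mask = _repair_mask(binarize(positions[i], thresholds), rng)
            key = mask.tobytes()
            fb = cache.get(key)
            if fb is None:
                fb = evaluate_mask(
                    mask, table, classifier_spec, split, clf_seed, cfg.weight_error
                )
                cache[key] = fb
                evaluations += 1
            if fb.cost < best_fit:
                best_fit = fb.cost
                best_mask = mask.copy()
                leader_pos = positions[i].copy()
        convergence.append(best_fit)
        positions = woa_step(positions, leader_pos, decay_a(t, cfg.max_iter), cfg, rng)
        pos_min = min(pos_min, float(positions.min()))
        pos_max = max(pos_max, float(positions.max()))

    return SelectionResult(
        best_mask=best_mask,
        best_fitness=float(best_fit),
        convergence=convergence,
        evaluations=evaluations,
        seed=cfg.seed,
        position_extremes=(pos_min, pos_max),
    )


class WOAFeatureSelector(SelectorMixin, BaseEstimator):
    """scikit-learn transformer wrapping binary-WOA feature selection.

    Parameters mirror :class:`woafs.woa.WOAConfig` plus the wrapper
    classifier and split; after ``fit`` the selected columns are exposed
    through the standard ``get_support()`` / ``transform`` interface, so the
    selector composes with pipelines and model selection.

    Attributes
    ----------
    support_ : bool ndarray of shape (n_features,)
        Selected-feature mask of the best whale found.
    best_fitness_ : float
        Wrapper cost of ``support_``.
    convergence_ : list of float
        Best-so-far cost per iteration (monotone non-increasing).
    n_evaluations_ : int
        Distinct wrapper evaluations performed (cache misses).

    Examples
    --------
    >>> from woafs import SyntheticSpec, generate_feature_table
    >>> t = generate_feature_table(SyntheticSpec(seed=3))
    >>> sel = WOAFeatureSelector(max_iter=10, random_state=0).fit(t.X, t.y)
    >>> sel.transform(t.X).shape[1] == sel.get_support().sum()
    True
    """

    def __init__(
        self,
        estimator: Any = "knn",
        n_agents: int = 30,
        max_iter: int = 100,
        b: float = 1.0,
        weight_error: float = 0.99,
        lb: float = -4.0,
        ub: float = 4.0,
        p_threshold: float = 0.5,
        test_size: float = 0.2,
        n_folds: int | None = None,
        random_state: int | None = None,
    ):
        self.estimator = estimator
        self.n_agents = n_agents
        self.max_iter = max_iter
        self.b = b
        self.weight_error = weight_error
        self.lb = lb
        self.ub = ub
        self.p_threshold = p_threshold
        self.test_size = test_size
        self.n_folds = n_folds
        self.random_state = random_state

    def fit(self, X, y):
        X, y = validate_data(self, X, y)
        classes = np.unique(y)
        if len(classes) != 2:
            raise ValueError("WOAFeatureSelector requires exactly two classes")
        mapping = {classes[0]: 1, classes[1]: 2}
        y12 = np.where(y == classes[0], 1, 2)
        table = FeatureTable(
            X, y12, [f"f{j}" for j in range(X.shape[1])], mapping
        )
        seed = self.random_state
        if seed is None:
            seed = int(np.random.SeedSequence().generate_state(1)[0] & 0x7FFFFFFF)
        cfg = WOAConfig(
            n_agents=self.n_agents,
            max_iter=self.max_iter,
            b=self.b,
            weight_error=self.weight_error,
            lb=self.lb,
            ub=self.ub,
            p_threshold=self.p_threshold,
            seed=seed,
        )
        split = SplitSpec(test_size=self.test_size, n_folds=self.n_folds, seed=seed)
        result = select_features(table, cfg, self.estimator, split)
        self.support_ = result.best_mask.astype(bool)
        self.best_fitness_ = result.best_fitness
        self.convergence_ = result.convergence
        self.n_evaluations_ = result.evaluations
        self.selection_result_ = result
        return self

    def _get_support_mask(self):
        check_is_fitted(self)
        return self.support_
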