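"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the package's own code paths: plain python sorts
and exhaustive enumeration only.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def knn_oracle(train_X, train_y, query, k: int) -> int:
    """Exhaustive distance-sort k-NN with the package's documented tie rule:
    majority vote; vote ties go to the tied class with the smaller summed
    neighbour distance, then to the lowest label."""
    dists = []
    for row, label in zip(train_X, train_y):
        d = math.sqrt(sum((a - b) ** 2 for a, b in zip(row, query)))
        dists.append((d, int(label)))
    dists.sort(key=lambda t: t[0])
    neigh = dists[:k]
    votes: dict[int, int] = {}
    sums: dict[int, float] = {}
    for d, lab in neigh:
        votes[lab] = votes.get(lab, 0) + 1
        sums[lab] = sums.get(lab, 0.0) + d
    top = max(votes.values())
    tied = sorted(lab for lab, v in votes.items() if v == top)
    return min(tied, key=lambda lab: (sums[lab], lab))


def knn_error_oracle(X_train, y_train, X_test, y_test, k: int) -> float:
    wrong = sum(
        knn_oracle(X_train, y_train, q, k) != int(t) for q, t in zip(X_test, y_test)
    )
    return wrong / len(y_test)


def enumerate_subset_costs(
    X_train, y_train, X_test, y_test, k: int, weight_error: float = 0.99
):
    """Cost of every non-empty feature subset under the fixed split.

    Returns a dict mapping the subset (as a tuple of column indices) to its
    wrapper cost rho*Err + (1-rho)*|F|/|T|.
    """
    n_total = X_train.shape[1]
    costs = {}
    for size in range(1, n_total + 1):
        for cols in itertools.combinations(range(n_total), size):
            cols_arr = list(cols)
            err = knn_error_oracle(
                X_train[:, cols_arr], y_train, X_test[:, cols_arr], y_test, k
            )
            costs[cols] = weight_error * err + (1 - weight_error) * size / n_total
    return costs


def class_mean_gaps(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Absolute between-class column mean differences (plain arithmetic)."""
    X = np.asarray(X, float)
    y = np.asarray(y)
    return np.abs(X[y == 1].mean(axis=0) - X[y == 2].mean(axis=0))
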