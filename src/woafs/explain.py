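"""Local surrogate (LIME-style) explanations and selection-frequency analysis.

``lime_explain`` follows the canonical tabular recipe: perturb one instance
with Gaussian noise scaled by the training-set per-feature SDs, score the
perturbations with the black-box classifier, weight them by an exponential
proximity kernel on standardized distance, and fit a weighted ridge
surrogate on the few most relevant features. The signed ridge coefficients
(on standardized features) are the reported per-feature contributions to
the class-1 probability.

``feature_frequency`` counts how often each feature is selected across
repeated optimization runs — the "dominant channel" analysis used to argue
that particular electrodes carry the discriminative signal.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import Ridge

__all__ = [
    "TrainStats",
    "Explanation",
    "FrequencyTable",
    "lime_explain",
    "contribution_heatmap",
    "feature_frequency",
]


@dataclasses.dataclass(frozen=True)
class TrainStats:
    """Per-feature means, SDs and quartile bin edges of the training data."""

    means: np.ndarray
    sds: np.ndarray
    quartiles: np.ndarray  # (3, n_features): 25/50/75th percentiles
    feature_names: tuple[str, ...]

    @classmethod
    def from_data(cls, X: np.ndarray, feature_names: Sequence[str] | None = None) -> "TrainStats":
        X = np.asarray(X, dtype=float)
        if feature_names is None:
            feature_names = [f"f{j}" for j in range(X.shape[1])]
        return cls(
            means=X.mean(axis=0),
            sds=X.std(axis=0),
            quartiles=np.percentile(X, [25, 50, 75], axis=0),
            feature_names=tuple(feature_names),
        )

    def range_condition(self, j: int, value: float) -> str:
        """Human-readable quartile bin of ``value`` for feature ``j``."""
        q1, q2, q3 = self.quartiles[:, j]
        name = self.feature_names[j]
        if value <= q1:
            return f"{name} <= {q1:.3g}"
        if value <= q2:
            return f"{q1:.3g} < {name} <= {q2:.3g}"
        if value <= q3:
            return f"{q2:.3g} < {name} <= {q3:.3g}"
        return f"{name} > {q3:.3g}"


@dataclasses.dataclass
class Explanation:
    """Signed local feature contributions for one instance.

    ``contributions`` is a list of (feature_name, weight, feature_value,
    range_condition), sorted by decreasing |weight| and truncated to the
    requested top_k. ``degenerate`` marks a constant black-box score, in
    which case every weight is zero.
    """

    instance_id: str
    class_probability: float
    contributions: list[tuple[str, float, float, str]]
    feature_names: tuple[str, ...]
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "instance_id": self.instance_id,
            "class_probability": self.class_probability,
            "degenerate": self.degenerate,
            "contributions": [
                {"feature": f, "weight": w, "value": v, "condition": c}
                for f, w, v, c in self.contributions
            ],
        }

    def weight_vector(self) -> np.ndarray:
        """Contribution per feature over the full feature set (0 if absent)."""
        w = np.zeros(len(self.feature_names))
        index = {n: j for j, n in enumerate(self.feature_names)}
        for f, weight, _, _ in self.contributions:
            w[index[f]] = weight
        return w


def lime_explain(
    predict_proba: Callable[[np.ndarray], np.ndarray],
    train_stats: TrainStats,
    instance: np.ndarray,
    n_perturb: int = 1000,
    kernel_width: float | None = None,
    top_k: int = 10,
    seed: int | None = None,
    instance_id: str = "instance",
    ridge_alpha: float = 1.0,
) -> Explanation:
    """Fit a weighted sparse linear surrogate around one prediction.

    ``predict_proba`` must map an (n, d) array to the class-1 probability of
    each row. Perturbations are Gaussian around the instance with the
    training SDs; a feature with zero training SD is never perturbed and
    receives a contribution of exactly 0. Proximity weights use
    exp(-d^2 / w^2) on standardized Euclidean distance with default
    w = 0.75 * sqrt(n_features). Identical seeds give identical output.
    """
    if n_perturb < 50:
        raise ValueError("n_perturb must be >= 50 for a stable surrogate")
    instance = np.asarray(instance, dtype=float)
    d = len(train_stats.feature_names)
    if instance.shape != (d,):
        raise ValueError("instance length must match the training feature set")
    rng = np.random.default_rng(seed)
    if kernel_width is None:
        kernel_width = 0.75 * np.sqrt(d)

    # a numerically constant feature (SD ~ 0 up to rounding) is never
    # perturbed, so its contribution is exactly zero
    tol = 1e-9 * np.maximum(1.0, np.abs(train_stats.means))
    sds = np.where(train_stats.sds > tol, train_stats.sds, 0.0)
    Z = instance + rng.standard_normal((n_perturb, d)) * sds
    Z[0] = instance  # keep the instance itself in the neighbourhood

    f = np.asarray(predict_proba(Z), dtype=float).reshape(n_perturb)
    prob = float(np.asarray(predict_proba(instance.reshape(1, -1))).reshape(()))

    varying = sds > 0
    if not np.any(varying) or float(np.ptp(f)) < 1e-12:
        warnings.warn(
            "black-box score is constant over the neighbourhood; "
            "surrogate is degenerate, returning zero weights",
            UserWarning,
            stacklevel=2,
        )
        return Explanation(instance_id, prob, [], train_stats.feature_names, degenerate=True)

    # standardized neighbourhood and proximity kernel
    sds_safe = np.where(varying, sds, 1.0)
    U = (Z - instance) / sds_safe
    dist = np.sqrt(np.sum(U[:, varying] ** 2, axis=1))
    w = np.exp(-(dist**2) / kernel_width**2)

    # pick top_k features by |weighted correlation| with the score
    wsum = w.sum()
    f_c = f - np.average(f, weights=w)
    U_c = U - np.average(U, axis=0, weights=w)[None, :]
    cov = (w[:, None] * U_c * f_c[:, None]).sum(axis=0) / wsum
    var_u = (w[:, None] * U_c**2).sum(axis=0) / wsum
    var_f = (w * f_c**2).sum() / wsum
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(var_u > 0, cov / np.sqrt(var_u * var_f), 0.0)
    corr[~varying] = 0.0
    k = min(top_k, int(varying.sum()))
    chosen = np.sort(np.argsort(-np.abs(corr), kind="stable")[:k])

    surrogate = Ridge(alpha=ridge_alpha)
    surrogate.fit(U[:, chosen], f, sample_weight=w)
    weights = surrogate.coef_

    order = np.argsort(-np.abs(weights), kind="stable")
    contributions = [
        (
            train_stats.feature_names[chosen[i]],
            float(weights[i]),
            float(instance[chosen[i]]),
            train_stats.range_condition(int(chosen[i]), float(instance[chosen[i]])),
        )
        for i in order
    ]
    return Explanation(instance_id, prob, contributions, train_stats.feature_names)


def contribution_heatmap(
    explanations: Sequence[Explanation],
    classes: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Stack explanations into an (instances x features) contribution matrix.

    When per-instance class labels are given, rows are grouped class-1 block
    first, then class-2 (stable within a block). The returned frame carries
    a trailing ``class`` column when classes are supplied; all-zero rows are
    preserved.
    """
    if not explanations:
        raise ValueError("no explanations to stack")
    names = explanations[0].feature_names
    for e in explanations:
        if e.feature_names != names:
            raise ValueError("explanations cover inconsistent feature sets")
    M = np.vstack([e.weight_vector() for e in explanations])
    ids = [e.instance_id for e in explanations]
    df = pd.DataFrame(M, columns=list(names), index=ids)
    if classes is not None:
        classes = np.asarray(classes)
        if len(classes) != len(explanations):
            raise ValueError("one class label per explanation required")
        order = np.argsort(classes, kind="stable")
        df = df.iloc[order]
        df["class"] = classes[order]
    return df


@dataclasses.dataclass
class FrequencyTable:
    """How many of ``n_runs`` selection runs chose each feature."""

    counts: np.ndarray
    n_runs: int
    feature_names: tuple[str, ...] | None = None

    def to_dataframe(self) -> pd.DataFrame:
        names = self.feature_names or tuple(f"f{j}" for j in range(len(self.counts)))
        df = pd.DataFrame({"feature": list(names), "count": self.counts.astype(int)})
        return df.sort_values(["count", "feature"], ascending=[False, True], kind="stable"
                              ).reset_index(drop=True)

    def save_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def feature_frequency(
    masks: Sequence[np.ndarray],
    feature_names: Sequence[str] | None = None,
) -> FrequencyTable:
    """Count, per feature, the runs whose selected mask contains it."""
    if len(masks) == 0:
        raise ValueError("at least one mask is required")
    M = np.asarray([np.asarray(m).astype(int) for m in masks])
    if M.ndim != 2:
        raise ValueError("masks must all have the same length")
    counts = M.sum(axis=0)
    names = tuple(feature_names) if feature_names is not None else None
    if names is not None and len(names) != M.shape[1]:
        raise ValueError("feature_names length must match mask length")
    return FrequencyTable(counts=counts, n_runs=M.shape[0], feature_names=names)


def save_explanations_json(explanations: Sequence[Explanation], path: str | Path) -> None:
    payload = [e.to_dict() for e in explanations]
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
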