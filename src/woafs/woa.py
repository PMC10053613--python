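"""Continuous whale optimization algorithm (WOA) core.

WOA is a population metaheuristic modelled on humpback bubble-net hunting.
Each agent (whale) holds a continuous position vector and, per iteration,
moves by one of three rules:

* encircling — step toward the best position found so far (the leader X*),
  ``X <- X* - A ∘ |C ∘ X* - X|``;
* spiral — a logarithmic helix around the leader,
  ``X <- |X* - X| · e^{b·l} · cos(2πl) + X*``;
* exploration — step relative to a randomly chosen agent instead of the
  leader, ``X <- X_rand - A ∘ |C ∘ X_rand - X|``.

The spiral branch is taken with probability 1/2 (draw p); otherwise the
magnitude of coefficient A decides between encircling (|A| < 1, exploit)
and exploration (|A| >= 1). A = 2a·r - a with r ~ U[0,1] per dimension and
a decaying linearly from 2 to 0 over the iteration budget, so the search
shifts from exploration to exploitation. Coefficient vectors are drawn per
dimension; the scalar branch test uses the first component of A, which
keeps the branch probabilities of the scalar formulation.

Positions are clipped to a box [lb, ub] after every update. The leader is
elitist: it only ever improves.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "WOAConfig",
    "SearchAgent",
    "decay_a",
    "compute_coefficients",
    "encircling_update",
    "spiral_update",
    "exploration_update",
    "woa_step",
    "minimize",
]

_DEFAULT_LB = -4.0
_DEFAULT_UB = 4.0


@dataclasses.dataclass
class WOAConfig:
    """Knobs of the optimizer and of the feature-subset cost.

    ``weight_error`` (rho) weighs the wrapper classification error and
    ``weight_ratio`` = 1 - rho weighs the selected-feature ratio in the
    subset cost; the default 0.99 makes error dominate. Bounds default to
    [-4, 4] so the sigmoid transfer spans roughly (0.018, 0.982) — wider
    boxes saturate the transfer and freeze the binary masks.
    """

    n_agents: int = 30
    max_iter: int = 100
    b: float = 1.0
    weight_error: float = 0.99
    lb: float = _DEFAULT_LB
    ub: float = _DEFAULT_UB
    p_threshold: float = 0.5
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_agents < 1:
            raise ValueError("n_agents must be >= 1")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if not self.lb < self.ub:
            raise ValueError("require lb < ub")
        if not 0.0 <= self.weight_error <= 1.0:
            raise ValueError("weight_error must lie in [0, 1]")

    @property
    def weight_ratio(self) -> float:
        return 1.0 - self.weight_error


@dataclasses.dataclass
class SearchAgent:
    """One whale: continuous position, derived binary mask, cached cost."""

    position: np.ndarray
    binary_mask: np.ndarray | None = None
    fitness: float = np.inf


def decay_a(iter_index: int, max_iter: int) -> float:
    """Linear schedule a = 2·(1 - t/T), from 2 at t=0 down to 0 at t=T."""
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    if not 0 <= iter_index <= max_iter:
        raise ValueError("iter_index must lie in [0, max_iter]")
    return 2.0 * (1.0 - iter_index / max_iter)


def compute_coefficients(a: float, r: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """A = 2a·r - a and C = 2·r, componentwise, for r ~ U[0,1]."""
    r = np.asarray(r, dtype=float)
    return 2.0 * a * r - a, 2.0 * r


def _check_lengths(*vecs: np.ndarray) -> None:
    n = {np.asarray(v).shape for v in vecs}
    if len(n) != 1:
        raise ValueError("all vectors must have the same length")


def encircling_update(
    X: np.ndarray,
    X_star: np.ndarray,
    A: np.ndarray,
    C: np.ndarray,
    lb: float = _DEFAULT_LB,
    ub: float = _DEFAULT_UB,
) -> np.ndarray:
    """Shrinking-encircling step toward the leader, clipped to [lb, ub]."""
    X, X_star, A, C = map(np.asarray, (X, X_star, A, C))
    _check_lengths(X, X_star, A, C)
    D = np.abs(C * X_star - X)
    return np.clip(X_star - A * D, lb, ub)


def spiral_update(
    X: np.ndarray,
    X_star: np.ndarray,
    l: float,
    b: float = 1.0,
    lb: float = _DEFAULT_LB,
    ub: float = _DEFAULT_UB,
) -> np.ndarray:
    """Logarithmic-spiral (bubble-net) step around the leader."""
    X, X_star = np.asarray(X), np.asarray(X_star)
    _check_lengths(X, X_star)
    D = np.abs(X_star - X)
    return np.clip(D * np.exp(b * l) * np.cos(2.0 * np.pi * l) + X_star, lb, ub)


def exploration_update(
    X: np.ndarray,
    X_rand: np.ndarray,
    A: np.ndarray,
    C: np.ndarray,
    lb: float = _DEFAULT_LB,
    ub: float = _DEFAULT_UB,
) -> np.ndarray:
    """Search step relative to a random agent instead of the leader."""
    X, X_rand, A, C = map(np.asarray, (X, X_rand, A, C))
    _check_lengths(X, X_rand, A, C)
    D = np.abs(C * X_rand - X)
    return np.clip(X_rand - A * D, lb, ub)


def woa_step(
    positions: np.ndarray,
    x_star: np.ndarray,
    a: float,
    cfg: WOAConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Advance every agent by one iteration of the three-rule update.

    Per agent: fresh per-dimension draw r (giving vectors A and C), scalar
    l ~ U[-1, 1] and branch draw p ~ U[0, 1]. Spiral when p >= p_threshold;
    otherwise encircle when |A| < 1 (first component) and explore toward a
    random other agent when |A| >= 1.
    """
    positions = np.asarray(positions, dtype=float)
    if positions.ndim != 2 or positions.shape[0] < 1:
        raise ValueError("positions must be a non-empty (n_agents x n_dim) array")
    n_agents, n_dim = positions.shape
    new = np.empty_like(positions)
    for i in range(n_agents):
        r = rng.random(n_dim)
        A, C = compute_coefficients(a, r)
        l = rng.uniform(-1.0, 1.0)
        p = rng.random()
        if p >= cfg.p_threshold:
            new[i] = spiral_update(positions[i], x_star, l, cfg.b, cfg.lb, cfg.ub)
        elif abs(A[0]) < 1.0:
            new[i] = encircling_update(positions[i], x_star, A, C, cfg.lb, cfg.ub)
        else:
            j = int(rng.integers(n_agents))
            if n_agents > 1:
                while j == i:
                    j = int(rng.integers(n_agents))
            new[i] = exploration_update(positions[i], positions[j], A, C, cfg.lb, cfg.ub)
    return new


def minimize(
    objective: Callable[[np.ndarray], float],
    n_dim: int,
    cfg: WOAConfig,
) -> tuple[np.ndarray, float, list[float]]:
    """Run continuous WOA on ``objective`` and return (best_x, best_f, curve).

    The curve holds the best-so-far objective after each of the ``max_iter``
    iterations and is monotone non-increasing by elitism.
    """
    if n_dim < 1:
        raise ValueError("n_dim must be >= 1")
    rng = np.random.default_rng(cfg.seed)
    positions = rng.uniform(cfg.lb, cfg.ub, (cfg.n_agents, n_dim))
    best_x = positions[0].copy()
    best_f = np.inf
    curve: list[float] = []
    for t in range(cfg.max_iter):
        for i in range(cfg.n_agents):
            f = float(objective(positions[i]))
            if f < best_f:
                best_f, best_x = f, positions[i].copy()
        curve.append(best_f)
        positions = woa_step(positions, best_x, decay_a(t, cfg.max_iter), cfg, rng)
    return best_x, best_f, curve
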