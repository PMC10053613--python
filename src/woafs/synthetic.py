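"""Synthetic two-class feature tables with a known informative subset.

Real motor-imagery BCI experiments yield a trials x channels feature table
in which only a handful of electrode channels carry class-discriminative
signal. The generator here emulates exactly that structure — a few columns
with a class-conditional mean shift, optional noisy-copy redundant columns,
and pure-noise columns — so that feature recovery, classification and
explanation can all be verified against known ground truth without any
external recording.

Noise model: class-conditional Gaussian with unit within-class standard
deviation, so ``effect_size`` reads directly as the standardised mean
separation (Cohen's d) of an informative column.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path

import numpy as np

from .io import FeatureTable, write_feature_csv, write_sidecar

__all__ = [
    "SyntheticSpec",
    "generate_feature_table",
    "generate_toy_epochs",
    "extract_channel_features",
    "write_synthetic",
]

# Standard fixture: 40 channels of which 5 discriminate at effect size 2.0,
# plus 3 redundant near-copies emulating neighbouring electrodes
# (copy = source + N(0, 0.5^2), i.e. source-copy correlation ~ 0.89).
_DEFAULT_REDUNDANCY = ((0, 37, 0.5), (1, 38, 0.5), (2, 39, 0.5))


@dataclasses.dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for a two-class feature table with known informative columns.

    Parameters
    ----------
    n_samples, n_features : int
        Table dimensions; both must be positive.
    informative_idx : tuple of int
        Columns carrying a class-conditional mean shift.
    effect_size : float
        Standardised mean separation of informative columns, in units of the
        within-class SD (which is 1). Zero erases all signal.
    class_balance : float
        Expected fraction of class-1 samples, in (0, 1).
    redundancy_pairs : tuple of (source, copy, noise_sd)
        Each copy column is overwritten with source + N(0, noise_sd^2).
    seed : int
        Controls every random draw; identical spec => identical table.
    """

    n_samples: int = 300
    n_features: int = 40
    informative_idx: tuple[int, ...] = (0, 1, 2, 3, 4)
    effect_size: float = 2.0
    class_balance: float = 0.5
    redundancy_pairs: tuple[tuple[int, int, float], ...] = _DEFAULT_REDUNDANCY
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1 or self.n_features < 1:
            raise ValueError("n_samples and n_features must be positive")
        info = set(self.informative_idx)
        if not info <= set(range(self.n_features)):
            raise ValueError("informative_idx out of range")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if not 0 < self.class_balance < 1:
            raise ValueError("class_balance must lie in (0, 1)")
        for src, copy, noise_sd in self.redundancy_pairs:
            if not (0 <= src < self.n_features and 0 <= copy < self.n_features):
                raise ValueError("redundancy index out of range")
            if copy in info:
                raise ValueError("a redundant copy may not be an informative column")
            if copy == src:
                raise ValueError("a column cannot copy itself")
            if noise_sd < 0:
                raise ValueError("redundancy noise_sd must be >= 0")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["informative_idx"] = sorted(self.informative_idx)
        d["redundancy_pairs"] = [list(p) for p in self.redundancy_pairs]
        return d


def generate_feature_table(spec: SyntheticSpec) -> FeatureTable:
    """Draw a feature table according to ``spec``.

    Class-1 informative columns are shifted by +effect_size/2 and class-2 by
    -effect_size/2 around zero, so the between-class separation is exactly
    ``effect_size`` within-class SDs in expectation.
    """
    rng = np.random.default_rng(spec.seed)
    y = np.where(rng.random(spec.n_samples) < spec.class_balance, 1, 2)
    X = rng.standard_normal((spec.n_samples, spec.n_features))
    half = spec.effect_size / 2.0
    for j in spec.informative_idx:
        X[:, j] += np.where(y == 1, half, -half)
    for src, copy, noise_sd in spec.redundancy_pairs:
        X[:, copy] = X[:, src] + rng.normal(0.0, noise_sd, spec.n_samples)
    names = [f"f{j}" for j in range(spec.n_features)]
    return FeatureTable(X, y, names)


def generate_toy_epochs(
    n_epochs: int,
    n_channels: int,
    n_timepoints: int,
    discriminative_channels: set[int] | tuple[int, ...] = (),
    seed: int = 0,
    power_ratio: float = 3.0,
    class_balance: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate labelled multichannel epochs with class-dependent band power.

    Every channel carries unit-variance Gaussian noise. On the discriminative
    channels, class-1 epochs additionally carry a fixed-frequency sinusoid
    with random phase whose amplitude is chosen so the expected total power is
    ``power_ratio`` times the baseline — the minimal caricature of an
    event-related band-power change.

    Returns ``(epochs, labels)`` with epochs shaped
    (n_epochs, n_channels, n_timepoints) and labels in {1, 2}.
    """
    if n_epochs < 1 or n_channels < 1 or n_timepoints < 2:
        raise ValueError("epoch dimensions must be positive (>= 2 timepoints)")
    disc = sorted(set(discriminative_channels))
    if disc and not (0 <= min(disc) and max(disc) < n_channels):
        raise ValueError("discriminative channel index out of range")
    if power_ratio < 1:
        raise ValueError("power_ratio must be >= 1")
    rng = np.random.default_rng(seed)
    labels = np.where(rng.random(n_epochs) < class_balance, 1, 2)
    epochs = rng.standard_normal((n_epochs, n_channels, n_timepoints))
    # amplitude so that 1 + amp^2/2 = power_ratio
    amp = np.sqrt(2.0 * (power_ratio - 1.0))
    t = np.arange(n_timepoints)
    for i in np.flatnonzero(labels == 1):
        for ch in disc:
            phase = rng.uniform(0, 2 * np.pi)
            epochs[i, ch] += amp * np.sin(2 * np.pi * 0.1 * t + phase)
    return epochs, labels


def extract_channel_features(
    epochs: np.ndarray,
    labels: np.ndarray,
    var_floor: float = 1e-12,
) -> FeatureTable:
    """Reduce epochs to one log-variance feature per channel.

    A channel whose within-epoch variance falls below ``var_floor`` (e.g. a
    constant-zero recording) is clamped to the floor and a warning is issued,
    since its log-power is otherwise undefined.
    """
    epochs = np.asarray(epochs, dtype=float)
    if epochs.ndim != 3:
        raise ValueError("epochs must be 3-D (epochs x channels x timepoints)")
    var = epochs.var(axis=2)
    if (var < var_floor).any():
        warnings.warn(
            "degenerate (near-constant) epoch channel: variance clamped to floor",
            UserWarning,
            stacklevel=2,
        )
        var = np.maximum(var, var_floor)
    names = [f"ch{j}" for j in range(epochs.shape[1])]
    return FeatureTable(np.log(var), np.asarray(labels), names)


def write_synthetic(table: FeatureTable, spec: SyntheticSpec, csv_path: str | Path) -> None:
    """Write the table as CSV plus a JSON sidecar recording the ground truth."""
    csv_path = Path(csv_path)
    write_feature_csv(table, csv_path)
    write_sidecar(csv_path.with_suffix(".json"), {"spec": spec.to_dict()})
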