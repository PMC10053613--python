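"""Repeated-run experiment protocol and mean ± SD reporting.

Metaheuristic selection is stochastic, so a single run is not evidence.
The protocol here repeats selection + evaluation over independent derived
seeds (20 runs by default, matching common practice for this family of
wrapper methods) and reports each metric as mean ± SD, retaining the
per-run masks for downstream selection-frequency analysis. Per-run seeds
derive deterministically from the master seed, and the same run seed is
used for every classifier arm, so cross-classifier comparisons are paired.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .classify import SplitSpec, evaluate_classifier, metrics
from .io import FeatureTable
from .selection import SelectionResult, select_features
from .woa import WOAConfig

__all__ = ["RunRecord", "ExperimentReport", "derive_seeds", "run_experiment", "compare_classifiers"]

METRIC_NAMES = ("accuracy", "sensitivity", "specificity", "auc")


def derive_seeds(master_seed: int | None, n: int) -> list[int]:
    """Deterministically spawn ``n`` per-run seeds (each < 2^31) from a master."""
    ss = np.random.SeedSequence(master_seed)
    return [int(s) & 0x7FFFFFFF for s in ss.generate_state(n, dtype=np.uint32)]


@dataclasses.dataclass
class RunRecord:
    seed: int
    accuracy: float
    sensitivity: float
    specificity: float
    auc: float
    mask: np.ndarray
    best_fitness: float
    convergence: list[float]
    position_extremes: tuple[float, float] | None = None

    def metric(self, name: str) -> float:
        return getattr(self, name)


@dataclasses.dataclass
class ExperimentReport:
    """Per-run records plus mean ± SD aggregates over the runs."""

    per_run: list[RunRecord]
    classifier: str
    master_seed: int | None

    @property
    def n_runs(self) -> int:
        return len(self.per_run)

    @property
    def masks(self) -> list[np.ndarray]:
        return [r.mask for r in self.per_run]

    def aggregate(self) -> dict[str, tuple[float, float]]:
        """Mean and SD of each metric (sample SD; 0 for a single run)."""
        out = {}
        for name in METRIC_NAMES:
            vals = np.array([r.metric(name) for r in self.per_run], dtype=float)
            sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
            out[name] = (float(np.mean(vals)), sd)
        return out

    def to_dict(self) -> dict:
        return {
            "classifier": self.classifier,
            "master_seed": self.master_seed,
            "n_runs": self.n_runs,
            "aggregate": {k: {"mean": m, "sd": s} for k, (m, s) in self.aggregate().items()},
            "per_run": [
                {
                    "seed": r.seed,
                    "accuracy": r.accuracy,
                    "sensitivity": r.sensitivity,
                    "specificity": r.specificity,
                    "auc": r.auc,
                    "best_fitness": r.best_fitness,
                    "mask": [int(b) for b in r.mask],
                    "convergence": list(r.convergence),
                }
                for r in self.per_run
            ],
        }

    def save_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")

    def summary_row(self) -> dict[str, str]:
        agg = self.aggregate()
        row = {"classifier": self.classifier}
        for name in METRIC_NAMES:
            m, s = agg[name]
            row[name] = f"{m:.4f} ± {s:.4f}" if not math.isnan(m) else "undefined"
        return row


def run_experiment(
    table: FeatureTable,
    cfg: WOAConfig = WOAConfig(),
    classifier_spec: Any = "knn",
    n_runs: int = 20,
    test_size: float = 0.2,
) -> ExperimentReport:
    """Repeat (select features, evaluate held-out metrics) ``n_runs`` times.

    Each run r uses a seed derived from ``cfg.seed``; the stratified split
    is fixed within a run and shared between the selection loop and the
    final evaluation, so the reported metrics describe the same held-out
    partition the wrapper optimized against.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    records = []
    for run_seed in derive_seeds(cfg.seed, n_runs):
        run_cfg = dataclasses.replace(cfg, seed=run_seed)
        split = SplitSpec(test_size=test_size, seed=run_seed)
        sel: SelectionResult = select_features(table, run_cfg, classifier_spec, split)
        counts, auc = evaluate_classifier(table, sel.best_mask, classifier_spec, split, run_seed)
        m = metrics(counts)
        records.append(
            RunRecord(
                seed=run_seed,
                accuracy=m.accuracy,
                sensitivity=m.sensitivity,
                specificity=m.specificity,
                auc=auc,
                mask=sel.best_mask,
                best_fitness=sel.best_fitness,
                convergence=sel.convergence,
                position_extremes=sel.position_extremes,
            )
        )
    name = classifier_spec if isinstance(classifier_spec, str) else type(classifier_spec).__name__
    return ExperimentReport(records, classifier=str(name), master_seed=cfg.seed)


def compare_classifiers(
    table: FeatureTable,
    cfg: WOAConfig = WOAConfig(),
    classifier_specs: tuple[str, ...] = ("knn", "lda", "dt", "rf", "lr"),
    n_runs: int = 20,
    test_size: float = 0.2,
) -> tuple[dict[str, ExperimentReport], pd.DataFrame]:
    """Run the protocol once per classifier (paired seeds) and tabulate.

    Returns the per-classifier reports and a summary table with one row per
    classifier and "mean ± sd" cells for accuracy / sensitivity /
    specificity / AUC.
    """
    reports = {
        str(spec): run_experiment(table, cfg, spec, n_runs, test_size)
        for spec in classifier_specs
    }
    summary = pd.DataFrame([r.summary_row() for r in reports.values()])
    return reports, summary
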