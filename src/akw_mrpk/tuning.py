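"""Hyperparameter grid search and evaluation metrics.

The grid search tunes the regularization parameter RP, the polynomial
degree d and the kernel coefficient r by stratified k-fold
cross-validation, scoring each triple by mean fold accuracy.  Ties are
broken towards the simpler model: smaller d, then smaller RP, then
smaller r, which also makes the result invariant to grid enumeration
order.

Metrics: computational time CT is the sum of per-patient prediction
times (milliseconds), speedup the ratio of single-node to cluster time,
and accuracy the percentage of correct predictions.  Timing quantities
are measured and reported only — they are hardware-dependent and never
asserted against published tables.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .datasets import TRAIN, LabeledDataset, to_keyed_instances
from .svm import KernelParams, train_svm


@dataclass(frozen=True)
class GridSpec:
    """Candidate grids for (RP, d, r) and the cross-validation layout."""

    rp_grid: tuple[float, ...] = (1e-3, 1e-2, 1e-1, 1.0, 10.0)
    d_grid: tuple[int, ...] = (2, 3, 4, 5)
    r_grid: tuple[float, ...] = (0.0, 0.5, 1.0)
    folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.rp_grid and self.d_grid and self.r_grid):
            raise ValueError("all parameter grids must be nonempty")
        if self.folds < 2:
            raise ValueError("cross-validation needs at least 2 folds")


@dataclass(frozen=True)
class GridSearchResult:
    best_rp: float
    best_d: int
    best_r: float
    table: pd.DataFrame  # one row per triple: rp, d, r, mean_accuracy

    @property
    def best(self) -> tuple[float, int, float]:
        return (self.best_rp, self.best_d, self.best_r)


@dataclass(frozen=True)
class MetricsReport:
    """Timing and accuracy summary of one prediction run."""

    ct_ms: float  # total computational time CT
    per_patient_ms: tuple[float, ...]
    n_patients: int
    correct: int
    total: int
    accuracy_pct: float
    speedup: float | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "ct_ms": self.ct_ms,
                    "n_patients": self.n_patients,
                    "correct": self.correct,
                    "total": self.total,
                    "accuracy_pct": self.accuracy_pct,
                    "speedup": self.speedup,
                }
            ]
        )


def accuracy(correct: int, total: int) -> float:
    """A = 100 * correct / total, in percent."""
    if total < 1:
        raise ValueError("total must be at least 1")
    if not 0 <= correct <= total:
        raise ValueError("correct must lie in [0, total]")
    return 100.0 * correct / total


def computational_time(per_patient_times_ms: Sequence[float]) -> float:
    """CT = sum of per-patient prediction times (ms)."""
    return float(np.sum(np.asarray(per_patient_times_ms, dtype=float))) if len(per_patient_times_ms) else 0.0


def speedup(ct_one_ms: float, ct_cluster_ms: float) -> float:
    """Single-node time divided by cluster time."""
    if ct_one_ms <= 0 or ct_cluster_ms <= 0:
        raise ValueError("speedup needs strictly positive timings")
    return ct_one_ms / ct_cluster_ms


def stratified_folds(
    labels: Sequence[int], k: int, seed: int = 0
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Seeded stratified k-fold split; class ratios match within one sample.

    Returns (train_indices, test_indices) pairs covering every row exactly
    once as a test member.
    """
    labels = np.asarray(labels)
    if k < 2:
        raise ValueError("need at least 2 folds")
    counts = {c: int((labels == c).sum()) for c in np.unique(labels)}
    if min(counts.values()) < k:
        raise ValueError(
            f"fold count {k} exceeds the smallest class size {min(counts.values())}"
        )
    rng = np.random.default_rng(seed)
    fold_members: list[list[int]] = [[] for _ in range(k)]
    for c in sorted(counts):
        idx = np.flatnonzero(labels == c)
        idx = idx[rng.permutation(idx.size)]
        for pos, row in enumerate(idx):
            fold_members[pos % k].append(int(row))
    folds = []
    all_rows = np.arange(labels.size)
    for members in fold_members:
        test_idx = np.sort(np.array(members, dtype=int))
        train_idx = np.setdiff1d(all_rows, test_idx)
        folds.append((train_idx, test_idx))
    return folds


def _cv_accuracy(
    dataset: LabeledDataset,
    folds: Sequence[tuple[np.ndarray, np.ndarray]],
    rp: float,
    params: KernelParams,
    tol: float,
    max_passes: int,
) -> float:
    targets = np.where(dataset.labels == 1, 1, -1)
    fold_accs = []
    for train_idx, test_idx in folds:
        train_ds = dataset.take_rows(train_idx)
        instances = to_keyed_instances(train_ds, [TRAIN] * train_ds.n_samples)
        model = train_svm(instances, rp, params, tol=tol, max_passes=max_passes)
        preds = model.predict(dataset.values[test_idx])
        fold_accs.append(float((preds == targets[test_idx]).mean()))
    return float(np.mean(fold_accs))


def grid_search(
    dataset: LabeledDataset,
    grid: GridSpec,
    tol: float = 1e-3,
    max_passes: int = 100,
) -> GridSearchResult:
    """Exhaustive CV search over (RP, d, r); best = highest mean accuracy.

    The folds are fixed once per call (seeded), so every triple is scored
    on identical splits.  Ties prefer smaller d, then RP, then r.
    """
    folds = stratified_folds(dataset.labels, grid.folds, grid.seed)
    rows = []
    for rp, d, r in itertools.product(grid.rp_grid, grid.d_grid, grid.r_grid):
        params = KernelParams(r=r, d=d)
        acc = _cv_accuracy(dataset, folds, rp, params, tol, max_passes)
        rows.append({"rp": rp, "d": d, "r": r, "mean_accuracy": acc})
    table = pd.DataFrame(rows)
    best = min(rows, key=lambda row: (-row["mean_accuracy"], row["d"], row["rp"], row["r"]))
    return GridSearchResult(
        best_rp=float(best["rp"]),
        best_d=int(best["d"]),
        best_r=float(best["r"]),
        table=table,
    )
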