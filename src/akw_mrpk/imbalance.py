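"""Class-imbalance preprocessing: SMOTE-style oversampling, undersampling
and inverse-frequency class weighting.

The three strategies are mutually exclusive alternatives; each rebalances
the minority (diabetic) class against the majority either by synthesizing
minority rows on segments between nearest minority neighbours, by
subsampling the majority, or by leaving the data untouched and weighting
the classifier's per-sample box constraints instead.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .datasets import LabeledDataset
from .errors import ConfigError

STRATEGIES = ("oversample", "undersample", "weights", "none")


@dataclass(frozen=True)
class BalancePlan:
    """How to rebalance classes before selection and classification.

    ``target_ratio`` is the minority:majority proportion after balancing
    (1.0 = fully balanced).  ``forced_lam`` pins the SMOTE interpolation
    weight instead of drawing it uniformly from (0, 1); useful for
    reproducing a specific synthetic row.
    """

    strategy: str = "none"
    target_ratio: float = 1.0
    k_neighbors: int = 5
    seed: int = 0
    forced_lam: float | None = None

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ConfigError(f"unknown balance strategy {self.strategy!r}")
        if not 0.0 < self.target_ratio <= 1.0:
            raise ConfigError("target_ratio must lie in (0, 1]")
        if self.k_neighbors < 1:
            raise ConfigError("k_neighbors must be >= 1")
        if self.forced_lam is not None and not 0.0 <= self.forced_lam <= 1.0:
            raise ConfigError("forced_lam must lie in [0, 1]")


def smote_interpolate(p, q, lam: float) -> np.ndarray:
    """Linear interpolation ``p + lam * (q - p)`` between two feature vectors."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("parent vectors must have the same length")
    if not 0.0 <= lam <= 1.0:
        raise ValueError("interpolation weight must lie in [0, 1]")
    return p + lam * (q - p)


def _split_classes(dataset: LabeledDataset) -> tuple[int, int, np.ndarray, np.ndarray]:
    """Return (minority_label, majority_label, minority_rows, majority_rows).

    On an exact tie the diabetic class (label 1) is treated as the minority.
    """
    counts = dataset.class_counts()
    if counts[0] == 0 or counts[1] == 0:
        raise ValueError("both classes must be present")
    minority = 1 if counts[1] <= counts[0] else 0
    majority = 1 - minority
    return (
        minority,
        majority,
        np.flatnonzero(dataset.labels == minority),
        np.flatnonzero(dataset.labels == majority),
    )


def oversample_minority(dataset: LabeledDataset, plan: BalancePlan) -> LabeledDataset:
    """Append SMOTE rows until minority:majority equals ``target_ratio``.

    Each synthetic row interpolates a seeded-random minority sample towards
    one of its ``k_neighbors`` nearest minority neighbours (Euclidean), so
    it always lies componentwise inside its parents' bounding box.  The
    synthetic count is rounded up: ceil(target_ratio * n_majority) -
    n_minority.  Existing rows are never removed.
    """
    minority, _, min_rows, maj_rows = _split_classes(dataset)
    if min_rows.size < 2:
        raise ValueError("SMOTE needs at least two minority samples")
    n_synthetic = math.ceil(plan.target_ratio * maj_rows.size) - min_rows.size
    if n_synthetic <= 0:
        return dataset

    rng = np.random.default_rng(plan.seed)
    base = dataset.values[min_rows]
    k = min(plan.k_neighbors, min_rows.size - 1)
    dist = cdist(base, base)
    np.fill_diagonal(dist, np.inf)
    # neighbour index table: k nearest minority neighbours of each minority row
    neighbours = np.argsort(dist, axis=1, kind="stable")[:, :k]

    synthetic = np.empty((n_synthetic, dataset.n_attributes))
    for s in range(n_synthetic):
        i = rng.integers(min_rows.size)
        j = neighbours[i, rng.integers(k)]
        lam = plan.forced_lam if plan.forced_lam is not None else rng.uniform()
        synthetic[s] = smote_interpolate(base[i], base[j], lam)

    values = np.vstack([dataset.values, synthetic])
    labels = np.concatenate([dataset.labels, np.full(n_synthetic, minority, dtype=int)])
    return dataclasses.replace(dataset, values=values, labels=labels)


def undersample_majority(dataset: LabeledDataset, plan: BalancePlan) -> LabeledDataset:
    """Uniformly subsample majority rows so minority:majority = target_ratio.

    Minority rows are untouched; surviving rows keep their original order.
    Requesting a ratio below the current one (which would require *adding*
    majority rows) is an error.
    """
    _, _, min_rows, maj_rows = _split_classes(dataset)
    n_keep = int(round(min_rows.size / plan.target_ratio))
    if n_keep > maj_rows.size:
        raise ValueError(
            "target_ratio unreachable by removing majority rows only "
            f"(need {n_keep} majority rows, have {maj_rows.size})"
        )
    rng = np.random.default_rng(plan.seed)
    kept_majority = rng.choice(maj_rows, size=n_keep, replace=False)
    keep = np.sort(np.concatenate([min_rows, kept_majority]))
    return dataset.take_rows(keep)


def class_weights(dataset: LabeledDataset) -> dict[int, float]:
    """Inverse-frequency weights w_c = N / (2 * N_c), one per label.

    The weighted class masses then agree exactly: w+ * N+ = w- * N- = N/2.
    """
    counts = dataset.class_counts()
    if counts[0] == 0 or counts[1] == 0:
        raise ValueError("class weights need both classes present")
    n = dataset.n_samples
    return {c: n / (2.0 * counts[c]) for c in (0, 1)}


def apply_balance(
    dataset: LabeledDataset, plan: BalancePlan
) -> tuple[LabeledDataset, dict[int, float] | None]:
    """Execute a balance plan; returns (dataset, class weight map or None)."""
    if plan.strategy == "none":
        return dataset, None
    if plan.strategy == "oversample":
        return oversample_minority(dataset, plan), None
    if plan.strategy == "undersample":
        return undersample_majority(dataset, plan), None
    return dataset, class_weights(dataset)
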