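"""End-to-end orchestration: load -> normalize -> split -> balance ->
select -> (tune) -> map/reduce classify -> metrics.

The stage ordering mirrors the method's workflow: class rebalancing feeds
the Associative Kruskal-Wallis selector, whose retained attributes feed
the polynomial-kernel classifier.  A stratified train/test split is drawn
right after normalization so that rebalancing and selection only ever see
training rows — synthetic minority samples never leak into the held-out
evaluation.  Every stage failure is re-raised with the stage name in the
message, and a fixed seed makes the whole run (selection report, CV table,
prediction file) reproducible byte for byte.
"""

from __future__ import annotations

import time
from contextlib import contextmanager
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .datasets import (
    TEST,
    TRAIN,
    KeyedInstance,
    LabeledDataset,
    SyntheticConfig,
    generate_synthetic,
    normalize,
    read_pima_csv,
    write_predictions,
)
from .errors import PipelineError
from .imbalance import BalancePlan, apply_balance
from .mapreduce import JobConfig, run_mrpk
from .selection import SelectionResult, select_features
from .svm import KernelParams
from .tuning import GridSearchResult, GridSpec, MetricsReport, accuracy, grid_search, speedup


@dataclass(frozen=True)
class PipelineConfig:
    """Full run description; either ``csv_path`` or ``synthetic`` feeds it."""

    csv_path: str | None = None
    label_column: str = "Outcome"
    impute_zero_codes: bool = False
    synthetic: SyntheticConfig | None = None
    balance: BalancePlan = field(default_factory=BalancePlan)
    n_drop: int = 2
    grid: GridSpec | None = None  # None -> use the fixed (rp, kernel) below
    rp: float = 1.0
    kernel: KernelParams = field(default_factory=lambda: KernelParams(r=1.0, d=2))
    test_fraction: float = 0.3
    n_mappers: int = 2
    backend: str = "serial"
    tol: float = 1e-3
    max_passes: int = 100
    seed: int = 0
    measure_speedup: bool = False
    outdir: str | None = None


@dataclass(frozen=True)
class PipelineResult:
    selection: SelectionResult
    predictions: dict[int, int]  # test key -> +1/-1
    metrics: MetricsReport
    grid_result: GridSearchResult | None
    rp: float
    kernel: KernelParams
    test_keys: tuple[int, ...]


@contextmanager
def _stage(name: str):
    try:
        yield
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        raise PipelineError(f"stage {name!r}: {exc}") from exc


def stratified_split(
    labels: np.ndarray, test_fraction: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Seeded stratified split; returns (train_rows, test_rows)."""
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must lie strictly in (0, 1)")
    rng = np.random.default_rng(seed)
    test_rows = []
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        idx = idx[rng.permutation(idx.size)]
        n_test = int(round(idx.size * test_fraction))
        n_test = min(max(n_test, 1), idx.size - 1)
        test_rows.append(idx[:n_test])
    test_rows = np.sort(np.concatenate(test_rows))
    train_rows = np.setdiff1d(np.arange(labels.size), test_rows)
    return train_rows, test_rows


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    with _stage("load"):
        if config.csv_path is not None:
            dataset = read_pima_csv(
                config.csv_path,
                label_column=config.label_column,
                impute_zero_codes=config.impute_zero_codes,
            )
        elif config.synthetic is not None:
            dataset = generate_synthetic(config.synthetic)
        else:
            raise ValueError("config needs either csv_path or synthetic")

    with _stage("normalize"):
        dataset, _ = normalize(dataset)

    with _stage("split"):
        train_rows, test_rows = stratified_split(
            dataset.labels, config.test_fraction, config.seed
        )
        train_ds = dataset.take_rows(train_rows)
        test_ds = dataset.take_rows(test_rows)

    with _stage("balance"):
        train_ds, weights = apply_balance(train_ds, config.balance)

    with _stage("select"):
        selection = select_features(train_ds, n_drop=config.n_drop)
        train_sel = train_ds.select_attributes(selection.selected)
        test_sel = test_ds.select_attributes(selection.selected)

    grid_result = None
    rp, kernel = config.rp, config.kernel
    if config.grid is not None:
        with _stage("tune"):
            grid_result = grid_search(
                train_sel, config.grid, tol=config.tol, max_passes=config.max_passes
            )
            rp = grid_result.best_rp
            kernel = KernelParams(r=grid_result.best_r, d=grid_result.best_d)

    with _stage("classify"):
        # test keys are original row indices (< N); train keys start at N so
        # every key in the job is unique even after balancing adds/drops rows
        n_total = dataset.n_samples
        train_instances = [
            KeyedInstance(
                key=n_total + i,
                features=train_sel.values[i],
                target=+1 if train_sel.labels[i] == 1 else -1,
                type=TRAIN,
            )
            for i in range(train_sel.n_samples)
        ]
        test_instances = [
            KeyedInstance(
                key=int(test_rows[i]),
                features=test_sel.values[i],
                target=+1 if test_sel.labels[i] == 1 else -1,
                type=TEST,
            )
            for i in range(test_sel.n_samples)
        ]
        job = JobConfig(
            n_mappers=config.n_mappers,
            tol=config.tol,
            max_passes=config.max_passes,
            seed=config.seed,
            backend=config.backend,
        )
        start = time.perf_counter()
        predictions = run_mrpk(
            train_instances, test_instances, job, rp, kernel, class_weight=weights
        )
        ct_ms = (time.perf_counter() - start) * 1000.0

    with _stage("metrics"):
        truth = {inst.key: inst.target for inst in test_instances}
        correct = sum(1 for k, pred in predictions.items() if pred == truth[k])
        total = len(predictions)
        per_patient = ct_ms / total if total else 0.0
        measured_speedup = None
        if config.measure_speedup and config.n_mappers > 1:
            start = time.perf_counter()
            run_mrpk(
                train_instances,
                test_instances,
                JobConfig(n_mappers=1, tol=config.tol, max_passes=config.max_passes, seed=config.seed),
                rp,
                kernel,
                class_weight=weights,
            )
            ct_one_ms = (time.perf_counter() - start) * 1000.0
            measured_speedup = speedup(ct_one_ms, ct_ms)
        metrics = MetricsReport(
            ct_ms=ct_ms,
            per_patient_ms=tuple([per_patient] * total),
            n_patients=total,
            correct=correct,
            total=total,
            accuracy_pct=accuracy(correct, total),
            speedup=measured_speedup,
        )

    result = PipelineResult(
        selection=selection,
        predictions=predictions,
        metrics=metrics,
        grid_result=grid_result,
        rp=rp,
        kernel=kernel,
        test_keys=tuple(int(k) for k in test_rows),
    )
    if config.outdir is not None:
        with _stage("write"):
            _write_artifacts(config, result)
    return result


def _write_artifacts(config: PipelineConfig, result: PipelineResult) -> None:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.selection.to_frame().to_csv(outdir / "selection_report.csv", index=False)
    write_predictions(outdir / "predictions.tsv", result.predictions)
    result.metrics.to_frame().to_csv(outdir / "metrics.csv", index=False)
    if result.grid_result is not None:
        result.grid_result.table.to_csv(outdir / "cv_table.csv", index=False)
    log = [
        f"seed: {config.seed}",
        f"balance: {config.balance.strategy} (ratio {config.balance.target_ratio})",
        f"n_drop: {config.n_drop}",
        f"selected: {', '.join(result.selection.selected)}",
        f"rp: {result.rp}",
        f"kernel: (x.y + {result.kernel.r})^{result.kernel.d}",
        f"mappers: {config.n_mappers} ({config.backend})",
        f"test accuracy: {result.metrics.accuracy_pct:.2f}% "
        f"({result.metrics.correct}/{result.metrics.total})",
    ]
    (outdir / "run_log.txt").write_text("\n".join(log) + "\n", encoding="utf-8")
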