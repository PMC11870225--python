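"""Local map/shuffle/reduce execution of the polynomial-kernel classifier.

This emulates the cluster workflow without Hadoop: test instances are
sharded round-robin over N mappers, every mapper trains its *own* SVM on
the full training set (same data, same settings, hence an identical model)
and predicts only its shard, the shuffle stage stably sorts the emitted
``<key, prediction>`` pairs, and a single reducer resolves any duplicate
keys by majority vote (exact tie -> +1) and renders ``key<TAB>label``
lines.  Because each mapper sees the whole training set, the final
predictions are invariant to the number of mappers — the engine's central
correctness property.

Backends: ``serial`` runs mappers in-process; ``process`` runs them in
separate OS processes and must produce byte-identical reducer output.
"""

from __future__ import annotations

from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

from .datasets import KeyedInstance, format_prediction_lines
from .svm import KernelParams, train_svm


class MapperOutput(NamedTuple):
    """Intermediate ``<key, prediction>`` record emitted by a mapper."""

    key: int
    prediction: int  # +1 or -1


@dataclass(frozen=True)
class JobConfig:
    """Execution settings for one map/shuffle/reduce job."""

    n_mappers: int = 1
    shard_rule: str = "round_robin"
    tol: float = 1e-3
    max_passes: int = 100
    seed: int = 0
    backend: str = "serial"  # or "process"

    def __post_init__(self) -> None:
        if self.n_mappers < 1:
            raise ValueError("n_mappers must be >= 1")
        if self.shard_rule != "round_robin":
            raise ValueError(f"unknown shard rule {self.shard_rule!r}")
        if self.backend not in ("serial", "process"):
            raise ValueError(f"unknown backend {self.backend!r}")


def shard_test_instances(
    test: Sequence[KeyedInstance], n_mappers: int
) -> list[list[KeyedInstance]]:
    """Split test instances round-robin by ascending key into disjoint shards.

    ``n_mappers`` is clamped to the number of test instances (minimum 1);
    shard sizes differ by at most one.
    """
    ordered = sorted(test, key=lambda inst: inst.key)
    n_mappers = max(1, min(n_mappers, max(len(ordered), 1)))
    shards: list[list[KeyedInstance]] = [[] for _ in range(n_mappers)]
    for pos, inst in enumerate(ordered):
        shards[pos % n_mappers].append(inst)
    return shards


def map_phase(
    shard: Sequence[KeyedInstance],
    train: Sequence[KeyedInstance],
    RP: float,
    params: KernelParams,
    job: JobConfig,
    class_weight: Mapping[int, float] | None = None,
) -> list[MapperOutput]:
    """One mapper: train on the full training set, predict the shard."""
    if not shard:
        return []
    model = train_svm(
        train,
        RP,
        params,
        class_weight=class_weight,
        tol=job.tol,
        max_passes=job.max_passes,
        seed=job.seed,
    )
    features = [inst.features for inst in shard]
    predictions = model.predict(features)
    return [
        MapperOutput(key=inst.key, prediction=int(pred))
        for inst, pred in zip(shard, predictions)
    ]


def shuffle_sort(outputs: Sequence[MapperOutput]) -> list[MapperOutput]:
    """Stable ascending sort of mapper records by key."""
    return sorted(outputs, key=lambda rec: rec.key)


def reduce_phase(sorted_records: Sequence[MapperOutput]) -> dict[int, int]:
    """Aggregate sorted records into one prediction per key.

    Duplicate keys (defensive: shards are disjoint in normal operation) are
    resolved by majority vote with an exact tie going to +1.
    """
    votes: dict[int, int] = {}
    for rec in sorted_records:
        votes[rec.key] = votes.get(rec.key, 0) + rec.prediction
    return {key: (1 if vote >= 0 else -1) for key, vote in votes.items()}


def _map_worker(args) -> list[MapperOutput]:
    shard, train, RP, params, job, class_weight = args
    return map_phase(shard, train, RP, params, job, class_weight)


def run_mrpk(
    train: Sequence[KeyedInstance],
    test: Sequence[KeyedInstance],
    job: JobConfig,
    RP: float,
    params: KernelParams,
    class_weight: Mapping[int, float] | None = None,
) -> dict[int, int]:
    """Full shard -> map -> shuffle -> reduce pipeline.

    Returns one prediction (+1/-1) per test key.
    """
    shards = shard_test_instances(test, job.n_mappers)
    tasks = [(shard, list(train), RP, params, job, class_weight) for shard in shards]
    if job.backend == "process" and len(shards) > 1:
        with ProcessPoolExecutor(max_workers=len(shards)) as pool:
            mapper_outputs = list(pool.map(_map_worker, tasks))
    else:
        mapper_outputs = [_map_worker(task) for task in tasks]
    merged: list[MapperOutput] = [rec for out in mapper_outputs for rec in out]
    return reduce_phase(shuffle_sort(merged))


def predictions_to_text(predictions: Mapping[int, int]) -> str:
    """Reducer part-file rendering (``key<TAB>{+1|-1}`` lines)."""
    return format_prediction_lines(predictions)
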