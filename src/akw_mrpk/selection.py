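"""Associative Kruskal-Wallis (AKW) feature selection.

Each attribute receives a composite score H built from two ingredients:

* a **total variance** term ``Va(T) = Va(C) + Va(D) + AV`` combining the
  attribute's empirical variance (routed through its continuous or discrete
  component depending on the attribute's kind) with an *associative value*
  ``AV = (a_N - sum_i a_i)^2``, the squared gap between the column's last
  observation and its running total; and

* a **rank factor**: the tie-corrected Kruskal-Wallis statistic of the
  attribute's pooled midranks grouped by class label,

      (N - 1) * sum_g n_g (AR_g - OR)^2 / sum_j (OR_j - OR)^2,

  where AR_g is the mean rank of class g and OR = (N + 1)/2 the overall
  mean rank.  This form is algebraically identical to the classical
  Kruskal-Wallis H with the usual tie correction; ties take midranks.

``H = Va(T) * rank_factor``.  Attributes are ranked by H descending and the
lowest-ranked ``n_drop`` are discarded (default 2, shrinking the PIMA table
from eight attributes to six).  H is a composite ranking score here, not a
calibrated test statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .datasets import CONTINUOUS, DISCRETE, LabeledDataset


@dataclass(frozen=True)
class RankSummary:
    """Rank bookkeeping for one attribute's Kruskal-Wallis comparison."""

    pooled_ranks: np.ndarray  # midranks over all N observations
    group_mean_ranks: dict[int, float]  # AR_g per class
    overall_mean_rank: float  # OR = (N + 1) / 2
    n_continuous: int  # observation count if the attribute is continuous
    n_discrete: int  # observation count if the attribute is discrete


@dataclass(frozen=True)
class AKWScores:
    """Per-attribute decomposition of the AKW ranking score."""

    attribute: str
    kind: str
    AV: float
    mu: float
    sigma2: float
    Va_C: float
    Va_D: float
    Va_T: float
    pmf: dict[float, float]
    rank_factor: float
    H: float
    rank: int  # 1 = most significant


@dataclass(frozen=True)
class SelectionResult:
    ranked_attributes: tuple[str, ...]  # by H descending
    selected: tuple[str, ...]
    dropped: tuple[str, ...]
    scores: tuple[AKWScores, ...]  # original attribute order

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "attribute": s.attribute,
                "kind": s.kind,
                "AV": s.AV,
                "mu": s.mu,
                "sigma2": s.sigma2,
                "Va_C": s.Va_C,
                "Va_D": s.Va_D,
                "Va_T": s.Va_T,
                "rank_factor": s.rank_factor,
                "H": s.H,
                "rank": s.rank,
                "kept": s.attribute in self.selected,
            }
            for s in self.scores
        ]
        return pd.DataFrame(rows)


def associative_value(values) -> float:
    """AV = (a_N - sum_i a_i)^2 with a_N the column's last observation."""
    a = np.asarray(values, dtype=float)
    if a.size == 0:
        raise ValueError("associative value needs at least one observation")
    return float((a[-1] - a.sum()) ** 2)


def population_variance(values) -> float:
    """sigma^2 = sum (a - mu)^2 / N (population denominator)."""
    a = np.asarray(values, dtype=float)
    if a.size == 0:
        raise ValueError("variance needs at least one observation")
    return float(np.var(a))


def empirical_pmf(values) -> dict[float, float]:
    """Relative frequency f(a) over the distinct observed values."""
    a = np.asarray(values, dtype=float)
    uniq, counts = np.unique(a, return_counts=True)
    freq = counts / a.size
    return {float(v): float(f) for v, f in zip(uniq, freq)}


def typed_variance(values, kind: str) -> tuple[float, float]:
    """(Va_C, Va_D): PMF-weighted variance routed to the attribute's kind.

    The component matching ``kind`` equals sum over distinct v of
    (v - mu)^2 f(v) — numerically the population variance — and the other
    component is zero.
    """
    a = np.asarray(values, dtype=float)
    if a.size == 0:
        raise ValueError("variance needs at least one observation")
    if kind not in (CONTINUOUS, DISCRETE):
        raise ValueError(f"unknown attribute kind: {kind!r}")
    mu = a.mean()
    pmf = empirical_pmf(a)
    v = sum((val - mu) ** 2 * f for val, f in pmf.items())
    return (float(v), 0.0) if kind == CONTINUOUS else (0.0, float(v))


def total_variance(AV: float, Va_C: float, Va_D: float) -> float:
    """Va(T) = Va(C) + Va(D) + AV."""
    return Va_C + Va_D + AV


def kruskal_rank_factor(values, labels, use_n_multiplier: bool = False) -> tuple[float, RankSummary]:
    """Tie-corrected Kruskal-Wallis ratio of between-class rank dispersion.

    Returns ``mult * sum_g n_g (AR_g - OR)^2 / sum_j (OR_j - OR)^2`` with
    midranks for ties and mult = N - 1 (the classical tie-corrected form);
    ``use_n_multiplier`` switches mult to N.  A fully tied column (zero
    denominator) yields 0.
    """
    a = np.asarray(values, dtype=float)
    y = np.asarray(labels)
    if a.size == 0:
        raise ValueError("rank factor needs at least one observation")
    if a.shape != y.shape:
        raise ValueError("values and labels must have equal length")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("rank comparison needs at least two classes")

    n = a.size
    ranks = rankdata(a)  # midranks
    overall = (n + 1) / 2.0
    group_means = {}
    between = 0.0
    for c in classes:
        mask = y == c
        ar = float(ranks[mask].mean())
        group_means[c if not isinstance(c, np.generic) else c.item()] = ar
        between += mask.sum() * (ar - overall) ** 2
    total = float(((ranks - overall) ** 2).sum())
    mult = n if use_n_multiplier else n - 1
    factor = 0.0 if total == 0.0 else mult * between / total
    summary = RankSummary(
        pooled_ranks=ranks,
        group_mean_ranks=group_means,
        overall_mean_rank=overall,
        n_continuous=n,
        n_discrete=0,
    )
    return factor, summary


def kruskal_h(
    values,
    labels,
    kind: str = CONTINUOUS,
    use_n_multiplier: bool = False,
) -> tuple[float, RankSummary]:
    """Composite AKW score H = Va(T) x rank factor for one attribute."""
    factor, summary = kruskal_rank_factor(values, labels, use_n_multiplier)
    if kind == DISCRETE:
        summary = RankSummary(
            pooled_ranks=summary.pooled_ranks,
            group_mean_ranks=summary.group_mean_ranks,
            overall_mean_rank=summary.overall_mean_rank,
            n_continuous=0,
            n_discrete=summary.pooled_ranks.size,
        )
    av = associative_value(values)
    va_c, va_d = typed_variance(values, kind)
    return total_variance(av, va_c, va_d) * factor, summary


def select_features(
    dataset: LabeledDataset,
    n_drop: int = 2,
    use_n_multiplier: bool = False,
) -> SelectionResult:
    """Score every attribute with H and drop the ``n_drop`` lowest-ranked.

    Ties in H are broken by original attribute order.  The result is
    deterministic and invariant to row permutations (ranks depend only on
    the value/label multiset).
    """
    m = dataset.n_attributes
    if not 0 <= n_drop < m:
        raise ValueError(f"n_drop must satisfy 0 <= n_drop < {m}")

    raw = []
    for j, (name, kind) in enumerate(
        zip(dataset.attribute_names, dataset.attribute_kinds)
    ):
        column = dataset.values[:, j]
        av = associative_value(column)
        va_c, va_d = typed_variance(column, kind)
        factor, _ = kruskal_rank_factor(column, dataset.labels, use_n_multiplier)
        va_t = total_variance(av, va_c, va_d)
        raw.append(
            {
                "attribute": name,
                "kind": kind,
                "AV": av,
                "mu": float(column.mean()),
                "sigma2": population_variance(column),
                "Va_C": va_c,
                "Va_D": va_d,
                "Va_T": va_t,
                "pmf": empirical_pmf(column),
                "rank_factor": factor,
                "H": va_t * factor,
            }
        )

    order = sorted(range(m), key=lambda j: (-raw[j]["H"], j))
    ranks = {j: pos + 1 for pos, j in enumerate(order)}
    scores = tuple(AKWScores(rank=ranks[j], **raw[j]) for j in range(m))
    ranked = tuple(raw[j]["attribute"] for j in order)
    kept_idx = sorted(order[: m - n_drop])
    dropped_idx = sorted(order[m - n_drop :])
    return SelectionResult(
        ranked_attributes=ranked,
        selected=tuple(dataset.attribute_names[j] for j in kept_idx),
        dropped=tuple(dataset.attribute_names[j] for j in dropped_idx),
        scores=scores,
    )
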