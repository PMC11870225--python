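"""Tabular clinical data containers, CSV I/O and the synthetic generator.

The central container is :class:`LabeledDataset`: N patients by M named
numeric attributes with a binary outcome (1 = diabetic).  Attributes carry a
*kind* tag (``continuous`` or ``discrete``) that the feature-selection
variance decomposition consumes.  The default schema follows the PIMA Indian
Diabetes table: eight risk factors (pregnancy count, 2-h plasma glucose,
diastolic blood pressure, triceps skinfold, 2-h serum insulin, BMI, diabetes
pedigree function, age) plus an outcome column.

The module also provides the ``<instance, target, type>`` record used by the
map/shuffle/reduce classifier, affine [0, 1] normalization with reusable
transform parameters, and a seeded synthetic generator that emulates the
PIMA shape (768 rows, roughly 65:35 class split) with configurable
class-conditional mean shifts so selection recovery is testable offline.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, FormatError, LabelError, ParseError

CONTINUOUS = "continuous"
DISCRETE = "discrete"

TRAIN = "train"
TEST = "test"

#: Canonical PIMA attribute order (Kaggle column names).
PIMA_ATTRIBUTES = (
    "Pregnancies",
    "Glucose",
    "BloodPressure",
    "SkinThickness",
    "Insulin",
    "BMI",
    "DiabetesPedigreeFunction",
    "Age",
)

#: Count-valued PIMA columns; everything else is treated as continuous.
_DISCRETE_PIMA = {"pregnancies", "age"}

#: PIMA columns where a literal 0 encodes a missing measurement.
ZERO_CODED = ("Glucose", "BloodPressure", "SkinThickness", "Insulin", "BMI")


def pima_attribute_kind(name: str) -> str:
    """Kind tag for a PIMA column name (case-insensitive); default continuous."""
    return DISCRETE if name.strip().lower() in _DISCRETE_PIMA else CONTINUOUS


@dataclass(frozen=True)
class LabeledDataset:
    """N samples x M named numeric attributes with binary labels."""

    attribute_names: tuple[str, ...]
    attribute_kinds: tuple[str, ...]
    values: np.ndarray  # shape (N, M), float
    labels: np.ndarray  # shape (N,), int in {0, 1}

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        labels = np.asarray(self.labels, dtype=int)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "labels", labels)
        if values.ndim != 2:
            raise ValueError("values must be a 2-D table")
        n, m = values.shape
        if n < 1 or m < 1:
            raise ValueError("dataset must have at least one row and one column")
        if len(self.attribute_names) != m or len(self.attribute_kinds) != m:
            raise ValueError("attribute metadata length must equal column count")
        if not np.all(np.isfinite(values)):
            raise ValueError("values must be finite numbers")
        if labels.shape != (n,):
            raise ValueError("labels length must equal row count")
        if not np.isin(labels, (0, 1)).all():
            raise LabelError("labels must take values in {0, 1}")
        for kind in self.attribute_kinds:
            if kind not in (CONTINUOUS, DISCRETE):
                raise ValueError(f"unknown attribute kind: {kind!r}")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_attributes(self) -> int:
        return self.values.shape[1]

    def class_counts(self) -> dict[int, int]:
        return {c: int((self.labels == c).sum()) for c in (0, 1)}

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.attribute_names.index(name)]

    def select_attributes(self, names: Sequence[str]) -> "LabeledDataset":
        """Project onto a subset of attributes, preserving the given order."""
        idx = [self.attribute_names.index(n) for n in names]
        return LabeledDataset(
            attribute_names=tuple(names),
            attribute_kinds=tuple(self.attribute_kinds[i] for i in idx),
            values=self.values[:, idx],
            labels=self.labels,
        )

    def take_rows(self, rows: Sequence[int] | np.ndarray) -> "LabeledDataset":
        rows = np.asarray(rows, dtype=int)
        return dataclasses.replace(
            self, values=self.values[rows], labels=self.labels[rows]
        )

    def to_frame(self, label_column: str = "Outcome") -> pd.DataFrame:
        frame = pd.DataFrame(self.values, columns=list(self.attribute_names))
        frame[label_column] = self.labels
        return frame


@dataclass(frozen=True)
class KeyedInstance:
    """``<instance, target, type>`` record: the unit of map-phase input.

    ``key`` is a 0-based row index, stable across a job; ``target`` is +1
    (diabetic) or -1, or ``None`` for a test instance of unknown outcome.
    """

    key: int
    features: np.ndarray
    target: int | None
    type: str  # TRAIN or TEST

    def __post_init__(self) -> None:
        object.__setattr__(self, "features", np.asarray(self.features, dtype=float))
        if self.type not in (TRAIN, TEST):
            raise ValueError(f"instance type must be train/test, got {self.type!r}")
        if self.type == TRAIN and self.target not in (+1, -1):
            raise ValueError("training instances must carry a target in {+1, -1}")
        if self.target not in (+1, -1, None):
            raise ValueError("target must be +1, -1 or None")


@dataclass(frozen=True)
class NormalizationParams:
    """Per-attribute (min, max) of the fitted data, reusable on new data."""

    attribute_names: tuple[str, ...]
    mins: np.ndarray
    maxs: np.ndarray


@dataclass(frozen=True)
class SyntheticConfig:
    """Settings for the PIMA-shaped synthetic generator.

    ``effect_size`` is the standardized class-conditional mean shift applied
    to each attribute in ``signal_attributes`` (shift = effect_size x
    within-class s.d.); all other attributes are class-independent.
    """

    n_samples: int = 768
    minority_fraction: float = 268 / 768
    signal_attributes: tuple[str, ...] = ("Glucose", "BMI")
    effect_size: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ConfigError("n_samples must be at least 2")
        if not 0.0 < self.minority_fraction < 1.0:
            raise ConfigError("minority_fraction must lie strictly in (0, 1)")
        if self.effect_size < 0:
            raise ConfigError("effect_size must be non-negative")
        unknown = set(self.signal_attributes) - set(PIMA_ATTRIBUTES)
        if unknown:
            raise ConfigError(f"signal attributes not in schema: {sorted(unknown)}")


def read_pima_csv(
    path,
    label_column: str = "Outcome",
    attribute_kinds: Mapping[str, str] | None = None,
    impute_zero_codes: bool = False,
) -> LabeledDataset:
    """Read a PIMA-dialect CSV (header row, comma-separated, binary outcome).

    Attribute kinds come from the built-in PIMA map (Pregnancies and Age
    discrete, the rest continuous) unless ``attribute_kinds`` overrides them.
    With ``impute_zero_codes`` the zero-coded clinical columns (glucose,
    blood pressure, skinfold, insulin, BMI — where 0 means "not measured")
    are median-imputed over the nonzero entries.
    """
    frame = pd.read_csv(path, header=0)
    if frame.shape[1] < 2:
        raise FormatError("expected at least one attribute column plus a label")
    header_numeric = [_is_number(c) for c in frame.columns]
    if all(header_numeric):
        raise FormatError("first row looks numeric: missing header row")

    # case-insensitive label column lookup
    matches = [c for c in frame.columns if c.strip().lower() == label_column.strip().lower()]
    if not matches:
        raise FormatError(f"label column {label_column!r} not found in header")
    label_column = matches[0]

    attr_cols = [c for c in frame.columns if c != label_column]
    numeric = {}
    for col in frame.columns:
        converted = pd.to_numeric(frame[col], errors="coerce")
        bad = converted.isna() & frame[col].notna()
        if bad.any():
            row = int(bad.idxmax())
            raise ParseError(
                f"non-numeric value {frame[col][row]!r} at row {row}, column {col!r}"
            )
        if converted.isna().any():
            row = int(converted.isna().idxmax())
            raise ParseError(f"missing value at row {row}, column {col!r}")
        numeric[col] = converted.to_numpy(dtype=float)

    labels = numeric[label_column]
    if not np.isin(labels, (0.0, 1.0)).all():
        bad_vals = sorted(set(labels) - {0.0, 1.0})
        raise LabelError(f"label column contains values outside {{0,1}}: {bad_vals}")

    values = np.column_stack([numeric[c] for c in attr_cols])
    if impute_zero_codes:
        zero_coded = {z.lower() for z in ZERO_CODED}
        for j, col in enumerate(attr_cols):
            if col.strip().lower() in zero_coded:
                column = values[:, j]
                nonzero = column[column != 0]
                if nonzero.size:
                    column[column == 0] = np.median(nonzero)

    if attribute_kinds is None:
        kinds = tuple(pima_attribute_kind(c) for c in attr_cols)
    else:
        lowered = {k.strip().lower(): v for k, v in attribute_kinds.items()}
        kinds = tuple(
            lowered.get(c.strip().lower(), pima_attribute_kind(c)) for c in attr_cols
        )
    return LabeledDataset(
        attribute_names=tuple(attr_cols),
        attribute_kinds=kinds,
        values=values,
        labels=labels.astype(int),
    )


def write_pima_csv(dataset: LabeledDataset, path, label_column: str = "Outcome") -> None:
    dataset.to_frame(label_column).to_csv(path, index=False)


def _is_number(token) -> bool:
    try:
        float(str(token))
    except ValueError:
        return False
    return True


def normalize(dataset: LabeledDataset) -> tuple[LabeledDataset, NormalizationParams]:
    """Affinely map every attribute onto [0, 1]; constant attributes map to 0.

    Returns the transformed dataset and the per-attribute (min, max) so the
    identical transform can be replayed on held-out data.
    """
    mins = dataset.values.min(axis=0)
    maxs = dataset.values.max(axis=0)
    params = NormalizationParams(dataset.attribute_names, mins, maxs)
    return apply_normalization(dataset, params), params


def apply_normalization(
    dataset: LabeledDataset, params: NormalizationParams
) -> LabeledDataset:
    """Replay a fitted [0, 1] transform; out-of-range values extrapolate."""
    if params.attribute_names != dataset.attribute_names:
        raise ValueError("normalization parameters fitted on different attributes")
    span = params.maxs - params.mins
    safe = np.where(span > 0, span, 1.0)
    scaled = (dataset.values - params.mins) / safe
    scaled[:, span == 0] = 0.0
    return dataclasses.replace(dataset, values=scaled)


def to_keyed_instances(
    dataset: LabeledDataset, split_assignment: Sequence[str]
) -> list[KeyedInstance]:
    """Encapsulate rows as ``<instance, target, type>`` records.

    Label 1 maps to target +1, label 0 to -1; keys are row indices and the
    row order is preserved.
    """
    if len(split_assignment) != dataset.n_samples:
        raise ValueError("split assignment length must equal the number of rows")
    records = []
    for i in range(dataset.n_samples):
        target = +1 if dataset.labels[i] == 1 else -1
        records.append(
            KeyedInstance(
                key=i,
                features=dataset.values[i],
                target=target,
                type=split_assignment[i],
            )
        )
    return records


# ---------------------------------------------------------------------------
# Synthetic PIMA-like generation
# ---------------------------------------------------------------------------

# name -> (kind, sampler(rng, n), within-class s.d., integer-valued?)
# Location/scale values approximate the published PIMA summary statistics.
_ATTRIBUTE_MODELS: dict[str, tuple] = {
    "Pregnancies": (DISCRETE, lambda rng, n: rng.poisson(3.4, n).astype(float), np.sqrt(3.4), True),
    "Glucose": (CONTINUOUS, lambda rng, n: rng.normal(112.0, 30.0, n), 30.0, False),
    "BloodPressure": (CONTINUOUS, lambda rng, n: rng.normal(70.0, 12.0, n), 12.0, False),
    "SkinThickness": (CONTINUOUS, lambda rng, n: np.clip(rng.normal(29.0, 10.0, n), 0.0, None), 10.0, False),
    "Insulin": (CONTINUOUS, lambda rng, n: rng.gamma(2.0, 60.0, n), np.sqrt(2.0) * 60.0, False),
    "BMI": (CONTINUOUS, lambda rng, n: rng.normal(32.0, 7.0, n), 7.0, False),
    "DiabetesPedigreeFunction": (CONTINUOUS, lambda rng, n: rng.gamma(2.2, 0.215, n), np.sqrt(2.2) * 0.215, False),
    "Age": (DISCRETE, lambda rng, n: 21.0 + rng.gamma(2.0, 6.0, n), np.sqrt(2.0) * 6.0, True),
}


def generate_synthetic(config: SyntheticConfig) -> LabeledDataset:
    """Generate a PIMA-shaped dataset with a known class-conditional signal.

    The minority (diabetic, label 1) row count is exactly
    ``round(n_samples * minority_fraction)`` for every seed.  Signal
    attributes receive an additive shift of ``effect_size`` within-class
    standard deviations in the minority class before any rounding; all other
    attributes are drawn identically in both classes.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    n_minority = int(round(n * config.minority_fraction))
    n_minority = min(max(n_minority, 1), n - 1)
    labels = np.zeros(n, dtype=int)
    labels[:n_minority] = 1
    labels = labels[rng.permutation(n)]

    columns = []
    kinds = []
    for name in PIMA_ATTRIBUTES:
        kind, sampler, sd, integral = _ATTRIBUTE_MODELS[name]
        column = sampler(rng, n)
        if name in config.signal_attributes:
            column = column + (labels == 1) * config.effect_size * sd
        if integral:
            column = np.round(np.clip(column, 0.0, None))
        columns.append(column)
        kinds.append(kind)
    return LabeledDataset(
        attribute_names=PIMA_ATTRIBUTES,
        attribute_kinds=tuple(kinds),
        values=np.column_stack(columns),
        labels=labels,
    )


# ---------------------------------------------------------------------------
# Prediction files ("key<TAB>label", emulating the reducer's part file)
# ---------------------------------------------------------------------------


def format_prediction_lines(predictions: Mapping[int, int]) -> str:
    """Render reducer output as tab-separated ``key<TAB>{+1|-1}`` lines."""
    lines = [f"{key}\t{'+1' if label > 0 else '-1'}" for key, label in sorted(predictions.items())]
    return "\n".join(lines) + ("\n" if lines else "")


def write_predictions(path, predictions: Mapping[int, int]) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        handle.write(format_prediction_lines(predictions))


def read_predictions(path) -> dict[int, int]:
    predictions: dict[int, int] = {}
    with open(path, encoding="utf-8") as handle:
        for line in handle:
            line = line.strip()
            if not line:
                continue
            key, label = line.split("\t")
            predictions[int(key)] = int(label)
    return predictions
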