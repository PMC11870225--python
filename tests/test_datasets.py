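import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from akw_mrpk import (
    ConfigError,
    FormatError,
    LabelError,
    ParseError,
    SyntheticConfig,
    apply_normalization,
    generate_synthetic,
    normalize,
    read_pima_csv,
    read_predictions,
    to_keyed_instances,
    write_pima_csv,
    write_predictions,
)
from akw_mrpk.datasets import PIMA_ATTRIBUTES, pima_attribute_kind


def _write_csv(tmp_path, text, name="data.csv"):
    path = tmp_path / name
    path.write_text(text, encoding="utf-8")
    return path


PIMA_HEADER = ",".join(PIMA_ATTRIBUTES) + ",Outcome"
THREE_ROWS = (
    PIMA_HEADER
    + "\n6,148,72,35,0,33.6,0.627,50,1"
    + "\n1,85,66,29,0,26.6,0.351,31,0"
    + "\n8,183,64,0,0,23.3,0.672,32,1\n"
)


class TestReadPimaCsv:
    def test_shape_and_kinds(self, tmp_path):
        ds = read_pima_csv(_write_csv(tmp_path, THREE_ROWS))
        assert (ds.n_samples, ds.n_attributes) == (3, 8)
        assert ds.attribute_names == PIMA_ATTRIBUTES
        kinds = dict(zip(ds.attribute_names, ds.attribute_kinds))
        assert kinds["Pregnancies"] == "discrete"
        assert kinds["Age"] == "discrete"
        assert kinds["Glucose"] == "continuous"
        assert list(ds.labels) == [1, 0, 1]

    def test_label_column_case_insensitive(self, tmp_path):
        ds = read_pima_csv(_write_csv(tmp_path, THREE_ROWS), label_column="outcome")
        assert ds.class_counts() == {0: 1, 1: 2}

    def test_missing_header_is_format_error(self, tmp_path):
        headerless = "6,148,72,35,0,33.6,0.627,50,1\n1,85,66,29,0,26.6,0.351,31,0\n"
        with pytest.raises(FormatError):
            read_pima_csv(_write_csv(tmp_path, headerless))

    def test_non_numeric_cell_names_row_and_column(self, tmp_path):
        bad = PIMA_HEADER + "\n6,148,72,35,0,33.6,0.627,50,1\n1,abc,66,29,0,26.6,0.351,31,0\n"
        with pytest.raises(ParseError, match="Glucose"):
            read_pima_csv(_write_csv(tmp_path, bad))

    def test_unknown_label_value(self, tmp_path):
        bad = PIMA_HEADER + "\n6,148,72,35,0,33.6,0.627,50,2\n"
        with pytest.raises(LabelError):
            read_pima_csv(_write_csv(tmp_path, bad))

    def test_zero_code_imputation(self, tmp_path):
        ds = read_pima_csv(_write_csv(tmp_path, THREE_ROWS), impute_zero_codes=True)
        # insulin zeros replaced by the nonzero median... all-zero column stays
        assert (ds.column("Insulin") == 0).all() or (ds.column("Insulin") > 0).all()
        # the default leaves zeros alone
        raw = read_pima_csv(_write_csv(tmp_path, THREE_ROWS))
        assert (raw.column("SkinThickness") == [35, 29, 0]).all()

    def test_roundtrip_preserves_values(self, tmp_path, tiny_dataset):
        path = tmp_path / "roundtrip.csv"
        write_pima_csv(tiny_dataset, path)
        back = read_pima_csv(path, attribute_kinds=dict(
            zip(tiny_dataset.attribute_names, tiny_dataset.attribute_kinds)))
        np.testing.assert_array_equal(back.values, tiny_dataset.values)
        np.testing.assert_array_equal(back.labels, tiny_dataset.labels)
        assert back.attribute_kinds == tiny_dataset.attribute_kinds


class TestNormalize:
    @pytest.mark.parametrize(
        "column, expected",
        [
            ([0.0, 5.0, 10.0], [0.0, 0.5, 1.0]),
            ([7.0, 7.0, 7.0], [0.0, 0.0, 0.0]),
            ([4.0, 6.0, 8.0], [0.0, 0.5, 1.0]),
        ],
    )
    def test_affine_map(self, column, expected, tiny_dataset):
        ds = tiny_dataset.take_rows([0, 1, 2])
        values = ds.values.copy()
        values[:, 0] = column
        ds = type(ds)(ds.attribute_names, ds.attribute_kinds, values, ds.labels)
        scaled, params = normalize(ds)
        np.testing.assert_allclose(scaled.values[:, 0], expected)
        assert params.mins[0] == min(column) and params.maxs[0] == max(column)

    @given(st.integers(0, 2**31 - 1))
    def test_idempotent(self, seed):
        rng = np.random.default_rng(seed)
        ds = generate_synthetic(SyntheticConfig(n_samples=40, seed=int(rng.integers(1000))))
        once, _ = normalize(ds)
        twice, _ = normalize(once)
        np.testing.assert_allclose(twice.values, once.values, atol=1e-12)

    def test_params_replay_on_new_data(self, pima_like):
        first = pima_like.take_rows(range(200))
        rest = pima_like.take_rows(range(200, 300))
        _, params = normalize(first)
        replayed = apply_normalization(rest, params)
        j = pima_like.attribute_names.index("Glucose")
        expected = (rest.values[:, j] - params.mins[j]) / (params.maxs[j] - params.mins[j])
        np.testing.assert_allclose(replayed.values[:, j], expected)


class TestKeyedInstances:
    def test_encoding_and_keys(self, tiny_dataset):
        split = ["train", "test", "train", "train", "test", "train"]
        records = to_keyed_instances(tiny_dataset, split)
        assert [r.key for r in records] == list(range(6))
        assert records[0].target == +1 and records[0].type == "train"
        assert records[1].target == -1 and records[1].type == "test"
        assert all((r.target == +1) == (tiny_dataset.labels[r.key] == 1) for r in records)

    def test_length_mismatch(self, tiny_dataset):
        with pytest.raises(ValueError):
            to_keyed_instances(tiny_dataset, ["train"] * 5)


class TestGenerateSynthetic:
    def test_minority_count_exact_for_all_seeds(self):
        for seed in range(10):
            ds = generate_synthetic(
                SyntheticConfig(n_samples=768, minority_fraction=0.349, seed=seed)
            )
            assert ds.class_counts()[1] == 268  # round(768 * 0.349)

    def test_deterministic_under_seed(self):
        cfg = SyntheticConfig(n_samples=120, seed=7)
        a, b = generate_synthetic(cfg), generate_synthetic(cfg)
        np.testing.assert_array_equal(a.values, b.values)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_signal_attribute_separates_classes(self):
        ds = generate_synthetic(SyntheticConfig(n_samples=768, effect_size=2.0, seed=3))
        glucose = ds.column("Glucose")
        t, _ = stats.ttest_ind(glucose[ds.labels == 1], glucose[ds.labels == 0])
        assert abs(t) > 10
        # non-signal attribute shows no such separation
        bp = ds.column("BloodPressure")
        t_bp, _ = stats.ttest_ind(bp[ds.labels == 1], bp[ds.labels == 0])
        assert abs(t_bp) < 5

    def test_unknown_signal_attribute_rejected(self):
        with pytest.raises(ConfigError):
            SyntheticConfig(signal_attributes=("NotAColumn",))

    def test_schema_matches_pima(self):
        ds = generate_synthetic(SyntheticConfig(n_samples=50, seed=0))
        assert ds.attribute_names == PIMA_ATTRIBUTES
        assert ds.attribute_kinds == tuple(pima_attribute_kind(n) for n in PIMA_ATTRIBUTES)


def test_prediction_file_roundtrip(tmp_path):
    preds = {3: 1, 0: -1, 12: 1}
    path = tmp_path / "part-00000.tsv"
    write_predictions(path, preds)
    text = path.read_text()
    assert text.splitlines()[0] == "0\t-1"  # sorted by key, tab-separated
    assert read_predictions(path) == preds
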