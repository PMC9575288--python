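"""Response/omics loading, the label transform and the box-plot filter."""

import numpy as np
import pytest

from nerd.core_data import (PreprocessReport, ResponseRecord, invert_labels,
                            iqr_outlier_mask, load_response_table, log_transform,
                            normalize_labels, preprocess_responses,
                            apply_standardization, standardize_omics)


# ------------------------------------------------------------------- loading

def test_matrix_orientation_skips_blanks(tmp_path):
    path = tmp_path / "resp.csv"
    path.write_text("drug,c1,c2,c3\nd1,0.5,,2.0\nd2,,1.5,\nd3,3.0,,0.7\n")
    records = load_response_table(path, orientation="matrix")
    assert len(records) == 5  # 9 cells, 4 blanks
    assert {(r.drug_id, r.cell_id) for r in records} == {
        ("d1", "c1"), ("d1", "c3"), ("d2", "c2"), ("d3", "c1"), ("d3", "c3")}


def test_long_orientation_preserves_ids_and_rejects_duplicates(tmp_path):
    ok = tmp_path / "ok.csv"
    rows = [f"d{i},c{i},{0.1 * (i + 1)}" for i in range(10)]
    ok.write_text("drug_id,cell_id,ic50\n" + "\n".join(rows) + "\n")
    records = load_response_table(ok, orientation="long")
    assert len(records) == 10
    assert [r.drug_id for r in records] == [f"d{i}" for i in range(10)]

    dup = tmp_path / "dup.csv"
    dup.write_text("drug_id,cell_id,ic50\nd1,c1,0.5\nd1,c1,0.7\n")
    with pytest.raises(ValueError, match="duplicate.*d1.*c1"):
        load_response_table(dup, orientation="long")


def test_non_numeric_ic50_names_row(tmp_path):
    path = tmp_path / "bad.csv"
    path.write_text("drug_id,cell_id,ic50\nd1,c1,0.5\nd2,c2,oops\n")
    with pytest.raises(ValueError, match="row 1"):
        load_response_table(path, orientation="long")


# ------------------------------------------------------------- log transform

def test_log_transform_values_and_errors():
    np.testing.assert_allclose(log_transform([1.0]), [0.0])
    np.testing.assert_allclose(log_transform([np.e, np.e ** 2]), [1.0, 2.0])
    with pytest.raises(ValueError, match="indices"):
        log_transform([1.0, 0.0, -2.0])


def test_log_transform_preserves_order(rng):
    for _ in range(100):
        x = rng.uniform(1e-6, 1e6, size=rng.integers(2, 50))
        np.testing.assert_array_equal(np.argsort(log_transform(x)), np.argsort(x))


# ----------------------------------------------------------------- IQR mask

def oracle_iqr_mask(values, k=1.5):
    """Brute-force box-plot mask: explicit sorted interpolated quartiles."""
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size

    def quantile(q):
        pos = q * (n - 1)
        lo, hi = int(np.floor(pos)), int(np.ceil(pos))
        return x[lo] + (pos - lo) * (x[hi] - x[lo])

    q1, q3 = quantile(0.25), quantile(0.75)
    iqr = q3 - q1
    v = np.asarray(values, dtype=float)
    return (v < q1 - k * iqr) | (v > q3 + k * iqr)


def test_iqr_mask_examples():
    assert not iqr_outlier_mask([5, 5, 5, 5, 5]).any()
    mask = iqr_outlier_mask([1, 2, 3, 4, 5, 6, 7, 8, 9, 100])
    assert mask.tolist() == [False] * 9 + [True]
    with pytest.raises(ValueError):
        iqr_outlier_mask([1, 2, 3])
    with pytest.raises(ValueError):
        iqr_outlier_mask([1, 2, np.nan, 4])


def test_iqr_mask_matches_oracle(rng):
    for _ in range(300):
        n = int(rng.integers(4, 500))
        x = rng.normal(scale=rng.uniform(0.1, 10), size=n)
        if rng.random() < 0.3:  # occasionally plant gross outliers
            x[rng.integers(0, n)] *= 50
        np.testing.assert_array_equal(iqr_outlier_mask(x), oracle_iqr_mask(x))


# ------------------------------------------------------------ normalization

def test_normalize_labels_examples_and_round_trip(rng):
    labels, bounds = normalize_labels([0.0, 1.0, 2.0])
    np.testing.assert_allclose(labels, [0.0, 0.5, 1.0])
    assert bounds == (0.0, 2.0)
    np.testing.assert_allclose(invert_labels([0.5], (0.0, 2.0)), [1.0])

    x = rng.normal(scale=5, size=1000)
    labels, bounds = normalize_labels(x)
    assert np.max(np.abs(invert_labels(labels, bounds) - x)) < 1e-9

    with pytest.raises(ValueError, match="degenerate"):
        normalize_labels([2.0, 2.0])


def test_inference_labels_outside_training_bounds_pass_through():
    labels, _ = normalize_labels([5.0, -1.0], bounds=(0.0, 2.0))
    np.testing.assert_allclose(labels, [2.5, -0.5])  # reported as-is, unclipped


# ------------------------------------------------------------ standardization

def test_standardize_omics_examples():
    out, stats = standardize_omics([[1.0], [3.0]], train_rows=[0, 1])
    np.testing.assert_allclose(out[:, 0], [-1.0, 1.0])  # population sd

    out, stats = standardize_omics([[7.0, 1.0], [7.0, 2.0]], train_rows=[0, 1])
    np.testing.assert_allclose(out[:, 0], 0.0)
    assert stats["sd"][0] == 0.0


def test_standardize_heldout_matches_formula(rng):
    X = rng.normal(size=(50, 6)) * rng.uniform(0.5, 3, size=6) + rng.normal(size=6)
    train = np.arange(30)
    out, stats = standardize_omics(X, train)
    mu = X[train].mean(axis=0)
    sd = X[train].std(axis=0)
    np.testing.assert_allclose(out[30:], (X[30:] - mu) / sd, atol=1e-12)
    # training block is exactly standardized
    assert np.abs(out[train].mean(axis=0)).max() < 1e-6
    assert np.abs(out[train].std(axis=0) - 1).max() < 1e-6


def test_standardize_is_idempotent_with_returned_stats(rng):
    X = rng.normal(size=(20, 4))
    out, _ = standardize_omics(X, np.arange(20))
    out2, _ = standardize_omics(out, np.arange(20))
    np.testing.assert_allclose(out, out2, atol=1e-9)


def test_apply_standardization_rejects_width_mismatch(rng):
    X = rng.normal(size=(10, 4))
    _, stats = standardize_omics(X, np.arange(10))
    with pytest.raises(ValueError, match="mismatch"):
        apply_standardization(rng.normal(size=(3, 5)), stats)


# ----------------------------------------------------------------- pipeline

def test_preprocess_conservation(rng):
    records = [ResponseRecord(f"d{i}", f"c{i}", v)
               for i, v in enumerate(rng.lognormal(size=200))]
    records += [ResponseRecord("dz", "cz", -1.0), ResponseRecord("dz2", "cz2", 0.0)]
    records += [ResponseRecord("dx", "cx", 1e9)]  # gross outlier on log scale
    retained, report = preprocess_responses(records)
    assert isinstance(report, PreprocessReport)
    assert report.n_in == len(records)
    assert report.n_in == report.n_retained + report.n_outliers + report.n_nonpositive
    assert report.n_nonpositive == 2
    assert report.n_outliers >= 1
    assert all(r.label is not None and 0 <= r.label <= 1 for r in retained)
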