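"""Splits, metrics, cross-validation rotation and the training contract."""

import numpy as np
import pytest
from scipy import stats as sps

from conftest import TINY_CONFIG
from nerd.train_eval import (MetricsReport, SplitSpec, compute_metrics,
                             data_reduction_experiment,
                             entity_blind_split_from_test_group, five_fold_cv,
                             make_split, mean_entity_similarity,
                             similarity_bins, train_model)


# ------------------------------------------------------------------- metrics

def test_perfect_prediction_metrics():
    m = compute_metrics([1, 2, 3], [1, 2, 3])
    assert m.cc_p == pytest.approx(1.0)
    assert m.cc_s == pytest.approx(1.0)
    assert m.r2 == pytest.approx(1.0)
    assert m.rmse == pytest.approx(0.0)
    assert m.n == 3


def test_shifted_prediction_hand_computation():
    m = compute_metrics([1, 2, 3], [2, 3, 4])
    assert m.rmse == pytest.approx(1.0)
    assert m.cc_p == pytest.approx(1.0)
    assert m.r2 == pytest.approx(-0.5)  # SS_res = 3, SS_tot = 2


def test_metrics_match_closed_forms(rng):
    for _ in range(200):
        n = int(rng.integers(5, 100))
        y = rng.normal(size=n)
        p = rng.normal(size=n)
        m = compute_metrics(y, p)
        assert m.cc_p == pytest.approx(np.corrcoef(y, p)[0, 1], abs=1e-10)
        ranks_y = sps.rankdata(y)
        ranks_p = sps.rankdata(p)
        assert m.cc_s == pytest.approx(np.corrcoef(ranks_y, ranks_p)[0, 1], abs=1e-10)
        assert m.rmse == pytest.approx(np.sqrt(np.mean((y - p) ** 2)), abs=1e-10)
        assert m.r2 == pytest.approx(
            1 - np.sum((y - p) ** 2) / np.sum((y - y.mean()) ** 2), abs=1e-10)
        assert -1 <= m.cc_p <= 1 and -1 <= m.cc_s <= 1 and m.rmse >= 0 and m.r2 <= 1


def test_spearman_invariant_under_monotone_transform(rng):
    for _ in range(50):
        y = rng.normal(size=30)
        p = rng.normal(size=30)
        base = compute_metrics(y, p).cc_s
        transformed = compute_metrics(y, np.exp(2 * p) + 5).cc_s
        assert base == pytest.approx(transformed, abs=1e-12)


def test_constant_truth_raises_not_nan():
    with pytest.raises(ValueError, match="constant"):
        compute_metrics([2, 2, 2], [1, 2, 3])


# -------------------------------------------------------------------- splits

def _mini_dataset(n_drugs=10, n_cells=10, seed=0):
    """Label-only dataset stub: responses with ids but no features needed."""
    from nerd.core_data import Dataset, ResponseRecord

    rng = np.random.default_rng(seed)
    responses = [ResponseRecord(f"d{i}", f"c{j}", 1.0, label=float(rng.random()))
                 for i in range(n_drugs) for j in range(n_cells)]
    ds = Dataset(responses=responses)
    return ds


def test_mixed_split_sizes_and_determinism():
    ds = _mini_dataset()
    split = make_split(ds, "mixed", seed=4)
    assert (len(split.train_idx), len(split.val_idx), len(split.test_idx)) == (80, 10, 10)
    split2 = make_split(ds, "mixed", seed=4)
    np.testing.assert_array_equal(split.train_idx, split2.train_idx)
    split3 = make_split(ds, "mixed", seed=5)
    assert not np.array_equal(split.train_idx, split3.train_idx)


def test_drug_blind_split_holds_out_whole_drugs():
    ds = _mini_dataset(n_drugs=10)
    split = make_split(ds, "drug_blind", seed=0)
    test_drugs = {ds.responses[i].drug_id for i in split.test_idx}
    train_drugs = {ds.responses[i].drug_id for i in split.train_idx}
    val_drugs = {ds.responses[i].drug_id for i in split.val_idx}
    assert len(test_drugs) == 1  # 10% of 10 drugs
    assert test_drugs.isdisjoint(train_drugs) and test_drugs.isdisjoint(val_drugs)
    assert len(split.test_idx) == 10  # all pairs of the held-out drug


def test_cell_blind_split_holds_out_whole_cells():
    ds = _mini_dataset()
    split = make_split(ds, "cell_blind", seed=1)
    test_cells = {ds.responses[i].cell_id for i in split.test_idx}
    rest_cells = {ds.responses[i].cell_id for i in
                  np.concatenate([split.train_idx, split.val_idx])}
    assert test_cells.isdisjoint(rest_cells)


def test_blind_split_needs_enough_entities():
    ds = _mini_dataset(n_drugs=2, n_cells=5)
    with pytest.raises(ValueError, match="at least 3"):
        make_split(ds, "drug_blind", seed=0)


def test_split_partitions_must_be_disjoint():
    with pytest.raises(ValueError, match="disjoint"):
        SplitSpec(np.array([0, 1]), np.array([1]), np.array([2]), "mixed", 0)


def test_five_fold_rotation_covers_every_piece_once():
    ds = _mini_dataset()
    folds = five_fold_cv(ds, seed=3)
    assert len(folds) == 5
    held_out = []
    for fold in folds:
        assert (len(fold.train_idx), len(fold.val_idx), len(fold.test_idx)) == (80, 10, 10)
        held_out.extend(fold.val_idx.tolist())
        held_out.extend(fold.test_idx.tolist())
    assert sorted(held_out) == list(range(100))  # each pair val or test exactly once
    folds2 = five_fold_cv(ds, seed=3)
    np.testing.assert_array_equal(folds[2].test_idx, folds2[2].test_idx)


def test_five_fold_needs_ten_pairs():
    from nerd.core_data import Dataset, ResponseRecord
    ds = Dataset(responses=[ResponseRecord("d", f"c{i}", 1.0) for i in range(9)])
    with pytest.raises(ValueError, match="at least 10"):
        five_fold_cv(ds)


# --------------------------------------------------------------- similarity

def test_mean_similarity_matches_brute_force(tiny_data):
    dataset, _, _ = tiny_data
    scores = mean_entity_similarity(dataset, "drug")
    ids = dataset.drug_ids
    fps = {d: dataset.drugs[d].fingerprint.bits.astype(float) for d in ids}
    for d in ids:
        sims = []
        for other in ids:
            if other == d:
                continue
            a, b = fps[d], fps[other]
            inter = float(a @ b)
            union = float(a.sum() + b.sum() - inter)
            sims.append(inter / union if union > 0 else 1.0)
        assert scores[d] == pytest.approx(np.mean(sims), abs=1e-12)


def test_similarity_bins_order_and_sizes(tiny_data):
    dataset, _, _ = tiny_data
    bins = similarity_bins(dataset, "drug", n_bins=5)
    sizes = [len(b) for b in bins]
    assert sum(sizes) == len(dataset.drugs)
    assert max(sizes) - min(sizes) <= 1
    scores = mean_entity_similarity(dataset, "drug")
    bin_means = [np.mean([scores[d] for d in b]) for b in bins]
    assert bin_means == sorted(bin_means)  # Set1 lowest ... Set5 highest


def test_similarity_bin_split_is_blind(tiny_data):
    dataset, _, _ = tiny_data
    groups = similarity_bins(dataset, "drug", n_bins=4)
    split = entity_blind_split_from_test_group(dataset, "drug", groups[0], seed=0)
    test_drugs = {dataset.responses[i].drug_id for i in split.test_idx}
    other = {dataset.responses[i].drug_id
             for i in np.concatenate([split.train_idx, split.val_idx])}
    assert test_drugs == set(groups[0]) & {r.drug_id for r in dataset.responses}
    assert test_drugs.isdisjoint(other)


# ----------------------------------------------------------------- training

def test_training_learns_tiny_planted_signal(tiny_trained):
    dataset, split, model = tiny_trained
    report = model.evaluate(dataset, split.train_idx)
    assert report.rmse < 0.25  # short schedule: learning, not convergence
    assert np.isfinite(report.cc_p)


def test_best_checkpoint_no_worse_than_final_epoch(tiny_trained):
    _, _, model = tiny_trained
    val_curve = [h["val_rmse"] for h in model.history]
    assert min(val_curve) == pytest.approx(val_curve[model.best_epoch])
    assert val_curve[model.best_epoch] <= val_curve[-1]


def test_training_is_reproducible_under_fixed_seed(tiny_data):
    dataset, _, _ = tiny_data
    split = make_split(dataset, "mixed", seed=2)
    m1 = train_model(dataset, split, TINY_CONFIG, seed=7)
    m2 = train_model(dataset, split, TINY_CONFIG, seed=7)
    r1 = m1.evaluate(dataset, split.test_idx)
    r2 = m2.evaluate(dataset, split.test_idx)
    assert r1.rmse == pytest.approx(r2.rmse, abs=1e-6)
    assert r1.cc_p == pytest.approx(r2.cc_p, abs=1e-6)


def test_empty_train_partition_is_rejected(tiny_data):
    dataset, _, _ = tiny_data
    n = len(dataset.responses)
    split = SplitSpec(np.array([], dtype=int), np.arange(0, 2), np.arange(2, n),
                      "mixed", 0)
    with pytest.raises(ValueError, match="empty training"):
        train_model(dataset, split, TINY_CONFIG, seed=0)


def test_data_reduction_sizes_and_identity_fraction(tiny_data):
    dataset, _, _ = tiny_data
    split = make_split(dataset, "mixed", seed=5)
    table = data_reduction_experiment(dataset, split, fractions=(1.0, 0.5),
                                      config=TINY_CONFIG, seed=5)
    assert set(table) == {1.0, 0.5}
    # identity fraction reproduces the ordinary run under the same seed
    full = train_model(dataset, split, TINY_CONFIG, seed=5)
    ref = full.evaluate(dataset, split.test_idx)
    assert table[1.0].rmse == pytest.approx(ref.rmse, abs=1e-6)
    with pytest.raises(ValueError, match="fewer than 10"):
        data_reduction_experiment(dataset, split, fractions=(0.01,),
                                  config=TINY_CONFIG, seed=5)


def test_checkpoint_round_trip(tmp_path, tiny_data, tiny_trained):
    from nerd.train_eval import load_checkpoint, save_checkpoint

    dataset, split, model = tiny_trained
    save_checkpoint(model, tmp_path)
    restored = load_checkpoint(dataset, tmp_path, TINY_CONFIG)
    np.testing.assert_allclose(
        model.predict_responses(dataset, split.test_idx),
        restored.predict_responses(dataset, split.test_idx), atol=1e-6)
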