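"""Undersampling, fold construction and the SVM meta-classifier."""

import numpy as np
import pytest

from bindstack.stacker import (
    TrainingConfig,
    cross_validate,
    load_model,
    make_folds,
    predict,
    save_model,
    train,
    undersample_negatives,
)


def separable_toy(n=40, seed=0):
    rng = np.random.default_rng(seed)
    half = n // 2
    X = np.vstack(
        [
            np.ones((half, 2)) + rng.uniform(-0.1, 0.1, (half, 2)),
            np.zeros((half, 2)) + rng.uniform(-0.1, 0.1, (half, 2)),
        ]
    )
    y = np.array([1] * half + [-1] * half)
    return X, y


class TestUndersampling:
    def test_one_to_one_keeps_all_positives(self):
        y = np.array([1] * 10 + [-1] * 100)
        kept = undersample_negatives(y, ratio=1.0, seed=3)
        assert (y[kept] == 1).sum() == 10 and (y[kept] == -1).sum() == 10

    def test_cap_when_negatives_are_scarce(self):
        y = np.array([1] * 10 + [-1] * 5)
        kept = undersample_negatives(y, ratio=1.0, seed=3)
        assert len(kept) == 15

    def test_deterministic_per_seed_and_varying_across_seeds(self):
        y = np.array([1] * 10 + [-1] * 200)
        a = undersample_negatives(y, seed=7)
        b = undersample_negatives(y, seed=7)
        np.testing.assert_array_equal(a, b)
        distinct = {tuple(undersample_negatives(y, seed=s)) for s in range(20)}
        assert len(distinct) > 15

    def test_degenerate_sets_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            undersample_negatives(np.array([-1, -1]))
        with pytest.raises(ValueError, match="negative"):
            undersample_negatives(np.array([1, 1]))


class TestFolds:
    def test_residue_fold_sizes_differ_by_at_most_one(self):
        folds = make_folds(103, 10, seed=0)
        sizes = sorted(np.bincount(folds), reverse=True)
        assert sizes == [11, 11, 11] + [10] * 7

    def test_protein_folds_keep_groups_whole(self):
        groups = np.repeat(np.arange(10), 20)
        folds = make_folds(200, 10, fold_unit="protein", groups=groups, seed=1)
        for g in range(10):
            assert np.unique(folds[groups == g]).size == 1
        assert sorted(np.bincount(folds)) == [20] * 10

    def test_no_protein_spans_two_folds_over_random_configs(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            n_groups = int(rng.integers(5, 30))
            sizes = rng.integers(1, 15, n_groups)
            groups = np.repeat(np.arange(n_groups), sizes)
            k = int(rng.integers(2, n_groups + 1))
            folds = make_folds(len(groups), k, "protein", groups, int(rng.integers(1e6)))
            for g in range(n_groups):
                assert np.unique(folds[groups == g]).size == 1

    def test_too_many_folds_rejected(self):
        with pytest.raises(ValueError):
            make_folds(5, 10)
        with pytest.raises(ValueError):
            make_folds(20, 8, "protein", np.repeat([0, 1, 2], [10, 5, 5]))


class TestTrainPredict:
    def test_separable_toy_reaches_full_training_accuracy(self, fast_config):
        X, y = separable_toy()
        model = train(X, y, fast_config)
        calls, _ = predict(model, X)
        assert (calls == y).mean() == 1.0
        assert model.composition["n_pos_after"] == model.composition["n_neg_after"]

    def test_single_class_after_undersampling_rejected(self, fast_config):
        X = np.zeros((4, 2))
        with pytest.raises(ValueError):
            train(X, np.array([1, 1, 1, 1]), fast_config)

    def test_predict_validates_input(self, fast_config):
        X, y = separable_toy()
        model = train(X, y, fast_config)
        with pytest.raises(ValueError, match="empty"):
            predict(model, np.empty((0, 2)))
        with pytest.raises(ValueError, match="width"):
            predict(model, np.zeros((3, 5)))

    def test_decision_scores_invariant_to_row_order(self, fast_config):
        X, y = separable_toy(seed=2)
        model = train(X, y, fast_config)
        _, scores = predict(model, X)
        perm = np.random.default_rng(0).permutation(len(X))
        _, permuted = predict(model, X[perm])
        np.testing.assert_allclose(permuted, scores[perm])

    def test_grid_search_records_selection(self):
        X, y = separable_toy(seed=3)
        config = TrainingConfig(cost_grid=(0.5, 8.0), gamma_grid=(0.25, 2.0), rng_seed=1)
        model = train(X, y, config)
        assert model.cost in config.cost_grid and model.gamma in config.gamma_grid
        assert len(model.selection) == 4

    def test_model_file_roundtrip(self, tmp_path, fast_config):
        X, y = separable_toy(seed=4)
        model = train(X, y, fast_config)
        save_model(model, tmp_path / "model.bin")
        back = load_model(tmp_path / "model.bin")
        np.testing.assert_allclose(
            predict(back, X)[1], predict(model, X)[1]
        )


class TestCrossValidation:
    def test_perfectly_informative_feature_scores_perfectly(self, fast_config):
        rng = np.random.default_rng(0)
        y = np.where(rng.random(400) < 0.2, 1, -1)
        X = np.column_stack([y.astype(float), rng.normal(size=400)])
        res = cross_validate(X, y, config=fast_config)
        assert res.pooled_metrics.sensitivity == 1.0
        assert res.pooled_metrics.specificity == 1.0

    def test_pooled_counts_conserve_the_dataset(self, small_dataset, fast_config):
        features, y, _, _ = small_dataset
        res = cross_validate(features, y, config=fast_config)
        assert res.pooled_counts.total == len(y)
        assert res.pooled_counts.positives == (y == 1).sum()
        # every row in exactly one test fold
        assert np.bincount(res.fold_ids).sum() == len(y)

    def test_test_folds_keep_natural_imbalance(self, small_dataset, fast_config):
        features, y, _, _ = small_dataset
        res = cross_validate(features, y, config=fast_config)
        for comp in res.compositions:
            # training used 1:1 undersampling, the held-out fold did not
            assert comp["n_pos_after"] == comp["n_neg_after"]
            fold_pos = comp["n_test_pos"] / comp["n_test"]
            assert fold_pos < 0.25  # far from 0.5: untouched imbalance

    def test_counts_reproducible_bit_for_bit(self, small_dataset, fast_config):
        features, y, _, _ = small_dataset
        a = cross_validate(features, y, config=fast_config)
        b = cross_validate(features, y, config=fast_config)
        assert [
            (c.tp, c.tn, c.fp, c.fn) for c in a.fold_counts
        ] == [(c.tp, c.tn, c.fp, c.fn) for c in b.fold_counts]
        np.testing.assert_array_equal(a.fold_ids, b.fold_ids)
        np.testing.assert_array_equal(a.decision_values, b.decision_values)

    def test_label_independent_feature_sits_at_chance(self):
        rng = np.random.default_rng(12)
        y = np.where(rng.random(1200) < 0.5, 1, -1)
        X = rng.normal(size=(1200, 3))
        config = TrainingConfig(cost_grid=(1.0,), gamma_grid=(0.5,), rng_seed=12)
        res = cross_validate(X, y, config=config)
        assert 0.4 < res.pooled_metrics.strength < 0.6
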