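"""Splitting, metrics, training, cross-validation and grid search."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest

from defpred.modeling import (
    DEFAULT_GRIDS,
    ConfusionMatrix,
    ModelSpec,
    accuracy,
    auroc,
    confusion,
    cross_validate,
    evaluate,
    expand_grid,
    grid_search,
    kfold,
    mcc,
    predict_scores,
    sensitivity,
    specificity,
    split_dataset,
    train,
)
from defpred.seqio import LabeledDataset, Peptide

from conftest import random_peptides


def make_dataset(rng, n_pos, n_neg):
    pos = random_peptides(n_pos, rng, prefix="pos")
    neg = random_peptides(n_neg, rng, prefix="neg")
    return LabeledDataset(
        [(p, "positive") for p in pos] + [(p, "negative") for p in neg]
    )


def oracle_auroc(scores, y):
    """Fraction of positive/negative pairs correctly ordered, ties half."""
    pos = [s for s, l in zip(scores, y) if l == 1]
    neg = [s for s, l in zip(scores, y) if l == 0]
    total = len(pos) * len(neg)
    credit = sum(1.0 if p > n else (0.5 if p == n else 0.0)
                 for p in pos for n in neg)
    return credit / total


class TestSplit:
    def test_balanced_80_20(self, rng):
        ds = make_dataset(rng, 100, 100)
        tr, va = split_dataset(ds, seed=1)
        assert tr.class_counts() == {"positive": 80, "negative": 80}
        assert va.class_counts() == {"positive": 20, "negative": 20}

    def test_deterministic(self, rng):
        ds = make_dataset(rng, 50, 40)
        ids1 = [p.id for p in split_dataset(ds, seed=7)[1].peptides]
        ids2 = [p.id for p in split_dataset(ds, seed=7)[1].peptides]
        assert ids1 == ids2

    def test_disjoint_exhaustive_over_random_datasets(self, rng):
        for i in range(50):
            ds = make_dataset(rng, int(rng.integers(5, 40)), int(rng.integers(5, 40)))
            tr, va = split_dataset(ds, seed=i)
            tr_ids = {p.id for p in tr.peptides}
            va_ids = {p.id for p in va.peptides}
            assert tr_ids | va_ids == {p.id for p in ds.peptides}
            assert not (tr_ids & va_ids)
            for label in ("positive", "negative"):
                n_class = ds.class_counts()[label]
                assert va.class_counts()[label] == round(0.2 * n_class)

    def test_tiny_class_errors(self, rng):
        ds = make_dataset(rng, 4, 20)
        with pytest.raises(ValueError, match="< 5"):
            split_dataset(ds)


class TestKfold:
    def test_five_folds_of_twenty(self):
        y = np.repeat([0, 1], 50)
        folds = kfold(y, k=5, seed=0)
        assert len(folds) == 5
        assert all(len(te) == 20 for _, te in folds)

    def test_partition_and_class_balance(self, rng):
        for i in range(10):
            n0, n1 = int(rng.integers(10, 40)), int(rng.integers(10, 40))
            y = np.array([0] * n0 + [1] * n1)
            folds = kfold(y, k=5, seed=i)
            seen = np.concatenate([te for _, te in folds])
            assert sorted(seen) == list(range(len(y)))
            for cls in (0, 1):
                sizes = [np.sum(y[te] == cls) for _, te in folds]
                assert max(sizes) - min(sizes) <= 1

    def test_k_too_small(self):
        with pytest.raises(ValueError):
            kfold(np.repeat([0, 1], 10), k=1)


class TestMetrics:
    def test_closed_form_on_enumerated_grid(self):
        for tp in range(0, 11, 2):
            for fp in range(0, 11, 2):
                for tn in range(0, 11, 2):
                    for fn in range(0, 11, 2):
                        cm = ConfusionMatrix(tp, fp, tn, fn)
                        P, N = tp + fn, tn + fp
                        if P:
                            assert sensitivity(cm) == pytest.approx(100 * tp / P)
                        if N:
                            assert specificity(cm) == pytest.approx(100 * tn / N)
                        if P + N:
                            assert accuracy(cm) == pytest.approx(
                                100 * (tp + tn) / (P + N)
                            )
                        denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
                        expected = (
                            (tp * tn - fp * fn) / math.sqrt(denom) if denom else 0.0
                        )
                        assert mcc(cm) == pytest.approx(expected)

    def test_perfect_and_chance(self):
        perfect = ConfusionMatrix(50, 0, 50, 0)
        assert mcc(perfect) == 1.0
        assert sensitivity(perfect) == specificity(perfect) == accuracy(perfect) == 100
        chance = ConfusionMatrix(25, 25, 25, 25)
        assert accuracy(chance) == 50 and mcc(chance) == 0.0

    def test_worked_mcc_example(self):
        cm = ConfusionMatrix(tp=40, fp=15, tn=35, fn=10)
        assert mcc(cm) == pytest.approx(1250 / math.sqrt(55 * 50 * 50 * 45))

    def test_auroc_matches_pairwise_oracle_with_ties(self, rng):
        for _ in range(100):
            n = int(rng.integers(10, 60))
            y = rng.integers(0, 2, n)
            if len(set(y)) < 2:
                y[0], y[1] = 0, 1
            # coarse scores force ties
            scores = rng.integers(0, 5, n) / 4.0
            assert auroc(scores, y) == pytest.approx(oracle_auroc(scores, y))

    def test_auroc_flip_identity_and_monotone_invariance(self, rng):
        y = rng.integers(0, 2, 50)
        y[:2] = [0, 1]
        scores = rng.random(50)
        assert auroc(scores, y) + auroc(scores, 1 - y) == pytest.approx(1.0)
        assert auroc(np.exp(5 * scores), y) == pytest.approx(auroc(scores, y))

    def test_confusion_thresholding(self):
        scores = np.array([0.9, 0.4, 0.6, 0.1])
        y = np.array([1, 1, 0, 0])
        cm = confusion(scores, y, 0.5)
        assert (cm.tp, cm.fn, cm.fp, cm.tn) == (1, 1, 1, 1)

    def test_evaluate_consistency_with_counts(self, rng):
        scores = rng.random(80)
        y = rng.integers(0, 2, 80)
        y[:2] = [0, 1]
        e = evaluate(scores, y)
        P, N = e.cm.positives, e.cm.negatives
        assert e.acc == pytest.approx((e.sens * P + e.spec * N) / (P + N))
        assert -1 <= e.mcc <= 1

    def test_single_class_auroc(self):
        with pytest.raises(ValueError):
            auroc([0.3, 0.7], [1, 1])
        with pytest.warns(UserWarning, match="single-class"):
            e = evaluate([0.3, 0.7], [1, 1])
        assert e.auroc is None and e.sens == 50.0


def separable_frame(n=60, seed=0):
    rng = np.random.default_rng(seed)
    y = np.repeat([0, 1], n // 2)
    X = pd.DataFrame({
        "f1": y * 10.0 + rng.normal(0, 0.1, n),
        "f2": rng.normal(0, 1, n),
    })
    return X, y


class TestTrainPredict:
    @pytest.mark.parametrize("kind,params", [
        ("SVM", {"C": 2, "g": 0.1, "k": "rbf"}),
        ("LR", {"C": 1}),
        ("RF", {"ne": 30}),
        ("ET", {"ne": 30}),
        ("KNN", {"nn": 5, "w": "distance"}),
        ("MLP", {"a": "identity", "HL": 3, "m": 500}),
    ])
    def test_separable_data_scores_separate(self, kind, params):
        X, y = separable_frame()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = train(X, y, ModelSpec(kind, params, seed=0))
            scores = predict_scores(model, X)
        assert scores.min() >= 0 and scores.max() <= 1
        assert scores[y == 1].min() > scores[y == 0].max()

    def test_permuted_columns_are_rejected(self):
        X, y = separable_frame()
        model = train(X, y, ModelSpec("LR", {}, seed=0))
        with pytest.raises(ValueError, match="contract"):
            predict_scores(model, X[["f2", "f1"]])

    def test_same_seed_same_scores(self):
        X, y = separable_frame()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            s1 = predict_scores(train(X, y, ModelSpec("SVM", {"g": 0.1}, seed=3)), X)
            s2 = predict_scores(train(X, y, ModelSpec("SVM", {"g": 0.1}, seed=3)), X)
        np.testing.assert_array_equal(s1, s2)

    def test_illegal_hyperparameter_names(self):
        with pytest.raises(ValueError, match="illegal"):
            ModelSpec("SVM", {"ne": 10})
        with pytest.raises(ValueError, match="unknown"):
            ModelSpec("GBM", {})


class TestCrossValidate:
    def test_separable_gives_perfect_auroc(self):
        X, y = separable_frame(n=100)
        report = cross_validate(X, y, ModelSpec("LR", {}, seed=0), seed=0)
        assert report.aggregate["auroc"] == pytest.approx(1.0)

    def test_aggregate_is_fold_mean(self):
        X, y = separable_frame(n=100, seed=2)
        report = cross_validate(X, y, ModelSpec("RF", {"ne": 10}, seed=2), seed=2)
        for key in ("sens", "spec", "acc", "mcc", "auroc"):
            assert report.aggregate[key] == pytest.approx(
                np.mean([getattr(f, key) for f in report.folds])
            )

    def test_shuffled_labels_near_chance(self):
        aurocs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X = pd.DataFrame(rng.normal(size=(100, 5)),
                             columns=[f"f{i}" for i in range(5)])
            y = np.repeat([0, 1], 50)
            report = cross_validate(X, y, ModelSpec("LR", {}, seed=seed), seed=seed)
            aurocs.append(report.aggregate["auroc"])
        assert 0.4 <= np.mean(aurocs) <= 0.6

    def test_no_leakage_between_folds(self):
        X, y = separable_frame(n=100)
        report = cross_validate(X, y, ModelSpec("LR", {}, seed=1), seed=1)
        for fold in report.provenance["fold_indices"]:
            assert not (set(fold["train"]) & set(fold["test"]))


class TestGridSearch:
    def test_single_point_grid(self):
        X, y = separable_frame(n=100)
        spec, _ = grid_search(X, y, "LR", {"C": [0.5]}, seed=0)
        assert spec.params == {"C": 0.5}

    def test_returned_spec_in_grid(self):
        X, y = separable_frame(n=100, seed=4)
        grid = {"ne": [10, 20]}
        spec, score = grid_search(X, y, "RF", grid, seed=4)
        assert spec.params in [{"ne": 10}, {"ne": 20}]
        assert 0 <= score <= 1

    def test_empty_grid_errors(self):
        X, y = separable_frame()
        with pytest.raises(ValueError, match="empty"):
            grid_search(X, y, "LR", {})

    def test_sane_knn_beats_crippled_on_noisy_blobs(self):
        wins = 0
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            y = np.repeat([0, 1], 60)
            X = pd.DataFrame({
                "f1": y * 1.5 + rng.normal(0, 1, 120),
                "f2": y * 1.5 + rng.normal(0, 1, 120),
            })
            spec, _ = grid_search(X, y, "KNN", {"nn": [1, 10]}, seed=seed)
            wins += spec.params["nn"] == 10
        assert wins >= 4

    def test_default_grids_contain_reference_optima(self):
        # the shipped grids must be able to reproduce the known-good settings
        assert 2 in DEFAULT_GRIDS["SVM"]["C"]
        assert {0.5, 1} <= set(DEFAULT_GRIDS["SVM"]["g"])
        assert "rbf" in DEFAULT_GRIDS["SVM"]["k"]
        assert {0.1, 1, 10} <= set(DEFAULT_GRIDS["LR"]["C"])
        assert {50, 90} <= set(DEFAULT_GRIDS["RF"]["ne"])
        assert {30, 40, 50} <= set(DEFAULT_GRIDS["ET"]["ne"])
        assert {9, 10} <= set(DEFAULT_GRIDS["KNN"]["nn"])
        assert {"identity", "tanh"} <= set(DEFAULT_GRIDS["MLP"]["a"])
        assert {3, 10, 15, 17} <= set(DEFAULT_GRIDS["MLP"]["HL"])
        # every grid expands without error
        for kind in DEFAULT_GRIDS:
            assert expand_grid(kind)
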