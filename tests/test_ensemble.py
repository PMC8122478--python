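"""Base banks, voting rules, cross-trained weights, gradient boosting."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from emgait import ensemble as ens
from emgait.features import SELECTED_FEATURES

import oracles


def _blob_matrix(rng, n_per_class=10, sep=8.0, n_classes=12,
                 features=SELECTED_FEATURES, noise=1.0):
    """Linearly separable per-class blobs in every feature block."""
    rows = []
    centers = {f: rng.normal(scale=sep, size=(n_classes, 5)) for f in features}
    for lab in range(1, n_classes + 1):
        for _ in range(n_per_class):
            row = {"subject": "s", "terrain": "t", "kind": "k", "label": lab}
            for f in features:
                vals = centers[f][lab - 1] + noise * rng.standard_normal(5)
                for i, m in enumerate(("TA", "MG", "RF", "VL", "ES")):
                    row[f"{m}_{f}"] = vals[i]
            rows.append(row)
    return pd.DataFrame(rows)


class TestBaseBank:
    def test_separable_blobs_training_accuracy_one(self, rng):
        df = _blob_matrix(rng, n_per_class=8, sep=12.0, noise=0.3)
        for kind in ("lda", "svm"):
            bank = ens.train_base_bank(df, kind)
            preds = bank.predict_labels(df)
            for j in range(preds.shape[1]):
                assert np.mean(preds[:, j] == df["label"].to_numpy()) == 1.0

    def test_shuffled_labels_give_chance_level(self, rng):
        from sklearn.model_selection import cross_val_score
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        df = _blob_matrix(rng, n_per_class=20, sep=8.0)
        y = rng.permutation(df["label"].to_numpy())
        from emgait.features import select_feature_block

        x = select_feature_block(df, "MAV")
        acc = cross_val_score(
            LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto"), x, y, cv=5
        ).mean()
        p = 1 / 12
        n = len(y)
        band = 2.58 * np.sqrt(p * (1 - p) / n)
        assert acc < p + band + 0.05  # no better than chance (99% band + CV slack)

    def test_deterministic_refit(self, rng):
        df = _blob_matrix(rng, n_per_class=6)
        probe = _blob_matrix(np.random.default_rng(99), n_per_class=3)
        p1 = ens.train_base_bank(df, "svm", seed=3).predict_labels(probe)
        p2 = ens.train_base_bank(df, "svm", seed=3).predict_labels(probe)
        np.testing.assert_array_equal(p1, p2)

    def test_single_class_rejected(self, rng):
        df = _blob_matrix(rng, n_per_class=4)
        df["label"] = 1
        with pytest.raises(ValueError):
            ens.train_base_bank(df, "lda")


class TestPluralityVote:
    def test_clear_majority(self, rng):
        assert ens.plurality_vote([1, 1, 1, 2, 2, 3], rng) == 1

    def test_unanimous(self, rng):
        assert ens.plurality_vote([4, 4, 4, 4, 4, 4], rng) == 4

    def test_empty_rejected(self, rng):
        with pytest.raises(ValueError):
            ens.plurality_vote([], rng)

    def test_three_way_tie_uniform(self):
        rng = np.random.default_rng(0)
        counts = {1: 0, 2: 0, 3: 0}
        n = 10_000
        for _ in range(n):
            counts[ens.plurality_vote([1, 1, 2, 2, 3, 3], rng)] += 1
        sigma = np.sqrt(n * (1 / 3) * (2 / 3))
        for c in counts.values():
            assert abs(c - n / 3) < 3 * sigma

    @given(labels=st.lists(st.integers(1, 12), min_size=1, max_size=6))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_winner_is_among_inputs(self, labels):
        rng = np.random.default_rng(1)
        assert ens.plurality_vote(labels, rng) in labels


class TestWeightedVote:
    def test_hand_example(self, rng):
        w = np.array([[0.9, 0.1], [0.2, 0.8]])
        assert ens.weighted_vote([1, 2], w, rng) == 1

    def test_uniform_weights_reduce_to_plurality(self):
        w = np.ones((6, 12))
        for trial in range(1000):
            labels = np.random.default_rng(trial).integers(1, 13, size=6)
            r1 = np.random.default_rng(500 + trial)
            r2 = np.random.default_rng(500 + trial)
            assert ens.weighted_vote(labels, w, r1) == ens.plurality_vote(labels, r2)

    def test_unanimous_vote_wins_for_any_positive_weight(self, rng):
        w = np.random.default_rng(4).uniform(0.1, 1.0, size=(6, 12))
        for c in (1, 5, 12):
            assert ens.weighted_vote([c] * 6, w, rng) == c

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            ens.weighted_vote([1, 2, 3], np.ones((6, 12)), rng)

    def test_matches_oracle_when_untied(self, rng):
        r = np.random.default_rng(8)
        for _ in range(200):
            labels = r.integers(1, 13, size=6)
            w = r.uniform(0, 1, size=(6, 12))
            ref = oracles.weighted_oracle(labels.tolist(), w.tolist())
            if ref is not None:
                assert ens.weighted_vote(labels, w, rng) == ref


class TestRecallMatrix:
    def test_perfect_classifier_row_of_ones(self):
        y = np.repeat(np.arange(1, 13), 5)
        preds = y[None, :]
        np.testing.assert_array_equal(ens.recall_matrix(y, preds), np.ones((1, 12)))

    def test_always_class1_row(self):
        y = np.repeat(np.arange(1, 13), 5)
        preds = np.ones((1, y.size), dtype=int)
        expected = np.zeros((1, 12))
        expected[0, 0] = 1.0
        np.testing.assert_array_equal(ens.recall_matrix(y, preds), expected)


class _StubBank:
    """Bank whose 'classifiers' corrupt the hidden true label per row.

    The feature matrix encodes the row id in every feature block's first
    channel; predictions are looked up from precomputed corrupted-label
    tables, emulating classifiers with designed per-class recalls.
    """

    def __init__(self, corrupted):  # corrupted: (N, n_rows) int array
        self.corrupted = corrupted

    def predict_labels(self, df):
        idx = df["TA_MAV"].to_numpy().astype(int)
        return self.corrupted[:, idx].T


class TestWeightDerivation:
    def test_separable_blobs_give_near_unit_weights(self, rng):
        df = _blob_matrix(rng, n_per_class=10, sep=12.0, noise=0.3)
        w = ens.derive_weight_matrix(df, "lda", k_inner=5, seed=0)
        assert w.shape == (6, 12)
        assert np.all(w >= 0.9)

    def test_recovers_designed_recalls(self):
        # label-corruption model at n = 10^4: recall estimates within
        # 0.03 of the designed values, at the high-recall operating
        # point (0.90-0.98) base classifiers actually reach here
        rng = np.random.default_rng(0)
        n = 10_008  # 834 per class
        y = np.tile(np.arange(1, 13), n // 12)
        designed = rng.uniform(0.90, 0.98, size=(6, 12))
        corrupted = np.empty((6, n), dtype=int)
        for j in range(6):
            keep = rng.uniform(size=n) < designed[j, y - 1]
            wrong = ((y - 1 + rng.integers(1, 12, size=n)) % 12) + 1
            corrupted[j] = np.where(keep, y, wrong)
        rows = {"subject": "s", "terrain": "t", "kind": "k"}
        df = pd.DataFrame([dict(rows, label=y[i]) for i in range(n)])
        for f in SELECTED_FEATURES:
            for m in ("TA", "MG", "RF", "VL", "ES"):
                df[f"{m}_{f}"] = np.arange(n, dtype=float)
        w = ens.derive_weight_matrix(
            df, "lda", k_inner=5, seed=1,
            bank_factory=lambda *a, **k: _StubBank(corrupted),
        )
        # the nested-cross-training estimator is exact: it must equal the
        # empirical recall of the corrupted tables bit for bit
        np.testing.assert_array_equal(w, ens.recall_matrix(y, corrupted))
        assert np.max(np.abs(w - designed)) < 0.03

    def test_too_small_class_rejected(self, rng):
        df = _blob_matrix(rng, n_per_class=3)
        with pytest.raises(ValueError, match="class"):
            ens.derive_weight_matrix(df, "lda", k_inner=5)


class TestFusionProperties:
    def test_condorcet_style_dominance(self):
        # six independent classifiers, recall 0.7, errors uniform:
        # plurality fusion beats the best individual on 10^4 draws
        rng = np.random.default_rng(5)
        n, r = 10_000, 0.7
        y = rng.integers(1, 13, size=n)
        votes = np.empty((n, 6), dtype=int)
        for j in range(6):
            keep = rng.uniform(size=n) < r
            wrong = ((y - 1 + rng.integers(1, 12, size=n)) % 12) + 1
            votes[:, j] = np.where(keep, y, wrong)
        fused = ens.fuse_predictions(votes, rng)
        fused_acc = np.mean(fused == y)
        indiv = max(np.mean(votes[:, j] == y) for j in range(6))
        assert fused_acc >= indiv

    def test_shared_confusion_degrades_fusion(self):
        # every base classifier confuses class 1 with class 2 at 60%:
        # fused recall on class 1 falls below the mean base recall
        rng = np.random.default_rng(6)
        n = 5_000
        y = np.ones(n, dtype=int)
        votes = np.where(rng.uniform(size=(n, 6)) < 0.6, 2, 1)
        fused = ens.fuse_predictions(votes, rng)
        fused_recall = np.mean(fused == 1)
        mean_base = np.mean(votes == 1)
        assert fused_recall <= mean_base


class TestGradientBoosting:
    def test_separable_blobs_fit_perfectly(self, rng):
        df = _blob_matrix(rng, n_per_class=8, sep=12.0, noise=0.3)
        model = ens.train_gbm(df, seed=0)
        preds = ens.predict_gbm(model, df)
        assert np.mean(preds == df["label"].to_numpy()) == 1.0

    def test_seeded_determinism(self, rng):
        df = _blob_matrix(rng, n_per_class=6)
        probe = _blob_matrix(np.random.default_rng(11), n_per_class=3)
        p1 = ens.predict_gbm(ens.train_gbm(df, seed=7), probe)
        p2 = ens.predict_gbm(ens.train_gbm(df, seed=7), probe)
        np.testing.assert_array_equal(p1, p2)

    def test_single_class_rejected(self, rng):
        df = _blob_matrix(rng, n_per_class=4)
        df["label"] = 3
        with pytest.raises(ValueError):
            ens.train_gbm(df)
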