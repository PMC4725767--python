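"""Margin classifier, feature ranking, CV curve, signature and ROC."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from protosig import (
    CVConfig,
    ExpressionMatrix,
    ImputationParams,
    ParameterError,
    SampleAnnotation,
    SyntheticConfig,
    cv_feature_selection,
    extract_signature,
    generate,
    impute_downshift,
    predict,
    rank_features,
    roc_auc,
    select_optimal,
    train_margin_classifier,
)
from protosig.classify import AccuracyCurve

from conftest import random_matrix


def brute_force_auc(scores, labels):
    """Independent oracle: pairwise comparison statistic with ties as 1/2."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestMarginClassifier:
    def test_separable_case_classifies_training_points(self):
        X = np.array([[1.0], [2.0], [-1.0], [-2.0]])
        y = np.array([1, 1, 0, 0])
        clf = train_margin_classifier(X, y)
        assert (clf.predict(X) == y).all()
        # boundary between -1 and 1
        assert clf.decision_function([[0.0]])[0] == pytest.approx(0.0, abs=0.5)

    def test_duplicating_a_sample_preserves_separable_predictions(self, rng):
        X = np.vstack([rng.normal(2.0, 0.3, (8, 3)), rng.normal(-2.0, 0.3, (8, 3))])
        y = np.array([1] * 8 + [0] * 8)
        # test points from the class regions (not on the boundary, where an
        # infinitesimal shift of the standardization constants could flip them)
        test = np.vstack([rng.normal(1.5, 0.6, (15, 3)), rng.normal(-1.5, 0.6, (15, 3))])
        base = train_margin_classifier(X, y).predict(test)
        Xdup = np.vstack([X, X[:1]])
        ydup = np.append(y, y[0])
        dup = train_margin_classifier(Xdup, ydup).predict(test)
        assert (base == dup).all()

    def test_label_flip_negates_scores(self, rng):
        X = rng.normal(size=(20, 4))
        y = (rng.random(20) < 0.5).astype(int)
        if y.sum() in (0, 20):
            y[0] = 1 - y[0]
        test = rng.normal(size=(10, 4))
        a = train_margin_classifier(X, y).decision_function(test)
        b = train_margin_classifier(X, 1 - y).decision_function(test)
        assert np.allclose(a, -b, atol=1e-8)

    def test_zero_variance_feature_dropped_with_warning(self, rng):
        X = rng.normal(size=(12, 3))
        X[:, 1] = 5.0
        y = np.array([1] * 6 + [0] * 6)
        with pytest.warns(UserWarning, match="zero-variance"):
            clf = train_margin_classifier(X, y)
        assert clf.keep_.tolist() == [True, False, True]


class TestRankFeatures:
    def _separating_study(self, seed):
        rng = np.random.default_rng(seed)
        n = 24
        vals = rng.normal(size=(40, n))
        labels = ["A"] * 8 + ["B"] * 8 + ["C"] * 8
        vals[0] += np.where(np.array(labels) == "A", 4.0, 0.0)  # perfect separator
        m = ExpressionMatrix(
            pd.DataFrame(vals, index=[f"P{i:02d}" for i in range(40)],
                         columns=[f"s{j}" for j in range(n)])
        )
        ann = SampleAnnotation(pd.Series(labels, index=m.sample_ids))
        return m, ann

    def test_perfect_separator_ranks_first_across_subsets(self):
        hits = 0
        for seed in range(50):
            m, ann = self._separating_study(seed)
            rng = np.random.default_rng(1000 + seed)
            keep = np.sort(rng.choice(24, size=18, replace=False))
            sub = ExpressionMatrix(m.data.iloc[:, keep])
            sub_ann = SampleAnnotation(ann.labels.iloc[keep])
            rk = rank_features(sub, sub_ann, "A")
            hits += rk["protein_id"].iloc[0] == "P00"
        assert hits >= 49

    def test_identical_proteins_tie_broken_by_id(self, rng):
        m = random_matrix(rng, 6, 12, 0.0)
        m.data.iloc[3] = m.data.iloc[1]  # P003 == P001
        ann = SampleAnnotation(pd.Series(["X"] * 6 + ["Y"] * 6, index=m.sample_ids))
        rk = rank_features(m, ann, "X")
        pos1 = rk.index[rk["protein_id"] == "P001"][0]
        pos3 = rk.index[rk["protein_id"] == "P003"][0]
        assert abs(pos1 - pos3) == 1 and pos1 < pos3

    def test_invariant_to_sample_order(self, rng):
        m = random_matrix(rng, 30, 10, 0.0)
        ann = SampleAnnotation(pd.Series(["X"] * 5 + ["Y"] * 5, index=m.sample_ids))
        perm = list(rng.permutation(list(m.sample_ids)))
        shuffled = ExpressionMatrix(m.data[perm])
        a = rank_features(m, ann, "X")["protein_id"]
        b = rank_features(shuffled, ann, "X")["protein_id"]
        assert a.tolist() == b.tolist()


class TestCvFeatureSelection:
    def test_null_labels_give_chance_accuracy(self):
        """Random labels, balanced classes: accuracy ~ per-model chance level.

        For a one-vs-rest model with a 1/3-positive class the majority call
        gives ~2/3 binary accuracy; the test asserts the mean is within
        a generous band around it rather than above it.
        """
        rng = np.random.default_rng(7)
        vals = rng.normal(size=(60, 18))
        m = ExpressionMatrix(
            pd.DataFrame(vals, index=[f"P{i}" for i in range(60)],
                         columns=[f"s{j}" for j in range(18)])
        )
        ann = SampleAnnotation(pd.Series(["A", "B", "C"] * 6, index=m.sample_ids))
        cfg = CVConfig(n_runs=60, feature_grid=(1, 3, 5), test_fraction=0.2, seed=3)
        curve = cv_feature_selection(m, ann, cfg)
        for cls, df in curve.per_class.items():
            for _, row in df.iterrows():
                se = row["sd_accuracy"] / np.sqrt(row["n_runs"])
                assert abs(row["mean_accuracy"] - 2.0 / 3.0) < max(4 * se, 0.15)

    def test_planted_markers_beat_single_feature_and_reach_high_accuracy(self):
        maxima, improvements = [], []
        for seed in range(5):
            cfg = SyntheticConfig(
                n_proteins=300, markers_per_class=5, marker_effect=1.25,
                missing_target_fraction=0.1, n_enriched_categories=4,
                category_size=15, seed=seed,
            )
            m, ann, cats, truth = generate(cfg)
            imp = impute_downshift(m, ImputationParams(seed=seed))
            cv = CVConfig(n_runs=30, feature_grid=(1, 5, 10), seed=seed + 50)
            curve = cv_feature_selection(imp, ann, cv)
            for cls, df in curve.per_class.items():
                maxima.append(df["mean_accuracy"].max())
        assert np.median(maxima) >= 0.9

    def test_deterministic_under_seed(self, rng):
        m = random_matrix(rng, 40, 12, 0.0)
        ann = SampleAnnotation(pd.Series(["X"] * 6 + ["Y"] * 6, index=m.sample_ids))
        cfg = CVConfig(n_runs=2, feature_grid=(1, 2), seed=9)
        a = cv_feature_selection(m, ann, cfg)
        b = cv_feature_selection(m, ann, cfg)
        for cls in a.per_class:
            pd.testing.assert_frame_equal(a.per_class[cls], b.per_class[cls])

    def test_requires_complete_matrix(self, rng):
        m = random_matrix(rng, 30, 12, 0.2)
        ann = SampleAnnotation(pd.Series(["X"] * 6 + ["Y"] * 6, index=m.sample_ids))
        with pytest.raises(ParameterError, match="imputed"):
            cv_feature_selection(m, ann, CVConfig(n_runs=2, feature_grid=(1,)))


class TestSelectOptimal:
    @pytest.mark.parametrize(
        "accs,expected",
        [
            ([0.80, 0.90, 0.90, 0.85], 2),  # earliest maximum
            ([0.5, 0.6, 0.7, 0.8], 4),      # strictly increasing -> last
            ([0.7, 0.7, 0.7, 0.7], 1),      # constant -> first
        ],
    )
    def test_earliest_maximum(self, accs, expected):
        curve = AccuracyCurve(
            {
                "A": pd.DataFrame(
                    {"feature_count": [1, 2, 3, 4], "mean_accuracy": accs,
                     "sd_accuracy": 0.0, "n_runs": 10}
                )
            }
        )
        assert select_optimal(curve) == {"A": expected}


class TestSignature:
    def test_negative_marker_gets_negative_direction(self):
        cfg = SyntheticConfig(n_proteins=200, markers_per_class=4,
                              marker_effect=2.0, missing_target_fraction=0.0,
                              n_enriched_categories=3, category_size=10, seed=11)
        m, ann, cats, truth = generate(cfg)
        sig, models = extract_signature(m, ann, {c: 4 for c in ann.classes})
        sig = sig.set_index(["class_label", "protein_id"])
        checked = 0
        for cls, markers in truth.markers.items():
            for pid, effect in markers.items():
                if (cls, pid) in sig.index:
                    expected = "positive" if effect > 0 else "negative"
                    assert sig.loc[(cls, pid), "direction"] == expected
                    checked += 1
        assert checked >= 6  # most planted markers should be recovered here

    def test_protein_may_mark_two_classes(self, rng):
        # one protein high in A, low in B: legitimately in both signatures
        vals = rng.normal(size=(30, 12)) * 0.1
        labels = ["A"] * 4 + ["B"] * 4 + ["C"] * 4
        vals[0] = np.where(np.array(labels) == "A", 3.0, np.where(np.array(labels) == "B", -3.0, 0.0))
        m = ExpressionMatrix(pd.DataFrame(
            vals, index=[f"P{i}" for i in range(30)], columns=[f"s{j}" for j in range(12)]
        ))
        ann = SampleAnnotation(pd.Series(labels, index=m.sample_ids))
        sig, _ = extract_signature(m, ann, {"A": 1, "B": 1, "C": 1})
        marked = sig[sig["protein_id"] == "P0"]
        assert set(marked["class_label"]) == {"A", "B"}


class TestRocAuc:
    def test_perfect_separation(self):
        r = roc_auc([3.0, 2.0, 1.0, -1.0, -2.0], [1, 1, 1, 0, 0])
        assert r.auc == pytest.approx(1.0)

    def test_all_tied_scores_give_half(self):
        r = roc_auc([1.0] * 6, [1, 0, 1, 0, 1, 0])
        assert r.auc == pytest.approx(0.5)

    def test_worked_example_eight_ninths(self):
        r = roc_auc([0.9, 0.8, 0.4, 0.7, 0.3, 0.2], [1, 1, 1, 0, 0, 0])
        assert r.auc == pytest.approx(8.0 / 9.0)

    def test_matches_brute_force_on_small_instances(self, rng):
        for _ in range(60):
            n = int(rng.integers(4, 13))
            labels = np.zeros(n, dtype=int)
            labels[rng.choice(n, size=int(rng.integers(1, n)), replace=False)] = 1
            if labels.sum() in (0, n):
                continue
            scores = np.round(rng.normal(size=n), 1)  # rounding forces ties
            r = roc_auc(scores, labels)
            assert r.auc == pytest.approx(brute_force_auc(scores, labels))

    def test_curve_endpoints_monotone_and_trapezoid(self, rng):
        scores = rng.normal(size=40)
        labels = (rng.random(40) < 0.4).astype(int)
        r = roc_auc(scores, labels)
        assert (r.fpr[0], r.tpr[0]) == (0.0, 0.0)
        assert (r.fpr[-1], r.tpr[-1]) == (1.0, 1.0)
        assert (np.diff(r.fpr) >= 0).all() and (np.diff(r.tpr) >= 0).all()
        assert r.auc == pytest.approx(np.trapezoid(r.tpr, r.fpr), abs=1e-12)

    def test_single_class_raises(self):
        with pytest.raises(ParameterError):
            roc_auc([1.0, 2.0], [1, 1])


class TestPredict:
    def test_training_samples_predicted_correctly_when_separable(self):
        cfg = SyntheticConfig(n_proteins=100, markers_per_class=3,
                              marker_effect=3.0, missing_target_fraction=0.0,
                              n_enriched_categories=2, category_size=10, seed=5)
        m, ann, cats, truth = generate(cfg)
        sig, models = extract_signature(m, ann, {c: 3 for c in ann.classes})
        correct = 0
        for sid in m.sample_ids:
            got = predict(models, m.data[sid], ann.classes)
            correct += got == ann.labels[sid]
        assert correct / m.n_samples >= 0.95

    def test_missing_feature_raises_naming_it(self):
        cfg = SyntheticConfig(n_proteins=50, markers_per_class=2,
                              marker_effect=3.0, missing_target_fraction=0.0,
                              n_enriched_categories=2, category_size=8, seed=6)
        m, ann, cats, truth = generate(cfg)
        sig, models = extract_signature(m, ann, {c: 2 for c in ann.classes})
        sample = m.data[m.sample_ids[0]].copy()
        victim = models[ann.classes[0]].feature_ids_[0]
        sample[victim] = np.nan
        with pytest.raises(ParameterError, match=str(victim)):
            predict(models, sample, ann.classes)

    def test_prediction_invariant_to_feature_order(self):
        cfg = SyntheticConfig(n_proteins=60, markers_per_class=2,
                              marker_effect=3.0, missing_target_fraction=0.0,
                              n_enriched_categories=2, category_size=8, seed=8)
        m, ann, cats, truth = generate(cfg)
        sig, models = extract_signature(m, ann, {c: 2 for c in ann.classes})
        sample = m.data[m.sample_ids[0]]
        shuffled = sample.iloc[::-1]
        assert predict(models, sample, ann.classes) == predict(models, shuffled, ann.classes)
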