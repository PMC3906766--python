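import numpy as np
import pandas as pd
import pytest
from scipy.stats import pearsonr
from sklearn.metrics import roc_auc_score

from divsig.classify import (
    ClassifierConfig,
    MajorityClassifier,
    OneVsOneSVM,
    examples_to_frame,
    majority_classifier,
    train_classifier,
)
from divsig.evaluate import balance_classes, cross_validate
from divsig.io import LabeledExample
from divsig.metrics import PairwiseScoreSet, auc, influence_score, loss_decode, mcc


def brute_force_auc(scores, labels):
    """O(n^2) pair-counting oracle: P(pos > neg), ties counted one half."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestMcc:
    def test_perfect_and_inverse(self):
        assert mcc(tp=5, fp=0, tn=5, fn=0) == 1.0
        assert mcc(tp=0, fp=5, tn=0, fn=5) == -1.0

    def test_zero_denominator_convention(self):
        # constant predictor: no predicted negatives
        assert mcc(tp=3, fp=7, tn=0, fn=0) == 0.0

    def test_equals_pearson_of_indicator_vectors(self):
        rng = np.random.default_rng(0)
        checked = 0
        while checked < 1000:
            tp, fp, tn, fn = (int(x) for x in rng.integers(0, 20, size=4))
            if tp + fp + tn + fn == 0:
                continue
            truth = [1] * tp + [0] * fp + [1] * fn + [0] * tn
            pred = [1] * tp + [1] * fp + [0] * fn + [0] * tn
            got = mcc(tp, fp, tn, fn)
            if len(set(truth)) < 2 or len(set(pred)) < 2:
                assert got == 0.0  # convention where correlation is undefined
            else:
                assert got == pytest.approx(pearsonr(truth, pred).statistic, abs=1e-12)
            checked += 1


class TestAuc:
    def test_perfect_ranking(self):
        assert auc([0.9, 0.8, 0.2, 0.1], [True, True, False, False]) == 1.0

    def test_constant_scores_give_half(self):
        assert auc([1.0] * 6, [True, False, True, False, True, False]) == 0.5

    def test_one_class_absent_errors(self):
        with pytest.raises(ValueError, match="both classes"):
            auc([0.1, 0.2], [True, True])

    def test_matches_pair_counting_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(1000):
            n = int(rng.integers(4, 51))
            scores = np.round(rng.random(n), 1)  # induces ties
            labels = rng.random(n) > 0.5
            if labels.all() or not labels.any():
                labels[0] = not labels[0]
            assert auc(scores, labels) == pytest.approx(
                brute_force_auc(scores, labels), abs=1e-12
            )

    def test_matches_sklearn_without_ties(self):
        rng = np.random.default_rng(2)
        scores = rng.random(40)
        labels = rng.random(40) > 0.4
        labels[0], labels[1] = True, False
        assert auc(scores, labels) == pytest.approx(roc_auc_score(labels, scores))


def _toy_examples(n_per_class=20, classes=("MTS", "none"), sep=3.0, seed=0):
    rng = np.random.default_rng(seed)
    out = []
    for k, cls in enumerate(classes):
        for i in range(n_per_class):
            out.append(
                LabeledExample(
                    id=f"{cls}{i}",
                    features={
                        "f1": k * sep + rng.normal(0, 0.3),
                        "f2": rng.normal(0, 1.0),
                    },
                    label=cls,
                )
            )
    return out


class TestMajorityClassifier:
    def test_predicts_modal_label(self):
        examples = _toy_examples(5, ("none",)) + _toy_examples(3, ("MTS",))
        model = majority_classifier(examples)
        X, _ = examples_to_frame(examples)
        assert set(model.predict(X)) == {"none"}

    def test_tie_broken_by_class_order(self):
        examples = _toy_examples(4, ("MTS",)) + _toy_examples(4, ("SP",))
        model = majority_classifier(examples)
        assert model.majority_ == "MTS"

    def test_mcc_zero_and_auc_half_on_any_dataset(self):
        examples = _toy_examples(15, ("MTS", "none"), seed=5)
        X, y = examples_to_frame(examples)
        model = MajorityClassifier().fit(X, y)
        pred = model.predict(X)
        is_pos = y == "MTS"
        pred_pos = pred == "MTS"
        tp = int(np.sum(pred_pos & is_pos))
        fp = int(np.sum(pred_pos & ~is_pos))
        fn = int(np.sum(~pred_pos & is_pos))
        tn = int(np.sum(~pred_pos & ~is_pos))
        assert mcc(tp, fp, tn, fn) == 0.0
        post = model.class_posteriors(X)
        assert auc(post["MTS"].to_numpy(), is_pos) == 0.5


class TestSvm:
    def test_linearly_separable_training_accuracy(self):
        examples = _toy_examples(20)
        X, y = examples_to_frame(examples)
        model = train_classifier(X, ClassifierConfig(kind="svm"), y=y)
        assert np.mean(model.predict(X) == y) == 1.0

    def test_three_class_has_three_machines(self):
        examples = _toy_examples(10, ("MTS", "SP", "none"))
        X, y = examples_to_frame(examples)
        model = train_classifier(X, ClassifierConfig(kind="svm"), y=y)
        assert isinstance(model, OneVsOneSVM)
        assert model.n_machines == 3
        assert len(model.pairwise_scores(X)[0].scores) == 3

    def test_xor_pattern_is_learnable(self):
        rng = np.random.default_rng(3)
        X, y = [], []
        for _ in range(80):
            a, b = rng.integers(0, 2), rng.integers(0, 2)
            X.append([a + rng.normal(0, 0.05), b + rng.normal(0, 0.05)])
            y.append("MTS" if a ^ b else "none")
        X = pd.DataFrame(X, columns=["x1", "x2"])
        y = np.array(y, dtype=object)
        model = train_classifier(X, ClassifierConfig(kind="svm"), y=y)
        assert np.mean(model.predict(X.to_numpy()) == y) == 1.0

    def test_single_class_training_errors(self):
        examples = _toy_examples(10, ("MTS",))
        X, y = examples_to_frame(examples)
        with pytest.raises(ValueError, match="single class"):
            train_classifier(X, ClassifierConfig(kind="svm"), y=y)

    def test_tree_baseline_fits(self):
        examples = _toy_examples(20)
        X, y = examples_to_frame(examples)
        model = train_classifier(X, ClassifierConfig(kind="tree"), y=y)
        assert np.mean(model.predict(X) == y) >= 0.9


class TestLossDecode:
    @staticmethod
    def _scores(mts_sp, mts_none, sp_none):
        return PairwiseScoreSet(
            {("MTS", "SP"): mts_sp, ("MTS", "none"): mts_none, ("SP", "none"): sp_none}
        )

    def test_zero_scores_give_equal_losses(self):
        decoded = loss_decode(self._scores(0.0, 0.0, 0.0))
        losses = list(decoded.losses.values())
        assert losses == pytest.approx([losses[0]] * 3)
        assert list(decoded.posteriors.values()) == pytest.approx([1 / 3] * 3)

    def test_strong_scores_favor_class(self):
        decoded = loss_decode(self._scores(3.0, 3.0, 0.0))
        assert decoded.label == "MTS"
        assert decoded.losses["MTS"] < min(decoded.losses["SP"], decoded.losses["none"])

    def test_two_class_monotone_in_score(self):
        s_small = PairwiseScoreSet({("MTS", "none"): 0.5})
        s_large = PairwiseScoreSet({("MTS", "none"): 2.0})
        d_small, d_large = loss_decode(s_small), loss_decode(s_large)
        assert d_large.posteriors["MTS"] > d_small.posteriors["MTS"] > 0.5


class TestInfluence:
    @staticmethod
    def _scores(a, b, c):
        return PairwiseScoreSet(
            {("MTS", "SP"): a, ("MTS", "none"): b, ("SP", "none"): c}
        )

    def test_identical_sets_have_zero_influence(self):
        s = self._scores(1.0, -0.5, 0.3)
        infl, lw, lwo = influence_score(s, s)
        assert infl == 0.0 and lw == lwo

    def test_sign_flip_changes_label_and_influence_positive(self):
        s = self._scores(2.0, 2.0, 0.0)
        infl, lw, lwo = influence_score(s, s.negated())
        assert infl > 0
        assert lw == "MTS" and lwo != "MTS"

    def test_symmetry(self):
        s1 = self._scores(1.0, 0.2, -0.4)
        s2 = self._scores(-0.3, 1.5, 0.8)
        assert influence_score(s1, s2)[0] == pytest.approx(influence_score(s2, s1)[0])


class TestCrossValidate:
    def test_perfectly_separable_data(self):
        examples = _toy_examples(25, sep=10.0)
        result = cross_validate(examples, ClassifierConfig(kind="svm"), folds=5, repeats=2)
        assert result.accuracy == 100.0
        assert result.accuracy_sd == 0.0

    def test_confusion_rows_sum_to_class_counts(self):
        examples = _toy_examples(15, ("MTS", "SP", "none"), sep=1.0, seed=9)
        result = cross_validate(examples, ClassifierConfig(kind="svm"), folds=3, repeats=2)
        assert result.confusion.loc["MTS"].sum() == pytest.approx(15)
        assert result.confusion.to_numpy().sum() == pytest.approx(45)
        assert result.accuracy == pytest.approx(
            100 * np.trace(result.confusion.to_numpy()) / 45, abs=1e-9
        )

    def test_bit_reproducible_given_seed(self):
        examples = _toy_examples(15, sep=1.0, seed=4)
        cfg = ClassifierConfig(kind="svm")
        r1 = cross_validate(examples, cfg, folds=5, repeats=2, seed=99)
        r2 = cross_validate(examples, cfg, folds=5, repeats=2, seed=99)
        assert r1.accuracy == r2.accuracy
        pd.testing.assert_frame_equal(r1.per_class, r2.per_class)
        pd.testing.assert_frame_equal(r1.confusion, r2.confusion)

    def test_class_smaller_than_folds_errors(self):
        examples = _toy_examples(3, ("MTS", "none"))
        with pytest.raises(ValueError, match="fold"):
            cross_validate(examples, ClassifierConfig(kind="svm"), folds=5)


class TestBalanceClasses:
    def test_subsamples_to_minimum(self):
        examples = (
            _toy_examples(45, ("none",))
            + _toy_examples(18, ("MTS",))
            + _toy_examples(6, ("SP",))
        )
        balanced = balance_classes(examples, seed=0)
        counts = pd.Series([ex.label for ex in balanced]).value_counts()
        assert set(counts) == {6}

    def test_already_balanced_unchanged(self):
        examples = _toy_examples(8, ("MTS", "none"))
        balanced = balance_classes(examples, seed=1)
        assert sorted(ex.id for ex in balanced) == sorted(ex.id for ex in examples)

    def test_seeds_give_different_subsets_same_sizes(self):
        examples = _toy_examples(40, ("none",)) + _toy_examples(10, ("MTS",))
        b1 = balance_classes(examples, seed=1)
        b2 = balance_classes(examples, seed=2)
        assert len(b1) == len(b2) == 20
        assert {ex.id for ex in b1} != {ex.id for ex in b2}
        assert balance_classes(examples, seed=1) == b1  # deterministic
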