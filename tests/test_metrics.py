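"""Confusion metrics, kappa statistics and fold construction.

Independent oracles: scikit-learn for precision/recall/F1, statsmodels for
Cohen and Fleiss kappa point estimates, simulation for the null behaviour.
"""

import numpy as np
import pytest

from somnoscore.metrics import (AgreementCategory, ConfusionMatrix,
                                NoEvaluableEpochsError, cohen_kappa,
                                confusion, fleiss_kappa, mchugh_category,
                                report, subject_wise_folds)
from somnoscore.stages import SCOREABLE_STAGES, StageLabel

W, N1, N2, N3, REM = SCOREABLE_STAGES


def _embed_2x2(a, b, c, d):
    cm = np.zeros((5, 5), dtype=int)
    cm[0, 0], cm[0, 1], cm[1, 0], cm[1, 1] = a, b, c, d
    return ConfusionMatrix(cm)


class TestConfusion:
    def test_identical_labels_diagonal(self):
        labels = [W, N1, N2, N3, REM, N2]
        cm = confusion(labels, labels)
        assert cm.counts.sum() == 6
        assert np.all(cm.counts == np.diag(np.diag(cm.counts)))

    def test_masked_and_unscoreable_epochs_skipped(self):
        ref = [W, StageLabel.MOVEMENT, N2]
        pred = [W, W, N3]
        cm = confusion(ref, pred, np.array([True, False, True]))
        assert cm.total == 2
        assert cm.counts[N2.value, N3.value] == 1

    def test_empty_mask_gives_zero_matrix(self):
        cm = confusion([W, N2], [W, N2], np.zeros(2, bool))
        assert cm.total == 0
        with pytest.raises(NoEvaluableEpochsError):
            report(cm)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion([W], [W, N1])


class TestReport:
    def test_perfect_diagonal(self):
        cm = ConfusionMatrix(np.diag([5, 5, 5, 5, 5]))
        rep = report(cm)
        assert rep.acc == pytest.approx(100.0)
        assert rep.mf1 == pytest.approx(100.0)

    def test_two_class_hand_example(self):
        with pytest.warns(UserWarning):
            rep = report(_embed_2x2(45, 5, 15, 35))
        assert rep.acc == pytest.approx(80.0)
        assert rep.f1[0] == pytest.approx(81.8181818, abs=1e-4)
        assert rep.f1[1] == pytest.approx(77.7777777, abs=1e-4)

    def test_absent_class_f1_zero_still_averaged(self):
        with pytest.warns(UserWarning):
            rep = report(_embed_2x2(45, 5, 15, 35))
        assert rep.f1[2:].tolist() == [0.0, 0.0, 0.0]
        assert rep.mf1 == pytest.approx(np.mean(rep.f1))

    def test_matches_sklearn_on_random_matrices(self, rng):
        from sklearn.metrics import precision_recall_fscore_support

        for _ in range(200):
            cm = rng.integers(0, 30, size=(5, 5))
            if cm.sum() == 0 or (cm.sum(0) == 0).any() or (cm.sum(1) == 0).any():
                continue
            ref, pred = [], []
            for i in range(5):
                for j in range(5):
                    ref += [i] * cm[i, j]
                    pred += [j] * cm[i, j]
            p, r, f, _ = precision_recall_fscore_support(
                ref, pred, labels=range(5), zero_division=0)
            rep = report(ConfusionMatrix(cm))
            np.testing.assert_allclose(rep.precision, p * 100, atol=1e-10)
            np.testing.assert_allclose(rep.recall, r * 100, atol=1e-10)
            np.testing.assert_allclose(rep.f1, f * 100, atol=1e-10)


class TestCohenKappa:
    def test_perfect_agreement(self):
        res = cohen_kappa(ConfusionMatrix(np.diag([3, 3, 3, 3, 3])))
        assert res.kappa == pytest.approx(1.0)

    def test_hand_example_2x2(self):
        res = cohen_kappa(_embed_2x2(45, 5, 15, 35))
        assert res.kappa == pytest.approx(0.6, abs=1e-12)
        assert res.ci_low <= res.kappa <= res.ci_high
        assert res.p_value < 0.001

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.inter_rater import cohens_kappa

        for _ in range(50):
            cm = rng.integers(1, 40, size=(5, 5))
            ours = cohen_kappa(ConfusionMatrix(cm))
            ref = cohens_kappa(cm)
            assert ours.kappa == pytest.approx(ref.kappa, abs=1e-10)
            assert ours.se == pytest.approx(np.sqrt(ref.var_kappa), abs=1e-10)
            assert ours.ci_low == pytest.approx(ref.kappa_low, abs=1e-8)
            assert ours.ci_high == pytest.approx(ref.kappa_upp, abs=1e-8)

    def test_independent_raters_near_zero(self, rng):
        n = 10000
        a = rng.integers(0, 5, n)
        b = rng.integers(0, 5, n)
        cm = np.zeros((5, 5), dtype=int)
        np.add.at(cm, (a, b), 1)
        res = cohen_kappa(ConfusionMatrix(cm))
        # kappa ~ N(0, se0) under independence
        assert abs(res.kappa) < 3.5 * res.se
        assert mchugh_category(res.kappa) is AgreementCategory.NONE

    def test_kappa_one_iff_diagonal(self, rng):
        cm = rng.integers(1, 20, size=(5, 5))
        assert cohen_kappa(ConfusionMatrix(cm)).kappa < 1.0
        assert cohen_kappa(
            ConfusionMatrix(np.diag(np.diag(cm)))).kappa == pytest.approx(1.0)


class TestFleissKappa:
    def test_unanimous_agreement(self):
        table = np.zeros((6, 5), dtype=int)
        table[:3, 0] = 4
        table[3:, 2] = 4
        assert fleiss_kappa(table).kappa == pytest.approx(1.0)

    def test_two_item_three_rater_hand_example(self):
        # item 1: all three raters say W; item 2: two W, one N1
        table = np.array([[3, 0, 0, 0, 0], [2, 1, 0, 0, 0]])
        res = fleiss_kappa(table)
        assert res.kappa == pytest.approx(-0.2, abs=1e-12)

    def test_matches_statsmodels_point_estimate(self, rng):
        from statsmodels.stats.inter_rater import fleiss_kappa as sm_fleiss

        for _ in range(20):
            raters = 4
            votes = rng.integers(0, 5, size=(50, raters))
            table = np.zeros((50, 5), dtype=int)
            for i in range(50):
                np.add.at(table[i], votes[i], 1)
            assert fleiss_kappa(table).kappa == pytest.approx(
                sm_fleiss(table), abs=1e-10)

    def test_two_rater_binary_matches_cohen(self, rng):
        """Known equivalence on the induced 2x2 table (Scott's-pi form holds
        when the two raters share marginals; use symmetric data)."""
        n = 2000
        a = rng.integers(0, 2, n)
        flip = rng.random(n) < 0.15
        b = np.where(flip, 1 - a, a)
        # symmetrize by pooling both orientations
        A = np.concatenate([a, b])
        B = np.concatenate([b, a])
        cm = np.zeros((5, 5), dtype=int)
        np.add.at(cm, (A, B), 1)
        table = np.zeros((2 * n, 5), dtype=int)
        rows = np.arange(2 * n)
        np.add.at(table, (rows, A), 1)
        np.add.at(table, (rows, B), 1)
        assert fleiss_kappa(table).kappa == pytest.approx(
            cohen_kappa(ConfusionMatrix(cm)).kappa, abs=1e-10)

    def test_independent_raters_near_zero(self, rng):
        votes = rng.integers(0, 5, size=(4000, 3))
        table = np.zeros((4000, 5), dtype=int)
        for i in range(4000):
            np.add.at(table[i], votes[i], 1)
        res = fleiss_kappa(table)
        assert abs(res.kappa) < 3.5 * res.se

    def test_inconsistent_row_sums_rejected(self):
        with pytest.raises(ValueError):
            fleiss_kappa(np.array([[3, 0, 0, 0, 0], [2, 0, 0, 0, 0]]))


class TestMcHughBands:
    @pytest.mark.parametrize("kappa,expected", [
        (0.8221, AgreementCategory.STRONG),
        (0.6976, AgreementCategory.MODERATE),
        (0.20, AgreementCategory.NONE),
        (0.21, AgreementCategory.MINIMAL),
        (-0.5, AgreementCategory.NONE),
        (0.40, AgreementCategory.WEAK),
        (0.95, AgreementCategory.ALMOST_PERFECT),
        (0.90, AgreementCategory.STRONG),
    ])
    def test_banding(self, kappa, expected):
        assert mchugh_category(kappa) is expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            mchugh_category(1.5)


class TestSubjectWiseFolds:
    def test_leave_one_subject_out(self):
        ids = [f"S{i}" for i in range(20) for _ in range(2)]  # 39-ish records
        folds = subject_wise_folds(ids, 20, seed=0)
        assert len(set(folds.values())) == 20
        sizes = [sum(1 for v in folds.values() if v == f) for f in range(20)]
        assert sizes == [1] * 20

    def test_balanced_round_robin(self):
        ids = [f"S{i}" for i in range(78)]
        folds = subject_wise_folds(ids, 10, seed=1)
        sizes = [sum(1 for v in folds.values() if v == f) for f in range(10)]
        assert set(sizes) <= {7, 8}

    def test_partition_property(self):
        ids = [f"S{i}" for i in range(15)]
        folds = subject_wise_folds(ids, 4, seed=2)
        assert set(folds) == set(ids)  # every subject in exactly one fold

    def test_k_too_large_rejected(self):
        with pytest.raises(ValueError):
            subject_wise_folds(["a", "b"], 3)
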