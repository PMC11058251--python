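"""Class-weight formula and the stage-weighted cross-entropy."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from somnoscore import nn
from somnoscore.cnn import (ClassWeights, SleepStageCNN, _onehot,
                            compute_class_weights, weighted_cross_entropy)
from somnoscore.stages import SCOREABLE_STAGES, StageLabel


def _counts(vals):
    return dict(zip(SCOREABLE_STAGES, vals))


class TestComputeClassWeights:
    def test_balanced_counts(self):
        cw = compute_class_weights(_counts([100] * 5), StageLabel.N1)
        assert cw.w[StageLabel.N1.value] == pytest.approx(2.5)
        for s in SCOREABLE_STAGES:
            if s is not StageLabel.N1:
                assert cw.w[s.value] == pytest.approx(0.625)

    def test_imbalanced_counts(self):
        cw = compute_class_weights(
            _counts([500, 100, 800, 300, 300]), StageLabel.N1)
        assert cw.w[StageLabel.N1.value] == pytest.approx(10.0)
        assert cw.w[StageLabel.W.value] == pytest.approx(0.5 / 0.95)

    def test_degenerate_target_rejected(self):
        with pytest.raises(ValueError):
            compute_class_weights(_counts([10, 0, 10, 10, 10]), StageLabel.N1)
        with pytest.raises(ValueError):
            compute_class_weights(_counts([0, 5, 0, 0, 0]), StageLabel.N1)

    @given(st.lists(st.integers(1, 10000), min_size=5, max_size=5),
           st.integers(0, 4))
    @settings(max_examples=100, deadline=None)
    def test_weight_proportion_product_is_half(self, counts, target_idx):
        """w_i * p_i = 0.5 holds for every stage, for any valid counts."""
        cw = compute_class_weights(_counts(counts),
                                   SCOREABLE_STAGES[target_idx])
        np.testing.assert_allclose(cw.w * cw.p, 0.5, rtol=1e-12)


class TestWeightedCrossEntropy:
    def test_perfect_prediction_near_zero(self):
        Y = np.eye(5)[[0, 2, 4]]
        assert weighted_cross_entropy(Y, Y, np.ones(5)) < 1e-9

    def test_uniform_prediction_closed_form(self):
        Y = np.eye(5)[[1]]
        p = np.full((1, 5), 0.2)
        assert weighted_cross_entropy(p, Y, np.ones(5)) == pytest.approx(np.log(5))

    def test_weighted_single_row(self):
        w = np.array([0.625, 2.5, 0.625, 0.625, 0.625])
        Y = np.eye(5)[[1]]
        p = np.full((1, 5), 0.125)
        p[0, 1] = 0.5
        assert weighted_cross_entropy(p, Y, w) == pytest.approx(2.5 * np.log(2))

    def test_all_ones_matches_plain_cross_entropy(self, rng):
        """With unit weights the loss equals an independently coded CE."""
        for _ in range(20):
            n = int(rng.integers(2, 40))
            p = rng.dirichlet(np.ones(5), size=n)
            y = rng.integers(0, 5, n)
            Y = _onehot(y)
            plain = -np.mean([np.log(p[i, y[i]]) for i in range(n)])
            ours = weighted_cross_entropy(p, Y, np.ones(5))
            assert abs(ours - plain) < 1e-10

    def test_permutation_invariance(self, rng):
        p = rng.dirichlet(np.ones(5), size=12)
        Y = _onehot(rng.integers(0, 5, 12))
        w = rng.uniform(0.3, 3.0, 5)
        perm = rng.permutation(12)
        assert weighted_cross_entropy(p, Y, w) == pytest.approx(
            weighted_cross_entropy(p[perm], Y[perm], w), rel=1e-12)

    def test_monotone_in_target_class_weight(self, rng):
        p = rng.dirichlet(np.ones(5), size=10)
        y = np.full(10, 2)
        Y = _onehot(y)
        w_lo, w_hi = np.ones(5), np.ones(5)
        w_hi[2] = 4.0
        assert (weighted_cross_entropy(p, Y, w_hi)
                > weighted_cross_entropy(p, Y, w_lo))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            weighted_cross_entropy(np.ones((2, 5)) / 5, np.eye(5), np.ones(5))


class TestLossGradient:
    def test_finite_difference_gradient_of_logits(self, rng):
        """Analytic d(loss)/d(logits) matches central differences to 1e-5."""
        for _ in range(5):
            n = int(rng.integers(2, 8))
            logits = rng.normal(size=(n, 5))
            y = rng.integers(0, 5, n)
            Y = _onehot(y)
            w = rng.uniform(0.3, 3.0, 5)

            def loss(lg):
                return weighted_cross_entropy(nn.softmax(lg, axis=1), Y, w)

            p = nn.softmax(logits, axis=1)
            analytic = (w[y][:, None] * (p - Y)) / n
            eps = 1e-6
            for _ in range(10):
                i, j = int(rng.integers(0, n)), int(rng.integers(0, 5))
                up, dn = logits.copy(), logits.copy()
                up[i, j] += eps
                dn[i, j] -= eps
                num = (loss(up) - loss(dn)) / (2 * eps)
                assert abs(num - analytic[i, j]) < 1e-5

    def test_full_network_gradients(self, rng):
        """Backprop through the whole CNN agrees with finite differences."""
        m = SleepStageCNN(seed=1, dtype=np.float64)
        x = rng.normal(size=(3, 3000))
        y = rng.integers(0, 5, 3)
        Y = _onehot(y)
        w = np.array([2.5, 0.6, 0.6, 0.6, 0.6])

        def loss():
            p = nn.softmax(m.logits(x, train=True), axis=1)
            return weighted_cross_entropy(p, Y, w), p

        _, p = loss()
        m.backward((w[y][:, None] * (p - Y)) / 3)
        params, grads = m.parameters(), m.gradients()
        for pi in (0, 2, 4, 6, 9, 11):
            P, G = params[pi], grads[pi]
            for _ in range(3):
                idx = tuple(int(rng.integers(0, s)) for s in P.shape)
                eps, old = 1e-6, P[idx]
                P[idx] = old + eps
                lp, _ = loss()
                P[idx] = old - eps
                lm, _ = loss()
                P[idx] = old
                num = (lp - lm) / (2 * eps)
                denom = max(1e-6, abs(num) + abs(G[idx]))
                assert abs(num - G[idx]) / denom < 1e-4
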