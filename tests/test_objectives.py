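"""Loss formulas against independent brute-force loop oracles, and the
behavioural invariants of dynamic task weighting and class balancing."""

import numpy as np
import pytest

from specmol import objectives as obj
from specmol.autograd import Tensor


class TestDynamicTaskWeights:
    def test_direct_evaluation(self):
        state = obj.TaskState(lambda_raw=np.array([0.5]),
                              loss_history_mean=np.array([2.0]),
                              gamma=0.2, epsilon=0.0)
        new = obj.update_task_weights(state, np.array([3.0]))
        assert new.lambda_raw[0] == pytest.approx(0.55)

    def test_loss_at_history_mean_leaves_weight(self):
        state = obj.TaskState(lambda_raw=np.array([0.7, 1.3]),
                              loss_history_mean=np.array([1.0, 2.0]))
        new = obj.update_task_weights(state, np.array([1.0, 2.0]))
        np.testing.assert_allclose(new.lambda_raw, [0.7, 1.3])

    def test_gamma_zero_disables_adjustment(self):
        state = obj.TaskState(lambda_raw=np.array([0.7, 1.3]),
                              loss_history_mean=np.array([1.0, 2.0]),
                              gamma=0.0)
        new = obj.update_task_weights(state, np.array([9.0, 0.01]))
        np.testing.assert_allclose(new.lambda_raw, [0.7, 1.3])

    def test_monotone_response_and_floor(self):
        state = obj.TaskState(lambda_raw=np.array([1.0, 1.0, 1.0]),
                              loss_history_mean=np.array([1.0, 1.0, 1.0]),
                              gamma=0.5)
        new = obj.update_task_weights(state, np.array([2.0, 1.0, 0.0]))
        assert new.lambda_raw[0] > 1.0          # loss above history
        assert new.lambda_raw[1] == pytest.approx(1.0)
        assert new.lambda_raw[2] < 1.0          # loss below history
        # extreme negative deviation hits the floor, never goes negative
        state = obj.TaskState(lambda_raw=np.array([1.0]),
                              loss_history_mean=np.array([10.0]), gamma=5.0)
        new = obj.update_task_weights(state, np.array([0.0]))
        assert new.lambda_raw[0] == pytest.approx(obj.WEIGHT_FLOOR)

    def test_nan_loss_names_task(self):
        state = obj.TaskState.initial(2)
        with pytest.raises(FloatingPointError, match="task index 1"):
            obj.update_task_weights(state, np.array([1.0, np.nan]))

    def test_history_initialized_to_first_loss(self):
        state = obj.TaskState.initial(1)
        new = obj.update_task_weights(state, np.array([4.2]))
        np.testing.assert_allclose(new.lambda_raw, [1.0])  # first step: no-op
        np.testing.assert_allclose(new.loss_history_mean, [4.2])

    @pytest.mark.parametrize("raw,expected", [
        ([1.0, 3.0], [0.25, 0.75]),
        ([2.0, 2.0, 2.0], [1 / 3, 1 / 3, 1 / 3]),
    ])
    def test_normalization_examples(self, raw, expected):
        state = obj.TaskState(lambda_raw=np.array(raw))
        np.testing.assert_allclose(obj.normalize_task_weights(state), expected)

    def test_normalization_sums_to_one(self, rng):
        for _ in range(10):
            state = obj.TaskState(lambda_raw=rng.uniform(0.01, 5.0, size=6))
            assert obj.normalize_task_weights(state).sum() == \
                pytest.approx(1.0, abs=1e-12)


class TestClassWeights:
    def test_single_sample_class_weight_is_one(self):
        for beta in (0.5, 0.9, 0.999):
            cw = obj.class_weights([1, 1], beta_cb=beta)
            np.testing.assert_allclose(cw.w, [1.0, 1.0])

    def test_direct_evaluation(self):
        cw = obj.class_weights([2, 2], beta_cb=0.9)
        assert cw.w[0] == pytest.approx(0.1 / (1 - 0.81))

    def test_normalization_and_minority_boost(self):
        cw = obj.class_weights([10, 990], beta_cb=0.99)
        assert cw.w_norm.sum() == pytest.approx(2.0, abs=1e-9)
        assert cw.w_norm[0] > cw.w_norm[1]

    def test_beta_to_zero_equalizes(self):
        cw = obj.class_weights([3, 1000], beta_cb=1e-9)
        np.testing.assert_allclose(cw.w, [1.0, 1.0], rtol=1e-6)

    def test_weight_decreases_with_count(self):
        counts = np.array([1, 5, 50, 500])
        cw = obj.class_weights(counts, beta_cb=0.95)
        assert np.all(np.diff(cw.w) < 0)

    def test_zero_count_class_excluded(self, caplog):
        cw = obj.class_weights([0, 4], beta_cb=0.9)
        assert cw.w[0] == 0.0
        assert cw.w_norm.sum() == pytest.approx(1.0)  # C = 1 observed class


class TestPretrainLoss:
    def test_zero_when_prediction_equals_target(self):
        pred = np.ones((4, 5))
        loss = obj.pretrain_loss(pred, pred.copy(), np.array([1, 0, 1, 0],
                                                            dtype=bool),
                                 np.zeros(3), np.zeros(3))
        assert float(loss.data) == 0.0

    def test_unit_displacement(self):
        pred = np.zeros((2, 3))
        target = np.zeros((2, 3))
        pred[0, 0] = 1.0
        g_pred, g_tgt = np.array([1.0, 1.0]), np.array([1.0, 0.0])
        loss = obj.pretrain_loss(pred, target, np.array([True, False]),
                                 g_pred, g_tgt)
        assert float(loss.data) == pytest.approx(1.0 + 1.0)

    def test_matches_double_loop_oracle(self, rng):
        pred = rng.normal(size=(6, 4))
        target = rng.normal(size=(6, 4))
        mask = rng.random(6) < 0.5
        mask[0] = True
        gp, gt = rng.normal(size=3), rng.normal(size=3)
        expected = sum((pred[v, d] - target[v, d]) ** 2
                       for v in range(6) if mask[v] for d in range(4))
        expected += sum((gp[d] - gt[d]) ** 2 for d in range(3))
        loss = obj.pretrain_loss(pred, target, mask, gp, gt)
        assert float(loss.data) == pytest.approx(expected, abs=1e-9)

    def test_requires_some_target(self):
        with pytest.raises(ValueError):
            obj.pretrain_loss(np.zeros((2, 2)), np.zeros((2, 2)),
                              np.zeros(2, dtype=bool))


class TestWeightedBCE:
    def test_closed_form(self):
        _, loss = obj.weighted_bce(np.array([0.5]), np.array([1.0]))
        assert float(loss.data) == pytest.approx(np.log(2.0))

    def test_perfect_prediction_near_zero(self):
        _, loss = obj.weighted_bce(np.array([1.0, 0.0]), np.array([1.0, 0.0]))
        assert float(loss.data) < 1e-5

    def test_matches_loop_oracle(self, rng):
        p = rng.uniform(0.05, 0.95, size=12)
        y = (rng.random(12) < 0.4).astype(float)
        y[3] = np.nan
        w1, w0 = 1.7, 0.4
        per, loss = obj.weighted_bce(p, y, w1=w1, w0=w0)
        expected = [-w1 * yi * np.log(pi) - w0 * (1 - yi) * np.log(1 - pi)
                    for pi, yi in zip(p, y) if not np.isnan(yi)]
        np.testing.assert_allclose(per.data, expected, atol=1e-9)
        assert float(loss.data) == pytest.approx(np.mean(expected), abs=1e-9)

    def test_all_missing_contributes_zero(self):
        _, loss = obj.weighted_bce(np.array([0.5]), np.array([np.nan]))
        assert float(loss.data) == 0.0


class TestClassificationLoss:
    def test_uniform_weights_equal_losses(self):
        out = obj.classification_loss([Tensor(0.8), Tensor(0.8)], [0.5, 0.5])
        assert float(out.data) == pytest.approx(0.8)

    def test_degenerate_weighting_selects_task(self):
        out = obj.classification_loss([Tensor(3.0), Tensor(9.0)], [1.0, 0.0])
        assert float(out.data) == pytest.approx(3.0)

    def test_matches_dot_product(self, rng):
        losses = rng.uniform(0, 2, size=5)
        w = rng.uniform(0, 1, size=5)
        out = obj.classification_loss([Tensor(l) for l in losses], w)
        assert float(out.data) == pytest.approx(losses @ w, abs=1e-12)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            obj.classification_loss([Tensor(1.0)], [0.5, 0.5])


class TestSupCon:
    def test_identical_same_class_embeddings_zero(self):
        H = np.ones((2, 4))
        loss = obj.supcon_loss(H, [1, 1], tau=1.0)
        assert float(loss.data) == pytest.approx(0.0, abs=1e-12)

    def test_all_positives_zero(self, rng):
        H = rng.normal(size=(5, 3))
        loss = obj.supcon_loss(H, [2, 2, 2, 2, 2], tau=0.3)
        assert float(loss.data) == pytest.approx(0.0, abs=1e-12)

    def test_matches_double_loop_oracle(self, rng):
        n, tau = 8, 0.5
        H = rng.normal(size=(n, 6))
        labels = np.array([0, 1, 0, 1, 1, 0, 0, 1])
        Hn = H / np.linalg.norm(H, axis=1, keepdims=True)
        sim = Hn @ Hn.T
        per_anchor = []
        for i in range(n):
            num = sum(np.exp(sim[i, j] / tau) for j in range(n)
                      if j != i and labels[j] == labels[i])
            den = sum(np.exp(sim[i, k] / tau) for k in range(n) if k != i)
            per_anchor.append(-np.log(num / den))
        expected = np.mean(per_anchor)
        loss = obj.supcon_loss(H, labels, tau=tau)
        assert float(loss.data) == pytest.approx(expected, abs=1e-9)

    def test_nonnegative_on_random_batches(self):
        rng = np.random.Generator(np.random.PCG64(99))
        for _ in range(100):
            n = int(rng.integers(3, 10))
            H = rng.normal(size=(n, 5))
            labels = rng.integers(0, 3, size=n)
            loss = obj.supcon_loss(H, labels, tau=0.1)
            assert float(loss.data) >= -1e-12

    def test_no_positive_anchor_returns_zero(self, rng):
        loss = obj.supcon_loss(rng.normal(size=(3, 4)), [0, 1, 2])
        assert float(loss.data) == 0.0

    def test_invalid_tau(self, rng):
        with pytest.raises(ValueError):
            obj.supcon_loss(rng.normal(size=(3, 4)), [0, 0, 1], tau=0.0)


class TestTotalLoss:
    def test_lambda_zero(self):
        assert float(obj.total_loss(Tensor(1.3), Tensor(9.9), 0.0).data) \
            == pytest.approx(1.3)

    def test_arithmetic(self):
        assert float(obj.total_loss(Tensor(1.0), Tensor(0.5), 0.1).data) \
            == pytest.approx(1.05)

    def test_linear_in_lambda(self):
        vals = [float(obj.total_loss(Tensor(2.0), Tensor(3.0), lam).data)
                for lam in (0.0, 0.25, 0.5, 0.75, 1.0)]
        diffs = np.diff(vals)
        np.testing.assert_allclose(diffs, diffs[0], atol=1e-12)
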