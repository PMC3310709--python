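"""Tests for the online circuit: normalization, transfer, plasticity,
training dynamics and the fixed-point prediction."""

import numpy as np
import pytest

import poismix as pm
from poismix.circuit import _CONSTRAINT_CODES, _epoch_kernel
from poismix.mixture import FIELD_FLOOR


class TestFeedforwardNormalize:
    def test_plain_division(self):
        np.testing.assert_allclose(
            pm.feedforward_normalize([[2.0, 6.0]], 4.0, "plain"), [[1.0, 3.0]])

    def test_offset_adds_background(self):
        out = pm.feedforward_normalize([[2.0, 6.0]], 4.0, "offset")
        np.testing.assert_allclose(out, [[2.0, 4.0]])
        np.testing.assert_allclose(out.sum(), 4.0 + 2)  # A + D

    def test_plain_is_idempotent(self, rng):
        X = rng.uniform(0.1, 3.0, size=(5, 8))
        once = pm.feedforward_normalize(X, 7.0, "plain")
        twice = pm.feedforward_normalize(once, 7.0, "plain")
        np.testing.assert_allclose(once, twice, rtol=1e-12)

    def test_zero_row_raises_with_row_index(self):
        with pytest.raises(ValueError, match="row 1"):
            pm.feedforward_normalize([[1.0, 1.0], [0.0, 0.0]], 4.0, "plain")


class TestSynapticTransform:
    @pytest.mark.parametrize("variant", ["linear", "log_saturating"])
    def test_anchor_at_one(self, variant):
        assert pm.synaptic_transform([[1.0]], variant)[0, 0] == 0.0

    def test_log_branch(self):
        np.testing.assert_allclose(
            pm.synaptic_transform([[np.e]], "log_saturating"), [[1.0]])

    def test_linear_and_below_one_branch(self):
        assert pm.synaptic_transform([[3.0]], "linear")[0, 0] == 2.0
        assert pm.synaptic_transform([[0.5]], "log_saturating")[0, 0] == -0.5

    def test_continuity_at_one(self):
        lo = pm.synaptic_transform([[1.0 - 1e-9]], "log_saturating")[0, 0]
        hi = pm.synaptic_transform([[1.0 + 1e-9]], "log_saturating")[0, 0]
        assert abs(hi - lo) < 1e-8


class TestTransfer:
    def test_identical_rows_uniform_activity(self):
        W = np.tile([[1.0, 2.0]], (3, 1))
        g = pm.transfer(W, np.array([2.0, 1.0]), "linear")
        np.testing.assert_allclose(g, 1 / 3)

    def test_offset_invariance_linear(self, rng):
        """Adding a constant to all weights leaves activities unchanged for
        normalized stimuli (the constant drive term cancels in softmax)."""
        W = rng.uniform(0.5, 2.0, size=(4, 6))
        y = pm.feedforward_normalize(rng.uniform(0.1, 1.0, size=(3, 6)), 5.0, "plain")
        g1 = pm.transfer(W, y, "linear")
        g2 = pm.transfer(W + 3.7, y, "linear")
        np.testing.assert_allclose(g1, g2, atol=1e-12)

    def test_log_variant_equals_compact_posterior_above_one(self, rng):
        W = 1.0 + rng.uniform(0.0, 4.0, size=(4, 6))
        # rescale the above-background part so all rows share a sum while
        # every entry stays >= 1
        target = W.sum(axis=1).max()
        W = 1.0 + (W - 1.0) * ((target - 6.0) / (W.sum(axis=1) - 6.0))[:, None]
        A = float(target)
        y = pm.feedforward_normalize(rng.uniform(0.1, 1.0, size=(5, 6)), A, "plain")
        g = pm.transfer(W, y, "log_saturating")
        q = pm.posterior(y, W, mode="compact")
        np.testing.assert_allclose(g, q, atol=1e-12)


class TestPlasticity:
    def test_fixed_point_row_unchanged(self):
        W = np.array([[1.0, 2.0], [3.0, 1.0]])
        y = W[0].copy()
        out = pm.plasticity_update(W, y, np.array([0.7, 0.3]), 0.05)
        np.testing.assert_allclose(out[0], W[0], rtol=1e-12)

    def test_sum_conservation_when_scales_match(self, rng):
        """When a weight row's sum equals the stimulus sum, synaptic scaling
        leaves that sum unchanged (homeostatic stationary point)."""
        y = rng.uniform(0.5, 2.0, size=6)
        W = rng.uniform(0.1, 1.0, size=(3, 6))
        W *= y.sum() / W.sum(axis=1, keepdims=True)
        out = pm.plasticity_update(W, y, np.array([0.2, 0.3, 0.5]), 0.01)
        np.testing.assert_allclose(out.sum(axis=1), y.sum(), rtol=1e-12)

    def test_explicit_norm_rows_sum_to_A(self, rng):
        W = rng.uniform(0.5, 2.0, size=(3, 5))
        y = rng.uniform(0.0, 2.0, size=5)
        out = pm.plasticity_update(W, y, np.array([0.1, 0.6, 0.3]), 0.01,
                                   "explicit_norm", A=11.0)
        np.testing.assert_allclose(out.sum(axis=1), 11.0, rtol=1e-12)

    def test_row_sum_monotone_approach(self, rng):
        """Row sums started below/above the stimulus total move toward it
        monotonically under synaptic scaling, whatever the input statistics."""
        y = pm.feedforward_normalize(rng.uniform(0.1, 2.0, size=(200, 8)), 20.0, "plain")
        for factor in (0.5, 2.0):
            W = rng.uniform(0.5, 2.0, size=(3, 8))
            W *= factor * 20.0 / W.sum(axis=1, keepdims=True)
            prev_gap = np.abs(W.sum(axis=1) - 20.0)
            for i in range(200):
                g = pm.transfer(W, y[i], "linear")
                W = pm.plasticity_update(W, y[i], g, 0.02)
                gap = np.abs(W.sum(axis=1) - 20.0)
                assert np.all(gap <= prev_gap + 1e-12)
                prev_gap = gap


class TestKernel:
    def test_kernel_matches_numpy_reference(self, rng):
        """One compiled epoch equals stepping the reference functions."""
        X = pm.feedforward_normalize(rng.uniform(0.1, 2.0, size=(20, 7)), 10.0, "plain")
        for variant in ("linear", "log_saturating"):
            for constraint in ("synaptic_scaling", "explicit_norm", "none"):
                W0 = rng.uniform(0.5, 2.0, size=(3, 7))
                order = rng.permutation(20)
                Wk = np.ascontiguousarray(W0.copy())
                _epoch_kernel(Wk, np.ascontiguousarray(X), order, 1e-2,
                              variant == "log_saturating",
                              _CONSTRAINT_CODES[constraint], 10.0, FIELD_FLOOR)
                Wr = W0.copy()
                for n in order:
                    g = pm.transfer(Wr, X[n], variant)
                    Wr = pm.plasticity_update(Wr, X[n], g, 1e-2, constraint, A=10.0)
                np.testing.assert_allclose(Wk, Wr, rtol=1e-10, atol=1e-12)


class TestTrainCircuit:
    def test_seeded_determinism(self, blocks_data):
        X = blocks_data["X"][:300]
        cfg = pm.CircuitConfig(n_epochs=3, seed=7)
        W1, t1 = pm.train_circuit(X, cfg)
        W2, t2 = pm.train_circuit(X, cfg)
        np.testing.assert_array_equal(W1, W2)
        assert t1.loglik_per_iter == t2.loglik_per_iter

    def test_weight_row_sums_converge_to_stimulus_sum(self, blocks_data):
        W, _ = pm.train_circuit(blocks_data["X"],
                                pm.CircuitConfig(n_epochs=40, seed=1))
        np.testing.assert_allclose(W.sum(axis=1), 300.0, rtol=0.01)

    def test_single_neuron_learns_mean_stimulus(self, blocks_data):
        X = blocks_data["X"]
        est = pm.NeuralCircuitLearner(n_neurons=1, n_epochs=40,
                                      random_state=0).fit(X)
        Xn = pm.feedforward_normalize(X, 300.0, "plain")
        rel = np.abs(est.weights_[0] - Xn.mean(axis=0)) / Xn.mean(axis=0)
        assert np.median(rel) < 0.05

    def test_pure_hebbian_growth_diverges(self, blocks_data):
        from poismix.circuit import DivergenceError

        with pytest.warns(UserWarning, match="learning_rate"):
            cfg = pm.CircuitConfig(weight_constraint="none", learning_rate=5.0,
                                   n_epochs=150, seed=0)
        with pytest.raises(DivergenceError):
            pm.train_circuit(blocks_data["X"], cfg)

    def test_transform_returns_simplex_activities(self, blocks_data):
        est = pm.NeuralCircuitLearner(n_epochs=5, random_state=0).fit(blocks_data["X"])
        g = est.transform(blocks_data["X"][:50])
        assert g.shape == (50, 4)
        np.testing.assert_allclose(g.sum(axis=1), 1.0, rtol=1e-9)


class TestFixedPoint:
    def test_self_consistent_weights_give_zero_residual(self, normalized_blocks):
        Xn = normalized_blocks["Xn"]
        W = pm.init_fields(Xn, 4, 300.0, 0.1, 3)
        for _ in range(300):  # fixed-point iteration to self-consistency
            g = pm.transfer(W, Xn, "linear")
            W = (g.T @ Xn) / g.sum(axis=0)[:, None]
        resid = pm.fixed_point_residual(W, Xn, "linear")
        assert np.max(resid) < 1e-6

    def test_trained_beats_untrained(self, normalized_blocks):
        Xn = normalized_blocks["Xn"]
        est = pm.NeuralCircuitLearner(variant="log_saturating", n_epochs=60,
                                      learning_rate=1e-3, random_state=2).fit(Xn)
        r_trained = np.median(pm.fixed_point_residual(est.weights_, Xn, "log_saturating"))
        W0 = pm.init_fields(Xn, 4, 300.0, 0.1, 7)
        r_untrained = np.median(pm.fixed_point_residual(W0, Xn, "log_saturating"))
        assert r_trained < 0.05
        assert r_untrained >= 5 * r_trained


class TestAblationBehaviour:
    def test_row_sums_heterogeneous_without_ffi(self):
        """Without feedforward inhibition, heterogeneous-intensity stimuli
        leave weight row sums spread out; explicit normalization restores a
        common constant."""
        spec = pm.BlocksSpec(A=None, mean_intensity=300.0 / 256, seed=4)
        X, _, _ = pm.generate_blocks_dataset(spec, 800)
        W_scal, _ = pm.train_circuit(X, pm.CircuitConfig(
            ffi_mode="off", weight_constraint="synaptic_scaling",
            n_epochs=30, seed=0))
        W_expl, _ = pm.train_circuit(X, pm.CircuitConfig(
            ffi_mode="off", weight_constraint="explicit_norm", A=300.0,
            n_epochs=30, seed=0))
        spread_scal = np.ptp(W_scal.sum(axis=1)) / W_scal.sum(axis=1).mean()
        spread_expl = np.ptp(W_expl.sum(axis=1)) / W_expl.sum(axis=1).mean()
        assert spread_expl < 1e-9
        assert spread_scal > 0.02
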