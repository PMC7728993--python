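"""Neuronal state equations: sigmoid, the four drifts, and their contracts."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wcdcm.exceptions import InvalidParameterError, ShapeError
from wcdcm.neuronal import (ModelSpec, NeuronalParams, bilinear_drift,
                            sigmoid, two_state_bilinear_drift,
                            two_state_wc_drift, wc_drift)

from oracles import (naive_bilinear_drift, naive_two_state_bilinear,
                     naive_two_state_wc, naive_wc_drift,
                     random_single_state_instance,
                     random_two_state_instance, sigmoid_scalar)


class TestSigmoid:
    @pytest.mark.parametrize("alpha", [0.1, 1.0, 4.0, 50.0])
    def test_zero_at_origin(self, alpha):
        assert sigmoid(0.0, alpha) == 0.0

    def test_saturation_limits(self):
        assert sigmoid(1e6, 1.0) == pytest.approx(0.5)
        assert sigmoid(-1e6, 1.0) == pytest.approx(-0.5)

    def test_scalar_value_against_direct_evaluation(self):
        # S(0.5; alpha=4) = 1/(1+e^-2) - 1/2
        expected = 1.0 / (1.0 + math.exp(-2.0)) - 0.5
        assert sigmoid(0.5, 4.0) == pytest.approx(expected, abs=1e-15)
        assert sigmoid(0.5, 4.0) == pytest.approx(0.38080, abs=5e-6)

    def test_no_overflow_at_large_argument(self):
        with np.errstate(over="raise"):
            val = sigmoid(1.0, 1e3)
        assert val == pytest.approx(0.5)

    def test_odd_and_bounded(self, rng):
        x = rng.normal(0, 2, 200)
        s = sigmoid(x, 3.0)
        assert np.allclose(s, -sigmoid(-x, 3.0))
        assert np.all(np.abs(s) < 0.5)
        # far in the tails the open bound saturates to +-1/2 in floats
        assert np.all(np.abs(sigmoid(rng.normal(0, 50, 100), 3.0)) <= 0.5)

    @settings(derandomize=True, max_examples=200)
    @given(x=st.floats(-250.0, 250.0), alpha=st.floats(0.01, 50.0))
    def test_odd_bounded_monotone_property(self, x, alpha):
        s = sigmoid(x, alpha)
        assert abs(s) <= 0.5
        assert s == pytest.approx(-sigmoid(-x, alpha), abs=1e-15)
        # monotone non-decreasing in x
        assert sigmoid(x + 0.5, alpha) >= s

    def test_invalid_slope_raises(self):
        with pytest.raises(InvalidParameterError):
            sigmoid(1.0, 0.0)
        with pytest.raises(InvalidParameterError):
            sigmoid(1.0, -2.0)


class TestSingleStateDrifts:
    def test_origin_is_fixed_point(self, gt_wc):
        _, params, _ = gt_wc
        z, u = np.zeros(3), np.zeros(2)
        assert np.allclose(bilinear_drift(z, u, params), 0)
        assert np.allclose(wc_drift(z, u, params), 0)

    def test_hand_matrix_vector_product(self):
        p = NeuronalParams(A=[[-1.0, 0.0], [0.5, -1.0]],
                           B=np.zeros((1, 2, 2)), C=np.zeros((2, 1)))
        out = bilinear_drift([1.0, 0.0], [0.0], p)
        assert np.allclose(out, [-1.0, 0.5])

    @pytest.mark.parametrize("wc", [False, True])
    def test_matches_naive_loop_oracle(self, rng, wc):
        for _ in range(100):
            spec, p, z, u = random_single_state_instance(rng, wc=wc)
            fast = (wc_drift if wc else bilinear_drift)(z, u, p)
            if wc:
                slow = naive_wc_drift(z, u, p.A, p.B, p.C, p.alpha)
            else:
                slow = naive_bilinear_drift(z, u, p.A, p.B, p.C)
            assert np.allclose(fast, slow, atol=1e-12, rtol=0)

    def test_wc_relaxation_target_bounded(self, rng):
        # each component of (drift + z) = S(x) lies in (-1/2, 1/2)
        for _ in range(20):
            spec, p, z, u = random_single_state_instance(rng, wc=True)
            target = wc_drift(10 * z, u, p) + 10 * z
            assert np.all(np.abs(target) <= 0.5)

    def test_wc_odd_symmetry_without_input(self, rng):
        spec, p, z, _ = random_single_state_instance(rng, wc=True)
        u = np.zeros(spec.n_inputs)
        assert np.allclose(wc_drift(-z, u, p), -wc_drift(z, u, p),
                           atol=1e-14)

    def test_shape_mismatch_raises(self, gt_wc):
        _, params, _ = gt_wc
        with pytest.raises(ShapeError):
            wc_drift(np.zeros(2), np.zeros(2), params)
        with pytest.raises(ShapeError):
            bilinear_drift(np.zeros(3), np.zeros(3), params)


class TestTwoStateDrifts:
    def test_origin_is_fixed_point(self, rng):
        p, zE, zI, u = random_two_state_instance(rng, wc=True)
        z0 = np.zeros_like(zE)
        dE, dI = two_state_wc_drift(z0, z0, np.zeros_like(u) * 0, p)
        assert np.allclose(dE, 0) and np.allclose(dI, 0)
        dE, dI = two_state_bilinear_drift(z0, z0, 0 * u, p)
        assert np.allclose(dE, 0) and np.allclose(dI, 0)

    def test_inhibitory_pure_decay_without_excitatory_drive(self):
        # single region, wEI = 0: the inhibitory population decays alone
        p = NeuronalParams(w_ee=np.zeros((1, 1)), w_se=[0.5], w_si=[0.7],
                           w_ie=[0.4], w_ei=[0.0], C=np.zeros((1, 1)))
        _, dI = two_state_bilinear_drift([0.3], [2.0], [0.0], p)
        assert dI[0] == pytest.approx(-0.7 * 2.0)

    @pytest.mark.parametrize("wc", [False, True])
    def test_matches_naive_loop_oracle(self, rng, wc):
        for _ in range(100):
            p, zE, zI, u = random_two_state_instance(rng, wc=wc)
            if wc:
                fE, fI = two_state_wc_drift(zE, zI, u, p)
                sE, sI = naive_two_state_wc(
                    zE, zI, u, p.w_ee, p.w_se, p.w_si, p.w_ie, p.w_ei,
                    p.b_ee, p.b_ie, p.C, p.alpha_e, p.alpha_i)
            else:
                fE, fI = two_state_bilinear_drift(zE, zI, u, p)
                sE, sI = naive_two_state_bilinear(
                    zE, zI, u, p.w_ee, p.w_se, p.w_si, p.w_ie, p.w_ei,
                    p.b_ee, p.b_ie, p.C)
            assert np.allclose(fE, sE, atol=1e-12, rtol=0)
            assert np.allclose(fI, sI, atol=1e-12, rtol=0)

    def test_wc_relaxation_target_bounded(self, rng):
        for _ in range(20):
            p, zE, zI, u = random_two_state_instance(rng, wc=True)
            dE, dI = two_state_wc_drift(zE, zI, u, p)
            assert np.all(np.abs(dE + zE) < 0.5)
            assert np.all(np.abs(dI + zI) < 0.5)

    def test_missing_weights_raise(self):
        p = NeuronalParams(w_ee=np.zeros((2, 2)), w_se=[0.5, 0.5],
                           w_si=[0.5, 0.5], w_ie=[0.5, 0.5],
                           w_ei=[0.5, 0.5], C=np.zeros((2, 1)))
        with pytest.raises(InvalidParameterError):
            two_state_wc_drift([0.1, 0.1], [0.1, 0.1], [0.0], p)


class TestSmallSignalEquivalence:
    """At alpha = 4, S'(0) = 1: the Wilson-Cowan drift reduces to the
    bilinear drift with A replaced by A - I, up to the cubic Taylor
    remainder |S(x) - x| <= 2|x|^3."""

    def test_single_state(self, rng):
        for _ in range(50):
            spec, p, z, u = random_single_state_instance(rng, wc=True)
            p.alpha = np.full(spec.n_regions, 4.0)
            # rescale (z, u) until the drive satisfies |x| <= 1e-3 (the
            # u*B*z term is bilinear, so one rescale is not exact)
            for _ in range(4):
                x0 = np.abs(bilinear_drift(z, u, p)).max()
                if x0 <= 1e-3:
                    break
                s = 9e-4 / max(x0, 1e-12)
                z, u = z * s, u * s
            x = bilinear_drift(z, u, p)      # the linear drive
            assert np.all(np.abs(x) <= 1e-3 + 1e-15)
            wc = wc_drift(z, u, p)
            lin = x - z                      # bilinear drift with A - I
            assert np.all(np.abs(wc - lin) <= 2 * np.abs(x) ** 3 + 1e-16)

    def test_two_state(self, rng):
        for _ in range(50):
            p, zE, zI, u = random_two_state_instance(rng, wc=True)
            l = len(zE)
            p.alpha_e = np.full(l, 4.0)
            p.alpha_i = np.full(l, 4.0)
            p.w_se = np.zeros(l)   # remove the self term whose sign differs
            scale = 1e-3 / max(np.abs(zE).max(), np.abs(zI).max(),
                               np.abs(u).max(), 1.0)
            zE, zI, u = zE * scale, zI * scale, u * scale
            xE, xI = two_state_bilinear_drift(zE, zI, u, p)
            dE, dI = two_state_wc_drift(zE, zI, u, p)
            assert np.all(np.abs(dE - (xE - zE)) <= 2 * np.abs(xE) ** 3
                          + 1e-16)
            assert np.all(np.abs(dI - (xI - zI)) <= 2 * np.abs(xI) ** 3
                          + 1e-16)


class TestModelSpec:
    def test_diagonal_must_be_present(self):
        A = np.zeros((2, 2), dtype=bool)
        A[0, 1] = True
        with pytest.raises(InvalidParameterError):
            ModelSpec(("a", "b"), A, np.zeros((1, 2, 2), bool),
                      np.ones((2, 1), bool))

    def test_modulation_requires_connection(self):
        A = np.eye(2, dtype=bool)
        B = np.zeros((1, 2, 2), dtype=bool)
        B[0, 0, 1] = True    # modulates a connection absent from A
        with pytest.raises(InvalidParameterError):
            ModelSpec(("a", "b"), A, B, np.ones((2, 1), bool))

    def test_unknown_variant_rejected(self):
        with pytest.raises(InvalidParameterError):
            ModelSpec(("a",), np.eye(1, dtype=bool),
                      np.zeros((1, 1, 1), bool), np.ones((1, 1), bool),
                      variant="quadratic")

    def test_params_outside_mask_rejected(self, gt_wc):
        spec, params, _ = gt_wc
        bad = NeuronalParams(A=params.A.copy(), B=params.B, C=params.C,
                             alpha=params.alpha)
        bad.A[0, 1] = 0.3    # mask-false entry
        with pytest.raises(InvalidParameterError):
            bad.validate(spec)

    def test_nonpositive_alpha_rejected(self, gt_wc):
        spec, params, _ = gt_wc
        bad = NeuronalParams(A=params.A, B=params.B, C=params.C,
                             alpha=np.array([4.0, -1.0, 4.0]))
        with pytest.raises(InvalidParameterError):
            bad.validate(spec)
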