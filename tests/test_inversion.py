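"""VBL inversion: priors, free energy, fit metrics, small end-to-end fits."""

import math

import numpy as np
import pytest

from wcdcm.exceptions import ShapeError, UndefinedMetricError
from wcdcm.generative import BOLDSeries, InputTimeline, simulate_dataset
from wcdcm.hemodynamics import HemodynamicParams
from wcdcm.inversion import (InversionOptions, PriorSpec, default_priors,
                             detect_flatline, explained_variance,
                             free_energy, invert)
from wcdcm.neuronal import ModelSpec, NeuronalParams


class TestDefaultPriors:
    def test_free_parameter_count_matches_hand_count(self, gt_wc):
        # 3 self + 3 edges + 2 modulations + 1 input + 3 slopes
        # + 6 hemodynamic scalings + 3 log-precisions = 21
        spec, _, _ = gt_wc
        priors = default_priors(spec)
        assert priors.n_params == 21

    def test_masked_out_parameters_never_appear(self, gt_wc):
        # structural pinning: absent connections carry no free parameter
        spec, _, _ = gt_wc
        names = default_priors(spec).names
        assert "A[R1<-R2]" not in names          # mask-false connection
        assert "C[R2<-u1]" not in names          # input only into region 1
        assert "B2[R2<-R1]" not in names         # unmodulated connection

    def test_shrinkage_structure(self, gt_wc):
        spec, _, _ = gt_wc
        priors = default_priors(spec)
        for name, mu, var in zip(priors.names, priors.mean, priors.variance):
            if name.startswith("A["):
                tgt, src = name[2:-1].split("<-")
                if tgt == src:
                    assert mu == -0.5 and var == 1 / 256
                else:
                    assert mu == 0.0 and var == 1 / 16
            elif name.startswith("B"):
                assert mu == 0.0 and var == 1 / 16
            elif name.startswith("C["):
                assert mu == 0.0 and var == 1.0
            elif name.startswith("log_alpha"):
                assert mu == pytest.approx(math.log(4.0)) and var == 1 / 16
            elif name.startswith(("log_kappa", "log_tau")):
                assert mu == 0.0 and var == 1 / 256
            elif name.startswith("log_precision"):
                assert mu == 6.0 and var == 1 / 128
            else:
                raise AssertionError(f"unexpected parameter {name}")

    def test_bilinear_variant_has_no_slopes(self, gt_bilinear):
        spec, _, _ = gt_bilinear
        names = default_priors(spec).names
        assert not any(n.startswith("log_alpha") for n in names)
        assert len(names) == 18

    def test_two_state_parameters_on_log_scale(self):
        A = np.eye(2, dtype=bool); A[1, 0] = True
        B = np.zeros((1, 2, 2), bool); B[0, 1, 0] = True
        C = np.zeros((2, 1), bool); C[0, 0] = True
        spec = ModelSpec(("a", "b"), A, B, C, variant="wilson_cowan",
                         states="two")
        priors = default_priors(spec)
        assert any(n.startswith("log_wEE") for n in priors.names)
        assert any(n.startswith("log_wSI") for n in priors.names)
        assert any(n.startswith("log_alphaE") for n in priors.names)


def _tiny_prior(n=2, T=10):
    names = [f"p{i}" for i in range(n)] + ["log_precision[R1]"]
    mean = np.array([0.0] * n + [6.0])
    var = np.array([1.0] * n + [1 / 128])
    return PriorSpec(names=names, mean=mean, variance=var, n_theta=n)


class TestFreeEnergy:
    def test_posterior_equal_prior_has_zero_parameter_complexity(self):
        prior = _tiny_prior()
        mu, var = prior.theta()
        h0, hv0 = prior.noise()
        resid = np.zeros((10, 1))
        # accuracy with zero residuals: (N/2)(h - ln 2pi)
        F = free_energy(resid, h0, hv0, mu, np.diag(var), prior)
        expected_accuracy = 0.5 * 10 * (6.0 - math.log(2 * math.pi))
        assert F == pytest.approx(expected_accuracy, abs=1e-10)

    def test_accuracy_closed_form_at_fixed_precision(self):
        prior = _tiny_prior()
        mu, var = prior.theta()
        lam = 20.0
        h = np.array([math.log(lam)])
        resid = np.zeros((25, 1))
        F = free_energy(resid, h, prior.noise()[1], mu, np.diag(var), prior)
        acc = 0.5 * 25 * (math.log(lam) - math.log(2 * math.pi))
        kl_h = 0.5 * ((math.log(lam) - 6.0) ** 2 * 128)
        assert F == pytest.approx(acc - kl_h, abs=1e-10)

    def test_larger_residuals_strictly_decrease_F(self, rng):
        prior = _tiny_prior()
        mu, var = prior.theta()
        h0, hv0 = prior.noise()
        resid = rng.normal(0, 0.1, (30, 1))
        F1 = free_energy(resid, h0, hv0, mu, np.diag(var), prior)
        F2 = free_energy(2 * resid, h0, hv0, mu, np.diag(var), prior)
        assert F2 < F1


class TestExplainedVariance:
    def test_perfect_prediction(self, rng):
        y = BOLDSeries(TR=2.0, y=rng.normal(0, 1, (40, 2)))
        assert explained_variance(y, y) == pytest.approx(100.0)

    def test_mean_prediction_scores_zero(self, rng):
        y = BOLDSeries(TR=2.0, y=rng.normal(0, 1, (40, 2)))
        flat = BOLDSeries(TR=2.0, y=np.tile(y.y.mean(axis=0), (40, 1)))
        assert explained_variance(y, flat) == pytest.approx(0.0, abs=1e-10)

    def test_orthogonal_noise_variance_decomposition(self, rng):
        # var(noise) = var(pred)/3 and noise orthogonal to pred -> EV = 75
        T = 400
        pred = np.sin(2 * np.pi * np.arange(T) / 25.0)[:, None]
        noise = rng.normal(0, 1, (T, 1))
        noise -= noise.mean()
        pc = pred - pred.mean()
        noise -= pc * (noise.ravel() @ pc.ravel()) / (pc.ravel() @ pc.ravel())
        noise *= np.sqrt(pc.var() / 3) / noise.std()
        obs = BOLDSeries(TR=2.0, y=pred + noise)
        assert explained_variance(obs, BOLDSeries(TR=2.0, y=pred)) \
            == pytest.approx(75.0, abs=1e-6)

    def test_zero_variance_observed_raises(self):
        flat = BOLDSeries(TR=2.0, y=np.ones((10, 1)))
        with pytest.raises(UndefinedMetricError):
            explained_variance(flat, flat)

    def test_shape_mismatch_raises(self, rng):
        a = BOLDSeries(TR=2.0, y=rng.normal(0, 1, (10, 2)))
        b = BOLDSeries(TR=2.0, y=rng.normal(0, 1, (10, 3)))
        with pytest.raises(ShapeError):
            explained_variance(a, b)


class TestDetectFlatline:
    def test_constant_prediction_is_flat(self, rng):
        obs = BOLDSeries(TR=2.0, y=rng.normal(0, 1, (20, 2)))
        flat = BOLDSeries(TR=2.0, y=np.full((20, 2), 3.7))
        assert detect_flatline(flat, obs) is True

    def test_matching_prediction_is_not_flat(self, rng):
        obs = BOLDSeries(TR=2.0, y=rng.normal(0, 1, (20, 2)))
        assert detect_flatline(obs, obs) is False

    def test_threshold_boundary_is_strict(self, rng):
        obs = BOLDSeries(TR=2.0, y=rng.normal(0, 1, (64, 1)))
        # var(0.5*y) = 0.25 * var(y) exactly in floating point
        half = BOLDSeries(TR=2.0, y=0.5 * obs.y)
        assert detect_flatline(half, obs, tol=0.25) is False


@pytest.fixture(scope="module")
def small_fit(gt_wc, timeline_short):
    spec, params, hp = gt_wc
    ds = simulate_dataset(spec, params, hp, timeline_short, snr=np.inf,
                          n_real=1, seed=0)
    post = invert(ds.noisy[0], timeline_short, spec,
                  opts=InversionOptions(max_iter=48))
    return ds, post


class TestInvert:
    def test_noise_free_fit_explains_data(self, small_fit):
        _, post = small_fit
        assert post.explained_variance > 90.0
        assert not post.flatline

    def test_recorded_trajectory_non_decreasing(self, small_fit):
        _, post = small_fit
        assert np.all(np.diff(post.f_trajectory) >= 0)

    def test_posterior_covariance_symmetric_psd(self, small_fit):
        _, post = small_fit
        assert np.allclose(post.cov, post.cov.T)
        assert np.linalg.eigvalsh(post.cov).min() > 0

    def test_deterministic_given_data_and_options(self, gt_wc,
                                                  timeline_short, small_fit):
        spec, params, hp = gt_wc
        ds, post = small_fit
        again = invert(ds.noisy[0], timeline_short, spec,
                       opts=InversionOptions(max_iter=48))
        assert np.array_equal(post.mean, again.mean)
        assert post.free_energy == again.free_energy

    def test_mismatched_priors_rejected(self, gt_wc, gt_bilinear,
                                        timeline_short, small_fit):
        spec, _, _ = gt_wc
        spec_b, _, _ = gt_bilinear
        ds, _ = small_fit
        with pytest.raises(ShapeError):
            invert(ds.noisy[0], timeline_short, spec,
                   priors=default_priors(spec_b))

    def test_evidence_favors_generating_structure(self, gt_wc,
                                                  timeline_short, small_fit):
        # face validity: F(true structure) > F(structurally wrong model)
        spec, _, _ = gt_wc
        ds, post = small_fit
        A_wrong = np.eye(3, dtype=bool)
        A_wrong[0, 1] = A_wrong[0, 2] = A_wrong[2, 1] = True  # reversed edges
        B_wrong = np.zeros((2, 3, 3), bool)
        B_wrong[1, 0, 1] = B_wrong[1, 0, 2] = True
        C_wrong = np.zeros((3, 2), bool)
        C_wrong[1, 0] = True
        wrong = ModelSpec(spec.region_names, A_wrong, B_wrong, C_wrong,
                          variant="wilson_cowan")
        post_wrong = invert(ds.noisy[0], timeline_short, wrong,
                            opts=InversionOptions(max_iter=48))
        assert post.free_energy > post_wrong.free_energy
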