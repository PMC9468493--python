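"""Tests of the variational inversion building blocks.

The expensive whole-cohort behaviour lives in test_acceptance.py; here the
individual operations are checked against hand arithmetic and brute-force
numerical oracles on tiny problems.
"""

import math

import numpy as np
import pytest
from scipy import integrate
from scipy.stats import gamma as gamma_dist

from cainfer import (InversionConfig, KineticParams, ObservationParams,
                     PosteriorMoments, PriorEntry, PriorSpec, accept_run,
                     default_priors, free_energy, generative_predict,
                     invert_trace, observe, predict_trace, r_squared,
                     simulate, to_physical)
from cainfer.kinetic_model import KineticState
from cainfer.synthetic_traces import Trace, generate_trace


class TestToPhysical:
    def test_zero_exponent_recovers_prior_mean(self):
        assert to_physical(0.0, 0.9) == pytest.approx(0.9)

    def test_log_two_doubles(self):
        assert to_physical(math.log(2.0), 0.11) == pytest.approx(0.22)

    def test_unit_exponent(self):
        assert to_physical(1.0, 0.9) == pytest.approx(0.9 * math.e, rel=1e-9)

    def test_non_finite_raises(self):
        with pytest.raises(ValueError):
            to_physical(float("nan"), 1.0)


class TestDefaultPriors:
    def test_table_values(self):
        priors = default_priors()
        serca = priors["vs"]
        assert (serca.mean, serca.variance, serca.transform) == \
            (0.9, 2.0, "exp")
        calcium0 = priors["c_cs0"]
        assert (calcium0.mean, calcium0.variance, calcium0.transform) == \
            (0.1, 0.05, "identity")
        assert priors["tau"].mean == pytest.approx(7.14)
        assert priors["q0"].variance == pytest.approx(0.2)
        assert priors["p0"].mean == pytest.approx(0.5)

    def test_exp_entries_have_zero_vector_mean(self):
        priors = default_priors()
        mu = priors.vector_mean()
        names = priors.names()
        for j, name in enumerate(names):
            if priors[name].transform == "exp":
                assert mu[j] == 0.0
            else:
                assert mu[j] == priors[name].mean

    def test_data_scaled_observation_priors(self):
        # range 2.0: scale prior at twice the range, offset prior below the
        # minimum by the implied baseline contribution of the indicator
        y = np.array([1.0, 3.0, 2.0])
        priors = default_priors().for_trace(y)
        assert priors["kappa_f"].mean == pytest.approx(4.0)
        assert priors["d_f"].mean == pytest.approx(1.0 - 0.7 * 2.0)
        assert priors["kappa_f"].variance == pytest.approx(16.0)

    def test_flat_trace_gets_positive_scale_prior(self):
        priors = default_priors().for_trace(np.full(20, 5.0))
        assert priors["kappa_f"].mean > 0

    def test_invalid_entries_rejected(self):
        with pytest.raises(ValueError):
            PriorEntry(1.0, -1.0)
        with pytest.raises(ValueError):
            PriorEntry(-1.0, 1.0, "exp")


class TestRSquared:
    def test_perfect_fit(self):
        y = np.array([1.0, 2.0, 3.0])
        assert r_squared(y, y) == pytest.approx(1.0)

    def test_mean_prediction_scores_zero(self):
        y = np.array([1.0, 2.0, 3.0])
        assert r_squared(y, np.full(3, 2.0)) == pytest.approx(0.0)

    def test_hand_arithmetic(self):
        assert r_squared([1, 2, 3], [1, 2, 4]) == pytest.approx(0.5)

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError):
            r_squared([2.0, 2.0], [1.0, 2.0])


class TestGenerativePredict:
    def test_matches_direct_composition(self):
        """At prior-mean parameters the generative prediction equals
        simulate + observe composed directly."""
        cfg = InversionConfig()
        phi = ObservationParams(kappa_f=2.0, d_f=1.0)
        theta = np.array([0.1, 0.5, 0.5, 0, 0, 0, 0, 0, 0], dtype=float)
        y = generative_predict(theta, phi, cfg, n_frames=30)
        traj = simulate(KineticState(0.1, 0.5, 0.5), KineticParams(),
                        duration=29.0, frame_dt=1.0, micro_dt=0.1)
        direct = predict_trace(traj.c_cs, phi)
        assert y == pytest.approx(direct, rel=1e-12)

    def test_single_frame_is_observed_initial_state(self):
        phi = ObservationParams(kappa_f=2.0, d_f=1.0)
        theta = np.array([0.25, 0.5, 0.5, 0, 0, 0, 0, 0, 0])
        y = generative_predict(theta, phi, n_frames=1)
        assert y.shape == (1,)
        assert y[0] == pytest.approx(observe(0.25, phi))

    def test_serca_rate_perturbation_changes_prediction(self):
        phi = ObservationParams(kappa_f=2.0, d_f=1.0)
        base = np.array([0.1, 0.5, 0.5, 0, 0, 0, 0, 0, 0], dtype=float)
        shifted = base.copy()
        shifted[3] = 0.5  # SERCA V_max exponent
        y0 = generative_predict(base, phi, n_frames=60)
        y1 = generative_predict(shifted, phi, n_frames=60)
        assert not np.allclose(y0, y1)


def _toy_problem():
    """Linear-Gaussian toy: y = a*theta + noise, theta ~ N(0,1),
    noise precision sigma ~ Gamma(a0, b0). The evidence integral is
    computable by brute force; any mean-field moments must lower-bound it."""
    a = np.array([0.7, -0.4, 1.1])
    y = np.array([0.5, -0.1, 0.9])
    cfg = InversionConfig(sigma_prior_shape=3.0, sigma_prior_rate=2.0)
    priors = PriorSpec({"theta": PriorEntry(0.0, 1.0, "identity")})

    def log_evidence():
        def integrand(theta, sig):
            like = np.prod(np.sqrt(sig / (2 * np.pi))
                           * np.exp(-0.5 * sig * (y - a * theta) ** 2))
            return (like * np.exp(-0.5 * theta ** 2) / np.sqrt(2 * np.pi)
                    * gamma_dist.pdf(sig, 3.0, scale=0.5))
        val, _ = integrate.dblquad(integrand, 1e-6, 60.0,
                                   lambda s: -12.0, lambda s: 12.0,
                                   epsabs=1e-12, epsrel=1e-10)
        return math.log(val)

    return a, y, cfg, priors, log_evidence()


class TestFreeEnergy:
    def test_lower_bounds_log_evidence_on_toy(self):
        """F never exceeds the brute-force log evidence of a linear toy
        model, for a grid of posterior moments."""
        a, y, cfg, priors, ln_z = _toy_problem()
        best = -np.inf
        for mean in (-0.5, 0.0, 0.3, 0.6, 1.0):
            for var in (0.05, 0.2, 0.5):
                for shape, rate in ((3.0, 2.0), (4.5, 2.5), (4.0, 1.5)):
                    m = PosteriorMoments(
                        z_mean=np.array([mean]),
                        z_cov=np.array([[var]]),
                        predicted=a * mean,
                        jacobian=a[:, None],
                        sigma_shape=shape, sigma_rate=rate)
                    f = free_energy(m, y, priors, cfg)
                    assert f <= ln_z + 1e-9
                    best = max(best, f)
        # the optimised bound comes close to the true evidence
        assert best > ln_z - 1.0

    def test_duplicated_tight_parameter_leaves_f_unchanged(self):
        a, y, cfg, priors, _ = _toy_problem()
        m1 = PosteriorMoments(z_mean=np.array([0.3]),
                              z_cov=np.array([[0.2]]),
                              predicted=a * 0.3, jacobian=a[:, None],
                              sigma_shape=4.0, sigma_rate=2.0)
        f1 = free_energy(m1, y, priors, cfg)
        # add an irrelevant parameter at its own (tight) prior
        priors2 = priors.with_entry("dummy", PriorEntry(2.0, 1e-8, "identity"))
        m2 = PosteriorMoments(
            z_mean=np.array([0.3, 2.0]),
            z_cov=np.diag([0.2, 1e-8]),
            predicted=a * 0.3,
            jacobian=np.hstack([a[:, None], np.zeros((3, 1))]),
            sigma_shape=4.0, sigma_rate=2.0)
        f2 = free_energy(m2, y, priors2, cfg)
        assert f2 == pytest.approx(f1, abs=1e-6)

    def test_decreases_away_from_optimal_noise_precision(self):
        """A 1-D scan over the measurement-precision moments peaks near the
        residual-matched value and falls off on both sides."""
        a, y, cfg, priors, _ = _toy_problem()
        mean, var = 0.55, 0.2
        scan = []
        for rate_scale in (0.05, 0.3, 1.0, 3.0, 30.0):
            m = PosteriorMoments(z_mean=np.array([mean]),
                                 z_cov=np.array([[var]]),
                                 predicted=a * mean, jacobian=a[:, None],
                                 sigma_shape=4.5,
                                 sigma_rate=2.0 * rate_scale)
            scan.append(free_energy(m, y, priors, cfg))
        peak = int(np.argmax(scan))
        assert 0 < peak < len(scan) - 1
        assert scan[0] < scan[peak] and scan[-1] < scan[peak]

    def test_state_block_terms_contribute(self):
        """Adding a state-noise block (transition residuals, state entropy
        and the precision's gamma moments) changes F finitely, and larger
        transition residuals lower it for a fixed precision."""
        a, y, cfg, priors, _ = _toy_problem()
        base = dict(z_mean=np.array([0.3]), z_cov=np.array([[0.2]]),
                    predicted=a * 0.3, jacobian=a[:, None],
                    sigma_shape=4.0, sigma_rate=2.0)
        f_plain = free_energy(PosteriorMoments(**base), y, priors, cfg)
        state = dict(alpha_shape=5.0, alpha_rate=2.0, n_transitions=2,
                     state_logdet_sum=-10.0)
        f_small = free_energy(
            PosteriorMoments(**base, **state, state_ssr=0.1), y, priors, cfg)
        f_large = free_energy(
            PosteriorMoments(**base, **state, state_ssr=5.0), y, priors, cfg)
        assert np.isfinite(f_small) and f_small != f_plain
        assert f_large < f_small

    def test_non_positive_definite_covariance_raises(self):
        a, y, cfg, priors, _ = _toy_problem()
        m = PosteriorMoments(z_mean=np.array([0.0]),
                             z_cov=np.array([[-1.0]]),
                             predicted=a * 0.0, jacobian=a[:, None],
                             sigma_shape=3.0, sigma_rate=2.0)
        with pytest.raises(ValueError):
            free_energy(m, y, priors, cfg)


class TestInvertTraceContracts:
    def test_short_trace_raises(self):
        tr = Trace("r", np.arange(5.0), np.ones(5))
        with pytest.raises(ValueError):
            invert_trace(tr)

    def test_non_uniform_trace_raises(self):
        times = np.array([0, 1, 2, 3, 4, 5, 6, 7, 8, 10.0])
        tr = Trace.__new__(Trace)  # bypass Trace's own validation
        tr.roi_id = "r"
        tr.times = times
        tr.fluorescence = np.ones(10)
        tr.frame_dt = 1.0
        with pytest.raises(ValueError):
            invert_trace(tr)

    def test_flat_trace_terminates_and_stays_near_priors(self):
        """A constant trace carries no kinetic information: the inversion
        must terminate cleanly with kinetic posteriors within one prior sd
        of the prior means."""
        tr = Trace("flat", np.arange(60.0), np.full(60, 3.0))
        s = invert_trace(tr)
        assert s.n_iterations <= 100
        assert math.isnan(s.r_squared)
        priors = default_priors()
        for name in ("vs", "v1", "v2", "tau", "vp", "ks"):
            j = s.param_names.index(name)
            xi = s.z_mean[j]
            assert abs(xi) <= math.sqrt(priors[name].variance)

    def test_uninformative_likelihood_recovers_priors(self):
        """With a huge measurement-noise prior (tiny precision), the
        posterior means equal the prior means."""
        tr = generate_trace(obs_noise_sd=0.0, duration=12.0, seed=0)
        cfg = InversionConfig(sigma_prior_shape=1e-6, sigma_prior_rate=1e8,
                              max_iterations=5)
        s = invert_trace(tr, config=cfg)
        priors = default_priors().for_trace(tr.fluorescence)
        mu0 = priors.vector_mean()
        assert s.z_mean == pytest.approx(mu0, abs=1e-3)

    def test_acceptance_rule(self):
        tr = generate_trace(obs_noise_sd=0.0, duration=30.0, seed=0)
        s = invert_trace(tr)
        assert accept_run(s) == (s.alpha_hat > 0 and not s.diverged)
        s.alpha_rate = s.alpha_shape / 3.2
        assert accept_run(s)
        s.alpha_rate = -s.alpha_rate
        assert not accept_run(s)
        s.alpha_rate = float("nan")
        assert not accept_run(s)


class TestFreeEnergyAscent:
    def test_retained_iterations_non_decreasing(self):
        tr = generate_trace(obs_noise_sd=0.002, duration=60.0, seed=5)
        s = invert_trace(tr)
        f = np.asarray(s.free_energy_trajectory)
        assert f.size >= 1
        assert np.all(np.diff(f) >= 0)
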