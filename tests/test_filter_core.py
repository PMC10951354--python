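"""Unit and property tests for the generative model and recognition dynamics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy.stats import multivariate_normal

from cerebsim import (
    BeliefState,
    ConfigurationError,
    InstabilityError,
    LinearStateSpaceModel,
    NumericalError,
    compute_prediction_errors,
    flow_prediction,
    free_energy,
    free_energy_gradients,
    initial_belief,
    observation_prediction,
    recognition_step,
)

ONES2 = np.ones((2, 2))
TROT4 = np.array(
    [[1, -1, -1, 1], [-1, 1, 1, -1], [-1, 1, 1, -1], [1, -1, -1, 1]], dtype=float
)


def make_model(n_y=2, n_x=2, n_v=2, theta_g=None, theta_f=None, Pi_z=None,
               Pi_w=None, Pi_v=None):
    return LinearStateSpaceModel(
        theta_g=np.eye(n_y, n_x) if theta_g is None else theta_g,
        theta_f=np.eye(n_x, n_v) if theta_f is None else theta_f,
        Pi_z=np.eye(n_y) if Pi_z is None else Pi_z,
        Pi_w=np.eye(n_x) if Pi_w is None else Pi_w,
        Pi_v=np.eye(n_v) if Pi_v is None else Pi_v,
    )


def random_model(rng, n_y=3, n_x=2, n_v=2):
    def spd(n):
        a = rng.standard_normal((n, n))
        return a @ a.T + n * np.eye(n)

    return LinearStateSpaceModel(
        theta_g=rng.standard_normal((n_y, n_x)),
        theta_f=rng.standard_normal((n_x, n_v)),
        Pi_z=spd(n_y),
        Pi_w=spd(n_x),
        Pi_v=spd(n_v),
    )


def random_belief(rng, model):
    return BeliefState(
        mu_x=rng.standard_normal(model.n_x),
        mu_xprime=rng.standard_normal(model.n_x),
        mu_v=rng.standard_normal(model.n_v),
    )


class TestPredictions:
    @pytest.mark.parametrize(
        "theta_g, mu_x, expected",
        [
            (np.eye(2), [0.3, -0.7], [0.3, -0.7]),
            (np.eye(4), [1, 0, 0, 0], [1, 0, 0, 0]),
        ],
    )
    def test_identity_observation_mapping(self, theta_g, mu_x, expected):
        model = make_model(len(expected), len(mu_x), len(mu_x), theta_g=theta_g)
        np.testing.assert_allclose(
            observation_prediction(model, mu_x), expected
        )

    def test_observation_matches_matrix_product_oracle(self, rng):
        theta_g = rng.standard_normal((3, 2))
        model = make_model(3, 2, 2, theta_g=theta_g)
        mu_x = rng.standard_normal(2)
        oracle = np.array(
            [sum(theta_g[i, j] * mu_x[j] for j in range(2)) for i in range(3)]
        )
        np.testing.assert_allclose(observation_prediction(model, mu_x), oracle)

    @pytest.mark.parametrize(
        "theta_f, mu_x, mu_v, expected",
        [
            (ONES2, [0, 0], [1, 1], [2, 2]),          # all-ones pf pattern
            (np.eye(2), [1, -1], [0, 0], [-1, 1]),    # pure leak term
            (TROT4, [0] * 4, [1, 0, 0, 0], [1, -1, -1, 1]),  # trot pattern col 0
        ],
    )
    def test_flow_prediction(self, theta_f, mu_x, mu_v, expected):
        n = len(mu_x)
        model = make_model(n, n, n, theta_f=theta_f)
        np.testing.assert_allclose(flow_prediction(model, mu_x, mu_v), expected)

    def test_dimension_mismatch_raises(self):
        model = make_model()
        with pytest.raises(ConfigurationError):
            observation_prediction(model, [1.0, 2.0, 3.0])
        with pytest.raises(ConfigurationError):
            flow_prediction(model, [1.0, 2.0], [1.0, 2.0, 3.0])


class TestPredictionErrors:
    def test_perfect_prediction_gives_zero_sensory_error(self):
        model = make_model()
        belief = BeliefState(mu_x=[0.4, -0.2], mu_xprime=[0, 0], mu_v=[0, 0])
        eps = compute_prediction_errors(model, belief, [0.4, -0.2])
        np.testing.assert_allclose(eps.eps_y, 0.0)

    def test_allones_flow_error(self):
        model = make_model(theta_f=ONES2)
        belief = BeliefState(mu_x=[0, 0], mu_xprime=[0, 0], mu_v=[1, 1])
        eps = compute_prediction_errors(model, belief, [0, 0])
        np.testing.assert_allclose(eps.eps_x, [-2, -2])

    def test_cause_error_is_cause_estimate(self, rng):
        model = random_model(rng)
        belief = random_belief(rng, model)
        eps = compute_prediction_errors(model, belief, rng.standard_normal(model.n_y))
        np.testing.assert_array_equal(eps.eps_v, belief.mu_v)

    def test_nonfinite_observation_raises_with_state_dump(self):
        model = make_model()
        belief = BeliefState(mu_x=[0, 0], mu_xprime=[0, 0], mu_v=[0, 0])
        with pytest.raises(NumericalError, match="mu_x"):
            compute_prediction_errors(model, belief, [np.nan, 0.0])


class TestFreeEnergy:
    def test_zero_errors_unit_precisions_give_zero(self):
        model = make_model()
        belief = BeliefState(mu_x=[0.5, 0.5], mu_xprime=[-0.5, -0.5], mu_v=[0, 0])
        # mu_xprime = -mu_x makes the flow error vanish with theta_f v = 0
        F = free_energy(model, belief, [0.5, 0.5])
        assert F.total == pytest.approx(0.0, abs=1e-12)

    def test_single_sensory_error(self):
        model = make_model()
        # eps_y = (2, 0) while the flow and cause errors vanish
        belief = BeliefState(mu_x=[-2, 0], mu_xprime=[2, 0], mu_v=[0, 0])
        F = free_energy(model, belief, [0, 0])
        assert F.quadratic_terms[0] == pytest.approx(2.0)
        assert F.total == pytest.approx(2.0)

    def test_matches_gaussian_log_density_oracle(self, rng):
        """F equals the sum of three negative Gaussian log-densities with
        the 2*pi constants dropped."""
        for _ in range(10):
            model = random_model(rng)
            belief = random_belief(rng, model)
            y = rng.standard_normal(model.n_y)
            eps = compute_prediction_errors(model, belief, y)
            expected = 0.0
            for e, Pi in (
                (eps.eps_y, model.Pi_z),
                (eps.eps_x, model.Pi_w),
                (eps.eps_v, model.Pi_v),
            ):
                d = len(e)
                logpdf = multivariate_normal(np.zeros(d), np.linalg.inv(Pi)).logpdf(e)
                expected += -logpdf - 0.5 * d * np.log(2 * np.pi)
            assert free_energy(model, belief, y).total == pytest.approx(expected)

    def test_decomposition_identity(self, rng):
        for _ in range(5):
            model = random_model(rng)
            belief = random_belief(rng, model)
            F = free_energy(model, belief, rng.standard_normal(model.n_y))
            assert F.total == pytest.approx(
                sum(F.quadratic_terms) - sum(F.logdet_terms)
            )
            assert all(q >= 0 for q in F.quadratic_terms)

    def test_non_pd_precision_rejected(self):
        with pytest.raises(ConfigurationError, match="Pi_z"):
            make_model(Pi_z=np.array([[1.0, 2.0], [2.0, 1.0]]))
        with pytest.raises(ConfigurationError, match="symmetric"):
            make_model(Pi_w=np.array([[1.0, 0.5], [0.0, 1.0]]))


def finite_difference_gradients(model, belief, y, h=1e-6):
    """Central finite differences of the implemented free energy."""
    from dataclasses import replace

    grads = []
    for name in ("mu_x", "mu_xprime", "mu_v"):
        base = getattr(belief, name)
        g = np.empty_like(base)
        for i in range(len(base)):
            up, dn = base.copy(), base.copy()
            up[i] += h
            dn[i] -= h
            f_up = free_energy(model, replace(belief, **{name: up}), y).total
            f_dn = free_energy(model, replace(belief, **{name: dn}), y).total
            g[i] = (f_up - f_dn) / (2 * h)
        grads.append(g)
    return tuple(grads)


class TestGradients:
    def test_zero_errors_give_zero_gradients(self):
        model = make_model()
        belief = BeliefState(mu_x=[0.5, 0.5], mu_xprime=[-0.5, -0.5], mu_v=[0, 0])
        for g in free_energy_gradients(model, belief, [0.5, 0.5]):
            np.testing.assert_allclose(g, 0.0, atol=1e-12)

    def test_velocity_gradient_substitution(self):
        model = make_model(Pi_w=2 * np.eye(2))
        # eps_x = mu_xprime + mu_x - theta_f mu_v = (1, 0)
        belief = BeliefState(mu_x=[0, 0], mu_xprime=[1, 0], mu_v=[0, 0])
        _, g_xp, _ = free_energy_gradients(model, belief, [0, 0])
        np.testing.assert_allclose(g_xp, [2, 0])

    def test_analytic_gradients_match_finite_differences(self, rng):
        for _ in range(30):
            model = random_model(rng)
            belief = random_belief(rng, model)
            y = rng.standard_normal(model.n_y)
            analytic = free_energy_gradients(model, belief, y)
            numeric = finite_difference_gradients(model, belief, y)
            for a, n in zip(analytic, numeric):
                np.testing.assert_allclose(a, n, rtol=1e-6, atol=1e-8)


class TestRecognitionStep:
    def test_drift_only_update(self):
        model = make_model()
        # zero sensory and flow errors; only the velocity drift moves mu_x
        belief = BeliefState(mu_x=[0.5, 0.5], mu_xprime=[1.0, 0.0], mu_v=[1.5, 0.5])
        y = [0.5, 0.5]
        eps = compute_prediction_errors(model, belief, y)
        np.testing.assert_allclose(eps.eps_y, 0, atol=1e-12)
        np.testing.assert_allclose(eps.eps_x, 0, atol=1e-12)
        # cause error remains; neutralise its influence with tiny Pi_v
        model = make_model(Pi_v=1e-15 * np.eye(2))
        new = recognition_step(model, belief, y, dt=0.1)
        np.testing.assert_allclose(new.mu_x, [0.6, 0.5], atol=1e-12)
        np.testing.assert_allclose(new.mu_xprime, belief.mu_xprime, atol=1e-10)

    def test_velocity_decrement(self):
        model = make_model(Pi_v=1e-15 * np.eye(2))
        belief = BeliefState(
            mu_x=[0, 0], mu_xprime=[1, 0], mu_v=[0, 0],
            kappa_x=0.0, kappa_xprime=1.0, kappa_v=0.0,
        )
        # eps_x = (1, 0); with kappa_xprime = 1 and dt = 1 the velocity
        # belief is decremented by exactly Pi_w eps_x
        new = recognition_step(model, belief, [0, 0], dt=1.0)
        np.testing.assert_allclose(new.mu_xprime, [0, 0], atol=1e-12)

    def test_gradient_part_descends_free_energy(self, rng):
        """With y fixed, velocity pinned to zero and the drift suppressed,
        the gradient flow strictly decreases F until tolerance."""
        from dataclasses import replace

        model = random_model(rng, n_y=2, n_x=2, n_v=2)
        belief = BeliefState(
            mu_x=rng.standard_normal(2),
            mu_xprime=np.zeros(2),
            mu_v=rng.standard_normal(2),
            kappa_x=0.01, kappa_xprime=0.0, kappa_v=0.01,
        )
        y = rng.standard_normal(2)
        last = free_energy(model, belief, y).total
        decreasing = 0
        for _ in range(200):
            belief = recognition_step(model, belief, y, dt=1.0)
            belief = replace(belief, mu_xprime=np.zeros(2))
            now = free_energy(model, belief, y).total
            assert now <= last + 1e-12
            if now < last - 1e-12:
                decreasing += 1
            last = now
        assert decreasing > 100

    def test_step_is_affine_in_observation(self, rng):
        model = random_model(rng, n_y=2, n_x=2, n_v=2)
        belief = random_belief(rng, model)
        y1, y2 = rng.standard_normal(2), rng.standard_normal(2)
        a = 0.3
        mix = recognition_step(model, belief, a * y1 + (1 - a) * y2, dt=0.05)
        s1 = recognition_step(model, belief, y1, dt=0.05)
        s2 = recognition_step(model, belief, y2, dt=0.05)
        for attr in ("mu_x", "mu_xprime", "mu_v"):
            np.testing.assert_allclose(
                getattr(mix, attr),
                a * getattr(s1, attr) + (1 - a) * getattr(s2, attr),
                rtol=1e-10, atol=1e-12,
            )

    def test_identity_theta_f_decouples_channels(self):
        """With theta_f = I and diagonal precisions, perturbing one
        observation channel leaves the other channel's beliefs unchanged."""
        model = make_model(theta_f=np.eye(2), Pi_v=1e-6 * np.eye(2))
        b1 = BeliefState(mu_x=[0.1, 0.2], mu_xprime=[0, 0], mu_v=[0.1, 0.2])
        b2 = b1
        y_base = np.array([0.5, -0.3])
        y_pert = np.array([0.5, 1.7])
        for _ in range(50):
            b1 = recognition_step(model, b1, y_base, dt=0.01)
            b2 = recognition_step(model, b2, y_pert, dt=0.01)
        for attr in ("mu_x", "mu_xprime", "mu_v"):
            assert getattr(b1, attr)[0] == getattr(b2, attr)[0]
            assert getattr(b1, attr)[1] != getattr(b2, attr)[1]

    def test_divergence_guard_names_component(self):
        model = make_model()
        belief = BeliefState(mu_x=[0, 0], mu_xprime=[0, 0], mu_v=[0, 0])
        with pytest.raises(InstabilityError, match="mu_x"):
            recognition_step(model, belief, [1e9, 0], dt=1.0, divergence_bound=10.0)

    def test_nonpositive_dt_rejected(self):
        model = make_model()
        belief = BeliefState(mu_x=[0, 0], mu_xprime=[0, 0], mu_v=[0, 0])
        with pytest.raises(ConfigurationError):
            recognition_step(model, belief, [0, 0], dt=0.0)


_finite = st.floats(-10, 10, allow_nan=False, allow_infinity=False)


class TestAlgebraicProperties:
    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        mu=arrays(np.float64, 6, elements=_finite),
        y=arrays(np.float64, 2, elements=_finite),
    )
    def test_free_energy_nonnegative_quadratics_and_decomposition(self, mu, y):
        model = make_model()
        belief = BeliefState(mu_x=mu[:2], mu_xprime=mu[2:4], mu_v=mu[4:])
        F = free_energy(model, belief, y)
        assert all(q >= 0 for q in F.quadratic_terms)
        assert F.total == pytest.approx(sum(F.quadratic_terms) - sum(F.logdet_terms))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        mu=arrays(np.float64, 6, elements=_finite),
        y=arrays(np.float64, 2, elements=_finite),
    )
    def test_gradients_vanish_only_with_prediction_errors(self, mu, y):
        """The recognition fixed point: zero prediction errors with zero
        velocity are stationary for all three update equations."""
        model = make_model()
        belief = BeliefState(mu_x=mu[:2], mu_xprime=mu[2:4], mu_v=mu[4:])
        eps = compute_prediction_errors(model, belief, y)
        grads = free_energy_gradients(model, belief, y)
        if max(np.abs(np.concatenate([eps.eps_y, eps.eps_x, eps.eps_v]))) < 1e-12:
            for g in grads:
                np.testing.assert_allclose(g, 0, atol=1e-10)


class TestInitialBelief:
    def test_consistent_with_first_observation(self, rng):
        model = make_model(theta_f=np.eye(2))
        y0 = rng.standard_normal(2)
        belief = initial_belief(model, y0)
        eps = compute_prediction_errors(model, belief, y0)
        np.testing.assert_allclose(eps.eps_y, 0, atol=1e-12)
        np.testing.assert_allclose(eps.eps_x, 0, atol=1e-12)

    def test_rank_deficient_pattern_minimises_flow_error(self):
        model = make_model(theta_f=ONES2)
        y0 = np.array([1.0, 0.0])
        belief = initial_belief(model, y0)
        eps = compute_prediction_errors(model, belief, y0)
        # the all-ones pattern can only cancel the common component
        np.testing.assert_allclose(eps.eps_x, [0.5, -0.5], atol=1e-12)
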