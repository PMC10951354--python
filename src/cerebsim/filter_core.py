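"""Cerebellar generative model and recognition (filtering) dynamics.

The cerebellum is modelled as inverting a linear state-space generative
model under the free-energy principle.  Observations ``y`` (mossy-fibre
input) are generated from hidden states ``x`` through a linear mapping
``g(x) = theta_g x``; the motion of hidden states is driven by hidden
causes (control states) ``v`` through a linear flow
``f(x, v) = -x + theta_f v``.  All random fluctuations are Gaussian with
precisions (inverse covariances) ``Pi_z`` (sensory), ``Pi_w`` (state
motion) and ``Pi_v`` (cause prior).

Inference proceeds by gradient descent of the belief expectations
``mu_x`` (hidden states, granule cells), ``mu_xprime`` (their expected
velocity, also granule cells) and ``mu_v`` (hidden causes, Purkinje
cells) on the variational free energy

    F = 1/2 eps_y' Pi_z eps_y - 1/2 log|Pi_z|
      + 1/2 eps_x' Pi_w eps_x - 1/2 log|Pi_w|
      + 1/2 eps_v' Pi_v eps_v - 1/2 log|Pi_v|

with prediction errors

    eps_y = y - g(mu_x)
    eps_x = mu_xprime - f(mu_x, mu_v)
    eps_v = mu_v.

Only first-order generalised motion is carried (``mu_x``, ``mu_xprime``);
no higher derivatives, no action dynamics, and no learning of ``theta_f``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "ConfigurationError",
    "NumericalError",
    "InstabilityError",
    "LinearStateSpaceModel",
    "BeliefState",
    "PredictionErrors",
    "FreeEnergyValue",
    "observation_prediction",
    "flow_prediction",
    "compute_prediction_errors",
    "free_energy",
    "free_energy_gradients",
    "recognition_step",
    "initial_belief",
]

#: Divergence guard: a belief component whose magnitude exceeds this bound
#: raises :class:`InstabilityError`.
DEFAULT_DIVERGENCE_BOUND = 1e6


class ConfigurationError(ValueError):
    """Inconsistent model set-up (shapes, non-PD precisions, bad keys)."""


class NumericalError(FloatingPointError):
    """Non-finite values encountered; the message carries a state dump."""


class InstabilityError(RuntimeError):
    """Recognition dynamics diverged; names the offending component."""

    def __init__(self, message: str, partial_trace=None):
        super().__init__(message)
        self.partial_trace = partial_trace


def _as_matrix(a, name: str) -> np.ndarray:
    m = np.atleast_2d(np.asarray(a, dtype=float))
    if m.ndim != 2:
        raise ConfigurationError(f"{name} must be a 2-D matrix, got ndim={m.ndim}")
    return m


def _check_spd(m: np.ndarray, name: str) -> None:
    if m.shape[0] != m.shape[1]:
        raise ConfigurationError(f"{name} must be square, got shape {m.shape}")
    if not np.allclose(m, m.T, rtol=1e-10, atol=1e-12):
        raise ConfigurationError(f"{name} must be symmetric")
    # Cholesky is the cheapest reliable PD test at these dimensions.
    try:
        np.linalg.cholesky(m)
    except np.linalg.LinAlgError:
        raise ConfigurationError(f"{name} must be positive definite") from None


@dataclass(frozen=True)
class LinearStateSpaceModel:
    """The cerebellar generative model.

    Parameters
    ----------
    theta_g : (n_y, n_x) array
        Observation mapping (Golgi-cell predictions), dimensionless.
    theta_f : (n_x, n_v) array
        Control-to-motion mapping (parallel-fibre connectivity),
        dimensionless.  Its pattern encodes learned expectations about
        interactions among latent states: an identity matrix encodes no
        interaction, an all-ones matrix encodes whisking–respiration
        synchrony, the rank-one +/-1 pattern encodes trot-like inter-limb
        coordination.
    Pi_z, Pi_w, Pi_v : symmetric positive-definite arrays
        Precisions (inverse covariances) of sensory, state-motion and
        cause fluctuations, units 1/a.u.^2.
    """

    theta_g: np.ndarray
    theta_f: np.ndarray
    Pi_z: np.ndarray
    Pi_w: np.ndarray
    Pi_v: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "theta_g", _as_matrix(self.theta_g, "theta_g"))
        object.__setattr__(self, "theta_f", _as_matrix(self.theta_f, "theta_f"))
        for name in ("Pi_z", "Pi_w", "Pi_v"):
            object.__setattr__(self, name, _as_matrix(getattr(self, name), name))
            _check_spd(getattr(self, name), name)
        n_y, n_x = self.theta_g.shape
        n_x2, n_v = self.theta_f.shape
        if n_x2 != n_x:
            raise ConfigurationError(
                f"theta_f has {n_x2} rows but theta_g maps from n_x={n_x} states"
            )
        for name, n in (("Pi_z", n_y), ("Pi_w", n_x), ("Pi_v", n_v)):
            if getattr(self, name).shape != (n, n):
                raise ConfigurationError(
                    f"{name} must be {n}x{n}, got {getattr(self, name).shape}"
                )

    @property
    def n_y(self) -> int:
        return self.theta_g.shape[0]

    @property
    def n_x(self) -> int:
        return self.theta_g.shape[1]

    @property
    def n_v(self) -> int:
        return self.theta_f.shape[1]

    def logdet_precisions(self) -> tuple[float, float, float]:
        return tuple(
            float(np.linalg.slogdet(m)[1]) for m in (self.Pi_z, self.Pi_w, self.Pi_v)
        )


@dataclass(frozen=True)
class BeliefState:
    """Filter expectations and their gradient-descent rate constants.

    ``kappa_x``, ``kappa_xprime`` and ``kappa_v`` are the rates (1/time)
    at which the three expectations descend the free-energy gradient.
    """

    mu_x: np.ndarray
    mu_xprime: np.ndarray
    mu_v: np.ndarray
    kappa_x: float = 5.0
    kappa_xprime: float = 0.5
    kappa_v: float = 50.0

    def __post_init__(self):
        for name in ("mu_x", "mu_xprime", "mu_v"):
            v = np.asarray(getattr(self, name), dtype=float).ravel()
            if not np.all(np.isfinite(v)):
                raise NumericalError(f"{name} contains non-finite entries: {v!r}")
            object.__setattr__(self, name, v)
        for name in ("kappa_x", "kappa_xprime", "kappa_v"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be nonnegative")
        if len(self.mu_x) != len(self.mu_xprime):
            raise ConfigurationError("mu_x and mu_xprime must have equal length")


@dataclass(frozen=True)
class PredictionErrors:
    eps_y: np.ndarray
    eps_x: np.ndarray
    eps_v: np.ndarray


@dataclass(frozen=True)
class FreeEnergyValue:
    """Free energy with its six-term decomposition (additive 2*pi constants
    of the Gaussian densities are omitted)."""

    total: float
    quadratic_terms: tuple[float, float, float]  # sensory, state, cause
    logdet_terms: tuple[float, float, float]


def _check_belief_shapes(model: LinearStateSpaceModel, belief: BeliefState) -> None:
    if len(belief.mu_x) != model.n_x:
        raise ConfigurationError(
            f"mu_x has length {len(belief.mu_x)}, model expects n_x={model.n_x}"
        )
    if len(belief.mu_v) != model.n_v:
        raise ConfigurationError(
            f"mu_v has length {len(belief.mu_v)}, model expects n_v={model.n_v}"
        )


def observation_prediction(model: LinearStateSpaceModel, mu_x: np.ndarray) -> np.ndarray:
    """Predicted observation g(mu_x) = theta_g mu_x."""
    mu_x = np.asarray(mu_x, dtype=float).ravel()
    if len(mu_x) != model.n_x:
        raise ConfigurationError(
            f"mu_x has length {len(mu_x)}, model expects n_x={model.n_x}"
        )
    return model.theta_g @ mu_x


def flow_prediction(
    model: LinearStateSpaceModel, mu_x: np.ndarray, mu_v: np.ndarray
) -> np.ndarray:
    """Predicted state motion f(mu_x, mu_v) = -mu_x + theta_f mu_v."""
    mu_x = np.asarray(mu_x, dtype=float).ravel()
    mu_v = np.asarray(mu_v, dtype=float).ravel()
    if len(mu_x) != model.n_x or len(mu_v) != model.n_v:
        raise ConfigurationError(
            f"flow_prediction: expected lengths (n_x={model.n_x}, n_v={model.n_v}), "
            f"got ({len(mu_x)}, {len(mu_v)})"
        )
    return -mu_x + model.theta_f @ mu_v


def compute_prediction_errors(
    model: LinearStateSpaceModel, belief: BeliefState, y: np.ndarray
) -> PredictionErrors:
    """Sensory, state-motion and cause prediction errors.

    ``eps_v`` equals ``mu_v`` by construction: the prior expectation of the
    causes is zero, so any nonzero cause estimate is itself an error.
    """
    _check_belief_shapes(model, belief)
    y = np.asarray(y, dtype=float).ravel()
    if len(y) != model.n_y:
        raise ConfigurationError(f"y has length {len(y)}, model expects n_y={model.n_y}")
    if not np.all(np.isfinite(y)):
        raise NumericalError(
            f"non-finite observation: y={y!r}, belief mu_x={belief.mu_x!r}, "
            f"mu_xprime={belief.mu_xprime!r}, mu_v={belief.mu_v!r}"
        )
    eps_y = y - observation_prediction(model, belief.mu_x)
    eps_x = belief.mu_xprime - flow_prediction(model, belief.mu_x, belief.mu_v)
    eps_v = belief.mu_v.copy()
    return PredictionErrors(eps_y=eps_y, eps_x=eps_x, eps_v=eps_v)


def free_energy(
    model: LinearStateSpaceModel, belief: BeliefState, y: np.ndarray
) -> FreeEnergyValue:
    """Variational free energy of the belief given the observation."""
    eps = compute_prediction_errors(model, belief, y)
    quad = (
        0.5 * float(eps.eps_y @ model.Pi_z @ eps.eps_y),
        0.5 * float(eps.eps_x @ model.Pi_w @ eps.eps_x),
        0.5 * float(eps.eps_v @ model.Pi_v @ eps.eps_v),
    )
    logdet = tuple(0.5 * ld for ld in model.logdet_precisions())
    return FreeEnergyValue(
        total=sum(quad) - sum(logdet),
        quadratic_terms=quad,
        logdet_terms=logdet,
    )


def free_energy_gradients(
    model: LinearStateSpaceModel, belief: BeliefState, y: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Analytic gradients of F w.r.t. (mu_x, mu_xprime, mu_v).

        dF/dmu_x      = -theta_g' Pi_z eps_y + Pi_w eps_x
        dF/dmu_xprime =  Pi_w eps_x
        dF/dmu_v      = -theta_f' Pi_w eps_x + Pi_v eps_v
    """
    eps = compute_prediction_errors(model, belief, y)
    Pw_ex = model.Pi_w @ eps.eps_x
    grad_mu_x = -model.theta_g.T @ (model.Pi_z @ eps.eps_y) + Pw_ex
    grad_mu_xprime = Pw_ex
    grad_mu_v = -model.theta_f.T @ Pw_ex + model.Pi_v @ eps.eps_v
    return grad_mu_x, grad_mu_xprime, grad_mu_v


def recognition_step(
    model: LinearStateSpaceModel,
    belief: BeliefState,
    y: np.ndarray,
    dt: float,
    divergence_bound: float = DEFAULT_DIVERGENCE_BOUND,
) -> BeliefState:
    """Advance the belief one explicit Euler step of the recognition flow.

        d(mu_x)/dt      = mu_xprime - kappa_x      dF/dmu_x
        d(mu_xprime)/dt =           - kappa_xprime dF/dmu_xprime
        d(mu_v)/dt      =           - kappa_v      dF/dmu_v

    The drift term ``mu_xprime`` in the first equation distinguishes the
    motion of the expectation from the expected motion; they coincide only
    at the free-energy minimum.
    """
    if dt <= 0:
        raise ConfigurationError(f"dt must be positive, got {dt}")
    g_x, g_xp, g_v = free_energy_gradients(model, belief, y)
    mu_x = belief.mu_x + (belief.mu_xprime - belief.kappa_x * g_x) * dt
    mu_xprime = belief.mu_xprime - belief.kappa_xprime * g_xp * dt
    mu_v = belief.mu_v - belief.kappa_v * g_v * dt
    for name, v in (("mu_x", mu_x), ("mu_xprime", mu_xprime), ("mu_v", mu_v)):
        worst = float(np.max(np.abs(v))) if len(v) else 0.0
        if not np.isfinite(worst) or worst > divergence_bound:
            raise InstabilityError(
                f"recognition dynamics diverged: |{name}| reached {worst:.3g} "
                f"(bound {divergence_bound:.3g})"
            )
    return replace(belief, mu_x=mu_x, mu_xprime=mu_xprime, mu_v=mu_v)


def initial_belief(
    model: LinearStateSpaceModel,
    y0: np.ndarray,
    kappa_x: float = 5.0,
    kappa_xprime: float = 0.5,
    kappa_v: float = 50.0,
) -> BeliefState:
    """Belief consistent with the first observation.

    ``mu_x`` solves ``g(mu_x) = y0`` in the least-squares sense,
    ``mu_xprime`` starts at rest, and ``mu_v`` is the least-squares cause
    that makes the flow error vanish (``theta_f mu_v = mu_xprime + mu_x``).
    Starting on the prior manifold avoids a spurious initial prediction
    error that would otherwise kick the coupled process.
    """
    y0 = np.asarray(y0, dtype=float).ravel()
    if len(y0) != model.n_y:
        raise ConfigurationError(f"y0 has length {len(y0)}, expected n_y={model.n_y}")
    mu_x = np.linalg.pinv(model.theta_g) @ y0
    mu_xprime = np.zeros(model.n_x)
    mu_v = np.linalg.pinv(model.theta_f) @ (mu_xprime + mu_x)
    return BeliefState(
        mu_x=mu_x,
        mu_xprime=mu_xprime,
        mu_v=mu_v,
        kappa_x=kappa_x,
        kappa_xprime=kappa_xprime,
        kappa_v=kappa_v,
    )
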