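"""Closed-loop coupling of the cerebellar filter and the oscillator process.

Each step the process output is observed by the filter, and the filter's
state estimates are sent back to the process where they enter the
coupling terms ``k*sin(x_est - phi)`` — the in-silico analogue of
cerebellar-nuclei output contextualising extra-cerebellar dynamics.

Observation pathways
--------------------
``observation="phase"`` (default): the somatic state conveyed to the
filter is the oscillator phase measured in the frame co-rotating at the
regime's commanded rate, ``y_i = phi_i(unwrapped) - Phi_ref``, and the
descending estimate entering the coupling is ``x_i = mu_x,i + Phi_ref``.
In this frame the leak prior ``x' = -x + theta_f v`` reads "phase
misalignments decay unless a learned context sustains them", which is
what lets a patterned ``theta_f`` exert synchronising pressure (see
docs/methods.md for the analysis).

``observation="amplitude"``: the filter observes the somatic outputs
(w, r or limb displacements) directly and ``x_est = mu_x``.  This is the
face-value reading of the model equations; it tracks but cannot
synchronise the oscillators, and is provided for comparison.

CN suspension: inside the intervals of ``cn_active_schedule`` the
estimates reach the process; outside them the process-side coupling gain
is zeroed while the filter keeps assimilating observations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .filter_core import (
    BeliefState,
    ConfigurationError,
    InstabilityError,
    LinearStateSpaceModel,
    compute_prediction_errors,
    free_energy,
    initial_belief,
    recognition_step,
)
from .oscillators import (
    LIMB_ORDER,
    PhasePerturbation,
    QuadrupedState,
    RegimeSchedule,
    RegimeSegment,
    WhiskRespState,
    limb_output,
    limb_phase_step,
    wr_output,
    wr_phase_step,
    wrap_phase,
)

__all__ = [
    "WHISK_RESP",
    "LOCOMOTION",
    "FilterParams",
    "SimulationConfig",
    "SimulationTrace",
    "default_regime_schedule",
    "contextualised_theta_f",
    "set_contextualisation",
    "build_model",
    "run_coupled_simulation",
]

WHISK_RESP = "whisk_resp"
LOCOMOTION = "locomotion"

#: theta_f patterns encoding learned coordination, per scenario.
_COUPLED_THETA_F = {
    WHISK_RESP: np.ones((2, 2)),
    LOCOMOTION: np.array(
        [
            [1.0, -1.0, -1.0, 1.0],
            [-1.0, 1.0, 1.0, -1.0],
            [-1.0, 1.0, 1.0, -1.0],
            [1.0, -1.0, -1.0, 1.0],
        ]
    ),
}

_SCENARIO_DIM = {WHISK_RESP: 2, LOCOMOTION: 4}


@dataclass(frozen=True)
class FilterParams:
    """Precision scales and rate constants of the recognition dynamics.

    Precisions are isotropic: ``Pi = scale * I``.  ``pi_v`` defaults to a
    near-zero scale, a noninformative prior over the hidden causes.
    """

    pi_z: float = 1.0
    pi_w: float = 1.0
    pi_v: float = 1e-6
    kappa_x: float = 5.0
    kappa_xprime: float = 0.5
    kappa_v: float = 50.0
    divergence_bound: float = 1e6


def default_regime_schedule(duration: float, omega_0: float = 0.0) -> RegimeSchedule:
    """Low-rate whisking, a brief no-whisk gap, then high-rate sniffing.

    Low rate 2*pi rad/time on [0, 0.4*T); whisking stopped (alpha = 0) on
    [0.4*T, 0.5*T); high rate 4*pi on [0.5*T, T).
    """
    lo, hi = 2.0 * math.pi, 4.0 * math.pi
    return RegimeSchedule(
        segments=(
            RegimeSegment(0.0, 1.0, lo, omega_0),
            RegimeSegment(0.4 * duration, 0.0, lo, omega_0),
            RegimeSegment(0.5 * duration, 1.0, hi, omega_0),
        )
    )


@dataclass(frozen=True)
class SimulationConfig:
    """A fully specified coupled-simulation run.

    ``process`` is the initial oscillator state and carries the process
    parameters (gains, noise scales, angular velocities).  For the
    whisking scenario, (alpha, omega_w, omega_0) are overridden each step
    by ``regime_schedule``.  ``cn_active_schedule`` is a sorted tuple of
    non-overlapping (start, end) intervals during which cerebellar output
    reaches the process; ``None`` means always active.
    """

    scenario: str
    duration: float
    seed: int
    dt: float = 0.002
    contextualise: bool = True
    observation: str = "phase"
    process: Optional[object] = None
    regime_schedule: Optional[RegimeSchedule] = None
    perturbations: tuple = ()
    cn_active_schedule: Optional[tuple] = None
    filter_params: FilterParams = field(default_factory=FilterParams)
    init_phase_jitter: float = 0.0
    transient_fraction: float = 0.2

    def __post_init__(self):
        if self.scenario not in _SCENARIO_DIM:
            raise ConfigurationError(
                f"unknown scenario {self.scenario!r}; expected one of "
                f"{sorted(_SCENARIO_DIM)}"
            )
        if self.dt <= 0:
            raise ConfigurationError(f"dt must be positive, got {self.dt}")
        if self.duration < self.dt:
            raise ConfigurationError("duration must be at least one step")
        if self.observation not in ("phase", "amplitude"):
            raise ConfigurationError(
                f"observation must be 'phase' or 'amplitude', got {self.observation!r}"
            )
        if not 0.0 <= self.transient_fraction < 1.0:
            raise ConfigurationError("transient_fraction must lie in [0, 1)")
        if self.cn_active_schedule is not None:
            ivs = tuple(tuple(map(float, iv)) for iv in self.cn_active_schedule)
            object.__setattr__(self, "cn_active_schedule", ivs)
            last_end = -math.inf
            for start, end in ivs:
                if end <= start or start < last_end:
                    raise ConfigurationError(
                        "cn_active_schedule intervals must be sorted and "
                        f"non-overlapping, got {ivs}"
                    )
                last_end = end
        if self.process is None:
            default = WhiskRespState() if self.scenario == WHISK_RESP else QuadrupedState()
            object.__setattr__(self, "process", default)
        expected = WhiskRespState if self.scenario == WHISK_RESP else QuadrupedState
        if not isinstance(self.process, expected):
            raise ConfigurationError(
                f"scenario {self.scenario!r} requires a {expected.__name__} process"
            )

    @property
    def n_steps(self) -> int:
        return int(round(self.duration / self.dt))

    def cn_active_at(self, time: float) -> bool:
        if self.cn_active_schedule is None:
            return True
        return any(start <= time < end for start, end in self.cn_active_schedule)


def contextualised_theta_f(scenario: str) -> np.ndarray:
    """The learned coordination pattern for a scenario (all-ones for
    whisking–respiration, the rank-one +/-1 trot pattern for locomotion)."""
    try:
        return _COUPLED_THETA_F[scenario].copy()
    except KeyError:
        raise ConfigurationError(f"unknown scenario {scenario!r}") from None


def set_contextualisation(
    model: LinearStateSpaceModel, enabled: bool, scenario: str = None
) -> LinearStateSpaceModel:
    """Return the model with theta_f swapped for the scenario's coupled
    pattern (enabled) or the identity (disabled); theta_g is untouched."""
    if scenario is None:
        scenario = {2: WHISK_RESP, 4: LOCOMOTION}.get(model.n_x)
        if scenario is None:
            raise ConfigurationError(
                f"cannot infer scenario from n_x={model.n_x}; pass scenario="
            )
    pattern = contextualised_theta_f(scenario)
    if pattern.shape != (model.n_x, model.n_v):
        raise ConfigurationError(
            f"scenario {scenario!r} pattern {pattern.shape} does not match model "
            f"dimensions ({model.n_x}, {model.n_v})"
        )
    theta_f = pattern if enabled else np.eye(model.n_x)
    return LinearStateSpaceModel(
        theta_g=model.theta_g,
        theta_f=theta_f,
        Pi_z=model.Pi_z,
        Pi_w=model.Pi_w,
        Pi_v=model.Pi_v,
    )


def build_model(config: SimulationConfig) -> LinearStateSpaceModel:
    """Construct the cerebellar generative model for a simulation config."""
    n = _SCENARIO_DIM[config.scenario]
    fp = config.filter_params
    base = LinearStateSpaceModel(
        theta_g=np.eye(n),
        theta_f=np.eye(n),
        Pi_z=fp.pi_z * np.eye(n),
        Pi_w=fp.pi_w * np.eye(n),
        Pi_v=fp.pi_v * np.eye(n),
    )
    return set_contextualisation(base, config.contextualise, config.scenario)


@dataclass
class SimulationTrace:
    """Time-indexed record of one coupled run.

    All arrays share the leading dimension ``n_steps``; rows are recorded
    after each step, at times ``dt, 2*dt, ...``.  ``outputs`` maps somatic
    output names (w, r or l_fr..l_hl, t) to series; ``phases`` maps
    oscillator ids to wrapped phase series; ``phases_unwrapped`` to the
    cumulative phases used in the phase-observation pathway.
    """

    time: np.ndarray
    outputs: dict
    phases: dict
    phases_unwrapped: dict
    y: np.ndarray
    mu_x: np.ndarray
    mu_xprime: np.ndarray
    mu_v: np.ndarray
    eps_y: np.ndarray
    eps_x: np.ndarray
    eps_v: np.ndarray
    free_energy: np.ndarray
    regime: np.ndarray
    cn_active: np.ndarray
    alpha: np.ndarray
    reference_phase: np.ndarray
    config: SimulationConfig

    @property
    def n_steps(self) -> int:
        return len(self.time)

    @property
    def oscillator_ids(self) -> tuple:
        return tuple(self.phases.keys())

    def post_transient(self) -> np.ndarray:
        """Boolean mask excluding the initial transient window."""
        cut = self.config.transient_fraction * self.config.duration
        return self.time >= cut

    def to_frame(self):
        """Flatten the trace to a pandas DataFrame with stable columns."""
        import pandas as pd

        cols = {"time": self.time}
        cols.update(self.outputs)
        for key, series in self.phases.items():
            cols[f"phi_{key}"] = series
        ids = list(self.phases.keys())
        for j, key in enumerate(ids):
            cols[f"y_{key}"] = self.y[:, j]
            cols[f"mu_x_{key}"] = self.mu_x[:, j]
            cols[f"mu_xprime_{key}"] = self.mu_xprime[:, j]
            cols[f"mu_v_{key}"] = self.mu_v[:, j]
            cols[f"eps_y_{key}"] = self.eps_y[:, j]
            cols[f"eps_x_{key}"] = self.eps_x[:, j]
            cols[f"eps_v_{key}"] = self.eps_v[:, j]
        cols["free_energy"] = self.free_energy
        cols["regime"] = self.regime
        cols["cn_active"] = self.cn_active.astype(int)
        return pd.DataFrame(cols)


def _wrap_increment(new_phi: np.ndarray, old_phi: np.ndarray) -> np.ndarray:
    """Recover the (small) true phase increment from wrapped phases."""
    return (new_phi - old_phi + math.pi) % (2.0 * math.pi) - math.pi


def run_coupled_simulation(config: SimulationConfig) -> SimulationTrace:
    """Run the closed loop and return the full trace.

    Per step: (1) regime and perturbations are applied to the process;
    (2) the process advances one Euler–Maruyama step, with the cerebellar
    coupling fed by the current estimates when CN output is active and
    zeroed otherwise; (3) the observation is formed; (4) the filter
    advances one recognition step; (5) everything is recorded.
    Deterministic given (config, seed).
    """
    scenario = config.scenario
    n = _SCENARIO_DIM[scenario]
    n_steps = config.n_steps
    dt = config.dt

    seedseq = np.random.SeedSequence(config.seed)
    # one child stream per oscillator, plus one for initial conditions
    children = seedseq.spawn(n + 1)
    osc_rngs = [np.random.default_rng(s) for s in children[:n]]
    init_rng = np.random.default_rng(children[n])

    state = config.process
    if config.init_phase_jitter > 0:
        jitter = config.init_phase_jitter * init_rng.standard_normal(n)
        if scenario == WHISK_RESP:
            state = replace(
                state,
                phi_w=float(wrap_phase(state.phi_w + jitter[0])),
                phi_r=float(wrap_phase(state.phi_r + jitter[1])),
            )
        else:
            phi = wrap_phase(state.phases + jitter)
            state = replace(
                state,
                phi_fr=float(phi[0]),
                phi_fl=float(phi[1]),
                phi_hr=float(phi[2]),
                phi_hl=float(phi[3]),
            )
    if scenario == WHISK_RESP and config.regime_schedule is not None:
        from .oscillators import apply_regime

        state = apply_regime(state, config.regime_schedule, 0.0)

    model = build_model(config)
    unwrapped = state.phases.copy()
    ref = 0.0

    def _amplitude_obs(out):
        if scenario == WHISK_RESP:
            return out.as_array(("w", "r"))
        return out.as_array(tuple(f"l_{k}" for k in LIMB_ORDER))

    # initial observation and flow-consistent belief
    if config.observation == "phase":
        y0 = unwrapped - ref
    else:
        out0 = wr_output(state) if scenario == WHISK_RESP else limb_output(state)
        y0 = _amplitude_obs(out0)
    fp = config.filter_params
    belief = initial_belief(
        model, y0, kappa_x=fp.kappa_x, kappa_xprime=fp.kappa_xprime, kappa_v=fp.kappa_v
    )

    osc_ids = state.oscillator_ids
    out_names = (
        ("w", "r") if scenario == WHISK_RESP else tuple(f"l_{k}" for k in LIMB_ORDER) + ("t",)
    )
    rec_out = {name: np.empty(n_steps) for name in out_names}
    rec_phi = {k: np.empty(n_steps) for k in osc_ids}
    rec_phiu = {k: np.empty(n_steps) for k in osc_ids}
    rec = {
        name: np.empty((n_steps, n))
        for name in ("y", "mu_x", "mu_xprime", "mu_v", "eps_y", "eps_x", "eps_v")
    }
    rec_F = np.empty(n_steps)
    rec_regime = np.zeros(n_steps, dtype=int)
    rec_cn = np.empty(n_steps, dtype=bool)
    rec_alpha = np.empty(n_steps)
    rec_refphase = np.empty(n_steps)
    time = (np.arange(n_steps) + 1) * dt

    def _partial(upto):
        sl = slice(0, upto)
        return SimulationTrace(
            time=time[sl],
            outputs={k: v[sl] for k, v in rec_out.items()},
            phases={k: v[sl] for k, v in rec_phi.items()},
            phases_unwrapped={k: v[sl] for k, v in rec_phiu.items()},
            y=rec["y"][sl],
            mu_x=rec["mu_x"][sl],
            mu_xprime=rec["mu_xprime"][sl],
            mu_v=rec["mu_v"][sl],
            eps_y=rec["eps_y"][sl],
            eps_x=rec["eps_x"][sl],
            eps_v=rec["eps_v"][sl],
            free_energy=rec_F[sl],
            regime=rec_regime[sl],
            cn_active=rec_cn[sl],
            alpha=rec_alpha[sl],
            reference_phase=rec_refphase[sl],
            config=config,
        )

    from .oscillators import apply_perturbation, apply_regime

    t_prev = 0.0
    for i in range(n_steps):
        t_now = time[i]
        # (1) regime and perturbations
        regime_idx = 0
        if scenario == WHISK_RESP and config.regime_schedule is not None:
            regime_idx = config.regime_schedule.active_index(t_prev)
            state = apply_regime(state, config.regime_schedule, t_prev)
        if config.perturbations:
            before = state.phases
            state = apply_perturbation(state, config.perturbations, t_prev, t_now)
            for p in config.perturbations:
                if t_prev < p.time <= t_now:
                    idx = osc_ids.index(p.target)
                    unwrapped[idx] += p.delta_phi
            # guard: any residual mismatch means a perturbation target moved
            # the wrapped phase in a way not mirrored above
            del before

        cn = config.cn_active_at(t_prev)

        # (2) advance the process
        if config.observation == "phase":
            x_est = belief.mu_x + ref
        else:
            x_est = belief.mu_x
        if scenario == WHISK_RESP:
            step_state = state if cn else replace(state, k=0.0)
            old = step_state.phases
            new_state = wr_phase_step(step_state, x_est, dt, osc_rngs[0], osc_rngs[1])
            if not cn:
                new_state = replace(new_state, k=state.k)
            omega_ref = state.omega_w
        else:
            step_state = state if cn else replace(state, k_cb=0.0)
            old = step_state.phases
            new_state = limb_phase_step(step_state, x_est, dt, osc_rngs)
            if not cn:
                new_state = replace(new_state, k_cb=state.k_cb)
            omega_ref = state.omega
        unwrapped = unwrapped + _wrap_increment(new_state.phases, old)
        state = new_state
        ref += omega_ref * dt

        # (3) observation
        out = wr_output(state) if scenario == WHISK_RESP else limb_output(state)
        if config.observation == "phase":
            y = unwrapped - ref
        else:
            y = _amplitude_obs(out)

        # (4) one recognition step
        eps = compute_prediction_errors(model, belief, y)
        F = free_energy(model, belief, y)
        try:
            belief = recognition_step(
                model, belief, y, dt, divergence_bound=fp.divergence_bound
            )
        except InstabilityError as err:
            raise InstabilityError(str(err), partial_trace=_partial(i)) from None

        # (5) record
        for name in out_names:
            rec_out[name][i] = out[name]
        for j, k in enumerate(osc_ids):
            rec_phi[k][i] = state.phases[j]
            rec_phiu[k][i] = unwrapped[j]
        rec["y"][i] = y
        rec["mu_x"][i] = belief.mu_x
        rec["mu_xprime"][i] = belief.mu_xprime
        rec["mu_v"][i] = belief.mu_v
        rec["eps_y"][i] = eps.eps_y
        rec["eps_x"][i] = eps.eps_x
        rec["eps_v"][i] = eps.eps_v
        rec_F[i] = F.total
        rec_regime[i] = regime_idx
        rec_cn[i] = cn
        rec_alpha[i] = getattr(state, "alpha", 1.0)
        rec_refphase[i] = ref
        t_prev = t_now

    return _partial(n_steps)
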