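"""Extra-cerebellar generative processes: stochastic Kuramoto oscillators.

Two systems are provided.  The whisking–respiration process couples a
whisker oscillator (somatic output ``w = alpha * sin(phi_w)``, with
``alpha`` an amplitude gate that stops or restarts whisking) and a
respiration oscillator (``r = sin(phi_r)``) whose intrinsic angular
velocities may differ by an offset ``omega_0``.  The two oscillators are
never coupled directly; each phase is attracted only to the cerebellar
estimate of its own state through ``k * sin(x - phi)``, so any observed
synchrony is an effect of cerebellar inference.

The locomotion process drives the vertical displacement of the four
limbs (``l = sin(phi)``) during the stride cycle.  The front-right limb
is the intrinsic reference: the other three are pulled toward it with
fixed target offsets (pi for front-left, 3*pi/2 for hind-right, pi/2 for
hind-left), which is the acerebellar walking pattern.  Each limb is also
attracted to its cerebellar estimate with gain ``k_cb``.  Tail vertical
displacement is a passive sum of the two front limbs.

Both processes are integrated with Euler–Maruyama at the filter step
``dt``; each oscillator draws its phase noise from an independent stream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .filter_core import ConfigurationError

__all__ = [
    "TWO_PI",
    "wrap_phase",
    "WhiskRespState",
    "QuadrupedState",
    "RegimeSegment",
    "RegimeSchedule",
    "PhasePerturbation",
    "OscillatorOutputs",
    "wr_phase_step",
    "wr_output",
    "limb_phase_step",
    "limb_output",
    "tail_output",
    "apply_regime",
    "apply_perturbation",
]

TWO_PI = 2.0 * math.pi

#: Intrinsic target phase offsets of fl, hr, hl relative to fr (radians).
LIMB_OFFSETS = {"fl": math.pi, "hr": 1.5 * math.pi, "hl": 0.5 * math.pi}

LIMB_ORDER = ("fr", "fl", "hr", "hl")


def wrap_phase(phi):
    """Wrap phase(s) to [0, 2*pi)."""
    return np.asarray(phi, dtype=float) % TWO_PI


def _validate_nonneg(value: float, name: str) -> float:
    if value < 0:
        raise ConfigurationError(f"{name} must be nonnegative, got {value}")
    return float(value)


@dataclass(frozen=True)
class WhiskRespState:
    """Whisking–respiration oscillator pair.

    ``omega_r = omega_w + omega_0``.  ``alpha`` gates whisking amplitude;
    ``k`` is the gain of the cerebellar coupling term; ``sigma_w`` and
    ``sigma_r`` scale independent phase noise.
    """

    phi_w: float = 0.0
    phi_r: float = 0.0
    omega_w: float = TWO_PI
    omega_0: float = 0.0
    alpha: float = 1.0
    k: float = 15.0
    sigma_w: float = 0.0
    sigma_r: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "phi_w", float(wrap_phase(self.phi_w)))
        object.__setattr__(self, "phi_r", float(wrap_phase(self.phi_r)))
        if not 0.0 <= self.alpha <= 1.0:
            raise ConfigurationError(f"alpha must lie in [0, 1], got {self.alpha}")
        _validate_nonneg(self.k, "k")
        _validate_nonneg(self.sigma_w, "sigma_w")
        _validate_nonneg(self.sigma_r, "sigma_r")

    @property
    def omega_r(self) -> float:
        return self.omega_w + self.omega_0

    @property
    def phases(self) -> np.ndarray:
        return np.array([self.phi_w, self.phi_r])

    @property
    def oscillator_ids(self) -> tuple[str, ...]:
        return ("w", "r")


@dataclass(frozen=True)
class QuadrupedState:
    """Four-limb stride oscillators with a shared angular velocity.

    ``k_intr`` is the gain pulling fl/hr/hl toward the front-right limb
    at their intrinsic offsets; ``k_cb`` is the cerebellar coupling gain
    (the spinal/cerebellar naming is unambiguous here: the printed model
    reuses one symbol for both roles).
    """

    phi_fr: float = 0.0
    phi_fl: float = 0.0
    phi_hr: float = 0.0
    phi_hl: float = 0.0
    omega: float = TWO_PI
    k_intr: float = 0.75
    k_cb: float = 20.0
    sigma_fr: float = 0.0
    sigma_fl: float = 0.0
    sigma_hr: float = 0.0
    sigma_hl: float = 0.0
    delta_fl: float = LIMB_OFFSETS["fl"]
    delta_hr: float = LIMB_OFFSETS["hr"]
    delta_hl: float = LIMB_OFFSETS["hl"]

    def __post_init__(self):
        for name in ("phi_fr", "phi_fl", "phi_hr", "phi_hl"):
            object.__setattr__(self, name, float(wrap_phase(getattr(self, name))))
        for name in ("k_intr", "k_cb", "sigma_fr", "sigma_fl", "sigma_hr", "sigma_hl"):
            _validate_nonneg(getattr(self, name), name)

    @property
    def phases(self) -> np.ndarray:
        return np.array([self.phi_fr, self.phi_fl, self.phi_hr, self.phi_hl])

    @property
    def sigmas(self) -> np.ndarray:
        return np.array([self.sigma_fr, self.sigma_fl, self.sigma_hr, self.sigma_hl])

    @property
    def deltas(self) -> np.ndarray:
        """Intrinsic offsets, indexed like :data:`LIMB_ORDER` (fr entry 0)."""
        return np.array([0.0, self.delta_fl, self.delta_hr, self.delta_hl])

    @property
    def oscillator_ids(self) -> tuple[str, ...]:
        return LIMB_ORDER


@dataclass(frozen=True)
class RegimeSegment:
    start_time: float
    alpha: float
    omega_w: float
    omega_0: float


@dataclass(frozen=True)
class RegimeSchedule:
    """Piecewise-constant behavioural regime: (alpha, omega_w, omega_0).

    Segments are half-open intervals [start, next_start); the first
    segment must start at time 0 and starts must be strictly increasing.
    """

    segments: tuple[RegimeSegment, ...]

    def __post_init__(self):
        segs = tuple(
            s if isinstance(s, RegimeSegment) else RegimeSegment(*s)
            for s in self.segments
        )
        object.__setattr__(self, "segments", segs)
        if not segs:
            raise ConfigurationError("RegimeSchedule needs at least one segment")
        if segs[0].start_time != 0.0:
            raise ConfigurationError("first regime segment must start at time 0")
        starts = [s.start_time for s in segs]
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise ConfigurationError("regime start_times must be strictly increasing")

    def active_index(self, time: float) -> int:
        idx = 0
        for i, seg in enumerate(self.segments):
            if time >= seg.start_time:
                idx = i
            else:
                break
        return idx

    def active_segment(self, time: float) -> RegimeSegment:
        return self.segments[self.active_index(time)]


@dataclass(frozen=True)
class PhasePerturbation:
    """An abrupt additive phase jump on one oscillator."""

    time: float
    target: str
    delta_phi: float


@dataclass(frozen=True)
class OscillatorOutputs:
    """Somatic outputs keyed by oscillator id (plus 't' for the tail)."""

    values: dict

    def __getitem__(self, key):
        return self.values[key]

    def as_array(self, order: Sequence[str]) -> np.ndarray:
        return np.array([self.values[k] for k in order])


def wr_phase_step(
    state: WhiskRespState,
    x_est: np.ndarray,
    dt: float,
    rng_w: np.random.Generator,
    rng_r: np.random.Generator,
) -> WhiskRespState:
    """One Euler–Maruyama step of the whisking–respiration phases.

        dphi_w = [omega_w + k sin(x_w - phi_w)] dt + sigma_w sqrt(dt) xi_w
        dphi_r = [omega_r + k sin(x_r - phi_r)] dt + sigma_r sqrt(dt) xi_r

    ``x_est`` holds the cerebellar estimates (x_w, x_r) entering the
    coupling terms; there is no direct coupling between the oscillators.
    Each oscillator consumes noise from its own generator so that zeroing
    one noise scale leaves the other stream untouched.
    """
    if dt <= 0:
        raise ConfigurationError(f"dt must be positive, got {dt}")
    x_est = np.asarray(x_est, dtype=float).ravel()
    sq = math.sqrt(dt)
    dphi_w = (
        (state.omega_w + state.k * math.sin(x_est[0] - state.phi_w)) * dt
        + state.sigma_w * sq * rng_w.standard_normal()
    )
    dphi_r = (
        (state.omega_r + state.k * math.sin(x_est[1] - state.phi_r)) * dt
        + state.sigma_r * sq * rng_r.standard_normal()
    )
    return replace(
        state,
        phi_w=float(wrap_phase(state.phi_w + dphi_w)),
        phi_r=float(wrap_phase(state.phi_r + dphi_r)),
    )


def wr_output(state: WhiskRespState) -> OscillatorOutputs:
    """Somatic outputs: w = alpha sin(phi_w), r = sin(phi_r)."""
    return OscillatorOutputs(
        values={
            "w": state.alpha * math.sin(state.phi_w),
            "r": math.sin(state.phi_r),
        }
    )


def limb_phase_step(
    state: QuadrupedState,
    x_est: np.ndarray,
    dt: float,
    rngs: Sequence[np.random.Generator],
) -> QuadrupedState:
    """One Euler–Maruyama step of the four limb phases.

    The front-right limb has no intrinsic coupling; the others are pulled
    toward ``phi_fr + delta`` with gain ``k_intr``.  Every limb is pulled
    toward its cerebellar estimate with gain ``k_cb``.
    """
    if dt <= 0:
        raise ConfigurationError(f"dt must be positive, got {dt}")
    x_est = np.asarray(x_est, dtype=float).ravel()
    phi = state.phases
    drift = np.full(4, state.omega)
    drift[1:] += state.k_intr * np.sin(phi[0] + state.deltas[1:] - phi[1:])
    drift += state.k_cb * np.sin(x_est - phi)
    sq = math.sqrt(dt)
    noise = np.array([rng.standard_normal() for rng in rngs])
    new_phi = wrap_phase(phi + drift * dt + state.sigmas * sq * noise)
    return replace(
        state,
        phi_fr=float(new_phi[0]),
        phi_fl=float(new_phi[1]),
        phi_hr=float(new_phi[2]),
        phi_hl=float(new_phi[3]),
    )


def limb_output(state: QuadrupedState) -> OscillatorOutputs:
    """Vertical limb displacements l = sin(phi), plus the tail under 't'."""
    vals = {f"l_{lbl}": math.sin(p) for lbl, p in zip(LIMB_ORDER, state.phases)}
    vals["t"] = tail_output(state)
    return OscillatorOutputs(values=vals)


def tail_output(state: QuadrupedState) -> float:
    """Tail vertical displacement: passive sum of the two front limbs."""
    return math.sin(state.phi_fr) + math.sin(state.phi_fl)


def apply_regime(
    state: WhiskRespState, schedule: RegimeSchedule, time: float
) -> WhiskRespState:
    """Set (alpha, omega_w, omega_0) from the segment active at ``time``.

    Phases are untouched; the change is instantaneous at segment
    boundaries (half-open [start, next_start) convention, so a query
    exactly at a boundary already sees the new segment).
    """
    seg = schedule.active_segment(time)
    return replace(state, alpha=seg.alpha, omega_w=seg.omega_w, omega_0=seg.omega_0)


def apply_perturbation(state, perturbations: Sequence[PhasePerturbation], t_prev, t_now):
    """Apply, in time order, every perturbation with t_prev < time <= t_now."""
    phase_attr = {"w": "phi_w", "r": "phi_r"}
    if isinstance(state, QuadrupedState):
        phase_attr = {lbl: f"phi_{lbl}" for lbl in LIMB_ORDER}
    due = sorted(
        (p for p in perturbations if t_prev < p.time <= t_now), key=lambda p: p.time
    )
    for p in due:
        if p.target not in phase_attr:
            raise ConfigurationError(
                f"unknown perturbation target {p.target!r}; "
                f"valid targets: {sorted(phase_attr)}"
            )
        attr = phase_attr[p.target]
        state = replace(
            state, **{attr: float(wrap_phase(getattr(state, attr) + p.delta_phi))}
        )
    return state
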