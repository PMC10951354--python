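"""Scenario presets and the metrics that quantify coordination.

The whisking–respiration scenarios reproduce three pressure conditions —
an intrinsic angular-velocity offset, added phase noise, and abrupt
phase perturbations — each with and without cerebellar contextualisation
(the all-ones vs identity parallel-fibre pattern).  The locomotion
scenario runs the four-limb process with the trot-encoding pattern or
the identity, and summarises pairwise limb coordination with circular
statistics and stride-triggered averages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .engine import (
    LOCOMOTION,
    WHISK_RESP,
    SimulationConfig,
    SimulationTrace,
    default_regime_schedule,
    run_coupled_simulation,
)
from .filter_core import ConfigurationError
from .oscillators import LIMB_OFFSETS, PhasePerturbation, QuadrupedState, WhiskRespState

__all__ = [
    "ScenarioResult",
    "StrideEnsemble",
    "WR_CONDITIONS",
    "abs_difference_trace",
    "sync_manifold_distance",
    "phase_locking_stats",
    "stride_average",
    "tail_symmetry_index",
    "scenario_wr",
    "scenario_wr_suspension",
    "scenario_locomotion",
]

WR_CONDITIONS = ("offset", "offset_noise", "perturbation")

#: Study conditions for the whisking scenarios (chosen once; exposed via
#: config overrides).  Angular-velocity offset is 20% of the low-regime
#: rate and held fixed across regimes; phase noise sigma matches between
#: the two oscillators; perturbations kick the whisker phase by pi/2.
WR_DURATION = 30.0
WR_OMEGA_0 = 0.4 * math.pi
WR_SIGMA = 0.1
WR_COUPLING = 15.0
WR_PERTURBATION_TIMES = (6.0, 24.0)
WR_PERTURBATION_DELTA = 0.5 * math.pi

LOCO_DURATION = 40.0
LOCO_SIGMA = 0.1
LOCO_K_INTR = 0.75
LOCO_K_CB = 20.0
LOCO_INIT_JITTER = 0.1
#: the locomotion transient is the gait reorganisation itself, slower than
#: the whisk-scenario filter transient
LOCO_TRANSIENT_FRACTION = 0.5


class UsageError(TypeError):
    """A metric was applied to the wrong kind of trace."""


@dataclass(frozen=True)
class StrideEnsemble:
    """Per-stride curves resampled to a common stride-phase grid.

    ``curves`` maps output names to (n_strides, n_grid) arrays;
    ``phase_grid`` spans one full front-right stride cycle in [0, 2*pi).
    """

    phase_grid: np.ndarray
    curves: dict
    n_strides: int

    def mean(self, name: str) -> np.ndarray:
        return self.curves[name].mean(axis=0)

    def std(self, name: str) -> np.ndarray:
        return self.curves[name].std(axis=0)


@dataclass(frozen=True)
class ScenarioResult:
    trace: SimulationTrace
    metrics: dict
    scenario_id: str
    condition_labels: dict
    stride_ensemble: StrideEnsemble = None


def _require_wr(trace: SimulationTrace):
    if "w" not in trace.outputs or "r" not in trace.outputs:
        raise UsageError(
            "this metric needs a whisking-respiration trace with outputs w and r"
        )


def abs_difference_trace(trace: SimulationTrace) -> np.ndarray:
    """|w(t) - r(t)| per step: the instantaneous whisking-respiration
    discoordination."""
    _require_wr(trace)
    return np.abs(trace.outputs["w"] - trace.outputs["r"])


def sync_manifold_distance(trace: SimulationTrace) -> np.ndarray:
    """Perpendicular distance of (w, r) to the synchronisation manifold
    w = r, i.e. |w - r| / sqrt(2)."""
    return abs_difference_trace(trace) / math.sqrt(2.0)


def phase_locking_stats(
    trace: SimulationTrace, pair: tuple[str, str], post_transient: bool = True
) -> tuple[float, float]:
    """Circular mean and mean resultant length of a wrapped phase difference.

    ``pair`` names two oscillators of the trace (e.g. ``("fr", "hl")``).
    A concentration (mean resultant length) near 1 indicates tight phase
    locking; near 0, no consistent phase relation.
    """
    for key in pair:
        if key not in trace.phases:
            raise UsageError(
                f"unknown oscillator {key!r}; trace has {sorted(trace.phases)}"
            )
    a, b = (trace.phases_unwrapped[k] for k in pair)
    d = a - b
    if post_transient:
        d = d[trace.post_transient()]
    z = np.exp(1j * d).mean()
    return float(np.angle(z)), float(np.abs(z))


def stride_average(
    trace: SimulationTrace, n_strides: int = 14, n_grid: int = 100
) -> StrideEnsemble:
    """Stride-triggered average of limb and tail displacement.

    Strides are segmented at upward crossings of the front-right phase
    through 0 (mod 2*pi), starting after the transient window; each
    stride is resampled onto a fixed ``n_grid``-point phase grid.  Raises
    a data error if fewer than ``n_strides`` complete strides exist.
    """
    if "l_fr" not in trace.outputs:
        raise UsageError("stride_average needs a locomotion trace")
    phi = trace.phases_unwrapped["fr"]
    mask = trace.post_transient()
    start_idx = int(np.argmax(mask))
    # upward crossings of multiples of 2*pi
    cycles = np.floor(phi / (2.0 * math.pi))
    crossings = np.nonzero(np.diff(cycles) > 0)[0] + 1
    crossings = crossings[crossings >= start_idx]
    available = len(crossings) - 1
    if available < n_strides:
        raise ValueError(
            f"insufficient strides: requested {n_strides}, trace contains "
            f"{max(available, 0)} complete post-transient strides"
        )
    grid = np.linspace(0.0, 2.0 * math.pi, n_grid, endpoint=False)
    names = [k for k in trace.outputs if k.startswith("l_")] + ["t"]
    curves = {name: np.empty((n_strides, n_grid)) for name in names}
    for s in range(n_strides):
        i0, i1 = crossings[s], crossings[s + 1]
        # the stride coordinate is the true front-right phase within the
        # cycle, so identical strides resample identically regardless of
        # where the sampling grid happens to fall
        seg_phase = phi[i0:i1] - 2.0 * math.pi * cycles[i0]
        order = np.argsort(seg_phase)
        for name in names:
            seg = trace.outputs[name][i0:i1]
            curves[name][s] = np.interp(
                grid, seg_phase[order], seg[order], period=2.0 * math.pi
            )
    return StrideEnsemble(phase_grid=grid, curves=curves, n_strides=n_strides)


def tail_symmetry_index(ensemble: StrideEnsemble) -> float:
    """Symmetry of the stride-averaged tail curve about its half-cycle
    reflection: 1 - ||t(theta+pi) + t(theta)|| / (2 ||t|| + eps).

    A tail that retraces its excursion with opposite sign half a stride
    later (as when the two limb pairs alternate symmetrically) scores
    near 1; an irregular tail scores lower.  An implementation construct:
    the underlying observation is only qualitative (symmetric vs not).
    """
    t = ensemble.mean("t")
    t = t - t.mean()
    half = len(t) // 2
    reflected = np.roll(t, half)
    num = float(np.linalg.norm(t + reflected))
    den = 2.0 * float(np.linalg.norm(t)) + 1e-12
    return 1.0 - num / den


def _wr_config(condition: str, contextualise: bool, seed: int, **overrides):
    if condition not in WR_CONDITIONS:
        raise ConfigurationError(
            f"unknown condition {condition!r}; expected one of {WR_CONDITIONS}"
        )
    duration = overrides.pop("duration", WR_DURATION)
    sigma = WR_SIGMA if condition in ("offset_noise", "perturbation") else 0.0
    perturbations = ()
    if condition == "perturbation":
        perturbations = tuple(
            PhasePerturbation(time=t, target="w", delta_phi=WR_PERTURBATION_DELTA)
            for t in WR_PERTURBATION_TIMES
        )
    process = WhiskRespState(
        k=overrides.pop("k", WR_COUPLING),
        sigma_w=overrides.pop("sigma_w", sigma),
        sigma_r=overrides.pop("sigma_r", sigma),
    )
    schedule = overrides.pop(
        "regime_schedule",
        default_regime_schedule(duration, omega_0=overrides.pop("omega_0", WR_OMEGA_0)),
    )
    return SimulationConfig(
        scenario=WHISK_RESP,
        duration=duration,
        seed=seed,
        contextualise=contextualise,
        process=process,
        regime_schedule=schedule,
        perturbations=perturbations,
        **overrides,
    )


def _wr_metrics(trace: SimulationTrace) -> dict:
    d = abs_difference_trace(trace)
    post = trace.post_transient()
    whisking = trace.alpha > 0
    metrics = {
        "peak_abs_diff": float(d.max()),
        "post_transient_max_abs_diff": float(d[post].max()),
        "post_transient_whisking_max_abs_diff": float(d[post & whisking].max()),
        "mean_manifold_distance": float(sync_manifold_distance(trace)[post].mean()),
        "mean_tracking_error": float(
            np.mean(np.abs(trace.mu_x - trace.y)[post])
        ),
    }
    return metrics


def scenario_wr(
    condition: str, contextualise: bool, seed: int, **overrides
) -> ScenarioResult:
    """Run one whisking–respiration condition and compute its metrics."""
    config = _wr_config(condition, contextualise, seed, **overrides)
    trace = run_coupled_simulation(config)
    return ScenarioResult(
        trace=trace,
        metrics=_wr_metrics(trace),
        scenario_id=f"wr-{condition.replace('_', '-')}",
        condition_labels={
            "condition": condition,
            "contextualise": contextualise,
            "seed": seed,
        },
    )


def scenario_wr_suspension(
    seed: int, suspend_from: float = 21.0, **overrides
) -> ScenarioResult:
    """Offset + noise run in which CN output is suspended from
    ``suspend_from`` until the end while estimation continues.

    Adds window statistics comparing the suspended window with the
    active window of equal length that precedes it.
    """
    duration = overrides.pop("duration", WR_DURATION)
    config = _wr_config(
        "offset_noise",
        True,
        seed,
        duration=duration,
        cn_active_schedule=((0.0, suspend_from),),
        **overrides,
    )
    trace = run_coupled_simulation(config)
    metrics = _wr_metrics(trace)
    window = duration - suspend_from
    sus = (trace.time >= suspend_from)
    act = (trace.time >= suspend_from - window) & ~sus
    metrics.update(
        {
            "mu_v_std_active_window": float(trace.mu_v[act].std(axis=0).mean()),
            "mu_v_std_suspended_window": float(trace.mu_v[sus].std(axis=0).mean()),
            "tracking_error_active": float(np.mean(np.abs(trace.mu_x - trace.y)[act])),
            "tracking_error_suspended": float(
                np.mean(np.abs(trace.mu_x - trace.y)[sus])
            ),
        }
    )
    return ScenarioResult(
        trace=trace,
        metrics=metrics,
        scenario_id="wr-suspension",
        condition_labels={"condition": "offset_noise", "suspend_from": suspend_from,
                          "contextualise": True, "seed": seed},
    )


def scenario_locomotion(
    contextualise: bool, seed: int, n_strides: int = 14, **overrides
) -> ScenarioResult:
    """Run the four-limb + tail locomotion scenario.

    Limbs start from the intrinsic walking pattern (the acerebellar
    default gait) with a small seeded jitter; with contextualisation the
    cerebellar pattern reorganises them into the trot-like pairing.
    """
    duration = overrides.pop("duration", LOCO_DURATION)
    sigma = overrides.pop("sigma", LOCO_SIGMA)
    process = QuadrupedState(
        phi_fr=0.0,
        phi_fl=LIMB_OFFSETS["fl"],
        phi_hr=LIMB_OFFSETS["hr"],
        phi_hl=LIMB_OFFSETS["hl"],
        k_intr=overrides.pop("k_intr", LOCO_K_INTR),
        k_cb=overrides.pop("k_cb", LOCO_K_CB),
        sigma_fr=sigma,
        sigma_fl=sigma,
        sigma_hr=sigma,
        sigma_hl=sigma,
    )
    config = SimulationConfig(
        scenario=LOCOMOTION,
        duration=duration,
        seed=seed,
        contextualise=contextualise,
        process=process,
        init_phase_jitter=overrides.pop("init_phase_jitter", LOCO_INIT_JITTER),
        transient_fraction=overrides.pop(
            "transient_fraction", LOCO_TRANSIENT_FRACTION
        ),
        **overrides,
    )
    trace = run_coupled_simulation(config)
    pairs = {
        "fr_hl": ("fr", "hl"),
        "fl_hr": ("fl", "hr"),
        "fr_fl": ("fr", "fl"),
        "fr_hr": ("fr", "hr"),
    }
    metrics = {}
    for label, pair in pairs.items():
        mean, conc = phase_locking_stats(trace, pair)
        metrics[f"phase_diff_mean_{label}"] = mean
        metrics[f"phase_locking_{label}"] = conc
    ensemble = stride_average(trace, n_strides=n_strides)
    metrics["tail_symmetry_index"] = tail_symmetry_index(ensemble)
    metrics["n_strides"] = n_strides
    return ScenarioResult(
        trace=trace,
        metrics=metrics,
        scenario_id="locomotion",
        condition_labels={"contextualise": contextualise, "seed": seed},
        stride_ensemble=ensemble,
    )
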