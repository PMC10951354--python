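# Methods

## Model overview

`cerebsim` couples two components in a closed loop at a single rate:

1. **A cerebellar filter** — a gradient-descent (variational
   free-energy) filter over a linear state-space generative model with
   first-order generalised motion.  Beliefs are the expectations μ_x
   (hidden states), μ_x′ (their expected velocity) and μ_v (hidden
   causes / control states).  The flow prior is a leak plus a learned
   control mapping, f(x, v) = −x + θ_f v; the observation mapping θ_g is
   the identity in both shipped scenarios.  Only means are propagated:
   under the Laplace assumption the posterior variances are analytic
   functions of the means and are not separately integrated.

2. **A generative process** — stochastic Kuramoto phase oscillators
   producing the somatic outputs (whisker position, rib-cage expansion,
   limb vertical displacement, tail).  Oscillators are never coupled to
   each other directly (except the fixed intrinsic gait couplings of the
   locomotion process); each phase is attracted to the cerebellar
   estimate of its own state, `k·sin(x_est − φ)`.

Per step: regime parameters and any perturbation events are applied;
the process advances one Euler–Maruyama step using the current
estimates (or with the coupling gain zeroed when cerebellar-nuclei
output is suspended); the new observation is formed; the filter
advances one explicit Euler recognition step; everything is recorded.

## What the filter observes: the co-rotating frame

The somatic state conveyed to the filter is the oscillator phase
measured relative to the rhythm commanded by the current behavioural
regime: y_i = φ_i(unwrapped) − Φ_ref, with Φ̇_ref = ω_regime.  The
descending estimate entering the process coupling is correspondingly
x_i = μ_x,i + Φ_ref.  Three reasons drive this choice:

- **Dimensional consistency.**  The process coupling `k·sin(x − φ)`
  compares x with a phase; only a phase-valued estimate makes this term
  meaningful for all φ.

- **The amplitude-valued alternative cannot coordinate.**  If the
  filter observes the sinusoidal outputs directly, a transfer-function
  analysis of the recognition dynamics shows that the velocity belief
  μ_x′ absorbs the flow prior: at the oscillation frequency, the
  "differential" channel (the anti-synchrony direction that a patterned
  θ_f leaves without a cause of its own) is tracked with essentially
  the same gain as the common channel, for every setting of the rate
  constants and precisions.  The descending estimates then carry no
  synchronising pressure.  Worse, an amplitude-valued x ∈ [−1, 1]
  inside `k·sin(x − φ)` contributes a static pull toward φ ≈ 0 (the
  J₀ Fourier component), so gains large enough to matter freeze the
  oscillator instead of coordinating it.  Both effects were confirmed
  numerically over wide parameter sweeps.  The amplitude pathway is
  retained (`observation: "amplitude"`) for study, but no scenario uses
  it.

- **The frame makes the linear model meaningful.**  In the co-rotating
  frame the leak prior reads "phase misalignments decay to zero unless
  a learned context sustains them".  A patterned θ_f gives the common
  (coordinated) combination of misalignments a free cause — the cause
  integrates whatever the rhythm does — while denying one to the
  off-pattern combinations, which the filter therefore refuses to fully
  explain; the persistent prediction error flows down the coupling and
  drags behaviour back onto the coordination manifold.  With θ_f = I
  every channel has its own cause, every misalignment is absorbed, the
  residual vanishes, and the cerebellum exerts no pressure — the naive
  filter is a passive observer, as it should be.

Wrapped phases are stored in the oscillator states; the engine
accumulates unwrapped phases from per-step increments (all increments
are far below π per step, so wrapping is invertible), and perturbation
jumps are added to the accumulator explicitly.

## Parameters

All defaults are package choices, fixed before the validation runs and
exposed in the configuration.

| parameter | default | units | rationale |
|---|---|---|---|
| dt | 0.002 | time | ≥200 filter steps per oscillator cycle at the fastest regime (ω = 4π); explicit Euler stable for all rate products used |
| Π_z, Π_w | I | 1/a.u.² | equal trust in sensory input and flow prior |
| Π_v | 1e-6·I | 1/a.u.² | noninformative cause prior; larger leaks bias steady-state limb offsets by ~0.3 rad through the residual they leave in ε_x |
| κ_x | 5 | 1/time | sets differential-channel attenuation 1/(κ_x+1); also bounds the estimate's lag behind drifting inputs (≈ drift rate / κ_x) |
| κ_x′ | 0.5 | 1/time | small relative to κ_v so the velocity belief is not slowly corrupted while the cause integrator absorbs ramps |
| κ_v | 50 | 1/time | fast cause absorption (integral action) relative to every behavioural timescale |
| k (whisk) | 15 | 1/time | locks the offset condition at Δφ* ≈ ω₀(κ_x+1)/k ≈ 0.5 rad; k/κ_x = 3 keeps the naive condition's drift fast enough to sweep antiphase repeatedly |
| ω low / high | 2π / 4π | rad/time | locomotor whisking vs sniffing regimes; periods O(1) |
| ω₀ | 0.4π | rad/time | 20% offset of the low rate, held fixed across regimes |
| σ (phase noise) | 0.1 | rad/√time | visible jitter without masking the deterministic structure |
| regime schedule | 0–40% low, 40–50% no-whisk, 50–100% high | — | a brief whisking stop between locomotor whisking and object exploration |
| perturbations | +π/2 on φ_w at t = 6, 24 | rad | one kick per whisking regime |
| k_intr / k_cb (locomotion) | 0.75 / 20 | 1/time | the ratio sets the trot compromise (within-pair offset ≈ k_intr/k_cb·(κ_x+1)·π/2 ≈ 0.2 rad, comfortably inside the 0.3 rad locking check) while k_cb/(κ_x+1) ≫ k_intr makes cerebellar pressure dominate |
| initial beliefs | μ_x = y(0), μ_x′ = 0, μ_v = θ_f⁺(μ_x′+μ_x) | — | flow-consistent start; beginning at μ = 0 injects a spurious k-scaled kick when the process starts away from zero phase |
| locomotion start | walk offsets + 0.1 rad jitter | rad | the acerebellar default gait; an all-equal start sits exactly on the front-left limb's unstable antipodal equilibrium, and uniform-random starts fall into spurious compromise attractors |
| transient fraction | 0.2 (whisk), 0.5 (locomotion) | — | the locomotion transient is the walk→trot reorganisation itself |
| divergence bound | 1e6 | a.u. | belief magnitudes beyond this raise an instability error carrying the partial trace |

Whisk runs last 30 time units (42 whisking cycles), locomotion runs 40
(40 strides, 20 post-transient; stride averages use 14).  These sizes
were chosen to give every phase relation several full relative cycles
to express itself.

## What the process emulates — and what it does not

The Kuramoto processes stand in for extra-cerebellar pattern
generators: they produce self-sustained rhythms with state-dependent
rate and amplitude gating, independent phase noise per oscillator, and
(for locomotion) a fixed intrinsic gait.  They do not model
biomechanics, proprioceptive reflex loops, transport delays, or the
internal inference of those extra-cerebellar circuits; a passing test
therefore says the *coordination logic* behaves as described, not that
any quantity matches physiological recordings.  Somatic outputs are
unit sines, so "a.u." difference bounds (2 = full antiphase range,
1 = half) are properties of the output convention as much as of the
dynamics.

The two tail gaits deserve a caveat: because the front-left limb's
intrinsic target is exact antiphase to the front-right, the tail (the
sum of the two front limbs) is near-cancelling in *both* gaits; the
tail symmetry index consequently compares two small-amplitude curves
and is reported as a qualitative, seed-averaged contrast only.

## Numerical choices

- Explicit Euler for the recognition flow, Euler–Maruyama for the
  phases, one filter step per process step, no delays.
- Each oscillator draws noise from its own child of the run's seed
  (`SeedSequence.spawn`), so zeroing one noise source leaves the other
  streams bit-identical, and traces are reproducible bit-for-bit from
  (config, seed).
- Stride segmentation uses upward crossings of the front-right phase
  through multiples of 2π, and resamples on the *true* within-cycle
  phase, so identical strides resample identically regardless of where
  the sampling grid falls.
- Precision matrices are validated by Cholesky; belief vectors are
  checked finite at construction; dt ≤ 0, overlapping CN schedules,
  unknown oscillator targets and mismatched shapes are configuration
  errors.
- CSV traces are written with 17 significant digits and read back with
  the round-trip float parser, so serialisation is lossless.

## Known limitations

- **Suspension shrinks tracking, not cause variability.**  During CN
  suspension the filter keeps estimating while its output no longer
  constrains behaviour.  In this implementation the estimates then
  *lag* the desynchronising rhythms (the tracking error grows roughly
  twenty-fold), but the cause estimate μ_v *integrates* the uncorrected
  common drift, so its standard deviation in a suspended window is
  higher, not lower, than in the preceding active window.  A shrinking
  cause amplitude under desynchronisation is a signature of
  amplitude-coded causes (antiphase sensory streams cancel in a shared
  cause), and that coding cannot synchronise the loop in the first
  place (see the observation-pathway analysis above); within this model
  the two phenomena appear to be mutually exclusive.  The suspension
  scenario reports both window statistics so the behaviour is visible
  rather than hidden.
- Learning of θ_f (climbing-fibre plasticity), explicit action
  dynamics, nonlinear observation/flow mappings and higher-order
  generalised motion are out of scope; θ_f is fixed per run.
- The no-whisk regime caps |w − r| at |r| ≤ 1 by construction, so the
  coordinated condition's post-transient maximum sits just below 1
  whenever the schedule contains a whisking stop; the
  whisking-active maximum (≈0.5) is reported alongside it.
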