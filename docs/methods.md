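# Model and methods

## The model

Developing retina produces spontaneous, propagating depolarisations
("stage II" or cholinergic retinal waves) in the starburst amacrine cell
(SAC) layer.  `retinawave` models the SAC sheet as a two-dimensional
stochastic excitable medium with four fields:

* `v(x, t)` — membrane potential (mV),
* `r(x, t)` — the Morris–Lecar potassium gate, which doubles as the fast
  refractory variable,
* `s(x, t)` — slow after-hyperpolarisation (sAHP) activation, the
  tens-of-seconds refractory mosaic,
* `a(x, t)` — extracellular acetylcholine concentration (nM), the only
  field that diffuses; it carries all lateral excitation.

The local kinetics are Morris–Lecar with two additions — a saturating
nicotinic conductance driven by `a`, and the sAHP pathway driven through
`r`:

```
C dv/dt = − g_L (v − E_L) − g_Ca m∞(v)(v − E_Ca) − g_K r (v − E_K)
          − g_ACh a²/(K² + a²) (v − E_ACh) + I_noise + I_ext
dr/dt  = ( r∞(v) + κ s − r ) / τ_r(v)
ds/dt  = σ_s(v) (1 − s)/τ_R − s/τ_S
da/dt  = β σ_rel(v)² − a/τ_a + D ∇²a
```

with `m∞, r∞` tanh sigmoids, `τ_r(v)` the canonical 1/cosh gate time
(0.2 s scale), `σ_s` and `σ_rel` logistic gates with midpoint −40 mV and
steepness 0.2 mV⁻¹.  The squared release gate expresses the cooperativity
of calcium-triggered transmitter release; its practical effect is a
release onset near −55 mV with a negligible tail at rest.  The noise term
is a Bernoulli conductance: every 10 ms each cell independently opens a
3 nS excitatory channel with probability `rate × 10 ms`.

The sAHP enters as an additive term `κ s` in the r-gate target.  With the
default κ = 12 and s reaching ~0.2 after a burst, the target transiently
exceeds 1; we therefore read `r` as a refractory *drive* (gate fraction ×
effective channel multiplicity) rather than a strict open fraction, and the
invariant kept under forward integration is `r ≥ 0`.

### Parameter identification

The parameter registry (units: mV, nS, nF, nM, s, mm) is the package's
single source of defaults.  Several constants could only be fixed up to a
convention (which sigmoid a half-activation belongs to, tanh width versus
half-width, which reversal the synaptic conductance uses).  The ambiguous
entries were resolved by requiring, simultaneously:

1. a stable hyperpolarised rest state near −80 mV that persists when the
   sAHP is removed (`s = 0`), with a saddle and a depolarised excited state
   above it (the fast subsystem must be bistable for front analysis);
2. single noise-channel openings that stay below the −60 mV analysis
   threshold, while clusters of openings within ~2 s can ignite a burst —
   this is what makes isolated cells fire about once per 15 minutes while
   keeping the activity raster clean;
3. planar fronts through rested tissue near 0.1–0.15 mm/s, and front
   blockage at elevated `s`;
4. a single bursting cell able to recruit its neighbours through the ACh
   field (wave initiation from one cell), which couples the diffusion
   coefficient, the release rate and the clearance time: the local ACh
   plume a single cell can raise scales as `β dx²/D`, and it must both
   exceed an appreciable fraction of the receptor `K` = 800 nM and outlive
   the one-cell diffusion time `dx²/D`.

Requirement 4 fixes `D` = 0.001 mm²/s (an *effective* diffusivity — the
coupling stands in for dense recurrent connectivity, not literal Brownian
transport) and a clearance time of ~2 s; requirement 3 then lands the
front speed at 0.15 mm/s without further adjustment.  The Bernoulli rate
(2.6 s⁻¹) is calibrated so that the isolated-cell inter-event interval is
~15 minutes (`simulator.calibrate_noise_rate` automates this).

## Numerics

Operator splitting at a fixed `dt` = 1 ms: the reaction terms advance with
an explicit two-stage Runge–Kutta (Heun) step, the ACh diffusion with a
locally one-dimensional Crank–Nicolson step (tridiagonal solves along x
then y, sweep order alternating each step to cancel directional bias).
Boundaries are zero-flux, which conserves ACh mass to rounding error; the
analysis pipeline excludes a 5-cell boundary margin regardless.  The grid
is 64×64 over a 2 mm square (≈ one SAC per 31 µm cell).  Identical seeds
give bit-identical snapshot series.

Degenerate inputs: `D = 0` reduces every cell to the single-cell ODE (the
decoupled-limit test holds the grid integrator to 1e-6 of a reference
adaptive solver over 100 s); a uniform field is an exact fixed point of
the diffusion step; negative concentrations are clamped at zero after each
substep (the clamp never activates beyond rounding in normal runs).

## Front analysis

`s` is 300–11 000 times slower than the membrane scale (C/g_K = 5.3 ms),
so propagation is analysed in the *fast subsystem*: (v, r, a) with `s`
frozen.  Two independent routes compute the signed front speed c(s):

* **relaxation** — integrate the 1-D fast subsystem from a sigmoid initial
  front and fit the level-set position (midpoint between rest and excited
  v; the level choice does not affect the asymptotic speed) against time;
* **moving-frame Newton solve** — the stationary profile equations in the
  co-moving frame (first order in v and r via upwind differences, second
  order in a) with the speed as an extra unknown and a phase condition
  pinning the voltage midpoint; solved by damped Newton with a sparse
  banded Jacobian, seeded by the relaxation profile.  (A collocation
  boundary-value solver was tried first and could not hold the 5–10 µm
  front on a mm-scale truncation; the upwind Newton formulation shares the
  relaxation run's spatial operators but finds the profile and speed as a
  root, not as a time-asymptotic state.)

The two agree to a few percent across the propagating range of s; the
Newton residual converges to ~1e-6 (the finite-difference Jacobian floor).
c(s) is monotone decreasing; its root s\* is the propagation threshold and
feeds two derived results: the absolute refractory period (time for a
bursting cell's s(t) to decay back below s\*, ≈ τ_S log(s₀/s\*)) and the
excitability threshold map over the (g_K, g_ACh) plane, computed by
bisection on the relaxation speed.  Excitability is confirmed by direct
noise-free tissue simulation: excite a strip (or a point — both give the
same verdict) and test whether suprathreshold activity reaches the far
side of the domain within 10 s.

## Wave statistics

Snapshots every 10 ms; cells with `v > −60 mV` are active (the −55 mV
release threshold is available as an alternative); a 5-cell margin is
excluded.  Waves are spatiotemporal connected components (in-plane
4-neighbourhood, overlap-or-4-neighbourhood between consecutive frames;
8-neighbourhood available as a toggle).  A wave's size is its distinct
cell count, its duration first-to-last active snapshot.  Initiation points
are clusters of onset cells (active cells with no active spatiotemporal
predecessor); more than one cluster marks a collision.  Wave speed follows
the backward-tracing construction: from the most distal active point at
the final snapshot, hop backward in 0.5 s steps to the nearest active
member point, building the front polyline; the mean speed is the linear-fit
slope of distance-to-initiation against time along that trajectory (robust
to lattice quantisation; calibrated to <4% error on programmed disk waves),
and the maximum front speed is the fastest hop.  Collisions and waves under 50 cells or 1 s are excluded
from speed statistics.  Inter-wave intervals are per-cell times between
activity onsets, with onsets closer than 2 s merged.

The event population is deliberately a mixture: brief sub-burst threshold
crossings from noise-channel clusters (single cells, tens of ms) and true
propagating waves (tens to thousands of cells, seconds).  The reported
means over "all waves" average over this mixture — that is what makes the
mean duration sub-second while individual recruited bursts last longer.

## Forest-fire mapping

The Drossel–Schwabl lattice (tree/burning/empty; lightning f, regrowth p,
4-neighbour spread) is implemented in two variants: per-step spread (one
neighbour ring per step — the variant that mirrors the finite wave-front
speed) and instantaneous cluster burn (the classical model, used for
cross-checks against an independent implementation).  The retina → (p, f)
map rescales time by one burst duration and space by the elementary
excited patch (wave speed × burst duration):

```
p = burst_duration / refractory_period
f = per-cell rate × burst_duration × cells per lattice point
```

The self-organised-criticality predicate requires a double separation of
scales: p/f above ~100 (many regrowths per strike) while the characteristic
fire scale sqrt(p/f) stays below a quarter of the lattice side.  Avalanche
size distributions are compared by log-binned least-squares slopes with a
maximum-likelihood (Hill) exponent as cross-check; a negative quadratic
log-log coefficient below −0.25 flags faster-than-power-law (sub-critical)
decay.

## Synthetic fixtures

The analysis pipeline is calibrated on programmed inputs with closed-form
ground truth: expanding disk waves of known radial speed and per-cell
burst duration (single source, or two sources timed to collide), pure
power-law and exponential size samples (inverse-CDF), and spatially
independent Gaussian voltage noise for the correlation null.  Fixtures
emit the standard snapshot container, so every analysis entry point runs
unmodified on them.

## Problem sizes

Default test and reproduction runs use a 64×64 grid with 200 s warmup and
300–500 s of recorded time (the reference configuration in the source
material ran 2500–5000 s); isolated-cell statistics pool several
2500–3000 s single-cell runs; front analyses use 512-point 1-D domains of
8 mm.  These sizes keep full reproduction runs in the tens of minutes on
one CPU while leaving hundreds of waves and thousands of inter-wave
intervals per run.

## Calibration status

With the frozen defaults the package reproduces (at desk scale) the front
speed through rested tissue (~0.15 mm/s analysis, ~0.10 mm/s measured over
waves), the isolated-cell spontaneous interval (~14 min), the mean wave
size and duration, and an absolute refractory period of a few tens of
seconds.  Two rate statistics remain ~2–2.5× slower than the reference
values: the per-cell inter-wave interval (~120 s vs ~49 s) and the
multi-cell wave initiation interval (~150 s vs ~60 s).  In this
reconstruction the isolated-cell rate, the threshold-crossing rate and the
in-tissue ignition rate are all controlled by the same noise-channel and
cooperativity constants, and no reading of the ambiguous source constants
was found that satisfies all three at once; the isolated-cell anchor was
kept and the residual gap is documented rather than hidden.

## Known limitations

* The equations were reconstructed from a partially legible source (all
  equation images unavailable); the registry documents every convention
  chosen, and the identification constraints above are the authority for
  the ambiguous entries.  Absolute agreement of every headline statistic
  with the reference values is therefore approximate.
* No directional drift term: waves have no directional bias by
  construction.
* Homogeneous parameters: no cell-to-cell variability; the refractory
  mosaic arises purely from activity history and noise.
* The noise channel is binary (open/closed) with a single conductance;
  channel-number fluctuations are not modelled.
* The forest-fire comparison treats criticality phenomenologically;
  finite-size scaling collapse and the asymptotic-criticality debate are
  out of scope.
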