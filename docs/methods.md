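# Methods

This note documents the models, parameters and numerical choices behind
`mucoswim`, and what the synthetic experiments do and do not show about
real microparticle propulsion in mucus.

## Field model

The drive field is the superposition of a rotating component of amplitude
`B_r = β f` circling in the plane normal to the heading vector
`n(θ) = (−cos θ, sin θ, 0)` and a static component `B_s n`. The heading
convention (`θ = 0` points along −x) is used identically by the field
model, the propulsion simulator and the controller, so no sign
translations occur between modules. All angles are wrapped to (−π, π].

Two exact identities follow and are enforced as invariants: the total
field magnitude is constant (`|B|² = B_s² + B_r²`) and the projection of
the field onto the heading vector equals `B_s` at all times.

A configurable rotating-amplitude cap (default 10 mT) rejects protocols
outside the drive envelope; the three standard sweep protocols peak at
9.5, 8.75 and 10 mT and are exactly admitted. The cap abstracts the
voltage limit of a physical coil driver without modelling hardware.

Note on units: one published protocol annotation implies a ~16 mT
amplitude at β = 0.5, f = 15 Hz, which is inconsistent with `B_r = β f`
(7.5 mT). The definition `B_r = β f` is taken as normative throughout.

## Propulsion model

No constitutive law for spontaneous-symmetry-breaking propulsion in mucus
is established; the simulator uses a phenomenological law chosen as the
simplest family that reproduces every qualitative regime of interest:

```
U = c · ⟨f_rot⟩(f, f_c(β)) · g(B_s) · bump(β) · m(x, y) · (1 + ε)
```

* `⟨f_rot⟩` is the time-averaged rotation rate of an overdamped driven
  rotor: `f` below the step-out frequency `f_c`, `f − √(f² − f_c²)`
  above it. This is the classical average of `dφ/dt = ω_c sin(ωt − φ)`
  and is verified in the tests against direct integration of that ODE
  (the oracle integrates over an integer number of slip periods, making
  the asynchronous average exact up to solver tolerance).
* `f_c(β) = f_c0 (β/β_ref)^p` with `β_ref = 0.5`. Because `B_r = βf`, a
  naive torque balance would make synchrony frequency-independent; the
  exponent `p` is the minimal lever that lets presets place the step-out
  transition where each regime needs it (e.g. ≈61 Hz at β = 0.1 for the
  10–100 Hz protocol, producing a linear region up to ~50 Hz and
  diminishing velocity beyond).
* `g(B_s) = 1 + g_shape·|B_s|` is an even shaping with `g(0) = 1`; for
  the mucoadhesive coatings (PEG, chitosan) the presets give it a larger
  coefficient, reproducing increased velocity near the static-field
  extremes. Whether the true response is non-monotonic per coating is
  left to presets; no mechanism is asserted.
* `bump(β)` is an optional Gaussian enhancement centred in 1/β
  (default off). It phenomenologically encodes the resonance-like
  velocity spike near 1/β ≈ 3 observed for chitosan- and biotin-coated
  particles; no physical mechanism is modelled or claimed. Without it a
  fixed-frequency β-sweep under this law can only be flat-then-falling,
  never the observed rise-then-fall.
* `m(x, y)` is a unit-mean, spatially correlated lognormal mobility
  multiplier standing in for heterogeneous mucin concentration.
* `ε ~ N(0, σ_U)`, truncated at −0.9, is per-step multiplicative speed
  noise. Trial-to-trial variability therefore comes from both noise and
  each particle's local mucus environment.

The propulsion *sign* carries the entire direction reversal between the
two propulsion states: it is drawn uniformly from ±1 when `|B_s|` is at
or below a threshold `B_th` (default 0.1 mT) and equals `sign(B_s)`
above it. The dipole-tilt physics behind state selection is deliberately
abstracted into this threshold rule.

Motion integrates by forward Euler at the controller sample interval
(default 1/30 s), matching the experimental sampling; the dynamics are
non-stiff at these speeds (≤ ~25 µm/s) so Euler is adequate.

## Controller

`θ̇ = k α_d` with `α_d = ψ − θ` wrapped to the shortest arc, forward
Euler at `dt = 1/30 s`, `k = 5`. On an ideal plant the heading error
contracts by exactly `1 − k·dt = 5/6` per step; `k·dt ≥ 2` is
oscillatorily unstable and is asserted as a negative test. Manual target
switching by an operator is replaced by automatic capture at a radius
(default 3 µm). When the particle's propulsion sign is negative the
commanded bearing is flipped by π, since displacement is `s·n(θ)`. If the
position coincides with the target mid-step, the previous desired heading
is held to avoid an undefined bearing.

## Tracking and analysis

Frames are Otsu-thresholded (particle darker than background;
polarity configurable). Because Otsu degrades when the particle occupies
a tiny fraction of a noisy frame, a fallback threshold at the midpoint of
the background median and the extreme intensity is applied whenever the
foreground fraction exceeds 25%. The connected component nearest the
previous bounding box (largest, if none) is kept; the sub-pixel centroid
is the background-subtracted intensity-weighted mean over the component
dilated by 2 px, so anti-aliased edge pixels contribute. Pixel size is an
explicit input.

Velocities are finite differences between consecutive frames. Trajectory
velocity series are processed in a fixed order: (1) speeds above 3× the
pre-replacement mean are set to that mean (one-sided rule — speeds are
non-negative); (2) a centered 60-point moving average with truncated edge
windows (degenerate case: a window at least as long as the series yields
the global mean everywhere). The order and both steps are recorded as
flags on the series, and a series already flagged processed passes
through unchanged, making the operation idempotent on its own output.

Zero-intercept fits use `slope = Σ fU / Σ f²`; since conventions differ
for origin-constrained fits, R² is defined explicitly as
`1 − SS_res/SS_tot` with `SS_res` about the constrained line and `SS_tot`
about the mean of U (this can be negative when the line fits worse than
the mean, which is exactly what flags the step-out regime). Error bars
are standard errors, `sd/√n`, over pooled particle-trials; a single trial
reports SE = 0 with `n = 1` recorded.

## Synthetic data

The renderer draws an anti-aliased dark disk (radius 5 µm — a 10 µm
particle) on a bright background, default 256×256 px at 0.5 µm/px and
30 fps, with seeded Gaussian intensity noise. It emulates none of the
optics of real microscopy (no PSF, illumination gradients, defocus or
motion blur), so tracking tolerances demonstrated here (≤0.1 px noiseless,
≤0.5 px RMS at noise sd 0.05) bound performance on idealized, not real,
video.

The mucus field smooths white noise with a Gaussian kernel at the
requested correlation length (default 25 µm), restandardizes,
exponentiates with the lognormal σ that yields the requested coefficient
of variation (`σ = √ln(1+cv²)`, default cv 0.25), and rescales to sample
mean 1. It captures spatial heterogeneity of mobility only — not mucin
microstructure, viscoelastic anisotropy, or particle–fiber adhesion
dynamics.

Coating presets are versioned JSON data, not code constants. Published
velocity curves are plotted but not tabulated, so preset magnitudes are
invented; they are constrained only by the qualitative orderings bundled
alongside them (PEG fastest in the 1–19 Hz/β = 0.5 regime with biotin
slowest; chitosan fastest at ≥50 Hz in the 10–100 Hz/β = 0.1 regime;
chitosan non-monotone against 1/β at 14 Hz) and by the linear/step-out
structure of each regime. Passing the ordering checks shows the presets
encode those regimes consistently — it does not validate the magnitudes
against experiment.

Letter waypoint plans (A, R, S, M, U) are schematic vertex lists at
~50 µm extent; the experimental waypoint coordinates are unavailable.

## Experiment protocols and problem sizes

Per-trial velocity is the time-averaged x-velocity over a 10 s simulated
window at 30 Hz (the averaging window is this package's choice). Particle
counts default to the published ones per protocol (e.g. 9/9/10/7 for the
1–19 Hz sweep) with at least 3 trials each. The fixed-heading ensembles
are simulated vectorized over particles×trials. The β-sweep grid is
1/β ∈ [2, 10] in 0.5 steps (the published axis is 1/β without a tabulated
grid). Static sweeps draw the propulsion sign per trial and report signed
x-velocity. Ordering checks average over 20 independent seeds, each with
a fresh mucus field. Every run is bit-reproducible from (config, seed);
all sub-seeds derive from the run seed.

## Known limitations

* The propulsion law is phenomenological; no normal-stress fluid
  mechanics, 3D dipole dynamics, wall effects, particle interactions or
  sedimentation are modelled.
* Homogeneous-fluid, noise-free closed-loop navigation is essentially
  ideal; real operator-in-the-loop navigation contends with drift,
  imaging latency and identity loss that are out of scope here.
* The tracker manages a single particle; multi-particle identity
  management is not implemented.
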