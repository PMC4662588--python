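# Methods

## Model

The package simulates a chain of `n ≥ 2` passive damped harmonic
oscillators ("reeds") with displacements `x_j(t)`:

```
x_j'' + γ ω_j x_j' + ω_j² x_j = f₀ m_j sin(ωt)
                                + κ_{j-1,j}(x_{j-1} − x_j) + κ_{j,j+1}(x_{j+1} − x_j)
```

Assumptions baked into the model:

* **Passive and linear.** Damping is positive, coupling is real and
  non-negative, and there are no nonlinear terms. Every response scales
  linearly with `f₀`, superposition over forcing masks holds exactly, and
  the system matrix is symmetric, which implies reciprocity between any
  two reeds.
* **Oscillators are specified by frequency, not mass/stiffness.** Each
  reed is characterised directly by its natural frequency `f_j = ω_j/2π`
  and the shared damping ratio `γ` (so `Q = 1/γ` for an uncoupled reed).
* **Nearest-neighbour elastic coupling, free ends.** Coupling constants
  live on the `n−1` links; a missing link contributes no force, so the
  boundary condition is zero-flux. With uniform κ this reproduces the
  classic end terms `κ(x₂−x₁)` and `κ(x_{n−1}−x_n)`. Storing κ per link
  (rather than per reed) makes tapered boundary profiles unambiguous: the
  taper used in the boundary-condition experiment sets the outermost link
  to zero and ramps linearly over 10 links to the interior maximum,
  mirrored at both ends.
* **Parallel forcing by default.** All reeds receive the same force
  `f₀ sin ωt`; a forcing mask in [0,1] per reed restricts it (one-hot for
  the single-reed-drive experiment).

## Unit conventions for the coupling constant

κ has dimensions of (angular frequency)² and is stored in (rad/s)².
The two historical experiment families quote κ on different scales:

* the 21-reed bank (45–55 Hz) quotes κ in (rad/s)²: values of order
  10²–10³ are comparable with the per-link detuning
  `ω_{j+1}² − ω_j² ≈ 2ωΔω ≈ 2·10³ (rad/s)²`, which is the regime in which
  peak shifts, secondary peaks and multi-cycle lags appear;
* the 201-oscillator kilohertz banks quote κ in (rad/ms)² — the natural
  nondimensionalization when frequencies are expressed in kHz and time in
  ms. `bank.KAPPA_MS2 = 1e6` converts to SI. At kHz frequencies the
  per-link detuning is `≈ 3.5·10⁵ (rad/s)²`, so quoted values of
  200–1000 (rad/m s)² ≡ 2·10⁸–10⁹ (rad/s)² again put the coupling at
  0.5–3× the per-link detuning. Read literally in (rad/s)², those same
  numbers would be ~10⁻³ of the detuning and the chain would behave as
  uncoupled — none of the documented fine structure (ripples, plateaus,
  phase bands) would exist.

The ripple/plateau physics is controlled by the dimensionless ratio of κ
to the per-link detuning (the discrete chain with a linear gradient in
ω_j² is a Wannier–Stark-type problem), so this scaling is not cosmetic:
it selects the physical regime.

## Parameters

| parameter | default | meaning |
| --- | --- | --- |
| `γ` | 0.014 (21-reed), 0.025 (201-reed) | damping ratio; Q = 1/γ ≈ 70 resp. 40 |
| `gamma_for_kappa` | `3.37e-6·κ + 0.00553` | empirical co-variation of damping with coupling for the 21-reed bank (an elastic band supplies both); used by the coupling-sweep scenario |
| `f₀` | 1000 | forcing amplitude; arbitrary (linearity), kept for scale compatibility |
| Greenwood map | `F = 165.4 (10^{0.06 x} − 0.88)` Hz, x in mm from apex | standard human frequency–position fit; constants overridable via `GreenwoodMapParams`. 16.5–18.5 mm in 0.01 mm steps (one hair-cell width) gives 201 oscillators, ≈1.47–1.99 kHz in ≈2.5 Hz steps. The exponential map varies the step smoothly by about ±15% across the span |
| durations | 5 s (21-reed forced), 100 ms (201-reed forced), 50 ms (impulse) | long enough for the switch-on transient (envelope rate γω/2) to decay far below measurement level |
| solver | DOP853, rtol 1e-8, atol 1e-10 | high-order adaptive Runge–Kutta; the system is oscillatory, smooth and non-stiff at these Q values |
| output sampling | ≥40 samples per cycle of the fastest oscillation | dense enough for peak picking and envelope extraction |

## Two solution engines

1. **Time domain** (`timedomain`): the 2n-dimensional first-order system is
   integrated from rest (forced protocol) or from unit initial velocity on
   every reed with `f₀ = 0` (impulse protocol). For forced runs the output
   grid is made commensurate with the drive period (an integer number of
   samples per period).
2. **Frequency domain** (`phasor`): at steady state every reed oscillates
   at the drive frequency, so with the convention `x_j = Im(X_j e^{iωt})`
   the complex amplitudes solve a tridiagonal system
   `(ω_j² − ω² + iγω_jω + κ_L + κ_R) X_j − κ_L X_{j-1} − κ_R X_{j+1} = f₀ m_j`,
   solved with a banded LU (a dense path is retained as a cross-check).

The phasor solve is exact for this linear model and serves as the oracle
for the integrator: on randomized small banks the last-cycles amplitude
agrees within 1% and the phase within 0.005 cycles (test-enforced). The
test durations extend beyond 60 drive periods whenever the slowest
envelope time constant `2/(γω_min)` demands it, so the comparison is not
contaminated by residual transients.

## Measurement definitions

* **Steady-state amplitude** — the peak |x| over the last 3 drive cycles,
  refined by a parabolic fit around the maximum sample (accuracy ~1e-4
  relative at 40 samples/cycle; the amplitude measure is a peak, not an
  RMS).
* **Steady-state phase** — the argument of the single-bin discrete Fourier
  component at the drive frequency over a whole number of cycles; on the
  commensurate grid this is exact for a pure tone. Reported as lag in
  cycles behind the force, or re-referenced to the highest-frequency reed.
* **Phase unwrapping along the array** — adjacent differences are mapped
  to the asymmetric branch [−π/2, 3π/2). The lag of the traveling wave
  accumulates monotonically, and near amplitude minima it jumps by close
  to half a cycle per link, which a symmetric ±π branch would alias (for
  the strongly coupled 21-reed bank the symmetric unwrap reads 0.5 cycles
  total where the true accumulation is 2.5). The offset is configurable;
  0.5 recovers the conventional unwrap.
* **Peak detection** — local maxima of the log-magnitude profile with a
  prominence threshold in dB (default 1 dB for spectra, 0.5 dB for
  spatial ripples, which are shallow on a log scale); locations refined by
  a local quadratic fit through three samples; ties broken toward the
  lower axis value by ascending sort order. An optional floor discards
  peaks more than a given dB below the tallest.
* **Attenuation slopes** — with only one reed driven, straight-line fit of
  `20 log₁₀ amplitude` against `log₂ f_j` on each side, over the region
  5–30 dB below the peak. The window skips the top 5 dB (locally
  parabolic around the driven reed, which biases a log–log slope
  downward) and spans the next 25 dB. The high-frequency side steepens
  steadily with depth — the decay per link grows with detuning — so the
  quoted slope is tied to this window; deeper windows give systematically
  larger values.
* **Phase-band periodicity** — bands are delimited by amplitude minima
  (which coincide with the rapid phase transitions; test-enforced). Their
  spacing is widest next to the main peak and shrinks toward the apex, so
  the period is reported as the spacing of the two minima nearest the
  peak — the dominant bands of the pattern; the full minima list is
  available.
* **Impulse spectra** — magnitude FFT of the full record, no taper window
  (the records are transient-complete), zero-padded ×8 (a 50 ms record has
  20 Hz native resolution; padding plus quadratic interpolation resolves
  the ≈5% peak spacings). The headline spacing statistic is the ratio of
  the first two spectral peaks, averaged over mid-array reeds: the peak
  train compresses with frequency (≈1.06 first, ≈1.03 later), so the mean
  over *all* successive ratios would understate the leading spacing that
  characterises the beating.
* **Plateau clustering** — per reed, the frequency of the globally highest
  spectral peak (quadratic-interpolated); runs of ≥3 adjacent oscillators
  whose dominant frequencies agree within half the (padded) spectral grid
  step collapse into one plateau (min_run = 3 avoids single-oscillator
  "plateaus"). The low-frequency-end statistic averages adjacent-plateau
  ratios over the lowest third of the frequency span: the very first
  plateau abuts the free boundary and its ratio to the second (≈1.13)
  slightly overstates the typical low-end value (≈1.11).

## Degenerate inputs and edge cases

All-zero series yield empty peak sets; flat spectra yield NaN entries in
the dominant-frequency map; fewer than two detected minima or plateaus
raise informative errors rather than returning fabricated statistics.
Reeds that never enter the settling tolerance before the final period get
an infinite sentinel. `γ = 0` is accepted by the model but an exactly
resonant undamped solve raises a singular-matrix error.

## Fixture generator

`scenarios.generate_fixture_bank` draws small random banks (3–20 reeds,
40–60 Hz, κ up to 5000, γ in [0.005, 0.05]) from a seeded generator for
property tests and the engine cross-check. It emulates the *structure* of
the physical banks (graded frequencies, uniform-order coupling, positive
damping), not any particular instrument: real reed meters have machined
frequency ladders and a single elastic band whose coupling and damping
co-vary. Passing the cross-engine tests on these banks demonstrates the
correctness of the numerics over the parameter region the experiments
occupy; it says nothing about physical effects outside the model
(nonlinearity, activity, fluid coupling beyond nearest neighbours).

## Problem sizes

The test suite and the acceptance script run the experiments at their
native sizes: 21 and 201 oscillators, 5 s / 100 ms forced and 50 ms
impulse records, and a 601-point drive grid for the full response map
(the coarse `--scale` option of the scenario runner is a convenience, not
a requirement). The engine cross-check uses 50 randomized banks of up to
20 reeds.

## Known limitations

* The model is passive and linear by construction; active (negative
  damping) oscillators, complex-valued (dissipative) coupling and any
  otoacoustic interpretation are out of scope.
* Settling times depend strongly on the tolerance: at the 2% cycle-peak
  criterion the reeds sitting near response minima of the strongly coupled
  21-reed bank take up to ≈2.6 s to converge (their steady-state
  amplitudes are small, so a relative criterion is strict there), while a
  5–10% criterion — closer to a visual judgement of a transient plot —
  is met within about 2 s.
* dB/oct slopes and band periods are window- and threshold-dependent as
  described above; the defaults are fixed and recorded in every scenario's
  metadata.
* No eigenmode decomposition is exposed; the impulse spectra carry the
  modal information operationally.
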