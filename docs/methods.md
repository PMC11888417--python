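# Methods

Models, conventions, numerical choices, and known limitations of
`orgmodel`. Units throughout: time in seconds, rates in s⁻¹, optical path
length (OPL) in nanometres, phase in radians, power in watts, lengths of
optical apparatus in the units stated per field.

## 1. Response models

### Primary single-flash model

```
ΔOPL(t) = u(t) · [ A0 + A1 · (−e^(−τa·t) + e^(−τb·t)) ]
```

`t` is time after flash onset; `u(t)` is the unit step with `u(0) = 1`.
`A0` (nm, negative) is the rapid contraction that appears effectively
instantaneously at the acquisition rates considered; the bracketed
difference of exponentials is the slow elongation with amplitude scale
`A1` (nm) and rate constants `τa` (fast) and `τb` (slow).

The parameterisation is degenerate: `(A1, τa, τb)` and `(−A1, τb, τa)`
produce identical curves. All fitted results are canonicalised to
`τa ≥ τb` and `A1 ≥ 0` (`ResponseParams.canonical()`).

Closed forms (`derived_metrics`):

- peak time `t_max = ln(τa/τb) / (τa − τb)`, with the limit `1/τa` as
  `τb → τa`;
- peak height `ΔOPL(t_max)`;
- elongation rate `d(ΔOPL)/dt = A1 (τa e^(−τa t) − τb e^(−τb t))`,
  defined for `t > 0` only (the step makes the derivative undefined at 0).

Both closed forms are verified in the test suite against brute-force
oracles written independently of the implementation: a two-stage dense
grid argmax (1 ms coarse pass, 10 µs refinement around the coarse peak)
and central finite differences.

### Extensions

- **Two-flash** (`eval_two_flash`, 8 parameters + known `t_isi`): the sum
  of one response at the first onset and a second, independently
  parameterised response shifted by the inter-stimulus interval.
- **Adapting background** (`eval_background`): the single-flash model
  plus an ungated linear ramp `m·t` representing slow drift under a
  steady background. The ramp is not gated by the step and the fit does
  not zero-reference the baseline, since the ramp itself defines the
  pre-onset behaviour.
- **Alternative reduced models** (`eval_alternative`), identified by
  colour tags: `magenta` is the primary model; `green` replaces the step
  with a delayed onset `t0` and drops the constant offset; `red` and
  `blue` are single-exponential saturating elongations (with/without
  offset); `cyan` is a pure two-exponential elongation without
  contraction. These exist for model comparison on real or synthetic
  traces (`compare_models`).
- **En-face interferometric intensity** (`eval_enface_intensity`):
  `C1 + C2·cos(n·(4π/λ)·elongation + φ0)`, the intensity of the
  ISOS–COST interference fringe as the outer segment elongates.

## 2. Fitting

`scipy.optimize.least_squares` (Trust Region Reflective) with:

- rate constants bounded below at `1e-6` s⁻¹ (strict positivity without
  constraining the canonical ordering);
- `x_scale='jac'`, `ftol = xtol = gtol = 1e-14`;
- residual weighting: samples within 25 ms after each flash onset receive
  10× squared-error weight. The contraction occupies a handful of samples
  at 400 Hz; without overweighting it is fit poorly relative to the much
  longer elongation;
- zero-referencing: traces are re-referenced to the mean of the pre-onset
  samples before fitting (except the background fit, see above);
- initialisation: `A0` from the minimum over the first 50 ms post-onset,
  `A1` from the excursion above it, `τa = 5`, `τb = 0.1`. Noiseless
  recovery over broad random parameter ranges succeeds to relative error
  < 1e-3 (typically ~1e-15) from this single start.

### Confidence intervals

The 10× weighting is deliberate overweighting, not an inverse-variance
noise model, so the naive weighted covariance `σ̂²_w (JᵀWJ)⁻¹` is
miscalibrated (Monte-Carlo coverage of nominal 95% intervals was ~52%).
The package uses the sandwich estimator

```
cov = σ̂² · (JᵀWJ)⁻¹ (JᵀW²J) (JᵀWJ)⁻¹
```

with `σ̂²` estimated from the *unweighted* residuals. Intervals are
Student-t with `n − p` degrees of freedom. Monte-Carlo coverage under the
generator's noise model is ~94%.

### Diagnostics and reliability flags

`goodness_of_fit` reports R², overall RMS residual, and the RMS over the
late window (t ≥ 0.5 s after onset). Fits flag parameter reliability
against the post-onset observation window: `A1`/`τa` require ≥ 1 s,
`τb` ≥ 2.85 s; two-flash fits flag each flash's window separately.

### Ratio statistics

`response_ratios` forms second-flash/first-flash parameter ratios from a
two-flash fit with first-order error propagation
`σ_r = |r|·sqrt((σ_α/α)² + (σ_β/β)²)`; propagated sigmas agree with
200 000-sample Monte-Carlo estimates within 10% for relative
uncertainties up to 0.1. `ratio_trend` fits an ordinary least-squares
line through (interval, ratio) points and reports the interval at which
the trend reaches unity; a slope whose effect across the observed
interval range is below floating-point resolution is reported as flat
(`t_unity = NaN`).

## 3. Radiometry and dose response

Photon flux density over a uniformly illuminated circular retinal spot:

```
flux = T · P / (hc/λ) / (π (d/2)²)     [photons · s⁻¹ · µm⁻²]
```

with transmission `T` (default 1), power `P`, wavelength `λ`, spot
diameter `d`. Bleached photopigment fraction for fluence `Q = flux ·
duration`:

```
p = 1 − e^(−Q·s),   s = 2.95e-8 µm²  (photosensitivity at 555 nm)
```

Reference figures reproduced by this chain: a 5.05 µW / 10 ms / 555 nm
flash on a 360 µm spot bleaches ~4%; 10 s backgrounds of 114 nW and
236 nW deliver ~3.1e6 and ~6.5e6 photons s⁻¹ µm⁻² and bleach ~60% and
~85%.

Dose-response laws (`fit_loglinear`, `fit_michaelis_menten`):
`y = a·log10(b) + k` (solved by linear least squares) and
`y = vm·b/(b + b0)` with `b0 > 0` and `vm` free in sign (contraction
amplitudes saturate at negative values).

## 4. Phase extraction

Per time point, the phase difference between COST and ISOS is estimated
over the 9 A-scans of a cone subvolume as
`ΔΦ = arg( Σ COST·conj(ISOS) )` — the magnitude-weighted circular mean.
Time points whose summed magnitude is negligible are flagged invalid.

Temporal unwrapping maps successive phase differences into `(−π, π]` via
`d ↦ π − (π − d) mod 2π` and accumulates them, preserving the first valid
sample and bridging NaN gaps (the accumulated offset carries across
invalid samples). OPL conversion: `ΔOPL = ΔΦ · λ / (4π)` with `λ =
850 nm` by default (double-pass), so a π phase step is a quarter-wave,
212.5 nm. Extracted traces are zero-referenced to the mean of valid
pre-onset samples.

End-to-end: encoding a known trace into complex subvolumes and extracting
it back is exact to < 1e-6 nm RMS without noise, and < 15 nm RMS at
amplitude SNR 20 (SNR defined as 1 / RMS complex noise magnitude on
unit-magnitude phasors).

## 5. Window analysis

`truncation_sweep` refits progressively truncated copies of a trace
(windows measured from flash onset; the longest window is the reference)
and reports per-parameter percentage error `PE = |p − p_ref| / |p_ref| ×
100`. `minimum_window` returns the shortest window from which PE stays
below a threshold for all longer windows (sustained criterion, scanned
from the long end). On noisy ensembles at the study conditions the
contraction amplitude `A0` is the most window-stable parameter and the
slow rate `τb` the least — `τb` is only constrained by the late decay.

## 6. Synthetic data

`SimulationConfig` defaults are the study acquisition conditions: 400 Hz,
3 s duration, onset at 0.2 s, additive white Gaussian noise of σ = 10 nm,
NumPy `default_rng` seeding for bit reproducibility.

- **Two-flash attenuation**: the second response's amplitudes are scaled
  by `min(1, 2.3·t_isi + 0.31)` for `A0` and 0.85 for `A1` — the
  empirical recovery of the contraction with inter-stimulus interval, and
  the roughly interval-independent suppression of the elongation.
- **Pulse trains** compound the same attenuation cumulatively across
  flashes; per-flash effective parameters are recorded in the trace
  metadata.
- **Background traces** add the ramp `m·(t − onset)` so drift crosses
  zero at onset.
- **Subvolume series** encode a trace into 9 A-scan complex pairs: ISOS
  phases fixed per A-scan at random values, COST = ISOS phase + ΔΦ(t)
  from the trace, plus circular complex Gaussian noise with per-quadrature
  σ = 1/(SNR·√2).

## 7. File formats

Traces: CSV with columns `time_s, dopl_nm` (written with `%.17g`; read
with pandas `float_precision="round_trip"` so round trips are bit-exact)
plus a JSON sidecar `<stem>.meta.json` holding the sampling rate,
stimulus onsets, and free-form metadata. Non-uniform time grids are
rejected naming the offending index; NaN samples are preserved and their
indices flagged. Subvolume series: long-format CSV with per-A-scan
complex components. Fit reports: JSON conforming to
`src/orgmodel/schemas/fit_report.schema.json`.

## 8. Known limitations

- **Short-interval ratio bias.** At `t_isi ≈ 0.1` s the joint two-flash
  fit shows a small but real bias in the recovered `A0` ratio (response
  overlap makes the two contractions partially collinear). At 0.2 s and
  above, recovery is unbiased at the study noise level. Ratio estimates
  from very short intervals should be treated as approximate.
- **R² ceiling under noise.** With σ = 10 nm and the exemplar response
  over 3 s, the attainable R² is capped at `1 − σ²/Var(signal) ≈ 0.946`;
  R² values quoted for such data cluster just below 0.95 by construction,
  and RMS residual is the more interpretable figure.
- **CI calibration is approximate.** The sandwich intervals are
  first-order (linearised) and calibrated under additive white Gaussian
  noise; heavy-tailed or correlated noise will change coverage.
- **Bleach model.** The exponential bleaching law ignores pigment
  regeneration; it is accurate for stimuli short relative to
  regeneration time constants (the ≤ 10 s stimuli considered here).
- **Unwrapping.** The temporal unwrapper assumes per-sample phase steps
  stay within `(−π, π]`; responses faster than a quarter wavelength per
  sample at the acquisition rate would alias.
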