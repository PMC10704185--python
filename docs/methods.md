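# Methods

This note records the models, conventions and numerical choices behind
`twopeff`, and what the synthetic-data tests do and do not demonstrate.

## Pulse model

Pulses are intensity-only profiles P(t) ≥ 0 on a uniform time grid; no
complex field, spectral phase, chirp or dispersion propagation is modeled.
This matches the quantity an intensity autocorrelator or a FROG trace
delivers and is all that two-photon (2p) yield, F ∝ R∫P²dt, depends on.

Supported shapes:

- **sech²** — P(t) = Ppk·sech²(t/t₀), FWHM = 2·arccosh(√2)·t₀ ≈ 1.7627·t₀.
  Closed forms used for cross-checks: energy E = 2·Ppk·t₀ (hence
  Ppk = E·1.7627/(2·FWHM)) and ∫P²dt = (4/3)·Ppk²·t₀.
- **Gaussian** — FWHM = 2√(2 ln 2)·σ ≈ 2.3548·σ.
- **square** — rendered with cell-coverage anti-aliasing (each sample holds
  the fraction of its grid cell inside the rectangle), which keeps the
  trapezoidal energy exact and the interpolated FWHM accurate to a small
  fraction of one grid step despite the discontinuous edges.  Quantities
  involving P² (which the coverage rendering smooths) converge as O(dt) and
  are checked on finer grids.
- **composite** — a pointwise sum of sech² lobes (one main lobe at height 1
  plus side lobes), rescaled to the requested total energy.  This is the
  parametric stand-in for "low-quality" pulses whose energy partly sits
  outside the central peak.  The exact analytic shape of such distorted
  pulses in real lasers is instrument-specific; the family here reproduces
  their defining property — less ∫P²dt at matched energy and matched
  autocorrelation width — not any particular measured sample train.

Default grid: 8192 samples spanning 40× the FWHM, centered on the main
peak.  At these defaults the trapezoidal error is orders of magnitude below
every stated tolerance (tail truncation of a sech² at ±20 FWHM is ~10⁻³⁰ of
the peak).  Every integral in the package is a trapezoidal sum — a single
quadrature rule keeps trace-based and closed-form results comparable and
matches how instrument software integrates sampled traces.  A trace must
decay below 10⁻⁶ of its peak at both grid ends ("fully contained"), which
turns silent energy loss from out-of-range lobes into a hard error.

Internal units are SI (s, W, J).  Files carry their units in the header
(`time_fs,power_au`); arbitrary power units are accepted because the
fluorescence prediction renormalizes trace amplitude anyway.

## Autocorrelation

A(τ) = ∫P(t)P(t+τ)dt is computed by direct shift–multiply–sum at every
integer-sample lag, with trapezoidal end-weights and zero extension outside
the grid, then symmetrized (to cancel ~10⁻¹⁶ floating-point asymmetry) and
normalized to 1 at zero lag.  A direct O(N²) oracle in the test suite pins
the fast path to 10⁻⁹.  No FFT is used: at N = 8192 the O(N²) correlate is
fast enough and avoids any question of transform-induced error.

The ACF width is the **full** width at half maximum.  Deconvolution factors
are hard constants: 1.54 for sech² (the vendor convention; the numerically
exact ratio is ≈ 1.5427 and the test suite re-derives 1.543 ± 0.005 from
first principles at four pulse durations), √2 for Gaussian, 1 for square.
The non-uniqueness of the ACF — composite pulses tuned to the same 154 fs
width as a clean 100 fs sech² pulse but with up to 30% side-lobe energy —
is exercised explicitly: all such pulses predict strictly less fluorescence
at equal energy, monotonically in the side-lobe fraction.

## Fluorescence prediction and η

All fluorescence values are relative; no absolute proportionality constant
is ever fixed, so only ratios carry meaning.  Trace-based prediction
rescales the trace to integrate to the per-pulse energy at an assumed
average power (1 W by default — ratios are independent of the choice),
then returns R·∫P²dt.  This makes the prediction invariant to the trace's
amplitude units, exactly quadratic in average power, and inversely
proportional to repetition rate at fixed average power.

η is computed per measurement point: each fluorescence reading is divided
by the reference laser's log–log regression prediction at the same power
(which also brings the reference's own normalized values to mean 1), then
multiplied by (R_test·τ_test)/(R_ref·τ_ref).  Pulse durations are the
sech²-deconvolved values; since only duration *ratios* enter, the assumed
deconvolution shape cancels as long as it is applied consistently.  The
sampling unit for mean ± SD is one point (one power level in one session);
sessions are tracked and pooled by default.  The reported SD is dispersion
across points, not propagated instrument error.

A saturation guard rejects any laser whose log–log slope deviates from 2 by
more than 0.1 (configurable): fluorophore saturation and quenching bend the
power curve downward and would bias η.  The default power window is six
levels spanning 4–10 mW, inside the range where the quadratic law holds for
a standard green dye target.

Pairwise comparisons between lasers use Welch two-sample t-tests with Holm
step-down adjustment over all pairs, reported in an upper-triangular
matrix.  Welch/Holm was chosen over studentized-maximum-modulus procedures
(Dunnett's T3 style) because it is exact to implement, controls the
family-wise error rate without equal-variance assumptions, and preserves
the scientifically relevant distinction (clearly separated groups vs
overlapping ones); the output header names the method.

## Image pipeline

Frames are 16-bit unsigned with 12-bit depth scaled to 16 bits: counts are
multiples of 16 and the saturation ceiling is 4095·16 = 65520 (not 65535),
which is what the saturation check tests.  Normalization follows the
acquisition protocol: subtract the mean of a background region, divide by
exposure in ms.  The background region is the outer 10% border frame of the
image (configurable); the spot sits in the interior by construction in this
side-view geometry, and no hot-pixel rejection is applied.  Intensity is
the single brightest normalized pixel (ties broken row-major); FWHMs are
read from the raw one-pixel row (lateral, x) and column (axial, z) profiles
through that pixel with linear interpolation at half maximum — no
smoothing, no 2-D fitting.  The peak must sit ≥ 5 px inside the frame.

## Synthetic data

The generator emulates the study conditions end to end: frames are

    background + amplitude · η · (P/P_ref)² · G(x,z) · exposure + noise,

with G an anisotropic Gaussian centered on a pixel.  Defaults: 256×256
frames, lateral FWHM 8 px and axial FWHM 24 px (the ≈3:1 elongation of a
focused beam seen from the side; with the 62.5 nm default pixel these are
0.5 μm and 1.5 μm — order-of-magnitude choices for a high-NA 2p focus, not
measured values), background 100 counts, read noise 2 counts, reference
power 10 mW.  Noise is Poisson on the signal counts plus additive Gaussian
read noise — the minimal physically sensible camera model — followed by
12-bit quantization.  Per-frame multiplicative noise (`noise_cv`, default
1% in study presets) emulates alignment and power drift between readings.
Exposures are auto-selected in the 600 ms–5 s range to put the expected
peak near (but below) the ceiling, as in the acquisition protocol.

In a multi-laser study each laser's brightness is η·(R_ref·τ_ref)/(R·τ)
relative to the reference, i.e. η enters as a pure multiplicative factor on
the quadratic signal, so the analysis pipeline's recovered η is directly
comparable to the generator's `true_eta`.  Composite-pulse generation and
the image generator are deliberately decoupled: `side_lobe_fraction`
affects only pulse traces, so image-pipeline tests do not depend on pulse
physics.

ACF-width tuning of composite pulses exploits exact linearity: rescaling
all lobe delays and widths by s rescales the ACF width by s, so the tuner
converges in one or two proportional-rescale iterations (a couple more
absorb grid discretization), to 0.1% of the target.

What passing synthetic tests shows: the estimator chain (normalization →
regression → η) is unbiased within ~2% under quadratic signals with
realistic shot/read/drift noise, and the geometry estimators are unbiased
within 1% at SNR ≈ 20.  What it does not show: robustness to aberrated
(non-Gaussian) spots, structured background, camera nonlinearity, dye
photobleaching, or pulse-train instabilities — none of which the generator
models.  End-to-end recovery tests use 128×128 frames and one session per
laser, which keeps the whole suite interactive on a single core while
leaving each frame's photon statistics identical to the full-size scene.

## Degenerate inputs and tie-breaks

Zero-energy traces are rejected wherever a normalization is implied (ACF,
fluorescence prediction) and return 0 where the value is well defined
(energy, average power).  Profiles that never cross half maximum raise
errors rather than returning sentinel widths.  Equal-maximum pixels resolve
to the first in row-major order.  Identical comparison groups with zero
variance report p = 1 directly (the t statistic is undefined there).
Extrapolation beyond the reference power range warns but proceeds.

## Known limitations

- Intensity-only pulses: effects encoded purely in spectral phase are
  invisible except through their intensity-profile footprint.
- The scalar law assumes all pulses in a train identical; pulse-to-pulse
  variation folds into η without being separable.
- FROG phase retrieval is out of scope; traces are consumed as given.
- No detection-path PSF deconvolution and no focal-volume estimate; spot
  FWHMs are apparent (camera-plane) widths converted by the supplied pixel
  size, which must come from the user's calibration.
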