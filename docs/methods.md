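# Methods

## Model and assumptions

The package treats a UV-Vis spectrum as a finite sample of A(λ) on a
uniform wavelength grid (default 200-500 nm at 0.5 nm; 0.5 nm is chosen so
every reference difference interval — 16, 20, 10.5 and 14 nm — is an exact
integer number of steps). Mixtures are assumed Beer-Lambert additive:
A(λ) = Σ_i c_i·ε_i(λ). No stray-light, band-pass convolution or
wavelength-accuracy effects are modelled; wavelengths are plain floating nm
with no air/vacuum correction (irrelevant at UV-Vis bandwidths).

### Derivative operator

The first derivative is the centred difference quotient over the interval
Δλ, D[A](λ) = (A(λ+Δλ/2) − A(λ−Δλ/2))/Δλ, and order n is the n-fold
application with the same Δλ. Commercial instruments do not document their
internal derivative algorithm; the centred difference is chosen as the
reproducible reference semantics because it is linear, exact for
polynomials of degree ≤ 1 per application, annihilates constants, and has a
transparent noise response (SD ∝ 1/Δλ for uncorrelated noise, which is the
entire reason Δλ acts as a smoothing parameter). Consequences embraced
rather than hidden:

- The output grid shrinks by exactly n·Δλ/2 at each end and, for odd step
  counts (e.g. Δλ = 10.5 nm at 0.5 nm spacing), sits on half-step positions.
  Edges are truncated, never padded or reflected — padding manufactures
  artificial zero crossings.
- Amplitudes are true difference quotients in AU·nm⁻ⁿ. An ``instrument``
  scale (raw n-fold differences, undivided) is available because vendor
  firmwares differ; every selection/calibration step is invariant to the
  choice. Note that published derivative "slopes" from instrument software
  are often on such internal scales and can be orders of magnitude away
  from true AU·nm⁻ⁿ quotients; this package makes no attempt to mimic any
  vendor's scaling.
- A Savitzky-Golay mode (window spanning Δλ, polynomial order n+1) exists
  behind a flag for users who want least-squares differentiation; it is
  never the default, and for odd step counts its output stays on the source
  grid trimmed by ⌈n·k/2⌉ / ⌊n·k/2⌋ points, since the half-step shift of
  the centred contract cannot be realised there.

### Zero crossings and wavelength selection

A crossing is a strict sign change between adjacent grid points, located by
linear interpolation; a point that touches zero without a sign change is
not a crossing (there is no interpolation-stable root, and quantification
at such a point is ill-conditioned). Crossings whose local slope magnitude
falls below ``min_slope`` (default 1e-6 signal per nm) are discarded: in
essentially flat regions (e.g. the short-wavelength analyte's derivative
above ~300 nm) noise produces arbitrarily many spurious roots.

Candidate working wavelengths for a target analyte are the crossings of the
*pure interferent's* derivative — that is the method's logic, and pure
reference spectra are exactly what a method developer measures first.
Candidates are scored by |Pearson r| of the calibration mixtures' amplitude
against the target concentration; ties within 1e-9 go to the larger
calibration slope magnitude (sensitivity), then the lower wavelength, so
selection is deterministic. Noiseless pure spectra are used for candidate
generation even when calibration mixtures are noisy: crossing locations of
the model system are concentration-invariant, and scoring on the (noisy)
mixtures is what injects realism into the choice.

### Calibration and inverse prediction

Unweighted OLS of amplitude on concentration, with classical n−2
standard errors (scipy's ``linregress``); r is Pearson's correlation.
Unweighted is the default because the reference protocol reports none,
even though the 20-fold concentration ranges make responses
heteroscedastic under multiplicative noise; a 1/X-weighted mode
(statsmodels WLS) exists behind a flag. Inverse prediction is
X = (Y − b)/S; extrapolation outside the calibrated range is allowed (the
model object carries its range so callers can warn). LOD/LOQ use the ICH
σ/S convention with factors 3.3 and 10; σ defaults to the calibration's
intercept SD, with a blank-replicate σ accepted instead — both are
ICH-sanctioned and the choice is the caller's.

### Validation statistics

Sample SD (n−1) throughout; CV% = 100·SD/mean; Error% = 100·(mean−added)/
added; label-claim recovery 100·found/nominal; standard-addition recovery
100·(found_spiked − found_base)/added. Method comparison uses the
pooled-variance two-tailed t-test (the classical reading of an unqualified
"t-test"), with Welch behind a flag. Between-day rows pool all replicates
across days rather than averaging daily means. Report renderers round CV%,
Error% and recovery to 2 decimals and r to 3; JSON outputs keep full
precision.

## The synthetic system

Each species is a sum of Gaussian bands c·Σ ε_b·exp(−(λ−μ_b)²/2σ_b²). The
defaults are explicit fixtures — no claim is made that they equal the real
compounds' spectra — built to reproduce the *geometry* the method needs:

- clindamycin-like: dominant far-UV band (210 nm, SD 10, ε 8e-4) with a
  weak shoulder (245 nm, SD 15, ε 2e-4), plus a trace long-wavelength
  feature (390 nm, SD 9, ε 1e-5). The trace band gives the species a
  genuine first-derivative zero crossing on the long-wavelength analyte's
  band flank — mirroring the reference system, whose short-wavelength
  analyte likewise exhibits a reported first-derivative crossing in the
  360-390 nm region where the long-wavelength analyte is read.
- tretinoin-like: strong visible-edge band (360 nm, SD 30, ε 0.048; 12.5
  μg/ml gives 0.600 AU at the maximum) plus a secondary short-UV band
  (225 nm, SD 12, ε 0.012) sitting on the clindamycin-like main band's
  steep flank, providing the crossing at which the short-wavelength analyte
  is read. A single-band long-wavelength species would place its only
  crossing at its own band centre, where the other analyte has no signal at
  all — no working wavelength for that channel could exist; real compounds
  avoid this precisely because they have secondary spectral structure.

Band absorptivities were set analytically so that, under the photometric
noise below, the per-replicate noise at the *worst* accuracy-panel level is
about 1% of signal — the precision scale a routine spectrophotometric assay
of this kind actually achieves — before any end-to-end run was scored.

Noise is multiplicative (relative SD, default 0.3%) then additive
(default 0.0005 AU), with optional linear baseline drift; every sample's
stream derives from (seed, CRC32(sample_id)), so regeneration is
bit-identical and independent of generation order, and no hidden global RNG
exists. What the generator does **not** emulate: wavelength jitter,
correlated (1/f) instrument drift, stray light, chemical instability
(e.g. photodegradation of retinoids), or matrix absorbance beyond a linear
baseline. Passing tests therefore demonstrate the *algorithmic* correctness
and noise behaviour of the workflow, not instrument-transferable accuracy
claims for the real formulation.

### Study designs

The generator reproduces the reference protocol's designs: 8-level
calibration series (60-1200 μg/ml with the partner fixed at 12.5 μg/ml;
1.25-25 μg/ml with the partner fixed at 600 μg/ml), an accuracy panel of 3
levels per analyte (60/480/1200 and 1.25/5/15 μg/ml) with n replicates, and
a dosage-form extract at the label ratio (1.2 g : 25 mg per 100 g, 0.5 g
dissolved to 50 ml → 120 and 2.5 μg/ml). The calibration stage runs six
replicate series per design pooled into one regression — the reference
protocol's n = 6 — which is also what stabilises wavelength selection and
low-level inverse prediction under noise; single-series calibration is
available (``n_series=1``) and is used for the noiseless identities in the
test suite.

## In-silico validation study

``run_validation_study`` (and ``scripts/acceptance.py``) runs the whole
pipeline at first order, Δλ = 20 nm — one of the two first-order settings
of the reference protocol, the lower-noise one — under multiplicative noise
of SD 0.3% with no additive term, quantifies the 18-sample panel, and
summarises CV% and Error% per level. Problem sizes (601-point spectra, 96
calibration spectra, 18 panel spectra) keep the full study under a few
seconds. Typical results (seed 1): max CV% ≈ 0.6, max |Error%| ≈ 2.6, the
error maximum occurring at the lowest long-wavelength-analyte level where
relative calibration-intercept error is largest.

## Numerical choices and degenerate inputs

- Grid uniformity enforced to a relative 1e-9; Δλ must divide into grid
  steps to 1e-9 relative.
- Amplitude queries interpolate linearly and refuse extrapolation.
- A candidate whose mixture amplitudes have zero variance scores r = 0
  rather than NaN.
- Identical samples in the t-test return t = 0, p = 1.
- Degenerate calibration designs (all X equal, n < 3, zero slope at
  inversion) raise typed errors rather than returning NaNs.
- CSVs are written at %.17g and re-parsed with correctly-rounded float
  conversion, so read/write round-trips are exact to the last ulp.

## Known limitations

- Higher orders (3, 4) are implemented and tested for operator identities
  but the shipped fixtures are designed around orders 1-2, the orders the
  workflow defaults exercise.
- The selection criterion (max |r|) barely discriminates between
  near-perfect candidates on very clean data; the deterministic
  sensitivity tie-break and the n = 6 calibration protocol are what make
  the outcome stable. With grossly under-replicated noisy calibrations,
  selection can land on a low-SNR crossing.
- Savitzky-Golay mode trims edges on the source grid (see above) and so
  does not satisfy the half-step grid contract of the centred operator for
  odd step counts.
- No multivariate alternatives (CLS/PLS) or ratio-spectra derivative
  methods; the package implements the zero-crossing method only.
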