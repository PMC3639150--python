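# zerocross

Zero-crossing derivative spectrophotometry for the simultaneous
quantification of two co-formulated analytes whose zero-order UV-Vis spectra
overlap too strongly for direct absorbance measurement. The reference system
is a clindamycin phosphate / tretinoin combination gel: a
short-wavelength-band analyte calibrated over 60-1200 μg/ml next to a
long-wavelength-band analyte at 1.25-25 μg/ml.

## The method

For a Beer-Lambert mixture, absorbance is additive,
A(λ) = c_A·ε_A(λ) + c_B·ε_B(λ), and so is any wavelength derivative of it.
The package computes n-th order derivative spectra (n = 1..4) as iterated
centred difference quotients over a configurable interval Δλ,

    ¹D[A](λ) = (A(λ + Δλ/2) − A(λ − Δλ/2)) / Δλ,

which is linear in the spectrum and annihilates constant baseline offsets;
Δλ doubles as a smoothing parameter (derivative noise ∝ 1/Δλ). At a
wavelength λ* where the *interferent's* derivative crosses zero, the mixture
derivative amplitude Y(λ*) depends only on the target analyte, so an
ordinary calibration line Y = S·c + b measured at λ* quantifies the target
at any interferent concentration. Working wavelengths are auto-selected
among the interferent's crossings by the best linear response (maximum |r|)
of calibration mixtures, with sensitivity as tie-break. Validation
statistics follow ICH Q2 conventions: CV% = 100·SD/mean,
Error% = 100·(found − added)/added, LOD = 3.3σ/|S|, LOQ = 10σ/|S|,
label-claim and standard-addition recovery, and a pooled two-tailed t-test
for comparison against a reference method.

A synthetic-spectra module generates the whole two-analyte system (Gaussian
absorption bands, additive mixing, seeded multiplicative/additive photometric
noise) together with the reference calibration, accuracy-panel and
dosage-form designs, so the complete workflow is testable without
instrument data.

## Worked example

```python
import zerocross as zc
from zerocross import simulate as sim

cals = zc.calibrate_synthetic_system(order=1, delta_lambda_nm=20.0, n_series=1)
for analyte, cal in cals.items():
    print(analyte, cal.model.wavelength_nm, cal.model.r)

design = sim.generate_design("assay_sample")      # 120 / 2.5 ug/ml label ratio
spectra = sim.generate_spectrum_set(design)
models = {a: c.model for a, c in cals.items()}
print(zc.quantify_spectra(spectra, models))
```

prints (noiseless limit):

```
clindamycin: selected 225.01 nm from 3 candidate crossings (|r| = 1.000000)
tretinoin: selected 390.00 nm from 2 candidate crossings (|r| = 1.000000)

clindamycin: found 120.000 ug/ml of 120 nominal -> recovery 100.00%
tretinoin: found 2.500 ug/ml of 2.5 nominal -> recovery 100.00%
```

The clindamycin-like analyte is read at 225.01 nm, a zero crossing of the
tretinoin-like first derivative, and vice versa at 390.00 nm; both
calibrations are perfectly linear and the dosage-form extract quantifies at
100% recovery, confirming the readings are free of cross-interference.
Under multiplicative photometric noise (SD 0.3%, seed 1) the same pipeline
gives per-level CV% of 0.12-0.63 and |Error%| up to 2.56 on the six-level
accuracy panel (`examples/04_validation_study.py`).

The `examples/` scripts walk through each capability: spectral overlap,
crossing location, calibration + quantification, and the noisy validation
study. The same workflow is scriptable from the shell via the `zerocross`
CLI (`simulate`, `calibrate`, `quantify`, `validate`; see `--help`).

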