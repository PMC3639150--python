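"""Full calibration and quantification of a dosage-form extract.

Auto-selects working wavelengths by best linear response, fits both
calibration lines on noiseless 8-level mixture series, then quantifies a
synthetic gel extract at the label ratio (120 ug/ml clindamycin-like,
2.5 ug/ml tretinoin-like) and reports the label-claim recovery.
"""

import zerocross as zc
from zerocross import reports, simulate as sim

cals = zc.calibrate_synthetic_system(order=1, delta_lambda_nm=20.0, n_series=1)
print(reports.render_calibration_table([c.model for c in cals.values()]))
print()
for analyte, cal in cals.items():
    print(f"{analyte}: selected {cal.model.wavelength_nm:.2f} nm "
          f"from {len(cal.selection.candidates)} candidate crossings "
          f"(|r| = {abs(cal.selection.linearity_r):.6f})")

design = sim.generate_design("assay_sample")
spectra = sim.generate_spectrum_set(design)
models = {a: c.model for a, c in cals.items()}
found = zc.quantify_spectra(spectra, models).iloc[0]
print()
for analyte, nominal in (("clindamycin", 120.0), ("tretinoin", 2.5)):
    rec = zc.recovery_label_claim(found[analyte], nominal, analyte)
    print(f"{analyte}: found {found[analyte]:.3f} ug/ml of {nominal:g} nominal "
          f"-> recovery {rec.recovery_pct:.2f}%")
print("\nrecoveries at 100% confirm the zero-crossing readings are free of "
      "cross-interference in the noiseless limit")
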