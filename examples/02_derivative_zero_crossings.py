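"""Derivative spectra and the zero crossings that make selectivity possible.

Computes first-derivative spectra (difference interval 20 nm) of both pure
components and lists each species' zero-crossing wavelengths.  Measuring one
analyte exactly where the other's derivative crosses zero removes the
other's contribution at any concentration.
"""

import zerocross as zc

grid = zc.default_grid()
order, dl = 1, 20.0

for model, conc in ((zc.CLINDAMYCIN_LIKE, 600.0), (zc.TRETINOIN_LIKE, 12.5)):
    pure = zc.species_spectrum(model, conc, grid)
    d = zc.derivative_transform(pure, order, dl)
    crossings = zc.find_zero_crossings(d)
    print(f"{model.name} ({conc:g} ug/ml), order {order}, delta-lambda {dl:g} nm:")
    for c in crossings:
        print(f"  zero crossing at {c.wavelength_nm:7.2f} nm "
              f"(local slope {c.slope_at_crossing:+.2e} per nm)")
    print(f"  -> the other analyte can be read at "
          f"{'these wavelengths' if crossings else 'none'} free of "
          f"{model.name} interference")
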