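"""End-to-end zero-crossing quantification workflow.

Ties the pieces together the way the bench method is run: derive the pure
interferent spectra, locate their zero crossings, pick working wavelengths
by best linear response, calibrate each analyte on its mixture series, then
read unknown mixtures at the selected wavelengths and invert the calibration
lines.  Also provides the synthetic validation study (accuracy panel under
photometric noise) used for in-silico method qualification.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Mapping

import numpy as np
import pandas as pd

from .calibration import CalibrationModel, MeasurementSetting, fit_calibration, quantify
from .crossings import DEFAULT_MIN_SLOPE, WavelengthSelection, select_working_wavelength
from .derivative import amplitude_at, derivative_transform
from .errors import RangeError
from .spectra import MixtureDesign, Spectrum, SpectrumSet, blank_subtract
from . import simulate
from .simulate import (
    CLINDAMYCIN_FIXED,
    DEFAULT_SPECIES,
    NO_NOISE,
    NoiseModel,
    TRETINOIN_FIXED,
    generate_design,
    generate_spectrum_set,
    species_spectrum,
)


@dataclasses.dataclass(frozen=True)
class AnalyteCalibration:
    """Wavelength selection plus the fitted calibration for one analyte."""

    selection: WavelengthSelection
    model: CalibrationModel


def calibrate_analyte(
    calib_spectra: SpectrumSet,
    design: MixtureDesign,
    target_analyte: str,
    interferent_analyte: str,
    interferent_spectrum: Spectrum,
    order: int,
    delta_lambda_nm: float,
    min_slope: float = DEFAULT_MIN_SLOPE,
    *,
    wavelength_override: float | None = None,
    method: str = "central",
    weighting: str = "none",
) -> AnalyteCalibration:
    """Select the working wavelength (unless overridden) and calibrate.

    The amplitude of each calibration mixture's derivative at the chosen
    wavelength is regressed on the target concentration.
    """
    if wavelength_override is None:
        selection = select_working_wavelength(
            calib_spectra,
            design,
            target_analyte,
            interferent_analyte,
            interferent_spectrum,
            order,
            delta_lambda_nm,
            min_slope,
            method=method,
        )
        wavelength = selection.wavelength_nm
    else:
        wavelength = float(wavelength_override)
        selection = WavelengthSelection(
            analyte=target_analyte,
            order=order,
            delta_lambda_nm=float(delta_lambda_nm),
            wavelength_nm=wavelength,
            linearity_r=float("nan"),
            slope=float("nan"),
            candidates=(),
        )
    x = np.array(
        [design.concentration(s.sample_id, target_analyte) for s in calib_spectra]
    )
    y = np.array(
        [
            amplitude_at(
                derivative_transform(s, order, delta_lambda_nm, method=method),
                wavelength,
            )
            for s in calib_spectra
        ]
    )
    model = fit_calibration(
        (x, y),
        MeasurementSetting(
            analyte=target_analyte,
            order=order,
            delta_lambda_nm=float(delta_lambda_nm),
            wavelength_nm=wavelength,
        ),
        weighting=weighting,
    )
    return AnalyteCalibration(selection=selection, model=model)


def quantify_spectrum(
    spectrum: Spectrum,
    models: Mapping[str, CalibrationModel],
    *,
    blank: Spectrum | None = None,
    method: str = "central",
) -> dict[str, float]:
    """Concentrations (ug/ml) of every calibrated analyte in one spectrum."""
    s = blank_subtract(spectrum, blank) if blank is not None else spectrum
    out: dict[str, float] = {}
    for analyte, model in models.items():
        d = derivative_transform(
            s, model.order, model.delta_lambda_nm, method=method
        )
        try:
            y = amplitude_at(d, model.wavelength_nm)
        except RangeError as exc:
            raise RangeError(
                f"sample {spectrum.sample_id!r}: {exc}"
            ) from exc
        out[analyte] = quantify(model, y)
    return out


def quantify_spectra(
    spectra: SpectrumSet,
    models: Mapping[str, CalibrationModel],
    *,
    blank: Spectrum | None = None,
    method: str = "central",
) -> pd.DataFrame:
    """Per-sample concentration table for a collection of spectra."""
    rows = []
    for s in spectra:
        row = {"sample_id": s.sample_id}
        row.update(quantify_spectrum(s, models, blank=blank, method=method))
        rows.append(row)
    columns = ["sample_id", *models.keys()]
    return pd.DataFrame(rows, columns=columns).set_index("sample_id")


# ---------------------------------------------------------------------------
# Synthetic two-analyte system workflow


def calibrate_synthetic_system(
    order: int = 1,
    delta_lambda_nm: float = 20.0,
    noise: NoiseModel = NO_NOISE,
    species: Mapping[str, simulate.SpeciesModel] | None = None,
    grid=None,
    min_slope: float = DEFAULT_MIN_SLOPE,
    n_series: int = 6,
    *,
    method: str = "central",
) -> dict[str, AnalyteCalibration]:
    """Run the full calibration stage on generated data.

    Generates both 8-level calibration designs as ``n_series`` replicate
    series (six in the reference protocol) pooled into one regression,
    derives noiseless pure-component reference spectra at the designs' fixed
    partner levels for crossing candidates, selects working wavelengths and
    fits both calibration lines.  Returns {analyte: AnalyteCalibration}.
    """
    models = DEFAULT_SPECIES if species is None else dict(species)
    g = simulate.default_grid() if grid is None else grid
    pure = {
        "clindamycin": species_spectrum(models["clindamycin"], CLINDAMYCIN_FIXED, g),
        "tretinoin": species_spectrum(models["tretinoin"], TRETINOIN_FIXED, g),
    }
    out: dict[str, AnalyteCalibration] = {}
    for target, interferent, design_kind in (
        ("clindamycin", "tretinoin", "clindamycin_calibration"),
        ("tretinoin", "clindamycin", "tretinoin_calibration"),
    ):
        design = simulate.replicate_design(generate_design(design_kind), n_series)
        spectra = generate_spectrum_set(design, models, noise=noise, grid=g)
        out[target] = calibrate_analyte(
            spectra,
            design,
            target,
            interferent,
            pure[interferent],
            order,
            delta_lambda_nm,
            min_slope,
            method=method,
        )
    return out


def run_accuracy_panel(
    calibrations: Mapping[str, AnalyteCalibration],
    noise: NoiseModel = NO_NOISE,
    species: Mapping[str, simulate.SpeciesModel] | None = None,
    grid=None,
    n_replicates: int = 3,
    scope: str = "within_day",
) -> pd.DataFrame:
    """Quantify the synthetic accuracy panel and summarise per level.

    Returns one row per (analyte, added level) with found mean/SD, CV% and
    Error%, mirroring an ICH precision/accuracy table.
    """
    from .validation import precision_accuracy

    design = generate_design("accuracy_panel", n_replicates=n_replicates)
    spectra = generate_spectrum_set(design, species, noise=noise, grid=grid)
    models = {a: c.model for a, c in calibrations.items()}
    found = quantify_spectra(spectra, models)
    rows = []
    for analyte, levels in (
        ("clindamycin", simulate.ACCURACY_CLINDAMYCIN_LEVELS),
        ("tretinoin", simulate.ACCURACY_TRETINOIN_LEVELS),
    ):
        for level in levels:
            ids = [
                sid
                for sid in design.sample_ids
                if sid.startswith(f"acc_{analyte[:4]}_{level:g}_")
            ]
            row = precision_accuracy(
                found.loc[ids, analyte].to_numpy(), level, scope=scope
            )
            rows.append({"analyte": analyte, **row.to_dict()})
    return pd.DataFrame(rows)


def run_validation_study(
    seed: int,
    order: int = 1,
    delta_lambda_nm: float = 20.0,
    multiplicative_sd: float = 0.003,
    additive_sd: float = 0.0,
    n_replicates: int = 3,
    species: Mapping[str, simulate.SpeciesModel] | None = None,
) -> pd.DataFrame:
    """Seeded end-to-end precision/accuracy study on the synthetic system.

    Calibrates on noisy 8-level series, quantifies the noisy accuracy panel,
    and returns the per-level summary table.  Noise defaults to the
    photometric condition of the in-silico qualification: multiplicative
    SD 0.3%, no additive term.
    """
    noise = NoiseModel(
        additive_sd=additive_sd,
        multiplicative_sd=multiplicative_sd,
        seed=seed,
    )
    calibs = calibrate_synthetic_system(
        order=order, delta_lambda_nm=delta_lambda_nm, noise=noise, species=species
    )
    return run_accuracy_panel(
        calibs, noise=noise, species=species, n_replicates=n_replicates
    )
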