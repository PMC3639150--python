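"""Zero-crossing location and working-wavelength selection.

The zero-crossing method measures analyte A at a wavelength where the
interferent B's derivative spectrum is exactly zero, so B contributes no
signal there at any concentration.  Candidate wavelengths are therefore the
zero crossings of the *pure* interferent derivative trace; among them, the
working wavelength is chosen by the best linear response of the mixture
derivative amplitude to the target analyte's concentration.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np
from scipy import stats

from .derivative import DerivativeSpectrum, amplitude_at, derivative_transform
from .errors import SelectionError
from .spectra import MixtureDesign, Spectrum, SpectrumSet

#: default slope threshold (signal per nm) below which a crossing is treated
#: as noise in an essentially flat region and discarded
DEFAULT_MIN_SLOPE = 1e-6


@dataclasses.dataclass(frozen=True)
class ZeroCrossing:
    """A sign change of a derivative trace, located by linear interpolation."""

    wavelength_nm: float
    left_index: int
    right_index: int
    slope_at_crossing: float  # signal change per nm across the bracket


def find_zero_crossings(
    dspec: DerivativeSpectrum, min_slope: float = DEFAULT_MIN_SLOPE
) -> list[ZeroCrossing]:
    """Locate all sign changes of a derivative spectrum.

    One crossing per sign change, interpolated linearly between the
    bracketing grid points.  A point where the signal touches zero without
    changing sign is not a crossing (no interpolation-stable root there).
    Crossings whose local slope magnitude falls below ``min_slope`` are
    discarded as flat-region noise.  Returns crossings sorted by wavelength;
    an empty list is a valid result.
    """
    y = dspec.signal
    wl = dspec.wavelengths_nm
    out: list[ZeroCrossing] = []
    # strict sign changes between adjacent points (excludes exact zeros)
    prod = y[:-1] * y[1:]
    for i in np.nonzero(prod < 0)[0]:
        i = int(i)
        slope = (y[i + 1] - y[i]) / (wl[i + 1] - wl[i])
        lam = wl[i] - y[i] / slope
        if abs(slope) >= min_slope:
            out.append(ZeroCrossing(float(lam), i, i + 1, float(slope)))
    # single-point zeros with opposite signs on both sides
    for i in np.nonzero(y == 0)[0]:
        i = int(i)
        if 0 < i < y.size - 1 and y[i - 1] * y[i + 1] < 0:
            slope = (y[i + 1] - y[i - 1]) / (wl[i + 1] - wl[i - 1])
            if abs(slope) >= min_slope:
                out.append(ZeroCrossing(float(wl[i]), i - 1, i + 1, float(slope)))
    out.sort(key=lambda c: c.wavelength_nm)
    return out


@dataclasses.dataclass(frozen=True)
class CandidateScore:
    """Audit record for one scored crossing candidate."""

    wavelength_nm: float
    r: float
    slope: float
    intercept: float
    crossing_slope: float


@dataclasses.dataclass(frozen=True)
class WavelengthSelection:
    """Outcome of working-wavelength selection for one analyte/setting."""

    analyte: str
    order: int
    delta_lambda_nm: float
    wavelength_nm: float
    linearity_r: float
    slope: float
    candidates: tuple[CandidateScore, ...]

    def to_dict(self) -> dict:
        return {
            "analyte": self.analyte,
            "order": self.order,
            "delta_lambda_nm": self.delta_lambda_nm,
            "wavelength_nm": self.wavelength_nm,
            "linearity_r": self.linearity_r,
            "slope": self.slope,
            "candidates": [dataclasses.asdict(c) for c in self.candidates],
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


#: |r| ties closer than this are broken by sensitivity, then wavelength
R_TIE_TOL = 1e-9


def _score_candidate(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Pearson |r|-relevant regression of amplitude on concentration.

    Returns (r, slope, intercept); degenerate responses (zero variance in y)
    score r = 0.
    """
    if np.ptp(y) == 0.0:
        return 0.0, 0.0, float(np.mean(y))
    res = stats.linregress(x, y)
    return float(res.rvalue), float(res.slope), float(res.intercept)


def select_working_wavelength(
    calib_spectra: SpectrumSet,
    design: MixtureDesign,
    target_analyte: str,
    interferent_analyte: str,
    interferent_spectrum: Spectrum,
    order: int,
    delta_lambda_nm: float,
    min_slope: float = DEFAULT_MIN_SLOPE,
    *,
    method: str = "central",
) -> WavelengthSelection:
    """Choose the working wavelength for ``target_analyte``.

    Candidates are the zero crossings of the pure ``interferent_spectrum``
    derivative.  For each candidate, the derivative amplitude of every
    calibration mixture is regressed on the target concentration; the
    candidate with maximum |r| wins.  Ties in |r| (within 1e-9) fall back to
    the larger slope magnitude (sensitivity), then the lower wavelength, so
    the result is deterministic.
    """
    d_int = derivative_transform(
        interferent_spectrum, order, delta_lambda_nm, method=method
    )
    cands = find_zero_crossings(d_int, min_slope=min_slope)
    if not cands:
        raise SelectionError(
            f"no zero crossing of {interferent_analyte!r} order-{order} "
            f"derivative (delta_lambda {delta_lambda_nm:g} nm) survives "
            f"min_slope={min_slope:g}; try a smaller min_slope or another "
            "(order, delta_lambda) setting"
        )
    x = np.array(
        [design.concentration(s.sample_id, target_analyte) for s in calib_spectra],
        dtype=float,
    )
    if np.ptp(x) == 0.0:
        raise SelectionError(
            f"design does not vary {target_analyte!r}; cannot score linearity"
        )
    d_mix = [
        derivative_transform(s, order, delta_lambda_nm, method=method)
        for s in calib_spectra
    ]
    scored: list[CandidateScore] = []
    for c in cands:
        amps = np.array([amplitude_at(d, c.wavelength_nm) for d in d_mix])
        r, slope, intercept = _score_candidate(x, amps)
        scored.append(
            CandidateScore(
                wavelength_nm=c.wavelength_nm,
                r=r,
                slope=slope,
                intercept=intercept,
                crossing_slope=c.slope_at_crossing,
            )
        )
    best = scored[0]
    for cand in scored[1:]:
        if abs(cand.r) > abs(best.r) + R_TIE_TOL:
            best = cand
        elif abs(abs(cand.r) - abs(best.r)) <= R_TIE_TOL and abs(cand.slope) > abs(
            best.slope
        ):
            # candidates are wavelength-sorted, so equal sensitivity keeps
            # the lower wavelength automatically
            best = cand
    return WavelengthSelection(
        analyte=target_analyte,
        order=order,
        delta_lambda_nm=float(delta_lambda_nm),
        wavelength_nm=best.wavelength_nm,
        linearity_r=best.r,
        slope=best.slope,
        candidates=tuple(scored),
    )
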