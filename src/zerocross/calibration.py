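"""Calibration at a fixed (order, delta-lambda, wavelength) setting:
ordinary least squares, inverse prediction, and detection limits.

The calibration line Y = slope*X + intercept relates derivative amplitude Y
(signal units) to analyte concentration X (ug/ml).  Standard errors use the
classical unweighted-OLS formulas with n-2 degrees of freedom; r is Pearson's
correlation of X and Y.  Detection and quantification limits follow the
ICH Q2 sigma/slope convention: LOD = 3.3*sigma/|S|, LOQ = 10*sigma/|S|.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np
from scipy import stats

from .errors import FitError, QuantificationError

LOD_FACTOR = 3.3
LOQ_FACTOR = 10.0


@dataclasses.dataclass(frozen=True)
class MeasurementSetting:
    """The instrument-side context of a calibration: which analyte is read,
    at which derivative order, difference interval and wavelength."""

    analyte: str
    order: int
    delta_lambda_nm: float
    wavelength_nm: float


@dataclasses.dataclass(frozen=True)
class CalibrationModel:
    """A fitted calibration line with its classical OLS diagnostics."""

    analyte: str
    order: int
    delta_lambda_nm: float
    wavelength_nm: float
    slope: float
    intercept: float
    r: float
    sd_slope: float
    sd_intercept: float
    rsd_slope_pct: float
    n_points: int
    range_ug_ml: tuple[float, float]
    weighting: str = "none"

    def __post_init__(self) -> None:
        if self.n_points < 3:
            raise FitError("calibration needs at least 3 points")
        if not -1.0 <= self.r <= 1.0 + 1e-12:
            raise FitError(f"correlation coefficient out of range: {self.r}")
        lo, hi = self.range_ug_ml
        if not lo < hi:
            raise FitError("calibration range must have min < max")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["range_ug_ml"] = list(self.range_ug_ml)
        return d

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationModel":
        d = dict(d)
        d["range_ug_ml"] = tuple(d["range_ug_ml"])
        return cls(**d)

    @classmethod
    def from_json(cls, text: str) -> "CalibrationModel":
        return cls.from_dict(json.loads(text))


def fit_calibration(
    points,
    setting: MeasurementSetting,
    *,
    weighting: str = "none",
) -> CalibrationModel:
    """Fit Y on X by least squares at the given measurement setting.

    Parameters
    ----------
    points
        Iterable of (X, Y) pairs, or a pair of equal-length arrays (X, Y).
        X in ug/ml, Y in derivative-signal units.
    weighting
        ``none`` (default, unweighted OLS) or ``1/x`` (weighted least squares
        with weights 1/X, for heteroscedastic responses over wide ranges;
        X = 0 points are inadmissible there).
    """
    if isinstance(points, tuple) and len(points) == 2:
        x = np.asarray(points[0], dtype=float)
        y = np.asarray(points[1], dtype=float)
    else:
        arr = np.asarray(list(points), dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise FitError("points must be (X, Y) pairs")
        x, y = arr[:, 0], arr[:, 1]
    if x.size != y.size:
        raise FitError("X and Y differ in length")
    n = int(x.size)
    if n < 3:
        raise FitError(f"calibration needs at least 3 points, got {n}")
    if np.ptp(x) == 0.0:
        raise FitError("degenerate design: all X values equal")

    if weighting == "none":
        res = stats.linregress(x, y)
        slope, intercept = float(res.slope), float(res.intercept)
        sd_slope = float(res.stderr)
        sd_intercept = float(res.intercept_stderr)
        r = float(res.rvalue)
    elif weighting == "1/x":
        import statsmodels.api as sm

        if np.any(x <= 0):
            raise FitError("1/x weighting requires strictly positive X")
        wls = sm.WLS(y, sm.add_constant(x), weights=1.0 / x).fit()
        intercept, slope = (float(v) for v in wls.params)
        sd_intercept, sd_slope = (float(v) for v in wls.bse)
        r = float(stats.pearsonr(x, y).statistic)
    else:
        raise FitError(f"unknown weighting {weighting!r}")

    return CalibrationModel(
        analyte=setting.analyte,
        order=setting.order,
        delta_lambda_nm=setting.delta_lambda_nm,
        wavelength_nm=setting.wavelength_nm,
        slope=slope,
        intercept=intercept,
        r=r,
        sd_slope=sd_slope,
        sd_intercept=sd_intercept,
        rsd_slope_pct=100.0 * sd_slope / abs(slope) if slope != 0 else float("inf"),
        n_points=n,
        range_ug_ml=(float(np.min(x)), float(np.max(x))),
        weighting=weighting,
    )


def predict_signal(model: CalibrationModel, x: float) -> float:
    """Forward prediction Y = slope*X + intercept (extrapolation allowed)."""
    return model.slope * x + model.intercept


def quantify(model: CalibrationModel, y: float) -> float:
    """Inverse prediction X = (Y - intercept)/slope in ug/ml."""
    if model.slope == 0:
        raise QuantificationError(
            f"calibration slope for {model.analyte!r} is zero; cannot invert"
        )
    return (y - model.intercept) / model.slope


def lod_loq(sigma_response: float, slope: float) -> tuple[float, float]:
    """ICH detection and quantification limits from a response SD and slope.

    sigma defaults in practice to the calibration's sd_intercept (a blank
    replicate SD may be used instead); both are ICH-sanctioned choices.
    """
    if slope == 0:
        raise QuantificationError("zero slope: LOD/LOQ undefined")
    if sigma_response < 0:
        raise QuantificationError("sigma_response must be >= 0")
    return (
        LOD_FACTOR * sigma_response / abs(slope),
        LOQ_FACTOR * sigma_response / abs(slope),
    )
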