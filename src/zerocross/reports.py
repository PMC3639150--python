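"""Human-readable report rendering.

Machine-readable outputs everywhere else are JSON/CSV at full precision;
these renderers produce the compact fixed-precision text tables an analyst
expects in a validation report (regression statistics, precision/accuracy
rows, recovery and method-comparison blocks).  Rounding here is display-only.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping, Sequence

from .calibration import CalibrationModel
from .validation import MethodComparison, PrecisionAccuracyRow, RecoveryResult


def _fmt_eq(model: CalibrationModel) -> str:
    sign = "+" if model.intercept >= 0 else "-"
    return f"Y = {model.slope:.4g}*X {sign} {abs(model.intercept):.3g}"


def render_calibration_table(models: Sequence[CalibrationModel]) -> str:
    """Regression-statistics table, one column block per measurement setting."""
    lines = []
    header = (
        f"{'Parameter':<24}"
        + "".join(
            f"{'%dD (dl=%g) %g nm' % (m.order, m.delta_lambda_nm, round(m.wavelength_nm, 1)):>30}"
            for m in models
        )
    )
    lines.append(header)
    lines.append("-" * len(header))
    rows = [
        ("Analyte", [m.analyte for m in models]),
        ("Linearity range (ug/ml)", [f"{m.range_ug_ml[0]:g}-{m.range_ug_ml[1]:g}" for m in models]),
        ("Regression equation", [_fmt_eq(m) for m in models]),
        ("SD of slope", [f"{m.sd_slope:.3g}" for m in models]),
        ("RSD of slope (%)", [f"{m.rsd_slope_pct:.3f}" for m in models]),
        ("SD of intercept", [f"{m.sd_intercept:.3g}" for m in models]),
        ("Correlation coefficient", [f"{m.r:.3f}" for m in models]),
        ("n", [str(m.n_points) for m in models]),
    ]
    for name, values in rows:
        lines.append(f"{name:<24}" + "".join(f"{v:>30}" for v in values))
    return "\n".join(lines)


def render_precision_table(rows: Iterable[PrecisionAccuracyRow], title: str = "") -> str:
    """Precision/accuracy table: added, found mean+/-SD, CV%, Error%."""
    lines = []
    if title:
        lines.append(title)
    lines.append(
        f"{'Added':>10} {'Found (mean+/-SD)':>24} {'CV (%)':>8} {'Error (%)':>10} {'n':>4} {'scope':>12}"
    )
    for r in rows:
        lines.append(
            f"{r.added:>10.2f} {f'{r.found_mean:.2f}+/-{r.found_sd:.2f}':>24} "
            f"{r.cv_pct:>8.2f} {r.error_pct:>10.2f} {r.n:>4d} {r.scope:>12}"
        )
    return "\n".join(lines)


def render_recovery_table(results: Iterable[RecoveryResult], title: str = "") -> str:
    lines = []
    if title:
        lines.append(title)
    lines.append(f"{'Analyte':<14} {'Found':>12} {'Nominal':>12} {'Recovery (%)':>14} {'mode':>20}")
    for r in results:
        lines.append(
            f"{r.analyte:<14} {r.found:>12.4g} {r.nominal:>12.4g} "
            f"{r.recovery_pct:>14.2f} {r.mode:>20}"
        )
    return "\n".join(lines)


def render_method_comparison(cmp: MethodComparison) -> str:
    return (
        f"two-tailed t-test: t = {cmp.t_statistic:.4f}, "
        f"df = {cmp.degrees_of_freedom:g}, p = {cmp.p_value_two_tailed:.4f} "
        f"-> {cmp.conclusion} at alpha = {cmp.alpha:g}"
    )


def render_lod_loq(entries: Mapping[str, tuple[float, float]]) -> str:
    lines = [f"{'Analyte':<14} {'LOD (ug/ml)':>14} {'LOQ (ug/ml)':>14}"]
    for analyte, (lod, loq) in entries.items():
        lines.append(f"{analyte:<14} {lod:>14.4g} {loq:>14.4g}")
    return "\n".join(lines)
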