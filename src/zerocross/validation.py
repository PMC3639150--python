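"""ICH-style method-validation statistics.

Precision and accuracy summaries (CV%, Error%), recovery in label-claim and
standard-addition modes, and the two-method comparison t-test.  Conventions
follow pharmacopoeial practice: sample SD with n-1 denominator throughout,
CV% = 100*SD/mean, Error% = 100*(mean found - added)/added, recovery% =
100*found/nominal (label claim) or 100*(found_spiked - found_base)/added
(standard addition), pooled-variance two-tailed t-test for method comparison
(Welch available behind a flag).
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import stats

from .errors import ValidationError


@dataclasses.dataclass(frozen=True)
class PrecisionAccuracyRow:
    """One added-level summary row of a precision/accuracy table."""

    added: float
    found_mean: float
    found_sd: float
    cv_pct: float
    error_pct: float
    n: int
    scope: str  # "within_day" | "between_day"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclasses.dataclass(frozen=True)
class RecoveryResult:
    analyte: str
    found: float
    nominal: float
    recovery_pct: float
    mode: str  # "label_claim" | "standard_addition"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclasses.dataclass(frozen=True)
class MethodComparison:
    t_statistic: float
    degrees_of_freedom: float
    p_value_two_tailed: float
    alpha: float
    conclusion: str  # "significant" | "not_significant"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def summary_stats(values) -> tuple[float, float, int]:
    """Mean, sample SD (n-1) and n of a replicate series."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValidationError("need at least 2 replicates for an SD")
    return float(arr.mean()), float(arr.std(ddof=1)), int(arr.size)


def precision_accuracy(
    found, added: float, scope: str = "within_day"
) -> PrecisionAccuracyRow:
    """Summarise replicate found concentrations against the added level."""
    if added <= 0:
        raise ValidationError(f"added concentration must be positive, got {added}")
    if scope not in ("within_day", "between_day"):
        raise ValidationError(f"unknown scope {scope!r}")
    mean, sd, n = summary_stats(found)
    return precision_accuracy_from_moments(mean, sd, added, n=n, scope=scope)


def precision_accuracy_from_moments(
    found_mean: float,
    found_sd: float,
    added: float,
    *,
    n: int = 3,
    scope: str = "within_day",
) -> PrecisionAccuracyRow:
    """Build a summary row from a printed mean +/- SD (table re-analysis)."""
    if added <= 0:
        raise ValidationError(f"added concentration must be positive, got {added}")
    if found_sd < 0:
        raise ValidationError("SD must be >= 0")
    return PrecisionAccuracyRow(
        added=float(added),
        found_mean=float(found_mean),
        found_sd=float(found_sd),
        cv_pct=100.0 * found_sd / found_mean,
        error_pct=100.0 * (found_mean - added) / added,
        n=int(n),
        scope=scope,
    )


def recovery_label_claim(found: float, nominal: float, analyte: str = "") -> RecoveryResult:
    """Recovery against the declared (label) amount of the dosage form."""
    if nominal <= 0:
        raise ValidationError(f"nominal amount must be positive, got {nominal}")
    return RecoveryResult(
        analyte=analyte,
        found=float(found),
        nominal=float(nominal),
        recovery_pct=100.0 * found / nominal,
        mode="label_claim",
    )


def recovery_standard_addition(
    found_base: float, found_spiked: float, added: float, analyte: str = ""
) -> RecoveryResult:
    """Recovery of a known spike on top of the sample matrix."""
    if added <= 0:
        raise ValidationError(f"added amount must be positive, got {added}")
    return RecoveryResult(
        analyte=analyte,
        found=float(found_spiked - found_base),
        nominal=float(added),
        recovery_pct=100.0 * (found_spiked - found_base) / added,
        mode="standard_addition",
    )


def compare_methods_ttest(
    a, b, alpha: float = 0.05, *, welch: bool = False
) -> MethodComparison:
    """Two-sample two-tailed t-test between two analytical methods.

    Pooled-variance (Student) by default; ``welch=True`` drops the equal
    variance assumption.  Identical inputs give t = 0, p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("each method needs at least 2 results")
    if not 0 < alpha < 1:
        raise ValidationError(f"alpha must be in (0, 1), got {alpha}")
    res = stats.ttest_ind(a, b, equal_var=not welch)
    t = float(res.statistic)
    p = float(res.pvalue)
    if np.isnan(t):  # both samples constant and equal
        t, p = 0.0, 1.0
    df = float(res.df)
    return MethodComparison(
        t_statistic=t,
        degrees_of_freedom=df,
        p_value_two_tailed=p,
        alpha=alpha,
        conclusion="not_significant" if p > alpha else "significant",
    )
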