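"""QC gates and method-validation statistics.

Covers the run controls and validation figures of merit a standardized
immunoassay carries: specificity against a negative reference material,
accuracy against a certified positive reference material, inter/intra-day
repeatability of IC50, homogeneity of reference-material units, and
stability of stored units against the certified value.

Two-group comparisons use Welch's t-test.  With exactly two groups a
one-way ANOVA is equivalent to the pooled-variance t-test; Welch's form
is preferred here because group sizes are small and unequal (typically
n = 3 per condition vs n = 9 for the certified value) and because the
stability check only has summary statistics to work from.

All SDs are sample SDs (n − 1 denominator).  CV and RSD are synonymous:
100 × SD / mean, reported as percentages.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .core import ConfigurationError, GateResult, ReferenceMaterialSpec, round_half_away

__all__ = [
    "SummaryStats",
    "summary_stats",
    "negative_specificity_gate",
    "positive_accuracy_gate",
    "RepeatabilityDesign",
    "repeatability_report",
    "homogeneity_check",
    "GroupSummary",
    "StabilityFlag",
    "stability_compare",
]


@dataclass(frozen=True)
class SummaryStats:
    mean: float
    sd: float
    cv_percent: float
    n: int


def summary_stats(
    values: Sequence[float], report_decimals: int | None = None
) -> SummaryStats:
    """Mean, sample SD and CV% of a series of determinations.

    With ``report_decimals`` set, the CV is formed from the mean and SD
    rounded to that many decimals — the convention of lab reports whose
    CV row is computed from the printed (rounded) mean/SD rather than
    from full precision.  Default is full precision.
    """
    vals = np.asarray(values, dtype=float)
    if len(vals) < 2:
        raise ConfigurationError(
            f"dispersion undefined for {len(vals)} value(s); need ≥ 2"
        )
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1))
    if report_decimals is not None:
        m, s = round_half_away(mean, report_decimals), round_half_away(sd, report_decimals)
    else:
        m, s = mean, sd
    if m == 0:
        raise ConfigurationError("CV undefined: mean is zero")
    return SummaryStats(mean=mean, sd=sd, cv_percent=100.0 * s / m, n=len(vals))


# ---------------------------------------------------------------------------
# Specificity and accuracy gates
# ---------------------------------------------------------------------------


def negative_specificity_gate(
    neg_ods: Sequence[float], control_ods: Sequence[float], alpha: float = 0.05
) -> GateResult:
    """Specificity check: the negative reference material must not inhibit.

    Welch's two-sample t-test of negative-reference ODs against the 100%
    reaction control ODs; the gate passes when p > alpha, i.e. no
    inhibition (no false positive) is detected.  When both groups are
    degenerate (zero variance), the gate reduces to exact equality of
    means.
    """
    neg = np.asarray(neg_ods, dtype=float)
    ctrl = np.asarray(control_ods, dtype=float)
    if len(neg) < 2 or len(ctrl) < 2:
        raise ConfigurationError("each group needs ≥ 2 OD values")
    if neg.std(ddof=1) == 0.0 and ctrl.std(ddof=1) == 0.0:
        equal = float(neg.mean()) == float(ctrl.mean())
        return GateResult(
            passed=equal,
            p_value=1.0 if equal else 0.0,
            statistic=None,
            details={
                "neg_mean_od": float(neg.mean()),
                "control_mean_od": float(ctrl.mean()),
                "alpha": alpha,
                "test": "exact-equality (degenerate groups)",
            },
        )
    res = stats.ttest_ind(neg, ctrl, equal_var=False)
    return GateResult(
        passed=bool(res.pvalue > alpha),
        p_value=float(res.pvalue),
        statistic=float(res.statistic),
        details={
            "neg_mean_od": float(neg.mean()),
            "control_mean_od": float(ctrl.mean()),
            "alpha": alpha,
            "test": "Welch two-sample t",
        },
    )


def positive_accuracy_gate(
    measured: Sequence[float],
    spec: ReferenceMaterialSpec,
    threshold_percent: float = 15.0,
) -> GateResult:
    """Sensitivity/accuracy check against the certified positive
    reference material: relative deviation of the measured mean from the
    certified value must stay below the threshold (default 15%)."""
    if spec.kind != "positive" or spec.certified_value is None:
        raise ConfigurationError(
            "positive_accuracy_gate requires a positive ReferenceMaterialSpec "
            "with certified_value"
        )
    vals = np.asarray(measured, dtype=float)
    if len(vals) < 1:
        raise ConfigurationError("at least one measured value required")
    mean = float(vals.mean())
    deviation = 100.0 * abs(mean - spec.certified_value) / spec.certified_value
    return GateResult(
        passed=deviation < threshold_percent,
        p_value=None,
        statistic=deviation,
        details={
            "measured_mean": mean,
            "certified_value": spec.certified_value,
            "deviation_percent": deviation,
            "threshold_percent": threshold_percent,
            "n": len(vals),
        },
    )


# ---------------------------------------------------------------------------
# Repeatability
# ---------------------------------------------------------------------------


@dataclass
class RepeatabilityDesign:
    """Inter-day and intra-day IC50 (or content) determinations."""

    inter_day: Sequence[float] = field(default_factory=list)
    intra_day: Sequence[float] = field(default_factory=list)


def repeatability_report(design: RepeatabilityDesign) -> dict[str, SummaryStats | None]:
    """Per-group and pooled summary statistics for a repeatability study.

    A missing group yields a partial report with a warning rather than an
    error; ``total`` pools every available value.
    """
    out: dict[str, SummaryStats | None] = {}
    for name, vals in (("inter_day", design.inter_day), ("intra_day", design.intra_day)):
        if len(vals) >= 2:
            out[name] = summary_stats(vals)
        else:
            warnings.warn(f"repeatability group {name!r} missing or < 2 values")
            out[name] = None
    pooled = list(design.inter_day) + list(design.intra_day)
    out["total"] = summary_stats(pooled) if len(pooled) >= 2 else None
    return out


# ---------------------------------------------------------------------------
# Homogeneity and stability of reference-material units
# ---------------------------------------------------------------------------


def homogeneity_check(
    unit_values: Sequence[float], rsd_threshold: float = 15.0
) -> tuple[bool, float]:
    """Between-unit homogeneity: pass iff RSD% < threshold (default 15)."""
    if len(unit_values) < 3:
        raise ConfigurationError(
            f"homogeneity needs ≥ 3 units, got {len(unit_values)}"
        )
    rsd = summary_stats(unit_values).cv_percent
    return rsd < rsd_threshold, rsd


@dataclass(frozen=True)
class GroupSummary:
    mean: float
    sd: float
    n: int


@dataclass
class StabilityFlag:
    condition: str
    mean: float
    sd: float
    n: int
    p_value: float
    unstable: bool


def _as_summary(values: Sequence[float] | GroupSummary) -> GroupSummary:
    if isinstance(values, GroupSummary):
        return values
    vals = np.asarray(values, dtype=float)
    sd = float(vals.std(ddof=1)) if len(vals) >= 2 else 0.0
    mean = float(vals.mean()) if len(vals) else float("nan")
    return GroupSummary(mean, sd, len(vals))


def stability_compare(
    condition_groups: Mapping[str, Sequence[float] | GroupSummary],
    identified: GroupSummary,
    alpha: float = 0.05,
) -> list[StabilityFlag]:
    """Compare stored reference-material units to the certified value.

    Per storage condition, a Welch t-test from summary statistics against
    the identified (certified) mean/SD/n.  A condition is flagged
    unstable only for *degradation*: p < alpha AND group mean below the
    identified mean.  Elevated means are reported but never flagged.
    Groups with n < 2 are skipped with a warning.  No multiplicity
    correction is applied across conditions.
    """
    flags: list[StabilityFlag] = []
    for label, grp in condition_groups.items():
        g = _as_summary(grp)
        if g.n < 2:
            warnings.warn(f"stability condition {label!r} has n={g.n} < 2; skipped")
            continue
        if g.sd == 0.0 and identified.sd == 0.0:
            p = 1.0 if g.mean == identified.mean else 0.0
        else:
            res = stats.ttest_ind_from_stats(
                g.mean, g.sd, g.n,
                identified.mean, identified.sd, identified.n,
                equal_var=False,
            )
            p = float(res.pvalue)
        flags.append(
            StabilityFlag(
                condition=label,
                mean=g.mean,
                sd=g.sd,
                n=g.n,
                p_value=p,
                unstable=bool(p < alpha and g.mean < identified.mean),
            )
        )
    return flags
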