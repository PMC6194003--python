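"""Quantification core: inhibition rates, calibration fitting/inversion,
IC50, lower detection limit, and epitope arithmetic.

The measurement chain is

    OD450 ──(inhibition rate)──> Y(%) ──(invert Y = A·e^(−x/t) + y0)──> x
        ──(× dilution, × reaction volume, × epitopes/g)──> epitope count

Inhibition rates are kept raw for fitting even when they fall outside
[0, 100]; clamping would bias the calibration.  No extrapolation beyond
the standard range is performed: out-of-range samples are censored, not
quantified.
"""

from __future__ import annotations

import math
import warnings
from typing import Iterable, Sequence

import numpy as np
from scipy import optimize, stats

from .core import (
    AboveRangeError,
    AssayFailureError,
    BelowRangeError,
    CalibrationFit,
    CalibrationPoint,
    ConfigurationError,
    ControlSet,
    ConversionConstants,
    EpitopeQuantity,
    Ic50UnreachableError,
    InsufficientDesignError,
    PlateInvalidError,
    PlateReadout,
    PlateWell,
    SampleResult,
)

__all__ = [
    "inhibition_rate",
    "aggregate_controls",
    "calibration_points_from_plate",
    "fit_calibration",
    "calibrate_plate",
    "predict_inhibition",
    "invert_calibration",
    "ic50",
    "determine_ldl",
    "mass_to_epitopes",
    "epitopes_to_mass",
    "quantify_sample",
    "antigen_reduction",
]


# ---------------------------------------------------------------------------
# Inhibition rate
# ---------------------------------------------------------------------------


def inhibition_rate(a: float, b: float, c: float, d: float | None = None) -> float:
    """Percent inhibition of antibody binding from raw ODs.

        100 × ((a − b) − (c − d)) / (a − b)

    a: mean OD of the 100% reaction (non-inhibitory) control;
    b: mean OD of the blank; c: sample-well OD; d: blank applicable to
    the sample well.  With a single shared plate blank d defaults to b,
    reducing the formula to 100 × (a − c)/(a − b).

    The raw value is returned even when < 0 or > 100; flagging is the
    caller's concern.
    """
    if d is None:
        d = b
    for name, od in (("a", a), ("b", b), ("c", c), ("d", d)):
        if od < 0:
            raise ConfigurationError(f"OD {name} must be ≥ 0, got {od}")
    if a <= b:
        raise PlateInvalidError(
            f"100% control OD (a={a:.4g}) must exceed blank OD (b={b:.4g})"
        )
    return 100.0 * ((a - b) - (c - d)) / (a - b)


def aggregate_controls(wells: Iterable[PlateWell]) -> ControlSet:
    """Mean OD of 100%-reaction-control and blank wells on a plate."""
    controls = [w.od450 for w in wells if w.role == "full_reaction_control"]
    blanks = [w.od450 for w in wells if w.role == "blank"]
    if not controls:
        raise ConfigurationError(
            "no full_reaction_control wells on the plate; the 100% reaction "
            "control is required"
        )
    if not blanks:
        raise ConfigurationError("no blank wells on the plate; the blank is required")
    return ControlSet(
        a=float(np.mean(controls)),
        b=float(np.mean(blanks)),
        n_control=len(controls),
        n_blank=len(blanks),
    )


def calibration_points_from_plate(
    plate: PlateReadout, controls: ControlSet | None = None
) -> list[CalibrationPoint]:
    """Per-concentration replicate inhibition rates from a plate's
    standard wells, ascending in concentration."""
    if controls is None:
        controls = aggregate_controls(plate.wells)
    by_conc: dict[float, list[float]] = {}
    for w in plate.by_role("standard"):
        y = inhibition_rate(controls.a, controls.b, w.od450)
        by_conc.setdefault(w.concentration, []).append(y)
    return [
        CalibrationPoint(x=x, inhibition_values=tuple(vals))
        for x, vals in sorted(by_conc.items())
    ]


# ---------------------------------------------------------------------------
# Calibration curve: Y = A·exp(−x/t) + y0
# ---------------------------------------------------------------------------


def _model(x: np.ndarray, A: float, t: float, y0: float) -> np.ndarray:
    return A * np.exp(-x / t) + y0


def _initial_guess(xs: np.ndarray, ys: np.ndarray) -> tuple[float, float, float]:
    """Start values inside the basin for monotone saturation data.

    y0 starts at the largest observed inhibition; A at the lowest-level
    mean minus y0; t from a log-linear regression of log(y0 − Y) on x
    (the model gives log(y0 − Y) = log(−A) − x/t, slope −1/t).
    """
    y0 = float(ys.max())
    lowest = xs.min()
    A = float(ys[xs == lowest].mean() - y0)
    resid = y0 - ys
    mask = resid > 0
    t = float(np.median(xs))
    if mask.sum() >= 2 and len(np.unique(xs[mask])) >= 2:
        slope = np.polyfit(xs[mask], np.log(resid[mask]), 1)[0]
        if slope < 0:
            t = -1.0 / slope
    if A == 0.0:
        A = -1e-6  # degenerate flat data; let the optimizer confirm A ≈ 0
    return A, t, y0


def fit_calibration(points: Sequence[CalibrationPoint]) -> CalibrationFit:
    """Unweighted nonlinear least squares of Y = A·e^(−x/t) + y0 over all
    replicate points (not replicate means).

    t > 0 is enforced by optimizing log t; A and y0 are unconstrained,
    but a fit with A ≥ 0 (non-increasing curve) is flagged non-usable
    and downstream quantification will refuse it.

    Requires ≥ 4 distinct concentrations (3 parameters + 1 df).
    """
    concs = sorted({p.x for p in points})
    if len(concs) < 4:
        raise InsufficientDesignError(
            f"calibration needs ≥ 4 distinct concentrations, got {len(concs)}"
        )
    xs = np.array([p.x for p in points for _ in p.inhibition_values], dtype=float)
    ys = np.array(
        [v for p in points for v in p.inhibition_values], dtype=float
    )

    A0, t0, y00 = _initial_guess(xs, ys)

    def residuals(theta: np.ndarray) -> np.ndarray:
        A, log_t, y0 = theta
        return _model(xs, A, math.exp(log_t), y0) - ys

    theta0 = np.array([A0, math.log(t0), y00])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sol = optimize.least_squares(residuals, theta0, method="lm", xtol=1e-12)
    A, log_t, y0 = sol.x
    fit = CalibrationFit(
        A=float(A),
        t=float(math.exp(log_t)),
        y0=float(y0),
        residual_ss=float(2.0 * sol.cost),
        converged=bool(sol.success),
        x_min=float(concs[0]),
        x_max=float(concs[-1]),
        n_points=len(xs),
    )
    return fit


def predict_inhibition(fit: CalibrationFit, x: float | np.ndarray) -> float | np.ndarray:
    """Evaluate the calibration curve: A·e^(−x/t) + y0."""
    if not fit.converged:
        raise ConfigurationError("calibration fit did not converge; cannot predict")
    out = fit.A * np.exp(-np.asarray(x, dtype=float) / fit.t) + fit.y0
    return float(out) if np.isscalar(x) or np.ndim(x) == 0 else out


_REL_TOL = 1e-9  # slack at the range endpoints for float round-trips


def invert_calibration(fit: CalibrationFit, y: float) -> float:
    """Concentration (µg/mL) whose predicted inhibition equals ``y``.

        x = −t · ln((y − y0)/A)

    Exact inverse of :func:`predict_inhibition`.  Signals out-of-range:
    y at/above the plateau or above the highest standard raises
    :class:`AboveRangeError`; y below the curve at the lowest standard
    raises :class:`BelowRangeError`.  No extrapolation is performed.
    """
    if not fit.usable:
        raise ConfigurationError(
            "calibration fit is not usable (non-convergent or non-monotone); "
            "quantification refused"
        )
    if y >= fit.y0:
        raise AboveRangeError(
            f"inhibition {y:.4g}% at/above the plateau y0={fit.y0:.4g}%"
        )
    x = -fit.t * math.log((y - fit.y0) / fit.A)
    if x < fit.x_min * (1.0 - _REL_TOL):
        raise BelowRangeError(
            f"inhibition {y:.4g}% maps to {x:.4g} µg/mL, below the lowest "
            f"standard {fit.x_min:.4g} µg/mL"
        )
    if x > fit.x_max * (1.0 + _REL_TOL):
        raise AboveRangeError(
            f"inhibition {y:.4g}% maps to {x:.4g} µg/mL, above the highest "
            f"standard {fit.x_max:.4g} µg/mL"
        )
    return x


def ic50(fit: CalibrationFit) -> float:
    """Concentration producing 50% inhibition of antibody binding.

    Raises :class:`Ic50UnreachableError` when the curve never reaches 50%
    inside the validity range — typical for decellularized biomaterials
    with little residual antigen.
    """
    try:
        return invert_calibration(fit, 50.0)
    except (AboveRangeError, BelowRangeError) as exc:
        raise Ic50UnreachableError(
            f"50% inhibition not reachable within "
            f"[{fit.x_min:.4g}, {fit.x_max:.4g}] µg/mL: {exc}"
        ) from exc


def calibrate_plate(
    plate: PlateReadout,
    alpha: float = 0.05,
    set_ldl: bool = True,
) -> tuple[CalibrationFit, ControlSet]:
    """One-call calibration of a plate: aggregate the controls, form
    per-level inhibition rates from the standard wells, fit the curve
    and (optionally) determine the LDL from the same series."""
    controls = aggregate_controls(plate.wells)
    points = calibration_points_from_plate(plate, controls)
    fit = fit_calibration(points)
    if set_ldl and fit.usable:
        neg_sd = None
        neg_wells = plate.by_role("negative_reference")
        if len(neg_wells) >= 2:
            neg_inh = [
                inhibition_rate(controls.a, controls.b, w.od450) for w in neg_wells
            ]
            neg_sd = float(np.std(neg_inh, ddof=1))
        ldl, anchored = determine_ldl(points, alpha=alpha, negative_sd=neg_sd)
        fit.ldl = ldl
        fit.ldl_anchored = anchored
    return fit, controls


# ---------------------------------------------------------------------------
# Lower detection limit
# ---------------------------------------------------------------------------


def _level_detected(
    values: Sequence[float], alpha: float, negative_sd: float | None
) -> bool:
    """A level is detected when its replicate inhibition values are
    significantly greater than zero (one-sided one-sample t-test).  With
    fewer than 3 replicates the t-test is underpowered to the point of
    meaninglessness; fall back to mean > 3 × SD of the negative-reference
    inhibition values when that SD is supplied.
    """
    vals = np.asarray(values, dtype=float)
    if len(vals) >= 3:
        if np.ptp(vals) == 0.0:  # constant replicates: t undefined
            return float(vals[0]) > 0.0
        res = stats.ttest_1samp(vals, popmean=0.0, alternative="greater")
        return bool(res.pvalue < alpha)
    if negative_sd is None:
        raise ConfigurationError(
            "detectability with < 3 replicates needs negative_sd (SD of the "
            "negative-reference inhibition values) for the 3×SD rule"
        )
    return float(vals.mean()) > 3.0 * negative_sd


def determine_ldl(
    points: Sequence[CalibrationPoint],
    alpha: float = 0.05,
    negative_sd: float | None = None,
) -> tuple[float, bool]:
    """Lower detection limit from the standard dilution series.

    Working down the series, the LDL is the concentration one step above
    the highest level at which inhibition is no longer detectable.
    Returns ``(ldl, anchored)``: ``anchored`` is False when every tested
    level was detected, so the LDL is only bounded above by the lowest
    tested concentration.

    Raises :class:`AssayFailureError` when no level is detected, or when
    the top of the series is undetectable while lower levels are (a
    non-monotone detection pattern that indicates a failed run).
    """
    pts = sorted(points, key=lambda p: p.x)
    detected = [
        _level_detected(p.inhibition_values, alpha, negative_sd) for p in pts
    ]
    if not any(detected):
        raise AssayFailureError(
            "no calibration level shows detectable inhibition; assay failed"
        )
    if all(detected):
        return pts[0].x, False
    highest_undetected = max(i for i, d in enumerate(detected) if not d)
    if highest_undetected == len(pts) - 1:
        raise AssayFailureError(
            "highest standard concentration undetectable while lower levels "
            "are detected; non-monotone detection pattern"
        )
    return pts[highest_undetected + 1].x, True


# ---------------------------------------------------------------------------
# Epitope arithmetic
# ---------------------------------------------------------------------------


def mass_to_epitopes(
    mass_g: float, constants: ConversionConstants, basis: str = "per_reaction"
) -> EpitopeQuantity:
    """Epitope count carried by a mass (grams) of Gal-BSA."""
    if mass_g < 0:
        raise ConfigurationError(f"mass must be ≥ 0, got {mass_g}")
    return EpitopeQuantity(
        count=mass_g * constants.epitopes_per_gram,
        basis=basis,
        galbsa_equivalent_mass=mass_g,
    )


def epitopes_to_mass(quantity: EpitopeQuantity, constants: ConversionConstants) -> float:
    """Grams of Gal-BSA carrying the same epitope count (inverse of
    :func:`mass_to_epitopes`)."""
    return quantity.count / constants.epitopes_per_gram


# ---------------------------------------------------------------------------
# Sample quantification
# ---------------------------------------------------------------------------


def quantify_sample(
    fit: CalibrationFit,
    sample_wells: Sequence[PlateWell],
    controls: ControlSet,
    constants: ConversionConstants,
    dilution_factor: float = 1.0,
    mass_mg: float | None = None,
    cells: float | None = None,
    mass_basis: str = "wet",
    reaction_volume_ml: float = 0.1,
    sample_id: str | None = None,
) -> SampleResult:
    """Quantify one sample replicate group against a fitted calibration.

    Steps: per-replicate inhibition rates → mean/SD → inverse prediction
    of the in-well concentration → dilution correction → epitopes per
    reaction (the ``reaction_volume_ml`` lysate aliquot loaded per well)
    → normalization per mg tissue or per cell.

    ``mass_mg`` / ``cells`` give the amount of tissue or the cell count
    represented in one reaction aliquot of the *undiluted* lysate.  Exactly
    one may be given; with neither, the result stays per-reaction.

    Out-of-range signals are converted to censoring flags, never to
    extrapolated numbers: below the detection limit → ``below_ldl`` (no
    count reported), above the plateau/top standard → ``above_range``.
    """
    if not sample_wells:
        raise ConfigurationError("no sample wells supplied")
    if reaction_volume_ml <= 0:
        raise ConfigurationError(
            f"reaction_volume_ml must be > 0, got {reaction_volume_ml}"
        )
    if mass_mg is not None and cells is not None:
        raise ConfigurationError("give mass_mg or cells, not both")
    for name, v in (("mass_mg", mass_mg), ("cells", cells)):
        if v is not None and v <= 0:
            raise ConfigurationError(f"{name} must be > 0, got {v}")
    if not fit.usable:
        raise ConfigurationError(
            "calibration fit is not usable (non-convergent or non-monotone); "
            "quantification refused"
        )
    if len(sample_wells) < 3:
        warnings.warn(
            f"sample group has {len(sample_wells)} replicate(s); the method "
            "calls for 3 parallel wells",
            stacklevel=2,
        )

    sid = sample_id or sample_wells[0].group_id or "sample"
    inh = np.array(
        [inhibition_rate(controls.a, controls.b, w.od450) for w in sample_wells]
    )
    inh_mean = float(inh.mean())
    inh_sd = float(inh.std(ddof=1)) if len(inh) >= 2 else None

    def _result(conc: float | None, quantity: EpitopeQuantity | None, flag: str):
        return SampleResult(
            sample_id=sid,
            inhibition_mean=inh_mean,
            inhibition_sd=inh_sd,
            concentration=conc,
            quantity=quantity,
            censoring=flag,
            dilution_factor=dilution_factor,
            n_replicates=len(sample_wells),
        )

    try:
        x_well = invert_calibration(fit, inh_mean)
    except BelowRangeError:
        return _result(None, None, "below_ldl")
    except AboveRangeError:
        return _result(None, None, "above_range")

    if fit.ldl is not None and x_well < fit.ldl:
        return _result(None, None, "below_ldl")

    concentration = x_well * dilution_factor
    galbsa_g = concentration * reaction_volume_ml * 1e-6  # µg/mL × mL → g
    per_reaction = mass_to_epitopes(galbsa_g, constants)

    if mass_mg is not None:
        basis = "per_mg_dry" if mass_basis in ("dry", "freeze_dried") else "per_mg_wet"
        quantity = EpitopeQuantity(
            count=per_reaction.count / mass_mg,
            basis=basis,
            galbsa_equivalent_mass=per_reaction.galbsa_equivalent_mass / mass_mg,
        )
    elif cells is not None:
        quantity = EpitopeQuantity(
            count=per_reaction.count / cells,
            basis="per_cell",
            galbsa_equivalent_mass=per_reaction.galbsa_equivalent_mass / cells,
        )
    else:
        quantity = per_reaction

    return _result(concentration, quantity, "quantified")


def antigen_reduction(untreated: EpitopeQuantity, treated: EpitopeQuantity) -> float:
    """Percent antigen reduction of a treated (e.g. decellularized)
    material relative to its untreated counterpart, on the same basis."""
    if untreated.basis != treated.basis:
        raise ConfigurationError(
            f"basis mismatch: untreated {untreated.basis!r} vs treated "
            f"{treated.basis!r}"
        )
    if untreated.count <= 0:
        raise ConfigurationError("untreated count must be > 0 for a reduction")
    return 100.0 * (1.0 - treated.count / untreated.count)
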