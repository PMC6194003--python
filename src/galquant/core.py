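"""Domain types for quantitative α-Gal antigen determination.

The assay is an inhibition ELISA: sample antigen depletes a monoclonal
anti-Gal IgM (M86) before the antibody is offered a Gal-BSA-coated plate,
so the OD450 signal *decreases* with increasing antigen.  Everything
downstream — inhibition rates, the exponential-saturation calibration
curve, epitope counting, QC gates — is expressed in terms of the small
set of types defined here.

Concentrations are Gal-BSA-equivalent µg/mL on the pre-mix lysate basis
(before the 1:1 mix with antibody solution).  Epitope counts are plain
floats: realistic tissue loads exceed 1e14 per mg, far past exact-integer
territory, and no arithmetic here needs integer semantics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

__all__ = [
    "AVOGADRO",
    "WellRole",
    "ROLES",
    "GalQuantError",
    "PlateInvalidError",
    "ConfigurationError",
    "InsufficientDesignError",
    "BelowRangeError",
    "AboveRangeError",
    "Ic50UnreachableError",
    "AssayFailureError",
    "PlateWell",
    "PlateReadout",
    "ControlSet",
    "CalibrationPoint",
    "CalibrationFit",
    "ConversionConstants",
    "build_conversion_constants",
    "EpitopeQuantity",
    "SampleResult",
    "ReferenceMaterialSpec",
    "GateResult",
    "QCReport",
    "round_half_away",
    "format_count",
    "format_percent",
    "signif",
]

AVOGADRO = 6.02214e23  # molecules per mole

WellRole = Literal[
    "blank",
    "full_reaction_control",
    "standard",
    "sample",
    "positive_reference",
    "negative_reference",
]

ROLES: frozenset[str] = frozenset(
    (
        "blank",
        "full_reaction_control",
        "standard",
        "sample",
        "positive_reference",
        "negative_reference",
    )
)


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------


class GalQuantError(Exception):
    """Base class for all errors raised by this package."""


class PlateInvalidError(GalQuantError):
    """The plate has no usable signal window (e.g. control OD ≤ blank OD)."""


class ConfigurationError(GalQuantError):
    """A required role, field or parameter is missing or inconsistent."""


class InsufficientDesignError(GalQuantError):
    """Too few distinct calibration levels (or replicates) for the request."""


class BelowRangeError(GalQuantError):
    """Signal corresponds to a concentration below the calibrated range."""


class AboveRangeError(GalQuantError):
    """Signal at/above the curve plateau or beyond the highest standard."""


class Ic50UnreachableError(GalQuantError):
    """The fitted curve never reaches 50% inhibition inside its range."""


class AssayFailureError(GalQuantError):
    """No calibration level was detectable; the run cannot set an LDL."""


# ---------------------------------------------------------------------------
# Plate-level types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlateWell:
    """A single well of a 96-well plate.

    ``concentration`` (Gal-BSA-equivalent µg/mL, pre-mix lysate basis) is
    required for ``role="standard"`` and forbidden elsewhere.
    """

    row: str
    column: int
    role: str
    od450: float
    group_id: str = ""
    concentration: float | None = None

    def __post_init__(self) -> None:
        if self.row not in "ABCDEFGH" or len(self.row) != 1:
            raise ConfigurationError(f"well row must be A–H, got {self.row!r}")
        if not 1 <= self.column <= 12:
            raise ConfigurationError(f"well column must be 1–12, got {self.column}")
        if self.role not in ROLES:
            raise ConfigurationError(
                f"unknown well role {self.role!r}; allowed: {sorted(ROLES)}"
            )
        if not math.isfinite(self.od450) or self.od450 < 0:
            raise ConfigurationError(
                f"od450 must be finite and ≥ 0, got {self.od450} at {self.well_id}"
            )
        if self.role == "standard":
            if self.concentration is None or self.concentration <= 0:
                raise ConfigurationError(
                    f"standard well {self.well_id} requires concentration > 0"
                )
        elif self.concentration is not None:
            raise ConfigurationError(
                f"well {self.well_id} with role {self.role!r} must not carry "
                "a concentration"
            )

    @property
    def well_id(self) -> str:
        return f"{self.row}{self.column}"


@dataclass
class PlateReadout:
    """All wells of one plate read.  Well positions must be unique."""

    wells: list[PlateWell]
    plate_id: str = "plate"

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for w in self.wells:
            if w.well_id in seen:
                raise ConfigurationError(f"duplicate well {w.well_id}")
            seen.add(w.well_id)

    def by_role(self, role: str) -> list[PlateWell]:
        if role not in ROLES:
            raise ConfigurationError(f"unknown role {role!r}")
        return [w for w in self.wells if w.role == role]

    def groups(self, role: str) -> dict[str, list[PlateWell]]:
        """Replicate groups (ordered by first appearance) for one role."""
        out: dict[str, list[PlateWell]] = {}
        for w in self.by_role(role):
            out.setdefault(w.group_id, []).append(w)
        return out


@dataclass(frozen=True)
class ControlSet:
    """Plate-level anchors of the inhibition-rate formula.

    ``a`` is the mean OD of the 100% reaction (non-inhibitory) control,
    ``b`` the mean OD of the blank.  A plate with a ≤ b has no signal
    window and is invalid.
    """

    a: float
    b: float
    n_control: int
    n_blank: int

    def __post_init__(self) -> None:
        if self.a <= self.b:
            raise PlateInvalidError(
                f"100% control OD (a={self.a:.4g}) must exceed blank OD "
                f"(b={self.b:.4g}); no non-inhibitory signal window"
            )


@dataclass(frozen=True)
class CalibrationPoint:
    """One standard concentration with its per-replicate inhibition rates (%)."""

    x: float
    inhibition_values: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.x <= 0:
            raise ConfigurationError(f"standard concentration must be > 0, got {self.x}")
        if len(self.inhibition_values) < 1:
            raise ConfigurationError(f"no replicate values at x={self.x}")

    @property
    def mean(self) -> float:
        return sum(self.inhibition_values) / len(self.inhibition_values)


@dataclass
class CalibrationFit:
    """Parameters of the exponential-saturation calibration curve
    Y = A·exp(−x/t) + y0, with its validity range and detection limit.

    For a usable inhibition curve A < 0 and t > 0, so Y increases
    monotonically from A + y0 at x = 0 towards the plateau y0.
    """

    A: float
    t: float
    y0: float
    residual_ss: float
    converged: bool
    x_min: float
    x_max: float
    ldl: float | None = None
    ldl_anchored: bool = True  # False when every level was detected
    n_points: int = 0

    def __post_init__(self) -> None:
        if self.t <= 0:
            raise ConfigurationError(f"decay scale t must be > 0, got {self.t}")
        if not self.x_min < self.x_max:
            raise ConfigurationError("x_min must be < x_max")
        if self.ldl is not None and not (self.x_min <= self.ldl <= self.x_max):
            raise ConfigurationError(
                f"ldl={self.ldl} outside validity range [{self.x_min}, {self.x_max}]"
            )

    @property
    def monotone(self) -> bool:
        """Strictly increasing inhibition over the validity range."""
        return self.A < 0 and self.t > 0

    @property
    def usable(self) -> bool:
        return self.converged and self.monotone


# ---------------------------------------------------------------------------
# Epitope arithmetic types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConversionConstants:
    """Traceable constants converting Gal-BSA mass to epitope counts.

    Gal-BSA is BSA (66.33 kDa) carrying ~20 α-Gal epitopes per molecule,
    giving ≈9.08×10^18 molecules/g and ≈1.82×10^20 epitopes/g.
    """

    bsa_molar_mass_kda: float
    epitopes_per_molecule: float
    avogadro: float
    molecules_per_gram: float
    epitopes_per_gram: float


def build_conversion_constants(
    bsa_molar_mass_kda: float = 66.33,
    epitopes_per_molecule: float = 20.0,
    avogadro: float = AVOGADRO,
) -> ConversionConstants:
    """Derive molecule and epitope densities per gram of Gal-BSA.

    molecules/g = N_A / M (g/mol); epitopes/g = molecules/g × epitopes
    per molecule.
    """
    if bsa_molar_mass_kda <= 0:
        raise ConfigurationError(
            f"bsa_molar_mass_kda must be > 0, got {bsa_molar_mass_kda}"
        )
    if epitopes_per_molecule < 1:
        raise ConfigurationError(
            f"epitopes_per_molecule must be ≥ 1, got {epitopes_per_molecule}"
        )
    molar_mass_g = bsa_molar_mass_kda * 1000.0
    molecules = avogadro / molar_mass_g
    return ConversionConstants(
        bsa_molar_mass_kda=bsa_molar_mass_kda,
        epitopes_per_molecule=epitopes_per_molecule,
        avogadro=avogadro,
        molecules_per_gram=molecules,
        epitopes_per_gram=molecules * epitopes_per_molecule,
    )


Basis = Literal["per_reaction", "per_mg_wet", "per_mg_dry", "per_cell"]

BASES: frozenset[str] = frozenset(
    ("per_reaction", "per_mg_wet", "per_mg_dry", "per_cell")
)


@dataclass(frozen=True)
class EpitopeQuantity:
    """An epitope count together with its normalization basis and the
    Gal-BSA mass (grams) carrying the same number of epitopes."""

    count: float
    basis: str
    galbsa_equivalent_mass: float

    def __post_init__(self) -> None:
        if self.basis not in BASES:
            raise ConfigurationError(
                f"unknown basis {self.basis!r}; allowed: {sorted(BASES)}"
            )
        if self.count < 0:
            raise ConfigurationError(f"epitope count must be ≥ 0, got {self.count}")


Censoring = Literal["quantified", "below_ldl", "above_range"]


@dataclass
class SampleResult:
    """Outcome of quantifying one sample replicate group."""

    sample_id: str
    inhibition_mean: float
    inhibition_sd: float | None
    concentration: float | None  # µg/mL Gal-BSA-equivalent, dilution-corrected
    quantity: EpitopeQuantity | None
    censoring: str
    dilution_factor: float = 1.0
    n_replicates: int = 0

    def __post_init__(self) -> None:
        if self.censoring not in ("quantified", "below_ldl", "above_range"):
            raise ConfigurationError(f"unknown censoring flag {self.censoring!r}")
        if self.dilution_factor < 1:
            raise ConfigurationError(
                f"dilution_factor must be ≥ 1, got {self.dilution_factor}"
            )


@dataclass(frozen=True)
class ReferenceMaterialSpec:
    """Certified description of a run-control reference material."""

    kind: Literal["positive", "negative"]
    certified_value: float | None = None  # epitopes per mg (positive only)
    certified_sd: float | None = None
    certified_n: int | None = None
    storage_note: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("positive", "negative"):
            raise ConfigurationError(f"kind must be positive|negative, got {self.kind!r}")
        if self.kind == "positive" and (
            self.certified_value is None or self.certified_value <= 0
        ):
            raise ConfigurationError(
                "positive reference material requires certified_value > 0"
            )


@dataclass
class GateResult:
    """Pass/fail outcome of a single QC gate with its evidence."""

    passed: bool
    p_value: float | None = None
    statistic: float | None = None
    details: dict = field(default_factory=dict)


@dataclass
class QCReport:
    """Specificity / accuracy / repeatability gates for one run or method."""

    negative_gate: GateResult | None = None
    positive_gate: GateResult | None = None
    repeatability: dict | None = None


# ---------------------------------------------------------------------------
# Reporting precision helpers
# ---------------------------------------------------------------------------


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round with ties going away from zero (lab-report convention),
    unlike Python's banker's rounding."""
    if not math.isfinite(x):
        return x
    factor = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


def format_count(count: float, sig: int = 3) -> str:
    """Format an epitope count to `sig` significant figures, e.g. 6.66e+14."""
    if count == 0:
        return "0"
    return f"{count:.{sig - 1}e}"


def format_percent(value: float) -> str:
    """Percentages to 2 decimals, ties away from zero."""
    return f"{round_half_away(value, 2):.2f}"


def signif(x: float, digits: int) -> float:
    """Round to a number of significant figures (half away from zero)."""
    if x == 0 or not math.isfinite(x):
        return x
    exponent = math.floor(math.log10(abs(x)))
    return round_half_away(x / 10.0**exponent, digits - 1) * 10.0**exponent
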