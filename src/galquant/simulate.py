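"""Synthetic plate generator: forward model from true antigen content to
noisy OD450 readings.

The forward model is the measurement chain run backwards.  A well whose
lysate carries Gal-BSA-equivalent concentration x has expected inhibition
Y(x) = A·e^(−x/t) + y0, hence expected OD

    c = b + (a − b) · (1 − Y(x)/100)

around the plate's control anchors a (100% reaction control) and b
(blank).  Realized ODs get multiplicative Gaussian noise — plate-reader
noise scales with signal — truncated at zero.  Controls and blanks are
drawn with the same noise model around a and b.

The defaults mirror the assay's reference conditions: the ten-level
Gal-BSA standard series from 20 down to 0.039 µg/mL in two-fold steps,
three parallel wells per group, control OD ≈ 1.16, and a read-noise CV
near the ~15% CV observed on real 100%-control replicates.  The truth
curve (A = −100, y0 = 100) anchors 0% inhibition at x = 0 and a 100%
plateau, the idealization the inhibition-rate formula implies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core import (
    ConfigurationError,
    ConversionConstants,
    PlateReadout,
    PlateWell,
    build_conversion_constants,
)

__all__ = [
    "DEFAULT_STANDARD_SERIES",
    "SampleSpec",
    "SimulationConfig",
    "simulate_plate",
    "simulate_validation_dataset",
    "concentration_for_load",
]

# Two-fold Gal-BSA dilution series of the reference protocol (µg/mL).
DEFAULT_STANDARD_SERIES: tuple[float, ...] = (
    20.0, 10.0, 5.0, 2.5, 1.25, 0.625, 0.313, 0.156, 0.078, 0.039,
)


def concentration_for_load(
    epitopes_per_mg: float,
    mass_mg: float,
    constants: ConversionConstants | None = None,
    reaction_volume_ml: float = 0.1,
) -> float:
    """Lysate concentration (µg/mL Gal-BSA equivalent) such that one
    reaction aliquot carrying ``mass_mg`` of tissue contains
    ``epitopes_per_mg × mass_mg`` epitopes."""
    constants = constants or build_conversion_constants()
    mass_g = epitopes_per_mg * mass_mg / constants.epitopes_per_gram
    return mass_g * 1e6 / reaction_volume_ml  # g → µg, per mL


@dataclass(frozen=True)
class SampleSpec:
    """A simulated test sample.

    ``true_concentration`` is the Gal-BSA-equivalent concentration of the
    undiluted lysate (µg/mL); the well sees it divided by
    ``dilution_factor``.
    """

    sample_id: str
    true_concentration: float
    dilution_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.true_concentration < 0:
            raise ConfigurationError("true_concentration must be ≥ 0")
        if self.dilution_factor < 1:
            raise ConfigurationError("dilution_factor must be ≥ 1")


@dataclass
class SimulationConfig:
    """Truth parameters and plate layout for one simulated run."""

    truth_A: float = -100.0
    truth_t: float = 3.0
    truth_y0: float = 100.0
    control_od_a: float = 1.16
    blank_od_b: float = 0.10
    noise_cv: float = 15.0  # % multiplicative OD noise
    standard_series: Sequence[float] = DEFAULT_STANDARD_SERIES
    replicates: int = 3
    samples: Sequence[SampleSpec] = field(default_factory=tuple)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.control_od_a > self.blank_od_b >= 0:
            raise ConfigurationError(
                "need control_od_a > blank_od_b ≥ 0, got "
                f"a={self.control_od_a}, b={self.blank_od_b}"
            )
        if self.noise_cv < 0:
            raise ConfigurationError(f"noise_cv must be ≥ 0, got {self.noise_cv}")
        if self.replicates < 1:
            raise ConfigurationError(f"replicates must be ≥ 1, got {self.replicates}")
        if self.truth_t <= 0:
            raise ConfigurationError(f"truth_t must be > 0, got {self.truth_t}")
        if any(x <= 0 for x in self.standard_series):
            raise ConfigurationError("standard concentrations must be > 0")

    def expected_inhibition(self, x: float) -> float:
        return self.truth_A * math.exp(-x / self.truth_t) + self.truth_y0

    def expected_od(self, x: float) -> float:
        y = self.expected_inhibition(x)
        return self.blank_od_b + (self.control_od_a - self.blank_od_b) * (1.0 - y / 100.0)


class _WellCursor:
    """Row-major A1–H12 well allocator."""

    def __init__(self) -> None:
        self.index = 0

    def next(self) -> tuple[str, int]:
        if self.index >= 96:
            raise ConfigurationError("plate layout exceeds 96 wells")
        row = "ABCDEFGH"[self.index // 12]
        col = self.index % 12 + 1
        self.index += 1
        return row, col


def _noisy(rng: np.random.Generator, expected: float, cv: float) -> float:
    od = expected * (1.0 + rng.normal(0.0, cv / 100.0))
    return max(od, 0.0)


def simulate_plate(config: SimulationConfig, plate_id: str = "sim") -> PlateReadout:
    """Generate one noisy plate: blanks, 100% controls, the standard
    series and any configured samples, laid out row-major from A1.

    Deterministic for a fixed ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    cursor = _WellCursor()
    wells: list[PlateWell] = []

    for _ in range(config.replicates):
        row, col = cursor.next()
        wells.append(
            PlateWell(row, col, "blank",
                      _noisy(rng, config.blank_od_b, config.noise_cv), "blank")
        )
    for _ in range(config.replicates):
        row, col = cursor.next()
        wells.append(
            PlateWell(row, col, "full_reaction_control",
                      _noisy(rng, config.control_od_a, config.noise_cv), "control")
        )
    for x in config.standard_series:
        expected = config.expected_od(x)
        for _ in range(config.replicates):
            row, col = cursor.next()
            wells.append(
                PlateWell(row, col, "standard", _noisy(rng, expected, config.noise_cv),
                          f"std_{x:g}", concentration=x)
            )
    for spec in config.samples:
        x_well = spec.true_concentration / spec.dilution_factor
        expected = config.expected_od(x_well)
        for _ in range(config.replicates):
            row, col = cursor.next()
            wells.append(
                PlateWell(row, col, "sample", _noisy(rng, expected, config.noise_cv),
                          spec.sample_id)
            )
    return PlateReadout(wells=wells, plate_id=plate_id)


def simulate_validation_dataset(
    config: SimulationConfig, n_plates: int
) -> list[PlateReadout]:
    """Independent plates with sub-seeds ``seed + plate index`` — simple
    and reproducible.  Used for stochastic parameter-recovery studies."""
    if n_plates < 1:
        raise ConfigurationError(f"n_plates must be ≥ 1, got {n_plates}")
    plates = []
    for i in range(n_plates):
        cfg = SimulationConfig(
            truth_A=config.truth_A,
            truth_t=config.truth_t,
            truth_y0=config.truth_y0,
            control_od_a=config.control_od_a,
            blank_od_b=config.blank_od_b,
            noise_cv=config.noise_cv,
            standard_series=config.standard_series,
            replicates=config.replicates,
            samples=config.samples,
            seed=config.seed + i,
        )
        plates.append(simulate_plate(cfg, plate_id=f"sim_{i:03d}"))
    return plates
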