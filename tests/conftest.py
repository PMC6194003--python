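"""Shared fixtures: the method's published reference datasets (transcribed
printed determinations) and small simulated plates."""

from __future__ import annotations

import pytest

import galquant as gq

# Specificity study, n = 9 per group: ODs of the 100% reaction control
# (M86 + lysis buffer) and of the Gal-antigen-negative reference material.
CONTROL_ODS = [0.93, 1.30, 1.33, 1.10, 1.36, 1.07, 1.37, 0.99, 1.00]
NEGATIVE_REF_ODS = [1.12, 1.64, 0.92, 1.14, 1.17, 1.10, 1.30, 1.55, 1.20]

# Homogeneity study of the positive reference material: nine independent
# content determinations, in units of 1e14 epitopes/mg freeze-dried.
POSITIVE_REF_CONTENT = [5.78, 6.88, 6.81, 5.45, 6.65, 6.83, 6.65, 6.44, 8.43]

# Repeatability study: IC50 (µg/mL Gal-BSA) of the positive reference,
# four inter-day and four intra-day determinations.
IC50_INTER_DAY = [6.65, 6.62, 5.73, 6.94]
IC50_INTRA_DAY = [6.08, 5.71, 5.07, 4.60]

# Stability study of the positive reference material: per storage
# condition (mean, sd, n) in 1e14 epitopes/mg, against the certified
# summary (6.66, 0.83, 9).  Conditions marked degraded in the study:
# 37 °C day 3 and day 7.
STABILITY_GROUPS = {
    "-20C_month_1": (6.06, 0.20, 3),
    "-20C_month_6": (6.71, 0.10, 3),
    "-20C_month_12": (6.97, 0.20, 3),
    "freeze_thaw_1": (6.49, 0.62, 3),
    "freeze_thaw_3": (6.73, 0.15, 3),
    "freeze_thaw_5": (6.48, 0.23, 3),
    "4C_day_3": (6.40, 0.49, 3),
    "4C_day_7": (6.31, 0.40, 3),
    "4C_day_14": (6.16, 0.49, 3),
    "4C_day_30": (5.87, 1.02, 3),
    "25C_day_3": (7.49, 0.72, 3),
    "25C_day_7": (6.70, 1.83, 3),
    "25C_day_14": (7.10, 1.19, 3),
    "37C_day_1": (6.24, 1.31, 3),
    "37C_day_3": (4.34, 0.81, 3),
    "37C_day_7": (4.67, 0.69, 3),
}
DEGRADED_CONDITIONS = {"37C_day_3", "37C_day_7"}
IDENTIFIED_SUMMARY = (6.66, 0.83, 9)


@pytest.fixture(scope="session")
def constants() -> gq.ConversionConstants:
    return gq.build_conversion_constants()


@pytest.fixture
def noiseless_plate() -> gq.PlateReadout:
    cfg = gq.SimulationConfig(
        noise_cv=0.0,
        samples=(gq.SampleSpec("s_mid", 3.0), gq.SampleSpec("s_low", 0.2)),
        seed=11,
    )
    return gq.simulate_plate(cfg)


@pytest.fixture
def noiseless_fit(noiseless_plate):
    fit, controls = gq.calibrate_plate(noiseless_plate)
    return fit, controls
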