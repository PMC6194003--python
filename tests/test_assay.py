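"""Quantification core: inhibition rates, calibration fit/inversion,
IC50, detection limit, epitope arithmetic and sample quantification."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import galquant as gq
from galquant.core import CalibrationFit


def make_fit(A=-100.0, t=2.885, y0=100.0, x_min=0.039, x_max=20.0, ldl=None):
    return CalibrationFit(
        A=A, t=t, y0=y0, residual_ss=0.0, converged=True,
        x_min=x_min, x_max=x_max, ldl=ldl,
    )


class TestInhibitionRate:
    @pytest.mark.parametrize(
        "a, b, c, d, expected",
        [
            (1.16, 0.10, 1.16, 0.10, 0.0),     # sample equals the 100% control
            (1.20, 0.10, 0.10, 0.10, 100.0),   # complete inhibition
            (1.20, 0.10, 0.65, 0.10, 50.0),    # half of the signal window
        ],
    )
    def test_hand_computed_values(self, a, b, c, d, expected):
        assert gq.inhibition_rate(a, b, c, d) == pytest.approx(expected)

    def test_shared_blank_default(self):
        assert gq.inhibition_rate(1.20, 0.10, 0.65) == gq.inhibition_rate(
            1.20, 0.10, 0.65, 0.10
        )

    def test_raw_values_outside_0_100_preserved(self):
        assert gq.inhibition_rate(1.0, 0.0, 1.5) == pytest.approx(-50.0)
        assert gq.inhibition_rate(1.0, 0.5, 0.25) == pytest.approx(150.0)

    def test_no_signal_window_is_plate_invalid(self):
        with pytest.raises(gq.PlateInvalidError):
            gq.inhibition_rate(0.10, 0.10, 0.05)

    @given(
        a=st.floats(0.5, 3.0),
        b=st.floats(0.0, 0.4),
        c=st.floats(0.0, 3.0),
        k=st.floats(0.1, 10.0),
    )
    @settings(derandomize=True, max_examples=100, deadline=None)
    def test_scale_invariance(self, a, b, c, k):
        """Scaling all four ODs by k > 0 leaves the rate unchanged (exactly
        up to float division), and shifting both members of each
        difference by a constant does too."""
        base = gq.inhibition_rate(a, b, c, b)
        assert gq.inhibition_rate(k * a, k * b, k * c, k * b) == pytest.approx(
            base, rel=1e-9, abs=1e-9
        )
        s = 0.25
        assert gq.inhibition_rate(a + s, b + s, c + s, b + s) == pytest.approx(
            base, rel=1e-9, abs=1e-9
        )


class TestAggregateControls:
    def test_reference_control_mean(self):
        from conftest import CONTROL_ODS

        wells = [
            gq.PlateWell("A", i + 1, "full_reaction_control", od)
            for i, od in enumerate(CONTROL_ODS)
        ] + [gq.PlateWell("B", 1, "blank", 0.05)]
        cs = gq.aggregate_controls(wells)
        assert cs.a == pytest.approx(1.16, abs=0.005)
        assert cs.n_control == 9 and cs.n_blank == 1

    def test_single_wells(self):
        cs = gq.aggregate_controls(
            [
                gq.PlateWell("A", 1, "full_reaction_control", 1.0),
                gq.PlateWell("A", 2, "blank", 0.0),
            ]
        )
        assert (cs.a, cs.b) == (1.0, 0.0)

    def test_missing_blank_names_role(self):
        with pytest.raises(gq.ConfigurationError, match="blank"):
            gq.aggregate_controls([gq.PlateWell("A", 1, "full_reaction_control", 1.0)])


class TestFitCalibration:
    def test_noiseless_recovery(self):
        xs = [0.039, 0.156, 0.625, 2.5, 5.0, 10.0, 20.0]
        truth = (-95.0, 2.0, 95.0)
        points = [
            gq.CalibrationPoint(
                x, (truth[0] * math.exp(-x / truth[1]) + truth[2],) * 3
            )
            for x in xs
        ]
        fit = gq.fit_calibration(points)
        assert fit.converged and fit.usable
        assert fit.A == pytest.approx(truth[0], rel=1e-6)
        assert fit.t == pytest.approx(truth[1], rel=1e-6)
        assert fit.y0 == pytest.approx(truth[2], rel=1e-6)
        assert (fit.x_min, fit.x_max) == (min(xs), max(xs))

    def test_zero_inhibition_everywhere_flagged_non_usable(self):
        points = [gq.CalibrationPoint(x, (0.0, 0.0, 0.0)) for x in [0.1, 1, 5, 20]]
        fit = gq.fit_calibration(points)
        assert not fit.usable  # no concentration dependence
        with pytest.raises(gq.ConfigurationError):
            gq.invert_calibration(fit, 10.0)

    def test_too_few_levels_rejected(self):
        points = [gq.CalibrationPoint(x, (10.0 * x,)) for x in [1.0, 2.0, 4.0]]
        with pytest.raises(gq.InsufficientDesignError):
            gq.fit_calibration(points)

    def test_noisy_recovery_of_decay_scale(self):
        """5% multiplicative OD noise, 3 replicates: t recovered within
        15% of truth."""
        cfg = gq.SimulationConfig(truth_t=3.0, noise_cv=5.0, seed=42)
        plate = gq.simulate_plate(cfg)
        fit, _ = gq.calibrate_plate(plate, set_ldl=False)
        assert fit.usable
        assert fit.t == pytest.approx(3.0, rel=0.15)

    def test_monotone_on_accepted_fits(self):
        cfg = gq.SimulationConfig(noise_cv=8.0, seed=3)
        fit, _ = gq.calibrate_plate(gq.simulate_plate(cfg), set_ldl=False)
        xs = np.linspace(fit.x_min, fit.x_max, 200)
        ys = gq.predict_inhibition(fit, xs)
        assert fit.monotone
        assert np.all(np.diff(ys) > 0)


class TestPredictInvert:
    def test_anchors_and_midpoint(self):
        fit = make_fit()
        assert gq.predict_inhibition(fit, 0.0) == pytest.approx(0.0)
        assert gq.predict_inhibition(fit, 1e6) == pytest.approx(100.0)
        # x = t·ln 2 gives 50% when y0 = −A = 100
        assert gq.predict_inhibition(fit, 2.885 * math.log(2)) == pytest.approx(50.0)

    def test_invert_closed_form(self):
        assert gq.invert_calibration(make_fit(), 50.0) == pytest.approx(
            2.885 * math.log(2)
        )

    def test_round_trip_identity(self):
        fit = make_fit()
        assert gq.invert_calibration(fit, gq.predict_inhibition(fit, 1.25)) == (
            pytest.approx(1.25, rel=1e-9)
        )

    @given(
        A=st.floats(-120.0, -40.0),
        t=st.floats(0.5, 10.0),
        y0=st.floats(60.0, 120.0),
        frac=st.floats(0.0, 1.0),
    )
    @settings(derandomize=True, max_examples=100, deadline=None)
    def test_round_trip_property_over_validity_range(self, A, t, y0, frac):
        # cap the range at 15 decay scales: past that the curve is within
        # float epsilon of its plateau and inversion is ill-posed
        x_max = min(20.0, 15.0 * t)
        fit = make_fit(A=A, t=t, y0=y0, x_min=0.039, x_max=x_max)
        x = 0.039 + frac * (x_max - 0.039)
        y = gq.predict_inhibition(fit, x)
        assert gq.invert_calibration(fit, y) == pytest.approx(x, rel=1e-9)

    def test_plateau_is_above_range(self):
        fit = make_fit()
        with pytest.raises(gq.AboveRangeError):
            gq.invert_calibration(fit, fit.y0)

    def test_below_lowest_standard_is_below_range(self):
        fit = make_fit(x_min=1.0)
        y_low = gq.predict_inhibition(fit, 0.5)
        with pytest.raises(gq.BelowRangeError):
            gq.invert_calibration(fit, y_low)


class TestIc50:
    def test_closed_form(self):
        assert gq.ic50(make_fit()) == pytest.approx(2.885 * math.log(2))

    def test_plateau_below_50_unreachable(self):
        # Low-antigen decellularized materials may never reach 50% inhibition
        with pytest.raises(gq.Ic50UnreachableError):
            gq.ic50(make_fit(A=-40.0, y0=40.0))

    def test_replicate_run_summary(self):
        from conftest import IC50_INTER_DAY

        stats = gq.summary_stats(IC50_INTER_DAY)
        assert stats.mean == pytest.approx(6.49, abs=0.01)
        assert stats.cv_percent == pytest.approx(8.07, abs=0.01)


class TestDetermineLdl:
    @staticmethod
    def _points(levels, detected_mask, rng):
        """Build replicate inhibition values: detected levels get a clear
        positive mean, undetected ones hover around zero."""
        pts = []
        for x, det in zip(levels, detected_mask):
            if det:
                vals = 10.0 + rng.normal(0, 0.5, size=3)
            else:
                vals = rng.normal(0, 1.0, size=3)
            pts.append(gq.CalibrationPoint(x, tuple(vals)))
        return pts

    def test_selection_rule(self):
        rng = np.random.default_rng(5)
        levels = [0.01, 0.02, 0.04, 0.08, 0.16]
        pts = self._points(levels, [False, False, True, True, True], rng)
        ldl, anchored = gq.determine_ldl(pts)
        assert ldl == 0.04 and anchored

    def test_all_detected_reports_unanchored_lowest(self):
        rng = np.random.default_rng(6)
        pts = self._points([0.1, 0.2, 0.4], [True, True, True], rng)
        ldl, anchored = gq.determine_ldl(pts)
        assert ldl == 0.1 and not anchored

    def test_nothing_detected_is_assay_failure(self):
        rng = np.random.default_rng(7)
        pts = self._points([0.1, 0.2], [False, False], rng)
        with pytest.raises(gq.AssayFailureError):
            gq.determine_ldl(pts)

    def test_lowest_series_level_detected_in_reference_design(self):
        """In a clean run of the reference two-fold series the 0.039 µg/mL
        level is still detectable, making it the (unanchored) LDL."""
        cfg = gq.SimulationConfig(noise_cv=1.0, seed=9)
        plate = gq.simulate_plate(cfg)
        fit, _ = gq.calibrate_plate(plate)
        assert fit.ldl == pytest.approx(0.039)

    def test_few_replicates_need_negative_sd(self):
        pts = [gq.CalibrationPoint(x, (5.0, 6.0)) for x in [0.1, 0.2, 0.4, 0.8]]
        with pytest.raises(gq.ConfigurationError, match="negative_sd"):
            gq.determine_ldl(pts)
        ldl, anchored = gq.determine_ldl(pts, negative_sd=1.0)
        assert ldl == 0.1 and not anchored


class TestEpitopeArithmetic:
    def test_one_gram_of_galbsa(self, constants):
        q = gq.mass_to_epitopes(1.0, constants)
        assert q.count == pytest.approx(1.82e20, rel=0.005)

    def test_zero_mass(self, constants):
        assert gq.mass_to_epitopes(0.0, constants).count == 0.0

    def test_detection_limit_reaction_load(self, constants):
        # 0.039 µg/mL × 0.1 mL reaction ≈ 7.1e11 epitopes
        q = gq.mass_to_epitopes(0.039 * 0.1 * 1e-6, constants)
        assert q.count == pytest.approx(7.1e11, rel=0.005)

    def test_negative_mass_rejected(self, constants):
        with pytest.raises(gq.ConfigurationError):
            gq.mass_to_epitopes(-1e-9, constants)

    @given(m1=st.floats(0, 1e-3), m2=st.floats(0, 1e-3))
    @settings(derandomize=True, max_examples=50, deadline=None)
    def test_linearity(self, m1, m2, constants):
        cc = constants
        assert gq.mass_to_epitopes(m1 + m2, cc).count == pytest.approx(
            gq.mass_to_epitopes(m1, cc).count + gq.mass_to_epitopes(m2, cc).count,
            rel=1e-12, abs=1e-6,
        )


class TestQuantifySample:
    def test_cell_basis_matches_reference_conversion(self, constants):
        """67.43e-7 µg Gal-BSA equivalent per cell ≈ 1.2e9 epitopes/cell
        (wild-type porcine fibroblast level)."""
        count = 67.43e-7 * 1e-6 * constants.epitopes_per_gram
        assert count == pytest.approx(1.22e9, rel=0.01)

    def test_noiseless_quantification_recovers_truth(
        self, noiseless_plate, noiseless_fit, constants
    ):
        fit, controls = noiseless_fit
        res = gq.quantify_sample(
            fit, noiseless_plate.groups("sample")["s_mid"], controls, constants,
            mass_mg=2.0,
        )
        assert res.censoring == "quantified"
        assert res.concentration == pytest.approx(3.0, rel=1e-6)
        expected = 3.0 * 0.1 * 1e-6 * constants.epitopes_per_gram / 2.0
        assert res.quantity.count == pytest.approx(expected, rel=1e-6)
        assert res.quantity.basis == "per_mg_wet"

    def test_below_ldl_censored_without_count(self, constants):
        fit = make_fit(ldl=1.0, x_min=0.039)
        controls = gq.ControlSet(a=1.2, b=0.1, n_control=3, n_blank=3)
        # OD giving inhibition that inverts below the LDL
        y = gq.predict_inhibition(fit, 0.5)
        od = controls.b + (controls.a - controls.b) * (1 - y / 100)
        wells = [gq.PlateWell("H", i + 1, "sample", od, "s") for i in range(3)]
        res = gq.quantify_sample(fit, wells, controls, constants)
        assert res.censoring == "below_ldl"
        assert res.quantity is None and res.concentration is None

    def test_above_plateau_censored_above_range(self, constants):
        fit = make_fit()
        controls = gq.ControlSet(a=1.2, b=0.1, n_control=3, n_blank=3)
        wells = [gq.PlateWell("H", i + 1, "sample", 0.1, "s") for i in range(3)]
        res = gq.quantify_sample(fit, wells, controls, constants)
        assert res.censoring == "above_range"

    def test_dilution_correction(self, constants):
        """A diluted aliquot of a too-concentrated lysate quantifies back
        to the undiluted concentration."""
        cfg = gq.SimulationConfig(
            noise_cv=0.0, samples=(gq.SampleSpec("s", 40.0, dilution_factor=8.0),),
            seed=2,
        )
        plate = gq.simulate_plate(cfg)
        fit, controls = gq.calibrate_plate(plate)
        res = gq.quantify_sample(
            fit, plate.groups("sample")["s"], controls, constants,
            dilution_factor=8.0,
        )
        assert res.censoring == "quantified"
        assert res.concentration == pytest.approx(40.0, rel=1e-6)

    def test_simulated_tissue_load_round_trip(self, constants):
        """True load 5e14 epitopes/mg at 10% OD noise: with ~15% one-sigma
        spread per plate, most of 10 sub-seeded plates recover within 15%
        and the median recovery is unbiased to that tolerance."""
        true_load = 5e14
        mass_mg = 0.05
        conc = gq.concentration_for_load(true_load, mass_mg, constants)
        cfg = gq.SimulationConfig(
            noise_cv=10.0, samples=(gq.SampleSpec("tissue", conc),), seed=123,
        )
        recovered = []
        for plate in gq.simulate_validation_dataset(cfg, 10):
            fit, controls = gq.calibrate_plate(plate, set_ldl=False)
            res = gq.quantify_sample(
                fit, plate.groups("sample")["tissue"], controls, constants,
                mass_mg=mass_mg, mass_basis="dry",
            )
            assert res.censoring == "quantified"
            recovered.append(res.quantity.count)
        hits = sum(abs(r - true_load) / true_load <= 0.15 for r in recovered)
        assert hits >= 7
        assert np.median(recovered) == pytest.approx(true_load, rel=0.15)

    def test_sub_triplicate_warns(self, constants):
        fit = make_fit()
        controls = gq.ControlSet(a=1.2, b=0.1, n_control=3, n_blank=3)
        wells = [gq.PlateWell("H", 1, "sample", 0.6, "s")]
        with pytest.warns(UserWarning, match="3 parallel"):
            gq.quantify_sample(fit, wells, controls, constants)


class TestAntigenReduction:
    @pytest.mark.parametrize(
        "untreated, treated, expected",
        [
            (2.49e15, 1.6e13, 99.36),  # decellularized dural graft vs pericardium
            (1.0, 1.0, 0.0),
            (1.0, 0.0, 100.0),
        ],
    )
    def test_reduction_percent(self, untreated, treated, expected):
        u = gq.EpitopeQuantity(untreated, "per_mg_wet", 0.0)
        t = gq.EpitopeQuantity(treated, "per_mg_wet", 0.0)
        assert gq.antigen_reduction(u, t) == pytest.approx(expected, abs=0.005)

    def test_basis_mismatch_rejected(self):
        u = gq.EpitopeQuantity(1.0, "per_mg_wet", 0.0)
        t = gq.EpitopeQuantity(1.0, "per_cell", 0.0)
        with pytest.raises(gq.ConfigurationError, match="basis"):
            gq.antigen_reduction(u, t)
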