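"""Traveling-wave calibration: polynomial and linearized power round-trips."""

import math

import numpy as np
import pytest

from driftccs.errors import CalibrationError, InsufficientDataError, InvalidInputError
from driftccs.io import CalibrantIon, Feature, FrameMetadata
from driftccs.physics import HELIUM, IonSpecies, NITROGEN, reduced_ccs
from driftccs.singlefield import fit_single_field
from driftccs.synth import SyntheticIon, make_twims_campaign
from driftccs.twims import (
    PolynomialTwimsModel,
    PowerTwimsModel,
    apply_twims_calibration,
    corrected_arrival_time,
    delta_ccs_percent,
    fit_polynomial,
    fit_power,
)


def _taa_like_calibrants():
    """Tetraalkylammonium-style singly-charged helium-gas calibrant ladder."""
    return [
        CalibrantIon("TAA8", 130.1590, 1, 82.0),
        CalibrantIon("TAA12", 186.2216, 1, 105.0),
        CalibrantIon("TAA16", 242.2842, 1, 125.0),
        CalibrantIon("TAA20", 298.3468, 1, 144.0),
        CalibrantIon("TAA24", 354.4094, 1, 162.0),
        CalibrantIon("TAA28", 410.4720, 1, 178.0),
    ]


def _quadratic_features(calibrants, coeffs, t_acc, gas=HELIUM):
    """Plant arrival times so that Omega' is exactly the given quadratic of t'."""
    c0, c1, c2 = coeffs
    feats = []
    for cal in calibrants:
        ion = IonSpecies(cal.mz, cal.charge_z, cal.polarity)
        omega_r = reduced_ccs(cal.reference_ccs, ion, gas)
        # invert c2 t'^2 + c1 t' + (c0 - omega_r) = 0 for the positive root
        disc = math.sqrt(c1**2 - 4 * c2 * (c0 - omega_r))
        t_prime = (-c1 + disc) / (2 * c2)
        feats.append(Feature(cal.mz, t_prime + t_acc, 1e5))
    return feats


class TestPolynomialFit:
    def test_exact_quadratic_recovery(self):
        cals = _taa_like_calibrants()
        coeffs = (5.0, 0.08, 1.5e-5)
        feats = _quadratic_features(cals, coeffs, t_acc=1000.0)
        cal = fit_polynomial(feats, cals, HELIUM, degree_D=2, t_acc=1000.0)
        assert cal.coefficients == pytest.approx(coeffs, rel=1e-9)
        assert cal.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_accumulation_time_subtracted(self):
        cals = _taa_like_calibrants()
        feats = _quadratic_features(cals, (5.0, 0.08, 1.5e-5), t_acc=1000.0)
        cal = fit_polynomial(feats, cals, HELIUM, degree_D=2, t_acc=1000.0)
        # stored range is on corrected times: raw arrivals minus the 1000 ms
        raw = sorted(f.arrival_time for f in feats)
        assert cal.tA_range[0] == pytest.approx(raw[0] - 1000.0, abs=1e-9)
        assert cal.tA_range[1] == pytest.approx(raw[-1] - 1000.0, abs=1e-9)

    def test_overdetermination_enforced(self):
        cals = _taa_like_calibrants()[:3]  # 3 points cannot fit a quadratic safely
        feats = _quadratic_features(cals, (5.0, 0.08, 1.5e-5), t_acc=0.0)
        with pytest.raises(InsufficientDataError):
            fit_polynomial(feats, cals, HELIUM, degree_D=2)

    def test_degree_one_matches_single_field_standard_fit(self, tune_mix_calibrants):
        # collinear points, t_acc = 0: linear TWIMS and single-field agree
        slope, t0 = 0.1625, 0.21
        feats = []
        for c in tune_mix_calibrants:
            ion = IonSpecies(c.mz, c.charge_z, c.polarity)
            x = reduced_ccs(c.reference_ccs, ion, NITROGEN)
            feats.append(Feature(c.mz, slope * x + t0, 1e5, run_id="r", field_id=1))
        meta = FrameMetadata("r", 1, 1450.0, 3.95, 28.0, 78.236,
                             "2026-01-05T08:00:00", "positive")
        linear_cal = fit_single_field(feats, tune_mix_calibrants, [meta], NITROGEN)
        poly_cal = fit_polynomial(feats, tune_mix_calibrants, NITROGEN, degree_D=1)
        unknown = [Feature(500.0, 30.0, 1.0)]
        from driftccs.singlefield import calibrate_features
        a = calibrate_features(unknown, linear_cal, NITROGEN)[0].ccs
        b = apply_twims_calibration(unknown, poly_cal, NITROGEN)[0].ccs
        assert a == pytest.approx(b, rel=1e-9)


class TestPowerFit:
    def test_exact_power_law_recovery(self):
        cals = _taa_like_calibrants()
        camp = make_twims_campaign(cals, [], X_true=0.55, Y_true=25.0,
                                   t_acc=1000.0, gas=HELIUM)
        cal = fit_power(camp.calibrant_features, cals, HELIUM, t_acc=1000.0)
        assert cal.exponent_X == pytest.approx(0.55, rel=1e-9)
        assert math.exp(cal.lnY) == pytest.approx(25.0, rel=1e-9)
        assert cal.final_slope_a == pytest.approx(camp.a_true, rel=1e-9)
        assert abs(cal.final_intercept_b) < 1e-8
        assert cal.r_squared_final == pytest.approx(1.0, abs=1e-12)

    def test_zero_edc_means_plain_accumulation_offset(self):
        assert corrected_arrival_time(1350.0, 322.0, edc_C=0.0, t_acc=1000.0) == 350.0

    def test_synapt_edc_subtracts_sqrt_mz_term(self):
        # EDC coefficient 1.45: t' loses 1.45*sqrt(m/z)/1000 ms
        tA, mz = 12.5, 322.0481
        expected = tA - 1.45 * math.sqrt(mz) / 1000.0
        assert corrected_arrival_time(tA, mz, edc_C=1.45, t_acc=0.0) == (
            pytest.approx(expected, rel=1e-14)
        )

    def test_nonpositive_corrected_time_names_ion(self):
        cals = _taa_like_calibrants()
        feats = [Feature(c.mz, 500.0, 1e5) for c in cals]  # all below t_acc
        with pytest.raises(CalibrationError, match="TAA8"):
            fit_power(feats, cals, HELIUM, t_acc=1000.0)

    def test_too_few_calibrants(self):
        cals = _taa_like_calibrants()[:2]
        feats = [Feature(c.mz, 1200.0, 1e5) for c in cals]
        with pytest.raises(InsufficientDataError):
            fit_power(feats, cals, HELIUM, t_acc=1000.0)


class TestApplyCalibration:
    def test_calibrant_self_prediction_exact(self):
        cals = _taa_like_calibrants()
        camp = make_twims_campaign(cals, [], X_true=0.55, Y_true=25.0,
                                   t_acc=1000.0, gas=HELIUM)
        cal = fit_power(camp.calibrant_features, cals, HELIUM, t_acc=1000.0)
        recs = apply_twims_calibration(camp.calibrant_features, cal, HELIUM)
        for rec, c in zip(recs, cals):
            assert rec.ccs == pytest.approx(c.reference_ccs, rel=1e-9)

    def test_out_of_range_feature_flagged_extrapolated(self):
        # a small-molecule feature arriving below the calibrant ladder
        cals = _taa_like_calibrants()
        small = SyntheticIon("pterin_like", 164.0574, 1, 63.85)
        camp = make_twims_campaign(cals, [small], X_true=0.55, Y_true=25.0,
                                   t_acc=1000.0, gas=HELIUM)
        cal = fit_power(camp.calibrant_features, cals, HELIUM, t_acc=1000.0)
        rec = apply_twims_calibration(camp.sample_features, cal, HELIUM)[0]
        assert "extrapolated" in rec.flags
        assert rec.ccs == pytest.approx(63.85, rel=1e-6)  # exact forward model

    def test_extrapolation_flag_monotone_on_each_side(self):
        cals = _taa_like_calibrants()
        feats = _quadratic_features(cals, (5.0, 0.08, 1.5e-5), t_acc=0.0)
        cal = fit_polynomial(feats, cals, HELIUM, degree_D=2)
        lo, hi = cal.tA_range
        probe_times = [lo * 0.5, lo * 0.8, (lo + hi) / 2, hi * 1.1, hi * 1.4]
        probes = [Feature(200.0, t, 1.0) for t in probe_times]
        flags = [
            "extrapolated" in r.flags
            for r in apply_twims_calibration(probes, cal, HELIUM)
        ]
        assert flags == [True, True, False, True, True]

    def test_horner_vs_naive_power_sum(self):
        coeffs = (5.0, 0.08, 1.5e-5, -2e-9)
        t = 420.0
        naive = sum(c * t**d for d, c in enumerate(coeffs))
        horner = float(np.polynomial.polynomial.polyval(t, coeffs))
        assert horner == pytest.approx(naive, rel=1e-12)

    def test_record_per_feature_never_dropped(self):
        cals = _taa_like_calibrants()
        feats = _quadratic_features(cals, (5.0, 0.08, 1.5e-5), t_acc=1000.0)
        cal = fit_polynomial(feats, cals, HELIUM, degree_D=2, t_acc=1000.0)
        probes = [Feature(200.0, 50.0, 1.0), Feature(200.0, 1400.0, 1.0)]
        recs = apply_twims_calibration(probes, cal, HELIUM)
        assert len(recs) == 2 and "invalid" in recs[0].flags


class TestDeltaCCS:
    @pytest.mark.parametrize(
        "a,ref,expected",
        [
            (58.51, 58.44, 0.12),
            (63.53, 58.44, 8.71),
            (104.50, 104.90, 0.38),
            (62.41, 63.85, 2.26),
        ],
    )
    def test_cross_platform_delta_cells(self, a, ref, expected):
        assert round(delta_ccs_percent(a, ref), 2) == expected

    def test_identity_is_zero(self):
        assert delta_ccs_percent(153.5, 153.5) == 0.0

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(InvalidInputError):
            delta_ccs_percent(100.0, 0.0)


class TestTwimsModels:
    def test_model_fit_predict_summary(self):
        cals = _taa_like_calibrants()
        camp = make_twims_campaign(cals, [], X_true=0.5, Y_true=30.0,
                                   t_acc=1000.0, gas=HELIUM)
        res = PowerTwimsModel(camp.calibrant_features, cals, HELIUM,
                              t_acc=1000.0).fit()
        assert "power" in res.summary()
        res2 = PolynomialTwimsModel(camp.calibrant_features, cals, HELIUM,
                                    t_acc=1000.0, degree_D=2).fit()
        assert "polynomial" in res2.summary()
        # gently curved power-law data: a quadratic approximates well in range
        assert res2.calibration.r_squared >= 0.999
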