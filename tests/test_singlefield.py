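"""Single-field calibration: fitting, run assignment, untargeted application."""

import numpy as np
import pytest

from driftccs.errors import AssignmentError, InsufficientDataError
from driftccs.io import CalibrantIon, Feature, FrameMetadata
from driftccs.physics import IonSpecies, NITROGEN, reduced_ccs
from driftccs.singlefield import (
    SingleFieldModel,
    assign_calibration_run,
    calibrate_features,
    fit_single_field,
)
from driftccs.synth import DriftScenario, SyntheticIon, make_single_field_campaign


def _meta(run_id="cal_run", ts="2026-01-05T10:00:00", P=3.95, T_C=28.0,
          polarity="positive"):
    return FrameMetadata(run_id, 1, 1450.0, P, T_C, 78.236, ts, polarity)


def _line_features(calibrants, slope, t0, gas=NITROGEN):
    feats = []
    for c in calibrants:
        ion = IonSpecies(c.mz, c.charge_z, c.polarity)
        x = reduced_ccs(c.reference_ccs, ion, gas)
        feats.append(Feature(c.mz, slope * x + t0, 1e5, run_id="cal_run", field_id=1))
    return feats


class TestFitSingleField:
    def test_two_point_exact_recovery(self):
        cals = [
            CalibrantIon("a", 322.0481, 1, 153.73),
            CalibrantIon("b", 622.0290, 1, 202.96),
        ]
        feats = _line_features(cals, slope=0.17, t0=0.25)
        cal = fit_single_field(feats, cals, [_meta()], NITROGEN, mode="standard")
        assert cal.slope == pytest.approx(0.17, rel=1e-12)
        assert cal.intercept_t0 == pytest.approx(0.25, rel=1e-9)
        assert cal.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_synthetic_run_recovery(self, tune_mix_calibrants):
        feats = _line_features(tune_mix_calibrants, slope=0.1625, t0=0.21)
        cal = fit_single_field(feats, tune_mix_calibrants, [_meta()], NITROGEN)
        assert cal.slope == pytest.approx(0.1625, rel=1e-9)
        assert cal.r_squared >= 1.0 - 1e-12
        assert cal.tA_range[0] < cal.tA_range[1]

    def test_insufficient_calibrants_lists_missing(self, tune_mix_calibrants):
        feats = _line_features(tune_mix_calibrants[:1], 0.17, 0.2)
        with pytest.raises(InsufficientDataError, match="cal622"):
            fit_single_field(feats, tune_mix_calibrants, [_meta()], NITROGEN)

    def test_standard_and_enhanced_agree_when_pt_constant(self, tune_mix_calibrants):
        feats = _line_features(tune_mix_calibrants, 0.1625, 0.21)
        meta = _meta()
        unknowns = [Feature(500.0, 30.0, 1.0, run_id="s", field_id=1)]
        for_modes = {}
        for mode in ("standard", "enhanced"):
            res = SingleFieldModel(feats, tune_mix_calibrants, [meta], NITROGEN,
                                   mode=mode).fit()
            for_modes[mode] = res.predict(unknowns, sample_conditions=[meta])[0].ccs
        assert for_modes["standard"] == pytest.approx(for_modes["enhanced"], rel=1e-9)


class TestAssignCalibrationRun:
    def _cal(self, run_id, ts, polarity="positive"):
        cals = [
            CalibrantIon("a", 322.0481, 1, 153.73, polarity),
            CalibrantIon("b", 622.0290, 1, 202.96, polarity),
        ]
        feats = _line_features(cals, 0.17, 0.2)
        return fit_single_field(
            feats, cals, [_meta(run_id, ts, polarity=polarity)], NITROGEN
        )

    def test_following_closest_wins(self):
        c9 = self._cal("c9", "2026-01-05T09:00:00")
        c11 = self._cal("c11", "2026-01-05T11:00:00")
        sample = _meta("s", "2026-01-05T10:00:00")
        chosen, fallback = assign_calibration_run(sample, [c9, c11])
        assert chosen.source_run == "c11" and not fallback

    def test_fallback_to_preceding_when_none_follow(self):
        c9 = self._cal("c9", "2026-01-05T09:00:00")
        sample = _meta("s", "2026-01-05T10:00:00")
        chosen, fallback = assign_calibration_run(sample, [c9])
        assert chosen.source_run == "c9" and fallback

    def test_opposite_polarity_only_raises(self):
        cneg = self._cal("cneg", "2026-01-05T09:00:00", polarity="negative")
        sample = _meta("s", "2026-01-05T10:00:00")
        with pytest.raises(AssignmentError):
            assign_calibration_run(sample, [cneg])

    def test_tie_broken_by_run_id(self):
        a = self._cal("cal_a", "2026-01-05T11:00:00")
        b = self._cal("cal_b", "2026-01-05T11:00:00")
        sample = _meta("s", "2026-01-05T10:00:00")
        chosen, _ = assign_calibration_run(sample, [b, a])
        assert chosen.source_run == "cal_a"


class TestCalibrateFeatures:
    def test_calibrant_self_consistency(self, tune_mix_calibrants):
        feats = _line_features(tune_mix_calibrants, 0.1625, 0.21)
        cal = fit_single_field(feats, tune_mix_calibrants, [_meta()], NITROGEN)
        recs = calibrate_features(feats, cal, NITROGEN)
        for rec, c in zip(recs, tune_mix_calibrants):
            assert rec.ccs == pytest.approx(c.reference_ccs, rel=1e-9)

    def test_output_count_matches_input_even_when_invalid(self, tune_mix_calibrants):
        feats = _line_features(tune_mix_calibrants, 0.1625, 0.21)
        cal = fit_single_field(feats, tune_mix_calibrants, [_meta()], NITROGEN)
        unknowns = [
            Feature(500.0, 30.0, 1.0),
            Feature(500.0, 0.05, 1.0),  # below t0 -> invalid, still a record
        ]
        recs = calibrate_features(unknowns, cal, NITROGEN)
        assert len(recs) == 2
        assert "invalid" in recs[1].flags and recs[1].ccs is None

    def test_out_of_range_flagged_extrapolated(self, tune_mix_calibrants):
        feats = _line_features(tune_mix_calibrants, 0.1625, 0.21)
        cal = fit_single_field(feats, tune_mix_calibrants, [_meta()], NITROGEN)
        lo, hi = cal.tA_range
        recs = calibrate_features(
            [Feature(2000.0, hi * 1.5, 1.0), Feature(500.0, (lo + hi) / 2, 1.0)],
            cal, NITROGEN,
        )
        assert "extrapolated" in recs[0].flags
        assert "extrapolated" not in recs[1].flags

    def test_charge_column_respected(self, tune_mix_calibrants):
        feats = _line_features(tune_mix_calibrants, 0.1625, 0.21)
        cal = fit_single_field(feats, tune_mix_calibrants, [_meta()], NITROGEN)
        f = Feature(500.0, 30.0, 1.0, extra={"charge": 2})
        rec = calibrate_features([f], cal, NITROGEN)[0]
        assert rec.charge_z == 2


class TestDriftCorrection:
    def test_enhanced_recovers_truth_under_step_drift(self, tune_mix_calibrants):
        samples = [SyntheticIon("rotenone_like", 395.1489, 1, 194.7)]
        scenario = DriftScenario(n_runs=24, pressure_model="step", seed=11)
        camp = make_single_field_campaign(tune_mix_calibrants, samples, scenario)

        def ccs_series(mode):
            cals = [
                SingleFieldModel(r.features, tune_mix_calibrants, [r.metadata],
                                 NITROGEN, mode=mode).fit().calibration
                for r in camp.calibrant_runs
            ]
            out = []
            for r in camp.sample_runs:
                chosen, _ = assign_calibration_run(r.metadata, cals)
                recs = calibrate_features(r.features, chosen, NITROGEN,
                                          sample_conditions=[r.metadata])
                out.append(recs[0].ccs)
            return np.array(out)

        enhanced = ccs_series("enhanced")
        standard = ccs_series("standard")
        assert np.allclose(enhanced, 194.7, rtol=1e-9)
        # the conventional mode is visibly biased on drifting runs
        assert np.abs(standard - 194.7).max() > 0.1
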