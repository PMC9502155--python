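"""Stepped-field regression: axis construction, combination search, replicates."""

import itertools
import math

import numpy as np
import pytest

from driftccs.errors import InsufficientDataError
from driftccs.io import FrameMetadata, Feature
from driftccs.physics import NITROGEN, ccs_to_mobility
from driftccs.stepped import (
    SteppedFieldModel,
    build_field_axis,
    enumerate_and_fit,
    summarize_replicates,
)
from driftccs.synth import SyntheticIon, make_stepped_field_campaign
from driftccs.targets import Match


def _meta(voltages, P=3.95, T_C=28.0, L=78.236):
    return [
        FrameMetadata("r", i + 1, v, P, T_C, L, "2026-01-05T08:00:00", "positive")
        for i, v in enumerate(voltages)
    ]


class TestFieldAxis:
    def test_x_inversely_proportional_to_voltage(self):
        x = build_field_axis(_meta([700.0, 1400.0]))
        assert x[0] == pytest.approx(2.0 * x[1], rel=1e-14)

    def test_seven_field_ladder_strictly_decreasing(self):
        x = build_field_axis(_meta(list(range(850, 1451, 100))))
        assert len(x) == 7
        assert all(a > b for a, b in zip(x, x[1:]))

    def test_independent_arithmetic_oracle(self):
        metas = _meta([850.0, 1250.0], P=4.0, T_C=25.0, L=78.236)
        x = build_field_axis(metas)
        for m, got in zip(metas, x):
            expected = (
                1000.0 * 78.236**2 * (273.15 / 760.0) * 4.0
                / ((25.0 + 273.15) * m.drift_voltage_V)
            )
            assert got == pytest.approx(expected, rel=1e-12)

    def test_insufficient_fields_rejected(self):
        with pytest.raises(InsufficientDataError):
            build_field_axis(_meta([850.0]))
        with pytest.raises(InsufficientDataError):
            build_field_axis(_meta([850.0, 850.0]))


def _plant_matches(x, K0, t0=0.2, intensity=100.0, mz=322.0481):
    return [
        [Match(Feature(mz, float(xi / K0 + t0), intensity), 0.0)] for xi in x
    ]


class TestEnumerateAndFit:
    def test_noiseless_ion_recovered_exactly(self, protonated_322_target, nitrogen):
        metas = _meta(list(range(850, 1451, 100)))
        x = build_field_axis(metas)
        K0_true = 1.3667
        cands = _plant_matches(x, K0_true)
        fits = enumerate_and_fit(
            protonated_322_target, cands, x, [m.temperature_K for m in metas], nitrogen
        )
        assert len(fits) == 1
        assert fits[0].K0 == pytest.approx(K0_true, rel=1e-9)
        assert 1.0 - fits[0].r_squared < 1e-12
        assert fits[0].intercept_t0 == pytest.approx(0.2, abs=1e-9)

    def test_gross_outlier_rejected_but_subset_passes(self, protonated_322_target, nitrogen):
        metas = _meta(list(range(850, 1451, 100)))
        x = build_field_axis(metas)
        cands = _plant_matches(x, 1.3667)
        # displace one field's candidate grossly
        bad = cands[3][0].feature
        cands[3] = [Match(Feature(bad.mz, bad.arrival_time * 2.0, bad.intensity), 0.0)]
        temps = [m.temperature_K for m in metas]
        field_ids = [m.field_id for m in metas]
        all_fields = enumerate_and_fit(
            protonated_322_target, cands, x, temps, nitrogen, min_fields=7,
            field_ids=field_ids,
        )
        assert all_fields == []
        subset = enumerate_and_fit(
            protonated_322_target, cands, x, temps, nitrogen, min_fields=6,
            field_ids=field_ids,
        )
        assert subset and subset[0].n_fields == 6
        assert 4 not in subset[0].field_ids  # the displaced field (id 4) dropped

    def test_two_conformers_recovered_with_correct_pairing(
        self, protonated_322_target, nitrogen
    ):
        metas = _meta(list(range(850, 1451, 100)))
        x = build_field_axis(metas)
        temps = [m.temperature_K for m in metas]
        K0_a, K0_b = 1.40, 1.10  # > 0.5% apart in CCS so they are not merged
        cands = [
            [
                Match(Feature(322.0481, float(xi / K0_a + 0.2), 100.0), 0.0),
                Match(Feature(322.0481, float(xi / K0_b + 0.2), 60.0), 0.0),
            ]
            for xi in x
        ]
        fits = enumerate_and_fit(protonated_322_target, cands, x, temps, nitrogen)
        K0s = sorted(f.K0 for f in fits)
        assert K0s == pytest.approx([K0_b, K0_a], rel=1e-9)
        # each accepted fit pairs only features from its own planted line
        for f in fits:
            planted = 100.0 if abs(f.K0 - K0_a) < abs(f.K0 - K0_b) else 60.0
            assert {m.feature.intensity for m in f.features} == {planted}

    def test_brute_force_enumeration_oracle(self, protonated_322_target, nitrogen):
        """Independent exhaustive enumeration over <=3 candidates x 5 fields."""
        rng = np.random.default_rng(7)
        metas = _meta([850.0, 1000.0, 1150.0, 1300.0, 1450.0])
        x = build_field_axis(metas)
        temps = [m.temperature_K for m in metas]
        r2_threshold = 0.99
        cands = []
        for xi in x:
            k = rng.integers(1, 4)
            cands.append([
                Match(Feature(322.0481, float(xi / 1.3667 + 0.2)
                              * float(rng.uniform(0.97, 1.03)),
                              float(rng.uniform(10, 100))), 0.0)
                for _ in range(k)
            ])

        got = enumerate_and_fit(
            protonated_322_target, cands, x, temps, nitrogen,
            r2_threshold=r2_threshold, min_fields=5, merge_duplicates=False,
        )
        got_keys = {
            tuple(round(m.feature.arrival_time, 9) for m in f.features) for f in got
        }

        # oracle: plain itertools + polyfit, written independently
        expected_keys = set()
        for combo in itertools.product(*cands):
            ts = [m.feature.arrival_time for m in combo]
            slope, intercept = np.polyfit(x, ts, 1)
            pred = slope * x + intercept
            ss_res = float(np.sum((np.array(ts) - pred) ** 2))
            ss_tot = float(np.sum((np.array(ts) - np.mean(ts)) ** 2))
            r2 = 1.0 - ss_res / ss_tot
            if r2 >= r2_threshold and slope > 0:
                expected_keys.add(tuple(round(t, 9) for t in ts))
        assert got_keys == expected_keys

    def test_combination_count_bounded(self, protonated_322_target, nitrogen):
        metas = _meta([850.0, 1000.0, 1150.0])
        x = build_field_axis(metas)
        temps = [m.temperature_K for m in metas]
        cands = _plant_matches(x, 1.3667)
        fits = enumerate_and_fit(
            protonated_322_target, cands, x, temps, nitrogen, min_fields=2,
            merge_duplicates=False,
        )
        # with 1 candidate per field and skips allowed: C(3,3)+C(3,2) = 4 combos max
        assert len(fits) <= 4


class TestSteppedFieldModel:
    def test_campaign_roundtrip_via_model(self, protonated_322_target, nitrogen):
        ion = SyntheticIon("cal322", 322.0481, 1, 153.73)
        camp = make_stepped_field_campaign([ion], seed=3)
        model = SteppedFieldModel(
            protonated_322_target, camp.features_per_field, camp.metadata, nitrogen
        )
        res = model.fit()
        assert len(res.conformers) == 1
        assert res.conformers[0].ccs == pytest.approx(153.73, rel=1e-9)
        assert "153.7" in res.summary()

    def test_decoys_outside_tolerance_never_used(self, protonated_322_target, nitrogen):
        ion = SyntheticIon("cal322", 322.0481, 1, 153.73)
        camp = make_stepped_field_campaign([ion], decoy_ppm_offsets=(30.0,), seed=3)
        model = SteppedFieldModel(
            protonated_322_target, camp.features_per_field, camp.metadata, nitrogen,
            tol_ppm=20.0,
        )
        res = model.fit()
        assert len(res.conformers) == 1
        for m in res.conformers[0].features:
            assert "decoy" not in m.feature.extra


class TestReplicateSummary:
    def test_identical_replicates_zero_rsd(self):
        s = summarize_replicates([100.0, 100.0, 100.0])
        assert (s.mean_ccs, s.rsd_percent) == (100.0, 0.0)

    def test_hand_computed_mean_and_rsd(self):
        vals = [154.0, 154.6, 153.5]
        mean = sum(vals) / 3
        sd = math.sqrt(sum((v - mean) ** 2 for v in vals) / 2)
        s = summarize_replicates(vals)
        assert s.mean_ccs == pytest.approx(mean, rel=1e-12)
        assert s.rsd_percent == pytest.approx(100 * sd / mean, rel=1e-12)

    def test_single_replicate_flagged(self):
        s = summarize_replicates([154.0])
        assert s.rsd_percent == 0.0 and "single_replicate" in s.flags

    def test_empty_rejected(self):
        with pytest.raises(InsufficientDataError):
            summarize_replicates([])
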