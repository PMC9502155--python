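"""Synthetic IMS campaigns with known ground truth.

Every calibration mode in the package is exercised against data generated
by inverting the same physical forward models the calibrations assume:

* stepped-field: arrival times tA = x_field / K0_true + t0 across a ladder
  of drift voltages (default: the common 850–1450 V in 100 V steps of a
  commercial drift-tube QTOF);
* single-field: tA = s * Omega''(run P, T) + t0 with a fixed instrument
  slope s derived from the Mason–Schamp relation at the nominal drift
  temperature, interleaving calibrant and sample runs on a simulated
  timeline with configurable pressure/temperature drift;
* traveling-wave: arrival times obtained by inverting a power law
  Omega' = Y * t'^X, plus accumulation-time and EDC offsets.

All generators are pure functions of their parameters and seed: the same
inputs produce bit-identical campaigns.  Arrival-time noise is Gaussian and
multiplicative (a fraction of tA), default 0.  What these campaigns do not
emulate — peak shapes, isotope envelopes, chemical noise beyond simple
decoy features — is documented in the methods note.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from datetime import datetime, timedelta, timezone
from pathlib import Path

import numpy as np

from .errors import InvalidInputError
from .io import (
    CalibrantIon,
    CsvDialect,
    Feature,
    FrameMetadata,
    write_features_csv,
    write_frame_metadata,
)
from .physics import (
    BufferGas,
    HELIUM,
    IonSpecies,
    NITROGEN,
    ccs_to_mobility,
    celsius_to_kelvin,
    reduced_ccs,
)
from .stepped import build_field_axis

__all__ = [
    "SyntheticIon",
    "DriftScenario",
    "SteppedFieldCampaign",
    "SingleFieldCampaign",
    "TwimsCampaign",
    "make_stepped_field_campaign",
    "make_single_field_campaign",
    "make_twims_campaign",
    "DEFAULT_VOLTAGES",
    "TUNE_MIX_LIKE_IONS",
]

#: 850 -> 1450 V in 100 V increments: the 7-field drift-voltage ladder of a
#: standard commercial DTIMS stepped-field method
DEFAULT_VOLTAGES: tuple[float, ...] = tuple(float(v) for v in range(850, 1451, 100))

#: drift-tube geometry/conditions typical of a commercial 78 cm drift tube
DEFAULT_LENGTH_CM = 78.236
DEFAULT_PRESSURE_TORR = 3.95
DEFAULT_TEMPERATURE_C = 28.0
DEFAULT_T0_MS = 0.2

_EPOCH = datetime(2026, 1, 5, 8, 0, 0, tzinfo=timezone.utc)


@dataclass(frozen=True)
class SyntheticIon:
    """Ground-truth ion: name, m/z, charge and true CCS in the campaign gas."""

    name: str
    mz: float
    charge_z: int
    ccs: float
    polarity: str = "positive"

    def species(self) -> IonSpecies:
        return IonSpecies(self.mz, self.charge_z, self.polarity)

    def true_K0(self, gas: BufferGas, temperature_K: float) -> float:
        return ccs_to_mobility(self.ccs, self.species(), gas, temperature_K)


#: Agilent-tune-mix-like phosphazine singly-charged calibrant series
#: (m/z and nitrogen-gas CCS rounded to published single-field values)
TUNE_MIX_LIKE_IONS: tuple[SyntheticIon, ...] = (
    SyntheticIon("cal322", 322.0481, 1, 153.73),
    SyntheticIon("cal622", 622.0290, 1, 202.96),
    SyntheticIon("cal922", 922.0098, 1, 243.64),
    SyntheticIon("cal1222", 1221.9906, 1, 282.20),
    SyntheticIon("cal1522", 1521.9715, 1, 316.96),
)

DRIFT_MODELS = ("constant", "linear", "step", "random_walk")


@dataclass(frozen=True)
class DriftScenario:
    """Pressure/temperature drift program for a multi-run campaign.

    ``amplitude`` values are fractions of nominal: a 0.02 pressure amplitude
    spans +/-2% around the nominal pressure.  The ``step`` model produces
    three plateaus (low, nominal, high) in thirds of the timeline —
    mimicking discrete changes in instrument conditions; ``random_walk`` is
    a seeded bounded walk.
    """

    n_runs: int
    nominal_P: float = DEFAULT_PRESSURE_TORR  # Torr
    nominal_T_C: float = DEFAULT_TEMPERATURE_C
    pressure_model: str = "constant"
    temperature_model: str = "constant"
    pressure_amplitude: float = 0.02
    temperature_amplitude: float = 0.01
    noise_sd_tA: float = 0.0  # fraction of tA
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_runs < 1:
            raise InvalidInputError("scenario needs >= 1 run")
        for model in (self.pressure_model, self.temperature_model):
            if model not in DRIFT_MODELS:
                raise InvalidInputError(f"unknown drift model {model!r}; known: {DRIFT_MODELS}")

    def _series(self, model: str, nominal: float, amplitude: float,
                rng: np.random.Generator) -> np.ndarray:
        n = self.n_runs
        if model == "constant":
            return np.full(n, nominal)
        if model == "linear":
            ramp = np.linspace(-1.0, 1.0, n) if n > 1 else np.zeros(1)
            return nominal * (1.0 + amplitude * ramp)
        if model == "step":
            levels = np.array([-1.0, 0.0, 1.0])
            idx = np.minimum((np.arange(n) * 3) // max(n, 1), 2)
            return nominal * (1.0 + amplitude * levels[idx])
        # random_walk: bounded seeded walk
        steps = rng.normal(0.0, amplitude / 4.0, size=n)
        walk = np.clip(np.cumsum(steps), -amplitude, amplitude)
        return nominal * (1.0 + walk)

    def pressures(self, rng: np.random.Generator) -> np.ndarray:
        return self._series(self.pressure_model, self.nominal_P,
                            self.pressure_amplitude, rng)

    def temperatures_C(self, rng: np.random.Generator) -> np.ndarray:
        # amplitude applies to the Kelvin scale, then converted back
        t_k = self._series(self.temperature_model, celsius_to_kelvin(self.nominal_T_C),
                           self.temperature_amplitude, rng)
        return t_k - 273.15


# ---------------------------------------------------------------------------
# stepped-field campaign


@dataclass
class SteppedFieldCampaign:
    features_per_field: dict[int, list[Feature]]
    metadata: list[FrameMetadata]
    truth: dict[str, SyntheticIon]
    gas: BufferGas
    run_id: str

    def all_features(self) -> list[Feature]:
        return [f for feats in self.features_per_field.values() for f in feats]

    def write(self, outdir: str | Path, dialect: CsvDialect | None = None) -> dict[str, Path]:
        """Write features.csv and metadata.csv; returns the paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "features": outdir / "features.csv",
            "metadata": outdir / "metadata.csv",
        }
        write_features_csv(self.all_features(), paths["features"], dialect)
        write_frame_metadata(self.metadata, paths["metadata"])
        return paths


def make_stepped_field_campaign(
    ions: list[SyntheticIon],
    voltages: tuple[float, ...] = DEFAULT_VOLTAGES,
    pressure_torr: float = DEFAULT_PRESSURE_TORR,
    temperature_C: float = DEFAULT_TEMPERATURE_C,
    length_cm: float = DEFAULT_LENGTH_CM,
    t0_ms: float = DEFAULT_T0_MS,
    gas: BufferGas = NITROGEN,
    noise_sd_tA: float = 0.0,
    decoy_ppm_offsets: tuple[float, ...] = (),
    seed: int = 0,
    run_id: str = "stepped_run",
    polarity: str = "positive",
) -> SteppedFieldCampaign:
    """Generate a multi-field campaign with arrival times from Eq.-1 physics.

    Per ion and field, tA = x_field / K0_true + t0 (+ multiplicative
    Gaussian noise); K0_true follows from the ion's CCS at the campaign
    temperature.  Optional decoy features are planted at fixed ppm offsets
    from each ion with shuffled arrival times, to exercise m/z-tolerance
    filtering and the combination search.
    """
    if len(voltages) < 2:
        raise InvalidInputError("need >= 2 fields")
    rng = np.random.default_rng(seed)
    metadata = [
        FrameMetadata(
            run_id=run_id,
            field_id=i + 1,
            drift_voltage_V=v,
            pressure_P=pressure_torr,
            temperature_C=temperature_C,
            drift_length_L=length_cm,
            acquisition_timestamp=(_EPOCH + timedelta(seconds=30 * i)).isoformat(),
            polarity=polarity,
        )
        for i, v in enumerate(voltages)
    ]
    x = build_field_axis(metadata)
    T_K = celsius_to_kelvin(temperature_C)

    features: dict[int, list[Feature]] = {m.field_id: [] for m in metadata}
    for ion in ions:
        K0 = ion.true_K0(gas, T_K)
        base_intensity = float(rng.lognormal(mean=np.log(1e5), sigma=0.5))
        for m, x_n in zip(metadata, x):
            tA = x_n / K0 + t0_ms
            if noise_sd_tA > 0:
                tA *= 1.0 + rng.normal(0.0, noise_sd_tA)
            intensity = base_intensity * float(rng.uniform(0.8, 1.2))
            features[m.field_id].append(Feature(
                mz=ion.mz, arrival_time=tA, intensity=intensity,
                run_id=run_id, field_id=m.field_id,
            ))
            for k, ppm in enumerate(decoy_ppm_offsets):
                features[m.field_id].append(Feature(
                    mz=ion.mz * (1.0 + ppm / 1e6),
                    arrival_time=tA * float(rng.uniform(1.05, 1.3)),
                    intensity=intensity * 0.5,
                    run_id=run_id, field_id=m.field_id,
                    extra={"decoy": f"{ion.name}+{ppm}ppm#{k}"},
                ))
    return SteppedFieldCampaign(
        features_per_field=features, metadata=metadata,
        truth={ion.name: ion for ion in ions}, gas=gas, run_id=run_id,
    )


# ---------------------------------------------------------------------------
# single-field campaign


@dataclass
class SingleFieldRun:
    run_id: str
    is_calibrant_run: bool
    features: list[Feature]
    metadata: FrameMetadata


@dataclass
class SingleFieldCampaign:
    runs: list[SingleFieldRun]
    truth: dict[str, SyntheticIon]
    gas: BufferGas
    scenario: DriftScenario

    @property
    def calibrant_runs(self) -> list[SingleFieldRun]:
        return [r for r in self.runs if r.is_calibrant_run]

    @property
    def sample_runs(self) -> list[SingleFieldRun]:
        return [r for r in self.runs if not r.is_calibrant_run]

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        all_feats = [f for r in self.runs for f in r.features]
        paths = {
            "features": outdir / "features.csv",
            "metadata": outdir / "metadata.csv",
        }
        write_features_csv(all_feats, paths["features"])
        write_frame_metadata([r.metadata for r in self.runs], paths["metadata"])
        return paths


def make_single_field_campaign(
    calibrants: list[CalibrantIon],
    sample_ions: list[SyntheticIon],
    scenario: DriftScenario,
    calibrant_every: int = 10,
    voltage_V: float = 1450.0,
    length_cm: float = DEFAULT_LENGTH_CM,
    t0_ms: float = DEFAULT_T0_MS,
    gas: BufferGas = NITROGEN,
    run_spacing_min: float = 10.0,
    polarity: str = "positive",
) -> SingleFieldCampaign:
    """Interleave calibrant and sample runs on a timeline with P/T drift.

    Every ``calibrant_every``-th run (and the final run, so each sample has
    a following calibration) is a calibrant run.  Arrival times follow the
    linear-in-Omega'' model with the instrument slope fixed at the nominal
    temperature, i.e. tA = x(P_run, T_run)/K0(T_nominal) + t0 — the enhanced
    calibration's own forward model, exact when temperature's residual
    square-root effect on the slope is neglected.
    """
    if len(calibrants) < 2:
        raise InvalidInputError("need >= 2 calibrants")
    rng = np.random.default_rng(scenario.seed)
    pressures = scenario.pressures(rng)
    temps_C = scenario.temperatures_C(rng)
    T_nom_K = celsius_to_kelvin(scenario.nominal_T_C)

    def arrival_time(ccs: float, ion: IonSpecies, P: float, T_C: float) -> float:
        K0 = ccs_to_mobility(ccs, ion, gas, T_nom_K)
        x = (
            1000.0 * length_cm**2 * (273.15 / 760.0) * P
            / (celsius_to_kelvin(T_C) * voltage_V)
        )
        return x / K0 + t0_ms

    runs: list[SingleFieldRun] = []
    for i in range(scenario.n_runs):
        is_cal = (i % calibrant_every == 0) or (i == scenario.n_runs - 1)
        run_id = f"{'cal' if is_cal else 'sample'}_{i:04d}"
        meta = FrameMetadata(
            run_id=run_id, field_id=1, drift_voltage_V=voltage_V,
            pressure_P=float(pressures[i]), temperature_C=float(temps_C[i]),
            drift_length_L=length_cm,
            acquisition_timestamp=(_EPOCH + timedelta(minutes=run_spacing_min * i)).isoformat(),
            polarity=polarity,
        )
        feats: list[Feature] = []
        if is_cal:
            for cal in calibrants:
                ion = IonSpecies(cal.mz, cal.charge_z, cal.polarity)
                tA = arrival_time(cal.reference_ccs, ion, meta.pressure_P, meta.temperature_C)
                if scenario.noise_sd_tA > 0:
                    tA *= 1.0 + rng.normal(0.0, scenario.noise_sd_tA)
                feats.append(Feature(mz=cal.mz, arrival_time=tA,
                                     intensity=1e5, run_id=run_id, field_id=1))
        else:
            for s_ion in sample_ions:
                tA = arrival_time(s_ion.ccs, s_ion.species(), meta.pressure_P,
                                  meta.temperature_C)
                if scenario.noise_sd_tA > 0:
                    tA *= 1.0 + rng.normal(0.0, scenario.noise_sd_tA)
                feats.append(Feature(mz=s_ion.mz, arrival_time=tA,
                                     intensity=5e4, run_id=run_id, field_id=1))
        runs.append(SingleFieldRun(run_id, is_cal, feats, meta))

    return SingleFieldCampaign(
        runs=runs, truth={s.name: s for s in sample_ions}, gas=gas, scenario=scenario,
    )


# ---------------------------------------------------------------------------
# traveling-wave campaign


@dataclass
class TwimsCampaign:
    calibrant_features: list[Feature]
    calibrants: list[CalibrantIon]
    sample_features: list[Feature]
    truth: dict[str, SyntheticIon]
    gas: BufferGas
    X_true: float
    Y_true: float
    a_true: float  # = Y_true * sqrt(mB); final-line slope implied by the power law
    b_true: float  # = 0 under the exact power-law forward model
    t_acc: float
    edc_C: float


def make_twims_campaign(
    calibrants: list[CalibrantIon],
    sample_ions: list[SyntheticIon],
    X_true: float,
    Y_true: float,
    t_acc: float = 1000.0,
    edc_C: float = 0.0,
    noise_sd_tA: float = 0.0,
    gas: BufferGas = HELIUM,
    seed: int = 0,
) -> TwimsCampaign:
    """Generate TWIMS features by inverting the power law Omega' = Y t'^X.

    Per ion, t' = (Omega'/Y)^(1/X) and tA = t' + C*sqrt(m/z)/1000 + t_acc.
    Under this forward model the final calibration line is exactly
    Omega = Y*sqrt(mB) * t'' + 0, so the implied (a, b) are part of the
    returned ground truth.
    """
    if X_true <= 0 or Y_true <= 0:
        raise InvalidInputError("X_true and Y_true must be > 0")
    rng = np.random.default_rng(seed)

    def features_for(mz: float, z: int, pol: str, ccs: float, run_id: str) -> Feature:
        ion = IonSpecies(mz, z, pol)
        omega_r = reduced_ccs(ccs, ion, gas)
        t_prime = (omega_r / Y_true) ** (1.0 / X_true)
        tA = t_prime + edc_C * np.sqrt(mz) / 1000.0 + t_acc
        if noise_sd_tA > 0:
            tA *= 1.0 + rng.normal(0.0, noise_sd_tA)
        return Feature(mz=mz, arrival_time=float(tA), intensity=1e5, run_id=run_id)

    cal_feats = [
        features_for(c.mz, c.charge_z, c.polarity, c.reference_ccs, "twims_cal")
        for c in calibrants
    ]
    sample_feats = [
        features_for(s.mz, s.charge_z, s.polarity, s.ccs, "twims_sample")
        for s in sample_ions
    ]
    return TwimsCampaign(
        calibrant_features=cal_feats,
        calibrants=list(calibrants),
        sample_features=sample_feats,
        truth={s.name: s for s in sample_ions},
        gas=gas,
        X_true=X_true,
        Y_true=Y_true,
        a_true=Y_true * float(np.sqrt(gas.mass_mB)),
        b_true=0.0,
        t_acc=t_acc,
        edc_C=edc_C,
    )
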