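"""Single-field CCS calibration for drift-tube (and trapped) IMS.

At a single drift voltage the arrival time of an ion is, to an excellent
approximation, linear in its reduced CCS:

    standard mode:   tA = slope * Omega'  + t0      Omega'  = (1/z) sqrt(mI/(mI+mB)) Omega
    enhanced mode:   tA = slope * Omega'' + t0      Omega'' = (P/T) * Omega'

The standard mode treats the drift-gas pressure and temperature as constant
between the calibrant run and the sample runs; the enhanced mode folds each
run's measured P and T into the regressor so that instrument drift between
runs is corrected.  A third mode, ``tims_scan``, is the standard linear fit
with IMS scan numbers substituted for arrival times (no P/T term), as used
for trapped-IMS exports.

Calibrant runs are assigned to sample runs automatically by polarity and
acquisition timestamp: the closest calibration at or after the sample run
wins; if none follows, the closest preceding one is used and flagged.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .errors import AssignmentError, CalibrationError, InsufficientDataError, InvalidInputError
from .io import CalibrantIon, CCSRecord, Feature, FrameMetadata
from .physics import BufferGas, IonSpecies, adjusted_reduced_ccs, reduced_ccs, reduced_ccs_to_ccs
from .targets import DEFAULT_TOL_PPM, mass_error_ppm

__all__ = [
    "CalibrantPoint",
    "LinearCalibration",
    "SingleFieldModel",
    "SingleFieldResults",
    "fit_single_field",
    "assign_calibration_run",
    "calibrate_features",
    "run_conditions",
]

MODES = ("standard", "enhanced", "tims_scan")


def run_conditions(metadata: Sequence[FrameMetadata]) -> tuple[float, float]:
    """(mean P in Torr, mean T in K) over a run's frame metadata."""
    if not metadata:
        raise InsufficientDataError("no frame metadata for run")
    P = float(np.mean([m.pressure_P for m in metadata]))
    T = float(np.mean([m.temperature_K for m in metadata]))
    return P, T


@dataclass(frozen=True)
class CalibrantPoint:
    calibrant: CalibrantIon
    feature: Feature
    x_value: float  # Omega' or Omega'' depending on mode
    mass_error_ppm: float


@dataclass
class LinearCalibration:
    """A fitted single-field calibration line tA = slope * x + t0."""

    mode: str
    slope: float
    intercept_t0: float
    r_squared: float
    calibrant_points: list[CalibrantPoint]
    tA_range: tuple[float, float]
    source_run: str
    polarity: str
    pressure_P: float | None = None  # calibrant-run mean P (Torr)
    temperature_K: float | None = None  # calibrant-run mean T (K)
    fit_timestamp: str = ""  # acquisition timestamp of the calibrant run

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise InvalidInputError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.slope <= 0:
            raise CalibrationError(f"calibration slope must be > 0, got {self.slope}")
        if len(self.calibrant_points) < 2:
            raise InsufficientDataError("calibration needs >= 2 calibrant points")

    def to_json_dict(self) -> dict:
        return {
            "mode": self.mode,
            "slope": self.slope,
            "intercept_t0": self.intercept_t0,
            "r_squared": self.r_squared,
            "tA_range": list(self.tA_range),
            "source_run": self.source_run,
            "polarity": self.polarity,
            "pressure_P": self.pressure_P,
            "temperature_K": self.temperature_K,
            "fit_timestamp": self.fit_timestamp,
            "calibrant_points": [
                {
                    "name": p.calibrant.name,
                    "mz": p.calibrant.mz,
                    "z": p.calibrant.charge_z,
                    "reference_ccs": p.calibrant.reference_ccs,
                    "arrival_time": p.feature.arrival_time,
                    "x_value": p.x_value,
                    "mass_error_ppm": p.mass_error_ppm,
                }
                for p in self.calibrant_points
            ],
        }

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_json_dict(), indent=2) + "\n")


def _match_calibrants(
    calibrant_features: Iterable[Feature],
    calibrants: Sequence[CalibrantIon],
    tol_ppm: float,
) -> tuple[list[tuple[CalibrantIon, Feature, float]], list[str]]:
    """Per calibrant, the highest-intensity feature within tolerance."""
    feats = list(calibrant_features)
    matched, missing = [], []
    for cal in calibrants:
        hits = [
            (f, mass_error_ppm(f.mz, cal.mz))
            for f in feats
            if abs(mass_error_ppm(f.mz, cal.mz)) <= tol_ppm
        ]
        if not hits:
            missing.append(cal.name)
            continue
        hits.sort(key=lambda h: (-h[0].intensity, h[0].arrival_time, h[0].mz))
        matched.append((cal, hits[0][0], hits[0][1]))
    return matched, missing


def fit_single_field(
    calibrant_features: Iterable[Feature],
    calibrants: Sequence[CalibrantIon],
    conditions: Sequence[FrameMetadata],
    gas: BufferGas,
    mode: str = "standard",
    tol_ppm: float = DEFAULT_TOL_PPM,
) -> LinearCalibration:
    """OLS of calibrant arrival times on Omega' (standard/tims_scan) or
    Omega'' (enhanced), with P/T taken as the run means of ``conditions``."""
    if mode not in MODES:
        raise InvalidInputError(f"mode must be one of {MODES}, got {mode!r}")
    conditions = list(conditions)
    P, T = run_conditions(conditions)
    matched, missing = _match_calibrants(calibrant_features, calibrants, tol_ppm)
    if len(matched) < 2:
        raise InsufficientDataError(
            f"matched only {len(matched)} calibrant(s); missing: {missing}"
        )
    points: list[CalibrantPoint] = []
    for cal, feat, err in matched:
        ion = IonSpecies(mz=cal.mz, charge_z=cal.charge_z, polarity=cal.polarity)
        if mode == "enhanced":
            x = adjusted_reduced_ccs(cal.reference_ccs, ion, gas, P, T)
        else:
            x = reduced_ccs(cal.reference_ccs, ion, gas)
        points.append(CalibrantPoint(cal, feat, x, err))

    xs = np.array([p.x_value for p in points])
    ts = np.array([p.feature.arrival_time for p in points])
    fit = stats.linregress(xs, ts)
    if fit.slope <= 0:
        raise CalibrationError(
            f"negative/zero calibration slope ({fit.slope:.4g}) for run "
            f"{conditions[0].run_id}"
        )
    return LinearCalibration(
        mode=mode,
        slope=float(fit.slope),
        intercept_t0=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        calibrant_points=points,
        tA_range=(float(ts.min()), float(ts.max())),
        source_run=conditions[0].run_id,
        polarity=conditions[0].polarity,
        pressure_P=P,
        temperature_K=T,
        fit_timestamp=conditions[0].acquisition_timestamp,
    )


def assign_calibration_run(
    sample_run_meta: FrameMetadata,
    available_calibrations: Sequence[LinearCalibration],
) -> tuple[LinearCalibration, bool]:
    """Pick the calibration for a sample run by polarity and timestamp.

    Among polarity-matching calibrations at or after the sample run's
    timestamp, the closest wins (tie-break: source run id); if none follows,
    the closest preceding is chosen and the second return value is True
    (fallback used).
    """
    same_pol = [c for c in available_calibrations if c.polarity == sample_run_meta.polarity]
    if not same_pol:
        raise AssignmentError(
            f"no {sample_run_meta.polarity}-polarity calibration available for run "
            f"{sample_run_meta.run_id}"
        )
    t_sample = sample_run_meta.timestamp_dt

    def cal_time(c: LinearCalibration):
        dt = datetime.fromisoformat(c.fit_timestamp)
        return dt.replace(tzinfo=timezone.utc) if dt.tzinfo is None else dt

    following = [c for c in same_pol if cal_time(c) >= t_sample]
    if following:
        chosen = min(following, key=lambda c: (cal_time(c) - t_sample, c.source_run))
        return chosen, False
    chosen = min(same_pol, key=lambda c: (t_sample - cal_time(c), c.source_run))
    return chosen, True


def calibrate_features(
    features: Iterable[Feature],
    calibration: LinearCalibration,
    gas: BufferGas,
    sample_conditions: Sequence[FrameMetadata] | None = None,
    default_charge: int = 1,
    extra_flags: frozenset[str] = frozenset(),
) -> list[CCSRecord]:
    """Apply a single-field calibration to every feature (untargeted).

    Per feature, x = (tA - t0)/slope; in standard/tims_scan mode x is
    Omega', in enhanced mode x is Omega'' and is converted back with the
    *sample* run's mean P and T.  Charge defaults to ``default_charge``
    unless the feature carries a ``charge`` entry in ``extra``.  Every input
    feature yields exactly one record; out-of-range features are flagged
    ``extrapolated`` and tA <= t0 yields an ``invalid``-flagged record.
    """
    if calibration.mode == "enhanced":
        if sample_conditions is None:
            raise InvalidInputError("enhanced mode requires the sample run's conditions")
        P_s, T_s = run_conditions(sample_conditions)
    records: list[CCSRecord] = []
    lo, hi = calibration.tA_range
    for f in features:
        z = int(f.extra.get("charge", default_charge)) if f.extra else default_charge
        flags = set(extra_flags)
        tA = f.arrival_time
        if tA < lo or tA > hi:
            flags.add("extrapolated")
        x = (tA - calibration.intercept_t0) / calibration.slope
        if x <= 0:
            records.append(CCSRecord(
                name="", adduct="", mz=f.mz, charge_z=z, ccs=None,
                intensity=f.intensity, arrival_time=tA,
                flags=frozenset(flags | {"invalid"}),
            ))
            continue
        ion = IonSpecies(mz=f.mz, charge_z=z)
        if calibration.mode == "enhanced":
            omega_prime = x * T_s / P_s
        else:
            omega_prime = x
        ccs = reduced_ccs_to_ccs(omega_prime, ion, gas)
        records.append(CCSRecord(
            name="", adduct="", mz=f.mz, charge_z=z, ccs=ccs,
            intensity=f.intensity, arrival_time=tA, flags=frozenset(flags),
        ))
    return records


class SingleFieldModel:
    """Single-field calibration model built from one calibrant run.

    ``fit()`` performs the calibrant matching and the OLS and returns a
    :class:`SingleFieldResults` whose ``predict`` applies the calibration to
    unknown features.
    """

    def __init__(
        self,
        calibrant_features: Sequence[Feature],
        calibrants: Sequence[CalibrantIon],
        conditions: Sequence[FrameMetadata],
        gas: BufferGas,
        mode: str = "standard",
        tol_ppm: float = DEFAULT_TOL_PPM,
    ):
        self.calibrant_features = list(calibrant_features)
        self.calibrants = list(calibrants)
        self.conditions = list(conditions)
        self.gas = gas
        self.mode = mode
        self.tol_ppm = tol_ppm

    def fit(self) -> "SingleFieldResults":
        cal = fit_single_field(
            self.calibrant_features, self.calibrants, self.conditions,
            self.gas, self.mode, self.tol_ppm,
        )
        return SingleFieldResults(self, cal)


@dataclass
class SingleFieldResults:
    model: SingleFieldModel
    calibration: LinearCalibration
    flags: frozenset[str] = dc_field(default_factory=frozenset)

    def predict(
        self,
        features: Iterable[Feature],
        sample_conditions: Sequence[FrameMetadata] | None = None,
        default_charge: int = 1,
    ) -> list[CCSRecord]:
        return calibrate_features(
            features, self.calibration, self.model.gas,
            sample_conditions=sample_conditions, default_charge=default_charge,
        )

    def summary(self) -> str:
        c = self.calibration
        lines = [
            f"Single-field calibration ({c.mode}) from run {c.source_run} "
            f"[{c.polarity}]",
            f"slope {c.slope:.6f} ms per x-unit, t0 {c.intercept_t0:.4f} ms, "
            f"r^2 {c.r_squared:.8f}",
            f"calibrants used: {len(c.calibrant_points)}; "
            f"tA range [{c.tA_range[0]:.3f}, {c.tA_range[1]:.3f}] ms",
        ]
        if c.mode == "enhanced":
            lines.append(
                f"run conditions: P {c.pressure_P:.4f} Torr, T {c.temperature_K:.2f} K"
            )
        for p in c.calibrant_points:
            lines.append(
                f"  {p.calibrant.name}: mz {p.calibrant.mz:.4f} tA "
                f"{p.feature.arrival_time:.3f} ms  x {p.x_value:.6g}  "
                f"ref CCS {p.calibrant.reference_ccs:.2f}"
            )
        return "\n".join(lines)
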