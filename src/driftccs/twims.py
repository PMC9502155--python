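"""Non-linear CCS calibration for traveling-wave IMS (Synapt, SLIM).

The non-uniform dynamic fields of a traveling-wave separator make the
arrival-time/CCS relation non-linear, so CCS is obtained by empirical
calibration against reference ions.  Two methods are supported.

Polynomial:  the reduced CCS of the calibrants is fit as a degree-D
polynomial of the corrected arrival time t' = tA - t_acc, where t_acc is
the ion-accumulation time of the platform (1000 ms on the SLIM systems this
package targets, 0 elsewhere).

Linearized power law: arrival times are first corrected for the
accumulation time and, on Synapt instruments, the EDC (Enhanced Duty Cycle)
delay,

    t' = tA - C*sqrt(m/z)/1000 - t_acc      (C = 0 for SLIM)

then the power relation Omega' = Y * t'^X is linearized in log space
(ln Omega' = X ln t' + ln Y), a doubly-corrected time

    t'' = t'^X * z / sqrt(mu)

is formed with mu the ion–gas reduced mass, and a final linear regression
Omega = a * t'' + b maps t'' straight to CCS.

Features whose corrected arrival time falls outside the calibrant range are
flagged ``extrapolated``: the empirical curve is only trusted where it was
anchored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .errors import CalibrationError, InsufficientDataError, InvalidInputError
from .io import CalibrantIon, CCSRecord, Feature
from .physics import BufferGas, IonSpecies, reduced_ccs, reduced_ccs_to_ccs, reduced_mass
from .targets import DEFAULT_TOL_PPM, mass_error_ppm

__all__ = [
    "PolynomialCalibration",
    "PowerCalibration",
    "PolynomialTwimsModel",
    "PowerTwimsModel",
    "TwimsResults",
    "fit_polynomial",
    "fit_power",
    "apply_twims_calibration",
    "delta_ccs_percent",
    "corrected_arrival_time",
]


def corrected_arrival_time(
    tA: float, mz: float, edc_C: float = 0.0, t_acc: float = 0.0
) -> float:
    """t' = tA - C*sqrt(m/z)/1000 - t_acc  (ms)."""
    return tA - edc_C * math.sqrt(mz) / 1000.0 - t_acc


@dataclass
class PolynomialCalibration:
    """Omega' = x0 + x1 t' + ... + xD t'^D with t' = tA - t_acc."""

    degree_D: int
    coefficients: tuple[float, ...]  # ascending powers, length D+1
    t_acc: float
    r_squared: float
    tA_range: tuple[float, float]  # range of corrected t' over the calibrants, ms
    edc_C: float = 0.0
    source_run: str = ""

    def __post_init__(self) -> None:
        if self.degree_D < 1:
            raise InvalidInputError(f"degree must be >= 1, got {self.degree_D}")
        if len(self.coefficients) != self.degree_D + 1:
            raise InvalidInputError(
                f"need {self.degree_D + 1} coefficients, got {len(self.coefficients)}"
            )

    def reduced_ccs_at(self, t_prime: float) -> float:
        return float(np.polynomial.polynomial.polyval(t_prime, self.coefficients))

    def to_json_dict(self) -> dict:
        return {
            "method": "polynomial",
            "degree_D": self.degree_D,
            "coefficients": list(self.coefficients),
            "t_acc": self.t_acc,
            "edc_C": self.edc_C,
            "r_squared": self.r_squared,
            "tA_range": list(self.tA_range),
            "source_run": self.source_run,
        }


@dataclass
class PowerCalibration:
    """Two-stage linearized power calibration (see module docstring)."""

    exponent_X: float
    lnY: float
    final_slope_a: float
    final_intercept_b: float
    edc_C: float
    t_acc: float
    r_squared_loglog: float
    r_squared_final: float
    tA_range: tuple[float, float]  # range of corrected t' over the calibrants, ms
    source_run: str = ""

    def __post_init__(self) -> None:
        if self.exponent_X <= 0:
            raise CalibrationError(f"power exponent must be > 0, got {self.exponent_X}")
        if self.final_slope_a <= 0:
            raise CalibrationError(f"final slope must be > 0, got {self.final_slope_a}")

    def doubly_corrected_time(self, t_prime: float, ion: IonSpecies, gas: BufferGas) -> float:
        """t'' = t'^X * z / sqrt(mu)."""
        mu = reduced_mass(ion.ion_mass_mI, gas.mass_mB)
        return t_prime**self.exponent_X * ion.charge_z / math.sqrt(mu)

    def to_json_dict(self) -> dict:
        return {
            "method": "power",
            "exponent_X": self.exponent_X,
            "lnY": self.lnY,
            "final_slope_a": self.final_slope_a,
            "final_intercept_b": self.final_intercept_b,
            "edc_C": self.edc_C,
            "t_acc": self.t_acc,
            "r_squared_loglog": self.r_squared_loglog,
            "r_squared_final": self.r_squared_final,
            "tA_range": list(self.tA_range),
            "source_run": self.source_run,
        }


def _match_calibrants(
    calibrant_features: Iterable[Feature],
    calibrants: Sequence[CalibrantIon],
    tol_ppm: float,
) -> list[tuple[CalibrantIon, Feature]]:
    feats = list(calibrant_features)
    matched = []
    for cal in calibrants:
        hits = [f for f in feats if abs(mass_error_ppm(f.mz, cal.mz)) <= tol_ppm]
        if not hits:
            continue
        hits.sort(key=lambda f: (-f.intensity, f.arrival_time, f.mz))
        matched.append((cal, hits[0]))
    return matched


def _r_squared(y: np.ndarray, y_hat: np.ndarray) -> float:
    ss_res = float(np.sum((y - y_hat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    return 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot


def fit_polynomial(
    calibrant_features: Iterable[Feature],
    calibrants: Sequence[CalibrantIon],
    gas: BufferGas,
    degree_D: int = 2,
    t_acc: float = 0.0,
    tol_ppm: float = DEFAULT_TOL_PPM,
    source_run: str = "",
) -> PolynomialCalibration:
    """Least-squares polynomial of Omega' on t' = tA - t_acc.

    Requires at least D+2 calibrant points so the fit stays overdetermined
    (exact interpolation would hide calibrant errors).
    """
    if degree_D < 1:
        raise InvalidInputError(f"degree must be >= 1, got {degree_D}")
    if t_acc < 0:
        raise InvalidInputError(f"t_acc must be >= 0, got {t_acc}")
    matched = _match_calibrants(calibrant_features, calibrants, tol_ppm)
    if len(matched) < degree_D + 2:
        raise InsufficientDataError(
            f"degree-{degree_D} polynomial needs >= {degree_D + 2} calibrant points, "
            f"got {len(matched)}"
        )
    t_prime = np.array([f.arrival_time - t_acc for _, f in matched])
    omega_r = np.array([
        reduced_ccs(c.reference_ccs, IonSpecies(c.mz, c.charge_z, c.polarity), gas)
        for c, _ in matched
    ])
    coeffs = np.polynomial.polynomial.polyfit(t_prime, omega_r, degree_D)
    fitted = np.polynomial.polynomial.polyval(t_prime, coeffs)
    return PolynomialCalibration(
        degree_D=degree_D,
        coefficients=tuple(float(c) for c in coeffs),
        t_acc=t_acc,
        r_squared=_r_squared(omega_r, fitted),
        tA_range=(float(t_prime.min()), float(t_prime.max())),
        source_run=source_run,
    )


def fit_power(
    calibrant_features: Iterable[Feature],
    calibrants: Sequence[CalibrantIon],
    gas: BufferGas,
    edc_C: float = 0.0,
    t_acc: float = 0.0,
    tol_ppm: float = DEFAULT_TOL_PPM,
    source_run: str = "",
) -> PowerCalibration:
    """Three-stage linearized power calibration.

    Stage 1: OLS of ln Omega' on ln t' gives the exponent X and ln Y.
    Stage 2: t'' = t'^X * z / sqrt(mu) per calibrant.
    Stage 3: OLS of the reference CCS on t'' gives the final line a, b.
    """
    matched = _match_calibrants(calibrant_features, calibrants, tol_ppm)
    if len(matched) < 3:
        raise InsufficientDataError(
            f"power calibration needs >= 3 calibrant points, got {len(matched)}"
        )
    t_prime = []
    for cal, feat in matched:
        tp = corrected_arrival_time(feat.arrival_time, feat.mz, edc_C, t_acc)
        if tp <= 0:
            raise CalibrationError(
                f"corrected arrival time <= 0 for calibrant {cal.name} "
                f"(tA={feat.arrival_time} ms, C={edc_C}, t_acc={t_acc})"
            )
        t_prime.append(tp)
    t_prime = np.array(t_prime)
    ions = [IonSpecies(c.mz, c.charge_z, c.polarity) for c, _ in matched]
    omega_r = np.array([
        reduced_ccs(c.reference_ccs, ion, gas) for (c, _), ion in zip(matched, ions)
    ])

    loglog = stats.linregress(np.log(t_prime), np.log(omega_r))
    X, lnY = float(loglog.slope), float(loglog.intercept)
    if X <= 0:
        raise CalibrationError(f"power exponent X must be > 0, got {X:.4g}")

    t_dbl = np.array([
        tp**X * ion.charge_z / math.sqrt(reduced_mass(ion.ion_mass_mI, gas.mass_mB))
        for tp, ion in zip(t_prime, ions)
    ])
    omega_ref = np.array([c.reference_ccs for c, _ in matched])
    final = stats.linregress(t_dbl, omega_ref)

    return PowerCalibration(
        exponent_X=X,
        lnY=lnY,
        final_slope_a=float(final.slope),
        final_intercept_b=float(final.intercept),
        edc_C=edc_C,
        t_acc=t_acc,
        r_squared_loglog=float(loglog.rvalue**2),
        r_squared_final=float(final.rvalue**2),
        tA_range=(float(t_prime.min()), float(t_prime.max())),
        source_run=source_run,
    )


def apply_twims_calibration(
    features: Iterable[Feature],
    calibration: PolynomialCalibration | PowerCalibration,
    gas: BufferGas,
    default_charge: int = 1,
) -> list[CCSRecord]:
    """Calibrate every feature; one record per feature, never dropped.

    Corrected times outside the calibrant range are flagged ``extrapolated``;
    non-positive corrected times yield ``invalid``-flagged records.
    """
    lo, hi = calibration.tA_range
    records: list[CCSRecord] = []
    for f in features:
        z = int(f.extra.get("charge", default_charge)) if f.extra else default_charge
        tp = corrected_arrival_time(f.arrival_time, f.mz, calibration.edc_C, calibration.t_acc)
        flags: set[str] = set()
        if tp <= 0:
            records.append(CCSRecord(
                name="", adduct="", mz=f.mz, charge_z=z, ccs=None,
                intensity=f.intensity, arrival_time=f.arrival_time,
                flags=frozenset({"invalid"}),
            ))
            continue
        if tp < lo or tp > hi:
            flags.add("extrapolated")
        ion = IonSpecies(mz=f.mz, charge_z=z)
        if isinstance(calibration, PolynomialCalibration):
            omega_r = calibration.reduced_ccs_at(tp)
            ccs = reduced_ccs_to_ccs(omega_r, ion, gas) if omega_r > 0 else None
            if ccs is None:
                flags.add("invalid")
        else:
            t_dbl = calibration.doubly_corrected_time(tp, ion, gas)
            ccs = calibration.final_slope_a * t_dbl + calibration.final_intercept_b
            if ccs <= 0:
                ccs, flags = None, flags | {"invalid"}
        records.append(CCSRecord(
            name="", adduct="", mz=f.mz, charge_z=z, ccs=ccs,
            intensity=f.intensity, arrival_time=f.arrival_time,
            flags=frozenset(flags),
        ))
    return records


def delta_ccs_percent(ccs_a: float, ccs_ref: float) -> float:
    """Percent CCS difference 100*|ccs_a - ccs_ref|/ccs_ref.

    The standard cross-platform/cross-software comparison metric; reports
    round it to 2 decimals.
    """
    if ccs_ref <= 0:
        raise InvalidInputError(f"reference ccs must be > 0, got {ccs_ref}")
    return 100.0 * abs(ccs_a - ccs_ref) / ccs_ref


class _TwimsModelBase:
    def __init__(
        self,
        calibrant_features: Sequence[Feature],
        calibrants: Sequence[CalibrantIon],
        gas: BufferGas,
        t_acc: float = 0.0,
        tol_ppm: float = DEFAULT_TOL_PPM,
        source_run: str = "",
    ):
        self.calibrant_features = list(calibrant_features)
        self.calibrants = list(calibrants)
        self.gas = gas
        self.t_acc = t_acc
        self.tol_ppm = tol_ppm
        self.source_run = source_run


class PolynomialTwimsModel(_TwimsModelBase):
    """Polynomial TWIMS calibration model (default degree 2)."""

    def __init__(self, *args, degree_D: int = 2, **kwargs):
        super().__init__(*args, **kwargs)
        self.degree_D = degree_D

    def fit(self) -> "TwimsResults":
        cal = fit_polynomial(
            self.calibrant_features, self.calibrants, self.gas,
            degree_D=self.degree_D, t_acc=self.t_acc, tol_ppm=self.tol_ppm,
            source_run=self.source_run,
        )
        return TwimsResults(self, cal)


class PowerTwimsModel(_TwimsModelBase):
    """Linearized power-law TWIMS calibration model (EDC C = 0 for SLIM)."""

    def __init__(self, *args, edc_C: float = 0.0, **kwargs):
        super().__init__(*args, **kwargs)
        self.edc_C = edc_C

    def fit(self) -> "TwimsResults":
        cal = fit_power(
            self.calibrant_features, self.calibrants, self.gas,
            edc_C=self.edc_C, t_acc=self.t_acc, tol_ppm=self.tol_ppm,
            source_run=self.source_run,
        )
        return TwimsResults(self, cal)


@dataclass
class TwimsResults:
    model: _TwimsModelBase
    calibration: PolynomialCalibration | PowerCalibration
    flags: frozenset[str] = dc_field(default_factory=frozenset)

    def predict(self, features: Iterable[Feature], default_charge: int = 1) -> list[CCSRecord]:
        return apply_twims_calibration(
            features, self.calibration, self.model.gas, default_charge=default_charge
        )

    def summary(self) -> str:
        c = self.calibration
        if isinstance(c, PolynomialCalibration):
            coeffs = ", ".join(f"x{i}={v:.6g}" for i, v in enumerate(c.coefficients))
            lines = [
                f"TWIMS polynomial calibration (degree {c.degree_D}), "
                f"t_acc {c.t_acc} ms",
                f"coefficients: {coeffs}",
                f"r^2 {c.r_squared:.8f}; corrected-tA range "
                f"[{c.tA_range[0]:.3f}, {c.tA_range[1]:.3f}] ms",
            ]
        else:
            lines = [
                f"TWIMS linearized power calibration, EDC C {c.edc_C}, "
                f"t_acc {c.t_acc} ms",
                f"exponent X {c.exponent_X:.6f}, lnY {c.lnY:.6f} "
                f"(log-log r^2 {c.r_squared_loglog:.8f})",
                f"final line: a {c.final_slope_a:.6g}, b {c.final_intercept_b:.6g} "
                f"(r^2 {c.r_squared_final:.8f})",
                f"corrected-tA range [{c.tA_range[0]:.3f}, {c.tA_range[1]:.3f}] ms",
            ]
        return "\n".join(lines)
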