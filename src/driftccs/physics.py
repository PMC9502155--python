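"""Physical constants and closed-form mobility/CCS conversions.

The low-field Mason–Schamp relation links an ion's reduced mobility K0
(normalised to 273.15 K and 760 Torr) to its momentum-transfer collision
cross section Omega with a neutral buffer gas:

    Omega = (3 z e) / (16 N0) * sqrt(2 pi / (mu k T)) * (1 / K0)

with mu the ion–neutral reduced mass, k the Boltzmann constant and N0 the
buffer-gas number density at standard conditions.  Every calibration mode in
this package reduces to this equation plus two algebraic rescalings:

* the *reduced* CCS  Omega' = (1/z) * sqrt(mI / (mI + mB)) * Omega, which
  collapses calibrant ions of different mass and charge onto one calibration
  curve, and
* the *adjusted* reduced CCS  Omega'' = (P/T) * Omega', which additionally
  absorbs the drift-gas pressure and temperature of an individual run so
  that instrument drift between runs cancels out of a shared calibration.

Unit contract (used package-wide): arrival times in ms, drift length in cm,
pressure in Torr, temperature in K internally (degrees C at I/O boundaries),
K0 in cm^2/(V s), CCS in A^2, masses in Da.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .errors import InvalidInputError

__all__ = [
    "PhysicalConstants",
    "CONSTANTS",
    "BufferGas",
    "NITROGEN",
    "HELIUM",
    "BUFFER_GASES",
    "IonSpecies",
    "ELECTRON_MASS_DA",
    "PROTON_MASS_DA",
    "celsius_to_kelvin",
    "reduced_mass",
    "mobility_to_ccs",
    "ccs_to_mobility",
    "reduced_ccs",
    "reduced_ccs_to_ccs",
    "adjusted_reduced_ccs",
]

#: electron rest mass in Da; fixes the m/z <-> ion-mass bookkeeping
ELECTRON_MASS_DA = 5.48579909e-4
#: mass of a proton (H+ adduct shift) in Da
PROTON_MASS_DA = 1.007276466


@dataclass(frozen=True)
class PhysicalConstants:
    """CODATA constants used in the Mason–Schamp relation (read-only)."""

    boltzmann_k: float = 1.380649e-23  # J/K
    elementary_charge_e: float = 1.602176634e-19  # C
    loschmidt_N0: float = 2.6867801e25  # molecules/m^3 at 273.15 K, 760 Torr
    amu_to_kg: float = 1.66053906660e-27  # kg per Da
    standard_T: float = 273.15  # K
    standard_P: float = 760.0  # Torr

    def __post_init__(self) -> None:
        for name, value in self.__dict__.items():
            if value <= 0:
                raise InvalidInputError(f"constant {name} must be > 0, got {value}")


CONSTANTS = PhysicalConstants()


@dataclass(frozen=True)
class BufferGas:
    """A neutral drift gas, identified by name and average mass in Da."""

    name: str
    mass_mB: float

    def __post_init__(self) -> None:
        if self.mass_mB <= 0:
            raise InvalidInputError(f"buffer gas mass must be > 0, got {self.mass_mB}")


NITROGEN = BufferGas("nitrogen", 28.0134)
HELIUM = BufferGas("helium", 4.002602)

BUFFER_GASES: dict[str, BufferGas] = {
    "nitrogen": NITROGEN,
    "n2": NITROGEN,
    "helium": HELIUM,
    "he": HELIUM,
}


def get_buffer_gas(name: str | BufferGas) -> BufferGas:
    """Resolve a gas by name (case-insensitive; 'N2'/'He' aliases accepted)."""
    if isinstance(name, BufferGas):
        return name
    try:
        return BUFFER_GASES[name.strip().lower()]
    except KeyError:
        raise InvalidInputError(
            f"unknown buffer gas {name!r}; known: {sorted(BUFFER_GASES)}"
        ) from None


@dataclass(frozen=True)
class IonSpecies:
    """An ion characterised by m/z, charge state and polarity.

    The neutral-equivalent ion mass mI is mz*z minus (positive mode) or plus
    (negative mode) z electron masses, so that mI is the mass of the actual
    charged particle's atoms, not of the charge carriers.
    """

    mz: float
    charge_z: int
    polarity: str = "positive"
    ion_mass_mI: float = field(default=0.0)

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise InvalidInputError(f"mz must be > 0, got {self.mz}")
        if self.charge_z < 1:
            raise InvalidInputError(f"charge_z must be >= 1, got {self.charge_z}")
        if self.polarity not in ("positive", "negative"):
            raise InvalidInputError(f"polarity must be positive|negative, got {self.polarity!r}")
        if self.ion_mass_mI == 0.0:
            sign = -1.0 if self.polarity == "positive" else 1.0
            object.__setattr__(
                self,
                "ion_mass_mI",
                self.mz * self.charge_z + sign * self.charge_z * ELECTRON_MASS_DA,
            )
        if self.ion_mass_mI <= 0:
            raise InvalidInputError(f"ion mass must be > 0, got {self.ion_mass_mI}")


def celsius_to_kelvin(t_celsius: float) -> float:
    """Convert a temperature from degrees C to K."""
    t_k = t_celsius + 273.15
    if t_k <= 0:
        raise InvalidInputError(f"temperature {t_celsius} C is at or below absolute zero")
    return t_k


def reduced_mass(ion_mass_mI: float, gas_mass_mB: float) -> float:
    """Reduced mass mI*mB/(mI+mB) of the ion–neutral pair, in Da."""
    if ion_mass_mI <= 0 or gas_mass_mB <= 0:
        raise InvalidInputError(
            f"masses must be > 0, got mI={ion_mass_mI}, mB={gas_mass_mB}"
        )
    return ion_mass_mI * gas_mass_mB / (ion_mass_mI + gas_mass_mB)


def mobility_to_ccs(
    K0: float,
    ion: IonSpecies,
    gas: BufferGas,
    temperature_K: float,
    constants: PhysicalConstants = CONSTANTS,
) -> float:
    """CCS (A^2) from reduced mobility K0 (cm^2/(V s)) via Mason–Schamp.

    Temperature is the drift-gas temperature in K.  The result is strictly
    decreasing in both K0 and T.
    """
    if K0 <= 0:
        raise InvalidInputError(f"K0 must be > 0, got {K0}")
    if temperature_K <= 0:
        raise InvalidInputError(f"temperature must be > 0 K, got {temperature_K}")
    mu_kg = reduced_mass(ion.ion_mass_mI, gas.mass_mB) * constants.amu_to_kg
    K0_si = K0 * 1e-4  # cm^2/(V s) -> m^2/(V s)
    omega_m2 = (
        (3.0 * ion.charge_z * constants.elementary_charge_e)
        / (16.0 * constants.loschmidt_N0)
        * math.sqrt(2.0 * math.pi / (mu_kg * constants.boltzmann_k * temperature_K))
        / K0_si
    )
    return omega_m2 * 1e20  # m^2 -> A^2


def ccs_to_mobility(
    ccs: float,
    ion: IonSpecies,
    gas: BufferGas,
    temperature_K: float,
    constants: PhysicalConstants = CONSTANTS,
) -> float:
    """Reduced mobility K0 (cm^2/(V s)) from CCS (A^2); inverse of
    :func:`mobility_to_ccs`."""
    if ccs <= 0:
        raise InvalidInputError(f"ccs must be > 0, got {ccs}")
    if temperature_K <= 0:
        raise InvalidInputError(f"temperature must be > 0 K, got {temperature_K}")
    mu_kg = reduced_mass(ion.ion_mass_mI, gas.mass_mB) * constants.amu_to_kg
    omega_m2 = ccs * 1e-20
    K0_si = (
        (3.0 * ion.charge_z * constants.elementary_charge_e)
        / (16.0 * constants.loschmidt_N0)
        * math.sqrt(2.0 * math.pi / (mu_kg * constants.boltzmann_k * temperature_K))
        / omega_m2
    )
    return K0_si * 1e4


def _mass_term(ion: IonSpecies, gas: BufferGas) -> float:
    return math.sqrt(ion.ion_mass_mI / (ion.ion_mass_mI + gas.mass_mB))


def reduced_ccs(ccs: float, ion: IonSpecies, gas: BufferGas) -> float:
    """Reduced CCS  Omega' = (1/z) * sqrt(mI/(mI+mB)) * Omega."""
    if ccs <= 0:
        raise InvalidInputError(f"ccs must be > 0, got {ccs}")
    return ccs * _mass_term(ion, gas) / ion.charge_z


def reduced_ccs_to_ccs(ccs_reduced: float, ion: IonSpecies, gas: BufferGas) -> float:
    """Invert :func:`reduced_ccs`:  Omega = Omega' * z / sqrt(mI/(mI+mB))."""
    return ccs_reduced * ion.charge_z / _mass_term(ion, gas)


def adjusted_reduced_ccs(
    ccs: float, ion: IonSpecies, gas: BufferGas, pressure_torr: float, temperature_K: float
) -> float:
    """Adjusted reduced CCS  Omega'' = (P/T) * Omega'.

    P in Torr, T in K; used by the enhanced single-field calibration so that
    per-run pressure/temperature drift cancels out of the shared curve.
    """
    if pressure_torr <= 0 or temperature_K <= 0:
        raise InvalidInputError(
            f"P and T must be > 0, got P={pressure_torr}, T={temperature_K}"
        )
    return (pressure_torr / temperature_K) * reduced_ccs(ccs, ion, gas)
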