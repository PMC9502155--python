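"""Adduct-ion generation and m/z matching of features to target ions.

From a neutral monoisotopic mass and a configured adduct table (label, mass
shift, charge, polarity), the expected m/z of every adduct ion is

    expected_mz = (neutral_mass + mass_shift) / charge_z

with the mass shift carrying the adduct particles (protons, sodium cation,
...) including their electron bookkeeping.  Features are matched to a
target ion within a user-set ppm tolerance, and candidate lists can be
limited to the top-N features by intensity to keep the downstream
combination search tractable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .errors import InvalidInputError
from .io import Feature, TargetMolecule
from .physics import ELECTRON_MASS_DA, PROTON_MASS_DA

__all__ = [
    "AdductSpec",
    "TargetIon",
    "Match",
    "DEFAULT_ADDUCTS",
    "DEFAULT_TOL_PPM",
    "generate_target_ions",
    "match_features",
    "limit_by_intensity_rank",
]

#: Na+ = Na atom minus one electron
_SODIUM_CATION_DA = 22.98976928 - ELECTRON_MASS_DA

DEFAULT_TOL_PPM = 20.0


@dataclass(frozen=True)
class AdductSpec:
    """One adduct rule: label, total mass shift (Da), charge and polarity."""

    label: str
    mass_shift: float
    charge_z: int
    polarity: str

    def __post_init__(self) -> None:
        if self.charge_z < 1:
            raise InvalidInputError(f"adduct charge must be >= 1, got {self.charge_z}")
        if self.polarity not in ("positive", "negative"):
            raise InvalidInputError(f"polarity must be positive|negative, got {self.polarity!r}")


#: default adduct table: protonated forms up to 4+, sodiated, deprotonated
DEFAULT_ADDUCTS: tuple[AdductSpec, ...] = (
    AdductSpec("[M+H]+", PROTON_MASS_DA, 1, "positive"),
    AdductSpec("[M+2H]2+", 2 * PROTON_MASS_DA, 2, "positive"),
    AdductSpec("[M+3H]3+", 3 * PROTON_MASS_DA, 3, "positive"),
    AdductSpec("[M+4H]4+", 4 * PROTON_MASS_DA, 4, "positive"),
    AdductSpec("[M+Na]+", _SODIUM_CATION_DA, 1, "positive"),
    AdductSpec("[M-H]-", -PROTON_MASS_DA, 1, "negative"),
)


@dataclass(frozen=True)
class TargetIon:
    """A concrete adduct ion of a target molecule."""

    molecule: TargetMolecule
    adduct: AdductSpec

    @property
    def expected_mz(self) -> float:
        return (self.molecule.neutral_mass + self.adduct.mass_shift) / self.adduct.charge_z

    @property
    def ion_mass_mI(self) -> float:
        return self.molecule.neutral_mass + self.adduct.mass_shift

    @property
    def charge_z(self) -> int:
        return self.adduct.charge_z

    @property
    def polarity(self) -> str:
        return self.adduct.polarity

    @property
    def name(self) -> str:
        return self.molecule.name


@dataclass(frozen=True)
class Match:
    """A feature matched to a target ion, with its signed mass error."""

    feature: Feature
    mass_error_ppm: float


def generate_target_ions(
    molecules: Iterable[TargetMolecule],
    adducts: Sequence[AdductSpec] = DEFAULT_ADDUCTS,
    polarity: str | None = None,
) -> list[TargetIon]:
    """Cartesian product of molecules x adducts, filtered to ``polarity``.

    With ``polarity=None`` all adducts are kept.  Output order is molecules
    outer, adducts inner, as given.
    """
    if not adducts:
        raise InvalidInputError("adduct list must be non-empty")
    kept = [a for a in adducts if polarity is None or a.polarity == polarity]
    return [TargetIon(m, a) for m in molecules for a in kept]


def mass_error_ppm(observed_mz: float, expected_mz: float) -> float:
    """Signed relative mass error in parts per million."""
    return (observed_mz - expected_mz) / expected_mz * 1e6


def match_features(
    target: TargetIon, features: Iterable[Feature], tol_ppm: float = DEFAULT_TOL_PPM
) -> list[Match]:
    """Features within ``tol_ppm`` of the target's expected m/z.

    Returned sorted by descending intensity (ties: arrival time then mz
    ascending), each with its signed ppm error recorded.
    """
    if tol_ppm <= 0:
        raise InvalidInputError(f"tol_ppm must be > 0, got {tol_ppm}")
    expected = target.expected_mz
    hits = [
        Match(f, mass_error_ppm(f.mz, expected))
        for f in features
        if abs(mass_error_ppm(f.mz, expected)) <= tol_ppm
    ]
    hits.sort(key=lambda m: (-m.feature.intensity, m.feature.arrival_time, m.feature.mz))
    return hits


def limit_by_intensity_rank(features: Sequence[Feature], max_rank: int) -> list[Feature]:
    """Top ``max_rank`` features by intensity.

    Ties broken by lower arrival time, then lower mz — a fixed rule so the
    downstream combination search is deterministic.
    """
    if max_rank < 1:
        raise InvalidInputError(f"max_rank must be >= 1, got {max_rank}")
    ranked = sorted(features, key=lambda f: (-f.intensity, f.arrival_time, f.mz))
    return ranked[:max_rank]
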