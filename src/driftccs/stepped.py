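"""Stepped-field drift-tube CCS determination.

In a stepped-field (multi-field) DTIMS experiment the same sample is
acquired at several drift voltages.  Under the low-field drift relation the
arrival time at field n is linear in a per-field regressor,

    tA_n = x_n / K0 + t0,
    x_n  = 1000 * L^2 * (273.15/760) * P_n / (T_n * V_n)   [ms * cm^2/(V s)]

with L the drift length (cm), P_n the drift pressure (Torr), T_n the drift
temperature (K), V_n the drift voltage and t0 the time the ion spends
outside the drift cell.  The factor 1000 converts seconds to the package's
ms arrival-time unit, so the fitted slope is exactly 1/K0 with K0 in
cm^2/(V s).  CCS then follows from the Mason–Schamp relation.

Because several features may fall inside the m/z tolerance in each field,
every combination taking at most one candidate per field is regressed and
fits with r^2 at or above a threshold (default 0.99) are kept; distinct
surviving fits are reported as distinct conformers.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import stats

from .errors import InsufficientDataError, InvalidInputError
from .io import CCSRecord, Feature, FrameMetadata
from .physics import BufferGas, IonSpecies, mobility_to_ccs
from .targets import Match, TargetIon, limit_by_intensity_rank, match_features

__all__ = [
    "build_field_axis",
    "enumerate_and_fit",
    "summarize_replicates",
    "SteppedFieldModel",
    "SteppedFieldResults",
    "ConformerFit",
    "ReplicateSummary",
    "DEFAULT_R2_THRESHOLD",
]

logger = logging.getLogger(__name__)

DEFAULT_R2_THRESHOLD = 0.99
#: two passing fits closer than this in relative CCS sharing >= half their
#: features are considered the same conformer
DUPLICATE_CCS_REL_TOL = 0.005

_MS_PER_S = 1000.0


def build_field_axis(metadata: list[FrameMetadata]) -> np.ndarray:
    """Per-field regressor x_n = 1000 * L^2 * (273.15/760) * P_n/(T_n V_n).

    Ordered as ``metadata``; requires at least two fields with distinct
    drift voltages.
    """
    if len(metadata) < 2 or len({m.drift_voltage_V for m in metadata}) < 2:
        raise InsufficientDataError(
            "stepped-field regression needs >= 2 fields with distinct voltages"
        )
    return np.array([
        _MS_PER_S
        * m.drift_length_L**2
        * (273.15 / 760.0)
        * m.pressure_P
        / (m.temperature_K * m.drift_voltage_V)
        for m in metadata
    ])


@dataclass
class ConformerFit:
    """One accepted regression: a conformer of the target ion."""

    target: TargetIon
    features: tuple[Match, ...]  # one per used field, in field order
    field_ids: tuple[int, ...]
    slope: float
    intercept_t0: float
    r_squared: float
    K0: float
    ccs: float
    temperature_K: float  # representative T used in the Mason–Schamp step
    n_fields: int
    flags: frozenset[str] = frozenset()

    @property
    def summed_intensity(self) -> float:
        return sum(m.feature.intensity for m in self.features)

    def to_record(self) -> CCSRecord:
        mean_err = float(np.mean([m.mass_error_ppm for m in self.features]))
        mean_t = float(np.mean([m.feature.arrival_time for m in self.features]))
        return CCSRecord(
            name=self.target.name,
            adduct=self.target.adduct.label,
            mz=self.target.expected_mz,
            charge_z=self.target.charge_z,
            ccs=self.ccs,
            k0=self.K0,
            r_squared=min(self.r_squared, 1.0),
            n_fields=self.n_fields,
            intensity=self.summed_intensity,
            mass_error_ppm=mean_err,
            arrival_time=mean_t,
            flags=self.flags,
        )


def _fits_duplicate(a: ConformerFit, b: ConformerFit) -> bool:
    if abs(a.ccs - b.ccs) / b.ccs >= DUPLICATE_CCS_REL_TOL:
        return False
    fa = {id(m.feature) for m in a.features}
    fb = {id(m.feature) for m in b.features}
    smaller = min(len(fa), len(fb))
    return len(fa & fb) * 2 >= smaller


def enumerate_and_fit(
    target: TargetIon,
    per_field_candidates: list[list[Match]],
    x_axis: np.ndarray,
    temperatures_K: list[float],
    gas: BufferGas,
    r2_threshold: float = DEFAULT_R2_THRESHOLD,
    min_fields: int | None = None,
    field_ids: list[int] | None = None,
    merge_duplicates: bool = True,
) -> list[ConformerFit]:
    """Regress every candidate combination and keep fits with r^2 >= threshold.

    ``per_field_candidates[i]`` holds the (rank-limited) matches in field i,
    aligned with ``x_axis`` and ``temperatures_K``.  With ``min_fields``
    below the number of candidate-bearing fields, combinations may skip
    fields.  K0 = 1/slope; CCS is evaluated at the mean drift temperature of
    the fields in the combination.  Results are sorted by descending r^2,
    then descending summed intensity.  Fits whose CCS agree within 0.5% and
    that share at least half their features are merged (higher r^2 wins).
    """
    n = len(per_field_candidates)
    if not (0.0 < r2_threshold <= 1.0):
        raise InvalidInputError(f"r2_threshold must be in (0, 1], got {r2_threshold}")
    if len(x_axis) != n or len(temperatures_K) != n:
        raise InvalidInputError("per-field candidates, x-axis and temperatures must align")
    if field_ids is None:
        field_ids = list(range(n))

    available = sum(1 for c in per_field_candidates if c)
    if min_fields is None:
        min_fields = max(available, 2)
    if min_fields < 2:
        raise InvalidInputError(f"min_fields must be >= 2, got {min_fields}")
    if available < min_fields:
        return []  # target simply not detected in enough fields

    allow_skip = min_fields < available
    pools: list[list[Match | None]] = [
        (list(c) + [None]) if (allow_skip and c) else (list(c) if c else [None])
        for c in per_field_candidates
    ]

    ion = IonSpecies(mz=target.expected_mz, charge_z=target.charge_z,
                     polarity=target.polarity)

    accepted: list[ConformerFit] = []
    for combo in itertools.product(*pools):
        used = [(i, m) for i, m in enumerate(combo) if m is not None]
        if len(used) < max(min_fields, 2):
            continue
        idx = [i for i, _ in used]
        xs = x_axis[idx]
        ts = np.array([m.feature.arrival_time for _, m in used])
        fit = stats.linregress(xs, ts)
        r2 = fit.rvalue**2
        if r2 < r2_threshold:
            continue
        if fit.slope <= 0:
            logger.debug(
                "discarding passing fit with non-positive slope %.4g for %s %s",
                fit.slope, target.name, target.adduct.label,
            )
            continue
        K0 = 1.0 / fit.slope
        T_rep = float(np.mean([temperatures_K[i] for i in idx]))
        ccs = mobility_to_ccs(K0, ion, gas, T_rep)
        accepted.append(ConformerFit(
            target=target,
            features=tuple(m for _, m in used),
            field_ids=tuple(field_ids[i] for i in idx),
            slope=float(fit.slope),
            intercept_t0=float(fit.intercept),
            r_squared=float(r2),
            K0=K0,
            ccs=ccs,
            temperature_K=T_rep,
            n_fields=len(used),
        ))

    accepted.sort(key=lambda f: (-f.r_squared, -f.summed_intensity))
    if not merge_duplicates:
        return accepted
    distinct: list[ConformerFit] = []
    for fit in accepted:
        if any(_fits_duplicate(fit, kept) for kept in distinct):
            continue
        distinct.append(fit)
    return distinct


@dataclass
class ReplicateSummary:
    """Mean CCS and %RSD over technical replicates of one molecule/adduct."""

    name: str
    adduct: str
    n: int
    mean_ccs: float
    rsd_percent: float
    flags: frozenset[str] = frozenset()


def summarize_replicates(ccs_values: list[float], name: str = "", adduct: str = "") -> ReplicateSummary:
    """Arithmetic mean and %RSD (sample sd, n-1) of replicate CCS values.

    A single replicate yields RSD 0 with a ``single_replicate`` flag.
    """
    if not ccs_values:
        raise InsufficientDataError("at least one replicate is required")
    n = len(ccs_values)
    mean = float(np.mean(ccs_values))
    if n == 1:
        return ReplicateSummary(name, adduct, 1, mean, 0.0, frozenset({"single_replicate"}))
    sd = float(np.std(ccs_values, ddof=1))
    return ReplicateSummary(name, adduct, n, mean, 100.0 * sd / mean)


class SteppedFieldModel:
    """Stepped-field regression model for one target ion.

    Parameters
    ----------
    target:
        The adduct ion to search for.
    features_per_field:
        Mapping field_id -> features detected in that field.
    metadata:
        One :class:`FrameMetadata` per field (a single run).
    gas:
        Buffer gas of the drift cell.
    tol_ppm, max_rank:
        m/z tolerance for candidate matching and the per-field intensity-rank
        cap on candidates (keeps the combination count bounded by
        (max_rank+1)^n_fields).
    """

    def __init__(
        self,
        target: TargetIon,
        features_per_field: dict[int, list[Feature]],
        metadata: list[FrameMetadata],
        gas: BufferGas,
        tol_ppm: float = 20.0,
        max_rank: int = 3,
    ):
        self.target = target
        self.gas = gas
        self.tol_ppm = tol_ppm
        self.max_rank = max_rank
        self.metadata = sorted(metadata, key=lambda m: m.field_id)
        self.features_per_field = features_per_field
        self.x_axis = build_field_axis(self.metadata)
        self.temperatures_K = [m.temperature_K for m in self.metadata]
        self.field_ids = [m.field_id for m in self.metadata]

    def _candidates(self) -> list[list[Match]]:
        out: list[list[Match]] = []
        for m in self.metadata:
            feats = self.features_per_field.get(m.field_id, [])
            matches = match_features(self.target, feats, self.tol_ppm)
            kept = limit_by_intensity_rank([mm.feature for mm in matches], self.max_rank)
            kept_ids = {id(f) for f in kept}
            out.append([mm for mm in matches if id(mm.feature) in kept_ids])
        return out

    def fit(
        self,
        r2_threshold: float = DEFAULT_R2_THRESHOLD,
        min_fields: int | None = None,
    ) -> "SteppedFieldResults":
        conformers = enumerate_and_fit(
            self.target,
            self._candidates(),
            self.x_axis,
            self.temperatures_K,
            self.gas,
            r2_threshold=r2_threshold,
            min_fields=min_fields,
            field_ids=self.field_ids,
        )
        return SteppedFieldResults(self, conformers, r2_threshold)


@dataclass
class SteppedFieldResults:
    """Accepted conformer fits for one target ion."""

    model: SteppedFieldModel
    conformers: list[ConformerFit]
    r2_threshold: float
    extra_flags: frozenset[str] = dc_field(default_factory=frozenset)

    def to_records(self) -> list[CCSRecord]:
        return [c.to_record() for c in self.conformers]

    def summary(self) -> str:
        t = self.model.target
        lines = [
            f"Stepped-field fit: {t.name} {t.adduct.label} "
            f"(expected m/z {t.expected_mz:.4f}, z={t.charge_z})",
            f"fields: {len(self.model.metadata)}, r2 threshold: {self.r2_threshold}",
            f"conformers accepted: {len(self.conformers)}",
        ]
        for i, c in enumerate(self.conformers, 1):
            lines.append(
                f"  [{i}] CCS {c.ccs:.4f} A^2  K0 {c.K0:.6f} cm^2/(V s)  "
                f"r^2 {c.r_squared:.6f}  t0 {c.intercept_t0:.4f} ms  "
                f"fields {c.n_fields}"
            )
        return "\n".join(lines)
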