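"""Readers and writers for feature tables, instrument metadata and results.

Supported inputs are deliberately plain-text:

* feature tables as MZmine-style CSV (configurable column-name map; the
  MZmine 2 export reuses its retention-time column for IMS arrival time) or
  as a minimal CEF-like XML dialect (see :data:`CEF_SCHEMA_NOTE`);
* frame/field metadata as CSV, one row per (run_id, field_id) with drift
  voltage, pressure, temperature, drift length, acquisition timestamp and
  polarity;
* target-molecule and calibrant lists as CSV.

Readers never reorder, deduplicate or filter rows — all selection logic
lives downstream.  Results are written as a tab-delimited table with a
fixed column order and deterministic row ordering.
"""

from __future__ import annotations

import math
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field as dc_field
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import IntegrityError, RowParseError, SchemaError
from .physics import celsius_to_kelvin

__all__ = [
    "Feature",
    "FrameMetadata",
    "TargetMolecule",
    "CalibrantIon",
    "CCSRecord",
    "CsvDialect",
    "read_features_csv",
    "write_features_csv",
    "read_features_cef",
    "write_features_cef",
    "read_frame_metadata",
    "write_frame_metadata",
    "read_targets_csv",
    "read_calibrants_csv",
    "write_ccs_records",
    "read_ccs_records",
]

#: Normative sketch of the minimal CEF-like XML dialect this package reads
#: and writes.  Full vendor CEF is out of scope; only m/z, drift time and
#: intensity are carried.
CEF_SCHEMA_NOTE = """
<CEF version="1.0">
  <CompoundList>
    <Compound>                       <!-- one detected feature -->
      <Location m="322.0481"        <!-- m/z (Th), required -->
                dt="25.31"          <!-- drift/arrival time (ms), required -->
                i="100000"/>        <!-- intensity (counts), optional, default 0 -->
    </Compound>
  </CompoundList>
</CEF>
"""


@dataclass
class Feature:
    """One detected ion: m/z, arrival time and intensity within a run/field."""

    mz: float
    arrival_time: float  # ms
    intensity: float
    run_id: str = ""
    field_id: int | None = None
    extra: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mz = float(self.mz)
        self.arrival_time = float(self.arrival_time)
        self.intensity = float(self.intensity)
        if self.mz <= 0:
            raise ValueError(f"feature mz must be > 0, got {self.mz}")
        if self.arrival_time <= 0:
            raise ValueError(f"arrival_time must be > 0, got {self.arrival_time}")
        if self.intensity < 0:
            raise ValueError(f"intensity must be >= 0, got {self.intensity}")


@dataclass(frozen=True)
class FrameMetadata:
    """Per-field instrument conditions for one acquisition."""

    run_id: str
    field_id: int
    drift_voltage_V: float
    pressure_P: float  # Torr
    temperature_C: float
    drift_length_L: float  # cm
    acquisition_timestamp: str  # ISO-8601; naive timestamps taken as UTC
    polarity: str = "positive"

    def __post_init__(self) -> None:
        if self.drift_voltage_V <= 0:
            raise ValueError(f"drift voltage must be > 0, got {self.drift_voltage_V}")
        if self.pressure_P <= 0:
            raise ValueError(f"pressure must be > 0, got {self.pressure_P}")
        if self.drift_length_L <= 0:
            raise ValueError(f"drift length must be > 0, got {self.drift_length_L}")
        if self.temperature_C <= -273.15:
            raise ValueError(f"temperature below absolute zero: {self.temperature_C} C")
        if self.polarity not in ("positive", "negative"):
            raise ValueError(f"polarity must be positive|negative, got {self.polarity!r}")
        self.timestamp_dt  # fail fast on unparseable timestamps

    @property
    def temperature_K(self) -> float:
        return celsius_to_kelvin(self.temperature_C)

    @property
    def timestamp_dt(self) -> datetime:
        dt = datetime.fromisoformat(self.acquisition_timestamp)
        if dt.tzinfo is None:
            dt = dt.replace(tzinfo=timezone.utc)
        return dt


@dataclass(frozen=True)
class TargetMolecule:
    name: str
    neutral_mass: float  # Da

    def __post_init__(self) -> None:
        if self.neutral_mass <= 0:
            raise ValueError(f"neutral mass must be > 0, got {self.neutral_mass}")


@dataclass(frozen=True)
class CalibrantIon:
    """A reference ion with literature/stepped-field CCS used for calibration."""

    name: str
    mz: float
    charge_z: int
    reference_ccs: float  # A^2
    polarity: str = "positive"

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError(f"calibrant mz must be > 0, got {self.mz}")
        if self.reference_ccs <= 0:
            raise ValueError(f"reference ccs must be > 0, got {self.reference_ccs}")


#: fixed output column order of the results table
CCS_COLUMNS = [
    "name",
    "adduct",
    "mz",
    "charge_z",
    "ccs",
    "k0",
    "r_squared",
    "n_fields",
    "intensity",
    "mass_error_ppm",
    "arrival_time",
    "flags",
]


@dataclass
class CCSRecord:
    """One output row: ion identity, CCS and fit diagnostics."""

    name: str
    adduct: str
    mz: float
    charge_z: int
    ccs: float | None
    k0: float | None = None
    r_squared: float | None = None
    n_fields: int | None = None
    intensity: float = 0.0
    mass_error_ppm: float = 0.0
    arrival_time: float = 0.0
    flags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.ccs is not None and self.ccs <= 0 and "invalid" not in self.flags:
            raise ValueError(f"ccs must be > 0 when present, got {self.ccs}")
        if self.r_squared is not None and not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise ValueError(f"r_squared out of [0,1]: {self.r_squared}")


@dataclass(frozen=True)
class CsvDialect:
    """Column-name map for MZmine-style feature CSVs.

    Defaults match the MZmine 2 export convention where the retention-time
    column actually carries the IMS arrival time.  ``intensity`` may name an
    exact column; if None, the first column whose name contains
    'peak height', 'peak area', 'height' or 'intensity' (case-insensitive)
    is used.
    """

    mz: str = "row m/z"
    arrival_time: str = "row retention time"
    intensity: str | None = None
    run_id: str = "run_id"
    field_id: str = "field_id"


_INTENSITY_HINTS = ("peak height", "peak area", "height", "intensity")


def _resolve_intensity_column(columns: Sequence[str], dialect: CsvDialect) -> str:
    if dialect.intensity is not None:
        if dialect.intensity not in columns:
            raise SchemaError(f"missing required column {dialect.intensity!r} (intensity)")
        return dialect.intensity
    for hint in _INTENSITY_HINTS:
        for col in columns:
            if hint in col.lower():
                return col
    raise SchemaError(
        "no intensity column found; expected a column containing "
        f"one of {_INTENSITY_HINTS} or an explicit dialect.intensity"
    )


def read_features_csv(path: str | Path, dialect: CsvDialect | None = None) -> list[Feature]:
    """Read an MZmine-style feature CSV into a list of :class:`Feature`.

    Row order is preserved; unknown columns go into ``Feature.extra``.
    """
    dialect = dialect or CsvDialect()
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for required, role in ((dialect.mz, "m/z"), (dialect.arrival_time, "arrival time")):
        if required not in df.columns:
            raise SchemaError(f"missing required column {required!r} ({role})")
    intensity_col = _resolve_intensity_column(list(df.columns), dialect)

    known = {dialect.mz, dialect.arrival_time, intensity_col, dialect.run_id, dialect.field_id}
    features: list[Feature] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header line
        rec = dict(zip(df.columns, row))
        try:
            mz = float(rec[dialect.mz])
            t = float(rec[dialect.arrival_time])
            inten = float(rec[intensity_col]) if rec[intensity_col] != "" else 0.0
        except ValueError as exc:
            raise RowParseError(f"unparseable numeric value: {exc}", line=i) from None
        run_id = str(rec.get(dialect.run_id, "") or "")
        field_raw = rec.get(dialect.field_id, "")
        try:
            field_id = int(field_raw) if field_raw not in ("", None) else None
        except ValueError:
            raise RowParseError(f"unparseable field id {field_raw!r}", line=i) from None
        extra = {k: v for k, v in rec.items() if k not in known}
        features.append(
            Feature(mz=mz, arrival_time=t, intensity=inten, run_id=run_id,
                    field_id=field_id, extra=extra)
        )
    return features


def write_features_csv(
    features: Iterable[Feature], path: str | Path, dialect: CsvDialect | None = None
) -> None:
    """Write features as an MZmine-style CSV readable by read_features_csv."""
    dialect = dialect or CsvDialect()
    intensity_col = dialect.intensity or "intensity"
    rows = []
    for f in features:
        row = {
            dialect.mz: repr(f.mz),
            dialect.arrival_time: repr(f.arrival_time),
            intensity_col: repr(f.intensity),
            dialect.run_id: f.run_id,
            dialect.field_id: "" if f.field_id is None else f.field_id,
        }
        row.update(f.extra)
        rows.append(row)
    columns = [dialect.mz, dialect.arrival_time, intensity_col,
               dialect.run_id, dialect.field_id]
    if rows:
        for k in rows[0]:
            if k not in columns:
                columns.append(k)
    pd.DataFrame(rows, columns=columns).to_csv(path, index=False)


def read_features_cef(path: str | Path) -> list[Feature]:
    """Read the minimal CEF-like XML dialect (one Feature per Compound)."""
    try:
        tree = ET.parse(path)
    except ET.ParseError as exc:
        raise RowParseError(f"malformed XML in {path}: {exc}") from None
    features: list[Feature] = []
    for compound in tree.getroot().iter("Compound"):
        loc = compound.find("Location")
        if loc is None:
            raise SchemaError("Compound element without Location child")
        if "m" not in loc.attrib:
            raise SchemaError("Location element missing m (m/z) attribute")
        if "dt" not in loc.attrib:
            raise SchemaError("Location element missing dt (drift time) attribute")
        features.append(
            Feature(
                mz=float(loc.attrib["m"]),
                arrival_time=float(loc.attrib["dt"]),
                intensity=float(loc.attrib.get("i", 0.0)),
            )
        )
    return features


def write_features_cef(features: Iterable[Feature], path: str | Path) -> None:
    """Write features in the minimal CEF-like dialect (see CEF_SCHEMA_NOTE)."""
    root = ET.Element("CEF", version="1.0")
    clist = ET.SubElement(root, "CompoundList")
    for f in features:
        compound = ET.SubElement(clist, "Compound")
        ET.SubElement(
            compound, "Location",
            m=repr(f.mz), dt=repr(f.arrival_time), i=repr(f.intensity),
        )
    ET.indent(root)
    ET.ElementTree(root).write(path, encoding="unicode", xml_declaration=True)


_META_COLUMNS = [
    "run_id", "field_id", "voltage_V", "pressure_Torr",
    "temperature_C", "length_cm", "timestamp", "polarity",
]


def read_frame_metadata(path: str | Path) -> list[FrameMetadata]:
    """Read a frame-metadata CSV; one validated record per (run_id, field_id)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _META_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"frame metadata missing columns: {missing}")
    records: list[FrameMetadata] = []
    seen: set[tuple[str, int]] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):
        rec = dict(zip(df.columns, row))
        try:
            meta = FrameMetadata(
                run_id=str(rec["run_id"]),
                field_id=int(rec["field_id"]),
                drift_voltage_V=float(rec["voltage_V"]),
                pressure_P=float(rec["pressure_Torr"]),
                temperature_C=float(rec["temperature_C"]),
                drift_length_L=float(rec["length_cm"]),
                acquisition_timestamp=str(rec["timestamp"]),
                polarity=str(rec["polarity"]),
            )
        except ValueError as exc:
            raise RowParseError(str(exc), line=i) from None
        key = (meta.run_id, meta.field_id)
        if key in seen:
            raise IntegrityError(f"duplicate (run_id, field_id) = {key}")
        seen.add(key)
        records.append(meta)
    return records


def write_frame_metadata(records: Iterable[FrameMetadata], path: str | Path) -> None:
    rows = [
        {
            "run_id": m.run_id,
            "field_id": m.field_id,
            "voltage_V": m.drift_voltage_V,
            "pressure_Torr": m.pressure_P,
            "temperature_C": m.temperature_C,
            "length_cm": m.drift_length_L,
            "timestamp": m.acquisition_timestamp,
            "polarity": m.polarity,
        }
        for m in records
    ]
    pd.DataFrame(rows, columns=_META_COLUMNS).to_csv(path, index=False)


def read_targets_csv(path: str | Path) -> list[TargetMolecule]:
    """Read a target-molecule list (columns: name, neutral_mass)."""
    df = pd.read_csv(path)
    for col in ("name", "neutral_mass"):
        if col not in df.columns:
            raise SchemaError(f"target list missing column {col!r}")
    names = list(df["name"].astype(str))
    if len(set(names)) != len(names):
        raise IntegrityError("duplicate molecule names in target list")
    return [
        TargetMolecule(name=str(r["name"]), neutral_mass=float(r["neutral_mass"]))
        for _, r in df.iterrows()
    ]


def read_calibrants_csv(path: str | Path) -> list[CalibrantIon]:
    """Read a calibrant list (columns: name, mz, z, ccs, polarity)."""
    df = pd.read_csv(path)
    for col in ("name", "mz", "z", "ccs", "polarity"):
        if col not in df.columns:
            raise SchemaError(f"calibrant list missing column {col!r}")
    return [
        CalibrantIon(
            name=str(r["name"]), mz=float(r["mz"]), charge_z=int(r["z"]),
            reference_ccs=float(r["ccs"]), polarity=str(r["polarity"]),
        )
        for _, r in df.iterrows()
    ]


def _fmt(value, ndigits: int) -> str:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return ""
    return f"{value:.{ndigits}f}"


def write_ccs_records(records: Sequence[CCSRecord], path: str | Path) -> None:
    """Write results as a tab-delimited table.

    Rows are sorted by (name, adduct, mz); CCS is printed with 4 decimals.
    An empty record list yields a header-only file.
    """
    ordered = sorted(records, key=lambda r: (r.name, r.adduct, r.mz))
    rows = []
    for r in ordered:
        rows.append({
            "name": r.name,
            "adduct": r.adduct,
            "mz": _fmt(r.mz, 6),
            "charge_z": r.charge_z,
            "ccs": _fmt(r.ccs, 4),
            "k0": _fmt(r.k0, 6),
            "r_squared": _fmt(r.r_squared, 6),
            "n_fields": "" if r.n_fields is None else r.n_fields,
            "intensity": _fmt(r.intensity, 1),
            "mass_error_ppm": _fmt(r.mass_error_ppm, 3),
            "arrival_time": _fmt(r.arrival_time, 4),
            "flags": ";".join(sorted(r.flags)),
        })
    pd.DataFrame(rows, columns=CCS_COLUMNS).to_csv(path, sep="\t", index=False)


def read_ccs_records(path: str | Path) -> list[CCSRecord]:
    """Read back a results table written by :func:`write_ccs_records`."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)

    def opt_float(s: str) -> float | None:
        return None if s == "" else float(s)

    out = []
    for _, r in df.iterrows():
        out.append(CCSRecord(
            name=r["name"], adduct=r["adduct"], mz=float(r["mz"]),
            charge_z=int(r["charge_z"]), ccs=opt_float(r["ccs"]),
            k0=opt_float(r["k0"]), r_squared=opt_float(r["r_squared"]),
            n_fields=None if r["n_fields"] == "" else int(r["n_fields"]),
            intensity=float(r["intensity"] or 0.0),
            mass_error_ppm=float(r["mass_error_ppm"] or 0.0),
            arrival_time=float(r["arrival_time"] or 0.0),
            flags=frozenset(x for x in r["flags"].split(";") if x),
        ))
    return out
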