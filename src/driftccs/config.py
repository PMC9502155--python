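"""Run configuration: schema-validated, unknown keys rejected.

A run is described by a single YAML file and/or command-line flags (flags
win).  The same model backs every workflow; fields irrelevant to the chosen
workflow are simply unused.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, field_validator

from .errors import ConfigError
from .targets import AdductSpec, DEFAULT_ADDUCTS

__all__ = ["RunConfig", "load_config"]


class AdductConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    label: str
    mass_shift: float
    charge_z: int = Field(ge=1)
    polarity: Literal["positive", "negative"]

    def to_spec(self) -> AdductSpec:
        return AdductSpec(self.label, self.mass_shift, self.charge_z, self.polarity)


class RunConfig(BaseModel):
    """Validated configuration for one workflow run."""

    model_config = ConfigDict(extra="forbid")

    workflow: Literal["stepped", "single", "twims", "synth"]

    # paths
    features: Optional[Path] = None
    metadata: Optional[Path] = None
    targets: Optional[Path] = None
    calibrants: Optional[Path] = None
    out: Path = Path("driftccs_out")

    # matching / regression
    tolerance_ppm: float = Field(default=20.0, gt=0)
    r2_threshold: float = Field(default=0.99, gt=0, le=1)
    max_rank: int = Field(default=3, ge=1)
    min_fields: Optional[int] = Field(default=None, ge=2)

    # single-field
    mode: Literal["standard", "enhanced", "tims_scan"] = "standard"

    # traveling-wave
    twims_method: Literal["polynomial", "power"] = "power"
    degree_D: int = Field(default=2, ge=1, le=4)
    t_acc: float = Field(default=0.0, ge=0)
    edc_C: float = Field(default=0.0, ge=0)

    # general
    gas: str = "nitrogen"
    polarity: Literal["positive", "negative"] = "positive"
    adducts: Optional[list[AdductConfig]] = None
    default_charge: int = Field(default=1, ge=1)
    seed: int = 0
    plots: bool = False

    # synth workflow: which campaign to generate
    synth_kind: Literal["stepped", "single", "twims"] = "stepped"

    def adduct_specs(self) -> tuple[AdductSpec, ...]:
        if self.adducts is None:
            return DEFAULT_ADDUCTS
        return tuple(a.to_spec() for a in self.adducts)


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> RunConfig:
    """Build a RunConfig from an optional YAML file plus flag overrides.

    Overrides with value None are ignored; unknown keys in either source
    raise :class:`ConfigError`.
    """
    data: dict = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text())
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"config file {path} must contain a mapping")
        data.update(loaded)
    for key, value in (overrides or {}).items():
        if value is not None:
            data[key] = value
    try:
        return RunConfig(**data)
    except ValidationError as exc:
        raise ConfigError(str(exc)) from None
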