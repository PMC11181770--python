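"""Run configuration: loading, validation, defaults.

A run is driven by a single YAML file; unknown keys are rejected so that
typos surface as validation errors before any stage executes.
"""
from __future__ import annotations

import dataclasses
import datetime
import hashlib
import json
from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, field_validator

from ._types import ConfigurationError
from .metrics import DEFAULT_LOS_BINS
from .synthetic import GeneratorParams


class TimeRangeConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    start: datetime.date = datetime.date(2011, 1, 1)
    end: datetime.date = datetime.date(2020, 12, 31)


class RunConfig(BaseModel):
    """Validated configuration for the end-to-end pipeline."""

    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    out_dir: str = "epispell_out"
    models: list[int] = [1, 2, 3, 4]
    los_convention: Literal["nights", "days"] = "nights"
    year_assignment: Literal["discharge", "admission"] = "discharge"
    time_range: TimeRangeConfig = TimeRangeConfig()
    los_bins: list[int] = list(DEFAULT_LOS_BINS)
    # input files; when entries_path is absent the synthetic generator runs
    entries_path: str | None = None
    persons_path: str | None = None
    schema_map: dict[str, str] = {}
    # configuration files; packaged defaults are used when absent
    era_rules_path: str | None = None
    mapping_path: str | None = None
    categories_path: str | None = None
    # overrides for the synthetic generator (field names of GeneratorParams)
    simulate: dict = {}

    @field_validator("models")
    @classmethod
    def _check_models(cls, v: list[int]) -> list[int]:
        if not v or any(m not in {1, 2, 3, 4} for m in v):
            raise ValueError("models must be a non-empty subset of {1, 2, 3, 4}")
        return sorted(set(v))

    @field_validator("simulate")
    @classmethod
    def _check_simulate(cls, v: dict) -> dict:
        known = {f.name for f in dataclasses.fields(GeneratorParams)}
        unknown = set(v) - known
        if unknown:
            raise ValueError(f"unknown simulate key(s): {sorted(unknown)}")
        return v

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        try:
            return cls.model_validate(raw)
        except Exception as exc:
            raise ConfigurationError(f"invalid run configuration {path}: {exc}") from exc

    def generator_params(self) -> GeneratorParams:
        overrides = dict(self.simulate)
        if "date_range" in overrides:
            lo, hi = overrides["date_range"]
            overrides["date_range"] = (_as_date(lo), _as_date(hi))
        else:
            overrides["date_range"] = (self.time_range.start, self.time_range.end)
        overrides.setdefault("seed", self.seed)
        return GeneratorParams(**overrides)

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()


def _as_date(v) -> datetime.date:
    return v if isinstance(v, datetime.date) else datetime.date.fromisoformat(str(v))
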