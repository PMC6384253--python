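"""Pipeline configuration: a single YAML document, strictly validated.

Unknown keys are rejected so typos cannot silently fall back to
defaults, and configs round-trip losslessly through to_dict/from_dict.
"""

from __future__ import annotations

import dataclasses
import io
import os
from dataclasses import dataclass, field
from typing import Optional, Union

import yaml

from .errors import ConfigError
from .filters import FunctionalThresholds, QCThresholds
from .scoring import ScoringConfig


def _from_mapping(cls, data: dict, section: str):
    if not isinstance(data, dict):
        raise ConfigError(f"section {section!r} must be a mapping")
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown key(s) in {section!r}: {sorted(unknown)}")
    try:
        return cls(**data)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid value in section {section!r}: {exc}") from exc


@dataclass
class PipelineConfig:
    vcf: Optional[str] = None
    ped: Optional[str] = None
    out_dir: Optional[str] = None
    qc: QCThresholds = field(default_factory=QCThresholds)
    functional: FunctionalThresholds = field(default_factory=FunctionalThresholds)
    scoring: ScoringConfig = field(default_factory=ScoringConfig)
    obligate_carriers: list[str] = field(default_factory=list)
    missing_as_compatible: bool = False
    seed: int = 0
    verbosity: str = "INFO"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        if not isinstance(data, dict):
            raise ConfigError("config root must be a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown top-level key(s): {sorted(unknown)}")
        data = dict(data)
        for key, klass in (
            ("qc", QCThresholds),
            ("functional", FunctionalThresholds),
            ("scoring", ScoringConfig),
        ):
            if key in data:
                data[key] = _from_mapping(klass, data[key], key)
        try:
            return cls(**data)
        except (TypeError, ValueError) as exc:
            raise ConfigError(str(exc)) from exc


def load_config(source: Union[str, os.PathLike, io.TextIOBase]) -> PipelineConfig:
    if isinstance(source, (str, os.PathLike)):
        with open(source) as fh:
            return load_config(fh)
    data = yaml.safe_load(source)
    if data is None:
        data = {}
    return PipelineConfig.from_dict(data)


def dump_config(config: PipelineConfig, dest: Union[str, os.PathLike, io.TextIOBase]) -> None:
    if isinstance(dest, (str, os.PathLike)):
        with open(dest, "w") as fh:
            dump_config(config, fh)
            return
    yaml.safe_dump(config.to_dict(), dest, sort_keys=False)
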