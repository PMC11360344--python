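"""Run-level configuration: one JSON file resolving to all module configs.

Example config file (every key optional; defaults reproduce the standard
pipeline constants)::

    {
      "filter": "actigraph",
      "wear": "troiano",
      "cut_points": "freedson_adult_1998",
      "counts": {"epoch_length_s": 60, "scale_factor": 17.127404},
      "steps": {"axis": "y"},
      "troiano": {"min_nonwear_minutes": 60},
      "dialect": {"header_line_count": 10, "column_order": ["x", "y", "z"]}
    }
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from .counts import CountsConfig
from .errors import ContractError, FormatError
from .filters import FilterSpec, get_filter
from .metrics import FREEDSON_ADULT_1998, CutPointScheme
from .raw_io import RawCsvDialect
from .steps import StepConfig
from .wear import TroianoConfig

__all__ = ["RunConfig", "load_run_config"]

_SCHEMES = {"freedson_adult_1998": FREEDSON_ADULT_1998}


@dataclass
class RunConfig:
    counts: CountsConfig = field(default_factory=CountsConfig)
    steps: StepConfig = field(default_factory=StepConfig)
    troiano: TroianoConfig = field(default_factory=TroianoConfig)
    dialect: RawCsvDialect = field(default_factory=RawCsvDialect)
    filter_name: str = "actigraph"
    wear_mode: str = "troiano"  # 'troiano' | 'none'
    scheme_name: str = "freedson_adult_1998"

    def __post_init__(self) -> None:
        if self.wear_mode not in ("troiano", "none"):
            raise ContractError(f"wear mode must be 'troiano' or 'none', got '{self.wear_mode}'")
        if self.scheme_name not in _SCHEMES:
            raise ContractError(f"unknown cut-point scheme '{self.scheme_name}'")
        self.filter_spec  # resolve eagerly so bad names fail before computation

    @property
    def filter_spec(self) -> FilterSpec:
        return get_filter(self.filter_name)

    @property
    def scheme(self) -> CutPointScheme:
        return _SCHEMES[self.scheme_name]


def _build(cls, section: dict, name: str):
    try:
        return cls(**section)
    except TypeError as exc:
        raise FormatError(f"config section '{name}': {exc}") from None


def load_run_config(path: str | Path | None) -> RunConfig:
    """Load a RunConfig from a JSON file; ``None`` yields all defaults."""
    if path is None:
        return RunConfig()
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise FormatError(f"config file is not valid JSON: {exc}") from None
    known = {"filter", "wear", "cut_points", "counts", "steps", "troiano", "dialect"}
    unknown = set(doc) - known
    if unknown:
        raise FormatError(f"config file: unknown keys {sorted(unknown)}")
    dialect_section = dict(doc.get("dialect", {}))
    if "column_order" in dialect_section:
        dialect_section["column_order"] = tuple(dialect_section["column_order"])
    return RunConfig(
        counts=_build(CountsConfig, doc.get("counts", {}), "counts"),
        steps=_build(StepConfig, doc.get("steps", {}), "steps"),
        troiano=_build(TroianoConfig, doc.get("troiano", {}), "troiano"),
        dialect=_build(RawCsvDialect, dialect_section, "dialect"),
        filter_name=doc.get("filter", "actigraph"),
        wear_mode=doc.get("wear", "troiano"),
        scheme_name=doc.get("cut_points", "freedson_adult_1998"),
    )
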