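"""Run configuration: YAML-backed, flag-overridable."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigurationError

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Everything an end-to-end run needs.

    Paths may be None when the corresponding stage is skipped (e.g.
    ``fixed_transitions`` replaces fitting Model 2 from ``panel``).
    """

    population: str | None = None
    life_table: str | None = None
    cross_sections: str | None = None
    panel: str | None = None
    fixed_transitions: str | None = None
    fixed_transitions_sex: str = "both"

    window_start: int = 2002
    window_end: int = 2011
    estimation_year: int | None = None
    cohort_size: int = 200_000
    rule: str = "max"
    bootstrap_b: int = 1000
    seed: int = 0
    backend: str = "mc"
    toggles: dict = field(default_factory=lambda: {
        "prevalence": True, "transitions": True, "life_table": True})
    out_dir: str = "results"
    run_bootstrap: bool = False

    def __post_init__(self) -> None:
        est = self.estimation_year
        if est is None:
            self.estimation_year = self.window_end
        if not self.window_start < self.window_end <= self.estimation_year:
            raise ConfigurationError("years must be ordered: window_start < "
                                     "window_end <= estimation_year")
        if self.cohort_size < 1:
            raise ConfigurationError("cohort_size must be >= 1")
        if self.bootstrap_b < 1:
            raise ConfigurationError("bootstrap_b must be >= 1")
        if self.backend not in ("mc", "dp"):
            raise ConfigurationError("backend must be 'mc' or 'dp'")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - fields
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]
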