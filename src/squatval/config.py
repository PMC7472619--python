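"""Run configuration: one serializable object reproduces a whole run.

A :class:`RunConfig` wraps the population/noise spec plus the processing
knobs (filter settings, calibration window, peak-extraction mode).  It is
round-trippable through YAML/JSON so that ``config + seed`` is sufficient
to regenerate a study byte-for-byte.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .simulate import PopulationSpec

__all__ = ["RunConfig"]


@dataclass(frozen=True)
class RunConfig:
    population: PopulationSpec = field(default_factory=PopulationSpec)
    filter_order: int = 4
    filter_cutoff_hz: float = 3.0
    zero_phase: bool = True
    max_gap_s: float = 0.1
    #: "per-modality" (each system reads its own peak instant) or "shared"
    peak_mode: str = "per-modality"

    def __post_init__(self) -> None:
        if self.peak_mode not in ("per-modality", "shared"):
            raise ValueError("peak_mode must be 'per-modality' or 'shared'")
        if not self.zero_phase:
            raise ValueError(
                "only zero-phase filtering is supported: peak timing must be lag-free"
            )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "population" in d and isinstance(d["population"], dict):
            d["population"] = PopulationSpec.from_dict(d["population"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def with_overrides(self, **kw) -> "RunConfig":
        """CLI overrides: seed/subjects/trials land on the population spec."""
        pop_keys = {"seed", "n_subjects", "n_trials"}
        pop_kw = {k: v for k, v in kw.items() if k in pop_keys and v is not None}
        cfg_kw = {k: v for k, v in kw.items() if k not in pop_keys and v is not None}
        pop = self.population.replace(**pop_kw) if pop_kw else self.population
        return dataclasses.replace(self, population=pop, **cfg_kw)
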