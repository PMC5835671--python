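"""Run configuration: one serializable block of every pipeline threshold."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .rhythmicity import AnalysisConfig

__all__ = ["HygieneConfig", "ExpressionConfig", "RunConfig"]


@dataclass
class HygieneConfig:
    """Data-hygiene rules applied before any analysis."""

    death_run_hours: float = 24.0      # terminal zero run scoring death
    min_alive_days: float = 4.0        # survival needed for inclusion
    max_missing_fraction: float = 0.05
    exclude_first_day: bool = True     # adaptation day

    def __post_init__(self) -> None:
        if self.death_run_hours <= 0:
            raise ValueError("death_run_hours must be positive")
        if not 0 <= self.max_missing_fraction <= 1:
            raise ValueError("max_missing_fraction must lie in [0, 1]")


@dataclass
class ExpressionConfig:
    calibrator_sample: str | None = None  # None -> earliest-timepoint sample
    reference_genes: tuple[str, ...] = ("actb", "gapdh")
    alpha: float = 0.05


@dataclass
class RunConfig:
    """Everything a pipeline run needs, serializable losslessly."""

    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    hygiene: HygieneConfig = field(default_factory=HygieneConfig)
    expression: ExpressionConfig = field(default_factory=ExpressionConfig)
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["analysis"]["band_h"] = list(d["analysis"]["band_h"])
        d["expression"]["reference_genes"] = list(
            d["expression"]["reference_genes"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        a = dict(d.get("analysis", {}))
        if "band_h" in a:
            a["band_h"] = tuple(a["band_h"])
        e = dict(d.get("expression", {}))
        if "reference_genes" in e:
            e["reference_genes"] = tuple(e["reference_genes"])
        return cls(analysis=AnalysisConfig(**a),
                   hygiene=HygieneConfig(**d.get("hygiene", {})),
                   expression=ExpressionConfig(**e),
                   seed=int(d.get("seed", 0)))

    def save(self, path: str | Path) -> None:
        path = Path(path)
        text = (json.dumps(self.to_dict(), indent=2, sort_keys=True)
                if path.suffix == ".json"
                else yaml.safe_dump(self.to_dict(), sort_keys=True))
        path.write_text(text)

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        data = (json.loads(path.read_text()) if path.suffix == ".json"
                else yaml.safe_load(path.read_text()))
        return cls.from_dict(data)

    @property
    def hash(self) -> str:
        """Short provenance hash stamped into every output."""
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]
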