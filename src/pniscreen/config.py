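"""Pipeline operating configuration, with YAML round-tripping.

Houses the screening pipeline's operating constants: the 50% confidence
threshold, the 10,000-pixel small-focus cutoffs, the top-k presentation
counts (40, or 20 for tumor-only cases), and the simulated reviewer's rule.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

from .clinical import ReviewRule
from .proximity import RankingConfig

__all__ = ["PipelineConfig"]


@dataclass(frozen=True)
class PipelineConfig:
    threshold: float = 0.5
    min_area_tumor: int = 10_000
    min_area_nerve: int = 10_000
    connectivity: int = 8
    ranking: RankingConfig = RankingConfig()
    review: ReviewRule = ReviewRule()
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.threshold <= 1.0:
            raise ValueError("threshold must lie in [0, 1]")
        if min(self.min_area_tumor, self.min_area_nerve) < 0:
            raise ValueError("min_area must be >= 0")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")

    @property
    def min_area(self) -> dict[str, int]:
        return {"tumor": self.min_area_tumor, "nerve": self.min_area_nerve}

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["ranking"] = dataclasses.asdict(self.ranking)
        d["review"] = dataclasses.asdict(self.review)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "ranking" in data:
            _check_keys(RankingConfig, data["ranking"])
            data["ranking"] = RankingConfig(**data["ranking"])
        if "review" in data:
            _check_keys(ReviewRule, data["review"])
            data["review"] = ReviewRule(**data["review"])
        return cls(**data)

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ValueError(f"{path} does not contain a config mapping")
        return cls.from_dict(data)


def _check_keys(klass, data: dict) -> None:
    unknown = set(data) - {f.name for f in dataclasses.fields(klass)}
    if unknown:
        raise ValueError(f"unknown {klass.__name__} keys: {sorted(unknown)}")
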