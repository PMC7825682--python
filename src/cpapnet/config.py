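"""Pipeline configuration with lossless YAML round-tripping."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import yaml

from .cohort import DiscretizationRules

__all__ = ["PipelineConfig"]


@dataclass(frozen=True)
class PipelineConfig:
    """All tunables of the two-stage pipeline in one object.

    Defaults follow the clinical cutoffs and analysis choices the
    package documents: compatibility threshold 4 of 6, weighted
    modularity, best-response threshold 85%, representativeness 0.70,
    whole-centimetre ROC cutoffs 39–46.
    """

    rules: DiscretizationRules = field(default_factory=DiscretizationRules)
    compatibility_threshold: int = 4
    weighted_modularity: bool = True
    seed: int = 0
    best_threshold: float = 85.0
    representative_threshold: float = 0.70
    roc_cutoffs: tuple[float, ...] = (39, 40, 41, 42, 43, 44, 45, 46)
    table7_cutoffs: tuple[float, ...] = (39, 40, 41, 42, 43)

    def __post_init__(self) -> None:
        if not (1 <= self.compatibility_threshold <= 6):
            raise ValueError("compatibility_threshold must lie in 1..6")
        if not (0 <= self.best_threshold <= 100):
            raise ValueError("best_threshold is a percentage in [0, 100]")
        if not (0 < self.representative_threshold <= 1):
            raise ValueError("representative_threshold must lie in (0, 1]")
        if len(self.roc_cutoffs) == 0:
            raise ValueError("roc_cutoffs must not be empty")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["rules"] = dataclasses.asdict(self.rules)
        d["rules"]["age_bounds"] = list(self.rules.age_bounds)
        d["roc_cutoffs"] = list(self.roc_cutoffs)
        d["table7_cutoffs"] = list(self.table7_cutoffs)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        rules = d.pop("rules", None)
        if rules is not None:
            rules = dict(rules)
            if "age_bounds" in rules:
                rules["age_bounds"] = tuple(rules["age_bounds"])
            d["rules"] = DiscretizationRules(**rules)
        for key in ("roc_cutoffs", "table7_cutoffs"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_yaml(self, path: Union[str, Path]) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
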