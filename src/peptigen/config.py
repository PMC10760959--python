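"""Run configuration: one serializable object holds every tunable.

The config is the only mutable surface of the pipeline; it round-trips
through YAML unchanged and every named threshold is validated against
its documented bounds before a run starts.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .synthetic import CohortConfig, GenomeConfig, IdSimConfig

__all__ = ["Thresholds", "PanelConfig", "RunConfig"]

STAGES = ("simulate", "build_db", "filter", "profile", "classify", "present", "survive")


@dataclass(frozen=True)
class Thresholds:
    fdr: float = 0.01
    min_len: int = 8
    max_len: int = 11
    rank_cutoff: float = 2.0  # percent
    rphm_threshold: float = 8.55  # normal-tissue detection limit
    tissue_fraction: float = 0.10
    prevalence: float = 0.05
    cohort_expr_cutoff: float = 2.0  # rphm
    taa_fold: float = 3.0

    def validate(self) -> None:
        if not (0.0 < self.fdr < 1.0):
            raise ValueError(f"fdr out of bounds: {self.fdr}")
        if not (1 <= self.min_len <= self.max_len):
            raise ValueError(f"invalid length window: {self.min_len}-{self.max_len}")
        if not (0.0 < self.rank_cutoff <= 100.0):
            raise ValueError(f"rank_cutoff out of bounds: {self.rank_cutoff}")
        if self.rphm_threshold < 0 or self.cohort_expr_cutoff < 0:
            raise ValueError("rphm thresholds must be >= 0")
        if not (0.0 <= self.tissue_fraction < 1.0):
            raise ValueError(f"tissue_fraction out of bounds: {self.tissue_fraction}")
        if not (0.0 <= self.prevalence <= 1.0):
            raise ValueError(f"prevalence out of bounds: {self.prevalence}")
        if self.taa_fold < 1.0:
            raise ValueError(f"taa_fold must be >= 1: {self.taa_fold}")


@dataclass(frozen=True)
class PanelConfig:
    n_tumor: int = 2
    n_mtec: int = 3
    n_testis: int = 2
    n_per_normal: int = 3
    n_blood: int = 2
    n_marrow: int = 2
    depth: float = 30.0


def _as_plain(obj) -> dict:
    def convert(v):
        if isinstance(v, tuple):
            return [convert(x) for x in v]
        if isinstance(v, dict):
            return {k: convert(x) for k, x in v.items()}
        if isinstance(v, list):
            return [convert(x) for x in v]
        return v

    return {k: convert(v) for k, v in asdict(obj).items()}


def _from_plain(cls, data: dict):
    kwargs = {}
    for f in fields(cls):
        if f.name not in data:
            continue
        v = data[f.name]
        if isinstance(v, list):
            v = tuple(tuple(x) if isinstance(x, list) else x for x in v)
        kwargs[f.name] = v
    return cls(**kwargs)


@dataclass
class RunConfig:
    seed: int = 1
    thresholds: Thresholds = field(default_factory=Thresholds)
    genome: GenomeConfig = field(default_factory=GenomeConfig)
    panel: PanelConfig = field(default_factory=PanelConfig)
    identifications: IdSimConfig = field(default_factory=lambda: IdSimConfig(n_true=150, n_decoy=75, n_false=25))
    cohort: CohortConfig = field(default_factory=lambda: CohortConfig(n_samples=200, hazard_ratio=0.3))
    stages: dict[str, bool] = field(default_factory=lambda: {s: True for s in STAGES})

    def validate(self) -> None:
        self.thresholds.validate()
        self.genome.validate()
        self.cohort.validate()
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        # stages run strictly in order; enabled stages must form a prefix
        enabled = [self.stages.get(s, True) for s in STAGES]
        if True in enabled:
            last = max(i for i, on in enumerate(enabled) if on)
            for i in range(last):
                if not enabled[i]:
                    raise ValueError(
                        f"stage {STAGES[last]!r} requires {STAGES[i]!r}, which is disabled"
                    )

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "thresholds": _as_plain(self.thresholds),
            "genome": _as_plain(self.genome),
            "panel": _as_plain(self.panel),
            "identifications": _as_plain(self.identifications),
            "cohort": _as_plain(self.cohort),
            "stages": dict(self.stages),
        }

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        cfg = cls(
            seed=int(data.get("seed", 1)),
            thresholds=_from_plain(Thresholds, data.get("thresholds", {})),
            genome=_from_plain(GenomeConfig, data.get("genome", {})),
            panel=_from_plain(PanelConfig, data.get("panel", {})),
            identifications=_from_plain(IdSimConfig, data.get("identifications", {})),
            cohort=_from_plain(CohortConfig, data.get("cohort", {})),
            stages={**{s: True for s in STAGES}, **data.get("stages", {})},
        )
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})
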