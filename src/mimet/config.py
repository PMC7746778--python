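"""Run configuration: thresholds, paths, contrast, seed.

A benchmark run is fully described by a YAML document; unknown keys are
rejected so typos never silently fall back to defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .diffstats import Thresholds

__all__ = ["RunConfig", "load_config", "dump_config"]

VALID_PIPELINES = ("mangosteen", "cmp", "ml")


@dataclass
class RunConfig:
    """Everything a benchmark run needs.

    ``pipelines`` selects which prediction strategies run; ``case`` /
    ``control`` name the metadata group labels of the contrast (e.g. a
    disease cohort vs. its non-diseased controls); ``seed`` feeds every
    random stage through per-stage child seeds.
    """

    reference: str
    functions: str
    metabolites: str
    metadata: str
    case: str
    control: str
    pipelines: tuple[str, ...] = VALID_PIPELINES
    thresholds: Thresholds = field(default_factory=Thresholds)
    seed: int = 0
    output_dir: str = "results"

    def __post_init__(self) -> None:
        if isinstance(self.pipelines, str):
            self.pipelines = (self.pipelines,)
        self.pipelines = tuple(self.pipelines)
        unknown = set(self.pipelines) - set(VALID_PIPELINES)
        if unknown:
            raise ValueError(f"unknown pipelines {sorted(unknown)}; valid: {VALID_PIPELINES}")
        if isinstance(self.thresholds, dict):
            self.thresholds = Thresholds(**self.thresholds)

    def validate_paths(self) -> None:
        for name in ("reference", "functions", "metabolites", "metadata"):
            p = Path(getattr(self, name))
            if not p.exists():
                raise FileNotFoundError(f"{name} path does not exist: {p}")

    def to_dict(self) -> dict:
        doc = asdict(self)
        doc["pipelines"] = list(self.pipelines)
        return doc


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration.

    Missing threshold keys fall back to the benchmark defaults (alpha 0.2,
    5% prevalence, 99 null replicates, ...); unknown keys raise.
    """
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, dict):
        raise ValueError("config must be a YAML mapping")
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(doc) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    th = doc.pop("thresholds", {})
    if th:
        th_unknown = set(th) - set(Thresholds.__dataclass_fields__)
        if th_unknown:
            raise ValueError(f"unknown threshold keys: {sorted(th_unknown)}")
    return RunConfig(thresholds=Thresholds(**th), **doc)


def dump_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))
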