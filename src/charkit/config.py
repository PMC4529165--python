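"""Run configuration: thresholds, reference paths, seed."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .references import DEFAULT_MOTIFS

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """All tunable thresholds of a pipeline run, serializable to YAML.

    Defaults match the package-wide defaults documented on the individual
    operations; a config file overrides them per run.
    """

    alpha: float = 0.01
    gc_floor: float = 48.0
    changes_floor: int = 5
    identity_threshold: float = 0.99
    delineation_identity: float = 0.70
    distance_cap: float = 10.0
    jc_cap: float = 5.0
    standard_2c_pg: float = 2.5
    reference_58s_path: str | None = None  # None -> built-in synthetic profile
    motifs: tuple[str, str, str] = DEFAULT_MOTIFS
    seed: int = 0
    output_dir: str = "results"

    def __post_init__(self):
        self.motifs = tuple(self.motifs)
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        if not (0 <= self.gc_floor <= 100):
            raise ValueError("gc_floor must be a percentage")
        if not (0 < self.identity_threshold <= 1):
            raise ValueError("identity_threshold must lie in (0, 1]")
        if not (0 < self.delineation_identity <= 1):
            raise ValueError("delineation_identity must lie in (0, 1]")
        if self.changes_floor < 1:
            raise ValueError("changes_floor must be >= 1")

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["motifs"] = list(self.motifs)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        if "motifs" in data:
            data["motifs"] = tuple(data["motifs"])
        return cls(**data)
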