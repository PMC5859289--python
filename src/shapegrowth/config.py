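"""Run configuration with the study's default analysis constants."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Resolved settings of a pipeline run.

    Defaults are the tuned/reported analysis constants: kernel widths 2.75 y
    (shape) and 0.75 y (size), 10,000 permutations and bootstrap replicates,
    10-fold cross-validation with 100 repetitions, kernel-support threshold
    0.4, and age brackets <5, 5–10, 10–15, 15–20.  Every run writes its
    resolved config next to its outputs.
    """

    template: str | None = None
    pairs: str | None = None
    midline: str | None = None
    metadata: str | None = None
    out: str | None = None
    shape_width: float = 2.75
    size_width: float = 0.75
    n_perm: int = 10000
    n_boot: int = 10000
    k: int = 10
    repetitions: int = 100
    support_threshold: float = 0.4
    brackets: tuple = ((0.0, 5.0), (5.0, 10.0), (10.0, 15.0), (15.0, 20.0))
    seed: int = 0
    scale_in_gpa: bool = True
    robust_gpa: bool = True

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "brackets" in data:
            data["brackets"] = tuple(tuple(b) for b in data["brackets"])
        return cls(**data)

    def override(self, **kwargs) -> "RunConfig":
        data = asdict(self)
        data.update({k: v for k, v in kwargs.items() if v is not None})
        if "brackets" in data:
            data["brackets"] = tuple(tuple(b) for b in data["brackets"])
        return RunConfig(**data)

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["brackets"] = [list(b) for b in self.brackets]
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))
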