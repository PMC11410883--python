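"""Run configuration: seed, thresholds and classifier settings.

Precedence: command-line flags > config file (TOML) > defaults.  Every CLI
run writes the resolved configuration next to its outputs so results are
reproducible byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import tomllib
from dataclasses import dataclass
from pathlib import Path

from .errors import ValidationError


@dataclass
class RunConfig:
    seed: int = 0
    smoothing_window: int = 7
    reentrant_depth_fraction: float = 0.02
    drawing_threshold: float = 0.5
    pca_variance_retained: float = 0.99
    svm_c: float = 1.0
    linkage: str = "average"
    n_landmarks: int = 200

    @classmethod
    def load(cls, path: str | Path | None = None, **overrides) -> "RunConfig":
        values: dict = {}
        if path is not None:
            with open(path, "rb") as fh:
                data = tomllib.load(fh)
            unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
            if unknown:
                raise ValidationError(f"unknown config keys: {sorted(unknown)}")
            values.update(data)
        values.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**values)

    def dump(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True))
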