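"""Run configuration shared by the CLI subcommands.

A flat YAML file mirrors the CLI flags; flags explicitly given on the
command line override file values, which override the defaults.  Defaults
follow the pipeline's standard choices: dilation radius 3 voxels and the
cervical labels 2-8 (C2-C8).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional

import yaml

__all__ = ["RunConfig", "parse_label_range"]


@dataclass
class RunConfig:
    dilation_radius: int = 3
    labels: List[int] = field(default_factory=lambda: list(range(2, 9)))
    centerline_smoothing_mm: Optional[float] = None
    staple_tol: float = 1e-6
    staple_max_iter: int = 100
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def load(cls, path=None, **overrides) -> "RunConfig":
        """Build a config from an optional YAML file plus explicit overrides.

        Overrides whose value is ``None`` are ignored (flag not given).
        """
        values = {}
        if path is not None:
            loaded = yaml.safe_load(Path(path).read_text()) or {}
            known = {f.name for f in dataclasses.fields(cls)}
            unknown = set(loaded) - known
            if unknown:
                raise ValueError(f"unknown config keys: {sorted(unknown)}")
            values.update(loaded)
        values.update({k: v for k, v in overrides.items() if v is not None})
        if isinstance(values.get("labels"), str):
            values["labels"] = parse_label_range(values["labels"])
        return cls(**values)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def sha256(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()


def parse_label_range(text: str) -> List[int]:
    """Parse ``'2-8'`` or ``'2,3,5'`` into a sorted label list."""
    text = text.strip()
    if "-" in text and "," not in text:
        lo, hi = text.split("-", 1)
        return list(range(int(lo), int(hi) + 1))
    return sorted(int(t) for t in text.split(",") if t.strip())
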