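"""Run configuration: one flat document of every tunable the pipeline reads.

Defaults follow the mining campaign this toolkit reproduces where that work
states a value (the SSN edge threshold of 1e-110) and documented choices
elsewhere (see docs/methods.md).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    evalue_threshold: float = 1e-110
    window_genes: int = 10
    karlin_lambda: float = 0.267
    karlin_K: float = 0.041
    gap_open: int = 11
    gap_extend: int = 1
    substitution_matrix: str = "BLOSUM62"
    fingerprint_match_min: float = 1.0
    jaccard_cut: float = 0.5
    random_seed: int = 0

    def __post_init__(self) -> None:
        import math

        for name in ("evalue_threshold", "karlin_lambda", "karlin_K"):
            v = getattr(self, name)
            if not math.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be finite and positive, got {v}")
        if self.window_genes < 0:
            raise ValueError("window_genes must be >= 0")
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")
        if self.gap_extend > self.gap_open:
            raise ValueError("gap_extend must not exceed gap_open")
        for name in ("fingerprint_match_min", "jaccard_cut"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "RunConfig":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        data = json.loads(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
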