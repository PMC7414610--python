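"""Run configuration: one JSON document driving the whole pipeline.

Defaults mirror the recommended pediatric hand-held OCT protocol: the
12 mm × 8 mm, 600 × 80 raster; measurement radii expressed as visual angles
(rings at 4°, 5°, 6° plus the two annuli; 6° ≈ 1.73 mm at 288 µm/degree);
and equal 90° TSNIT quadrants.  Unknown keys are rejected so stale configs
fail loudly; every analysis output embeds the config's SHA-256 hash.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal

from pydantic import BaseModel, ConfigDict, Field

__all__ = ["RunConfig"]


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    um_per_degree: float = Field(288.0, gt=0)
    scheme: Literal["equal90", "gdx"] = "equal90"
    locations: list[str] = Field(
        default_factory=lambda: ["ring4", "ring5", "ring6", "annulus4-5", "annulus5-6"]
    )
    n_theta: int = Field(360, ge=4)
    n_r: int = Field(8, ge=1)
    capture_threshold: float = Field(0.9, ge=0, le=1)
    icc_form: Literal["A1", "C1"] = "A1"
    cov_method: Literal["rms", "per_pair"] = "rms"
    crop_window_mm: tuple[float, float] = (8.0, 8.0)
    theta_offset_deg: float = 0.0
    seed: int = 42
    out_dir: str = "results"
    log_level: str = "INFO"

    def canonical_json(self) -> str:
        return json.dumps(self.model_dump(mode="json"), sort_keys=True, separators=(",", ":"))

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical_json().encode()).hexdigest()[:16]

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls.model_validate(json.loads(Path(path).read_text()))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.model_dump(mode="json"), indent=1, sort_keys=True) + "\n")
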