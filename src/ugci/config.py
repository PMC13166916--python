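"""Run configuration: YAML-backed, validated with pydantic models.

A run is driven either by a synthetic landscape recipe or by paths to
existing rasters — exactly one of the two.  CLI flags override config
keys; every random choice flows from the single ``seed``.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, Field, model_validator

from .synthetic import LandscapeSpec, default_spec

__all__ = ["SyntheticConfig", "InputRasters", "RunConfig", "load_config"]


class SyntheticConfig(BaseModel):
    """Recipe knobs for the synthetic mosaic (see :func:`ugci.synthetic.default_spec`)."""

    shape: tuple[int, int] = (200, 200)
    noise: float = Field(0.05, ge=0)
    edge_deficit: float | dict[str, float] = 1.0

    def to_spec(self, seed: int) -> LandscapeSpec:
        return default_spec(seed=seed, shape=tuple(self.shape),
                            edge_deficit=self.edge_deficit, noise=self.noise)


class InputRasters(BaseModel):
    """Paths to pre-existing aligned GeoTIFF inputs."""

    landcover: Path
    vegetation_c: Path
    soil_c: Path
    net_uptake: Path
    soil_potential: Path

    @model_validator(mode="after")
    def _exists(self):
        for name, p in self.model_dump().items():
            if not Path(p).exists():
                raise ValueError(f"input raster {name!r} not found: {p}")
        return self


class RunConfig(BaseModel):
    """Everything a pipeline run needs; see the packaged example in README."""

    seed: int = 0
    out_dir: Path = Path("ugci_out")
    synthetic: SyntheticConfig | None = SyntheticConfig()
    inputs: InputRasters | None = None
    class_names: dict[int, str] = {
        1: "forest", 2: "park", 3: "agricultural", 4: "roadside",
        5: "water", 6: "impervious",
    }
    green_classes: list[int] = [1, 2, 3, 4]
    impervious_classes: list[int] = [6]
    connectivity: int = 8
    edge_distance_m: float = 30.0
    vertex_threshold: float = 0.5
    center_radius: float = 0.15
    limited_threshold: float = 0.15
    strategies_path: Path | None = None

    @model_validator(mode="after")
    def _one_source(self):
        if (self.synthetic is None) == (self.inputs is None):
            raise ValueError("provide exactly one of 'synthetic' or 'inputs'")
        return self

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def load_config(path: str | Path | None, **overrides) -> RunConfig:
    """Load a YAML config file (or defaults) and apply CLI overrides."""
    data: dict = {}
    if path is not None:
        data = yaml.safe_load(Path(path).read_text()) or {}
    if "inputs" in data and data["inputs"] is not None:
        data.setdefault("synthetic", None)
        if data.get("synthetic") is not None:
            data["synthetic"] = None
    for key, value in overrides.items():
        if value is not None:
            data[key] = value
    return RunConfig(**data)
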