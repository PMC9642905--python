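"""Run configuration: defaults, YAML loading, strict key checking, hashing."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field

import yaml

from endodomain.synthetic import EndosomeSpec, SceneSpec

__all__ = ["RunConfig", "load_config", "config_hash", "scene_spec_from_dict"]


@dataclass(frozen=True)
class RunConfig:
    """Measurement parameters; defaults mirror the documented protocol
    (three 3-um-diameter discs on endosomes, three off)."""

    threshold_ch1: float | str = "otsu"
    threshold_ch2: float | str = "otsu"
    disc_diameter_um: float = 3.0
    n_on_discs: int = 3
    n_off_discs: int = 3
    n_profile_samples: int | None = None
    coloc_include: str = "union"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("threshold_ch1", "threshold_ch2"):
            v = getattr(self, name)
            if isinstance(v, str) and v != "otsu":
                raise ValueError(f"{name} must be a number or 'otsu', got {v!r}")
        if self.coloc_include not in ("union", "intersection", "all"):
            raise ValueError("coloc_include must be union|intersection|all")
        if self.disc_diameter_um <= 0:
            raise ValueError("disc_diameter_um must be positive")
        if self.n_on_discs < 1 or self.n_off_discs < 1:
            raise ValueError("need at least one on- and one off-disc")


def load_config(path: str | os.PathLike) -> RunConfig:
    """Load a YAML (or JSON-equivalent) config; unknown keys are an error."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    return RunConfig(**raw)


def config_hash(config: RunConfig) -> str:
    """Short stable hash identifying a configuration in output rows."""
    payload = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def scene_spec_from_dict(raw: dict) -> SceneSpec:
    """Build a :class:`SceneSpec` from a plain mapping (e.g. parsed YAML)."""
    raw = dict(raw)
    endosomes = [
        EndosomeSpec(
            center=tuple(e["center"]),
            radius_um=e["radius_um"],
            ring_width_um=e["ring_width_um"],
            ring_intensity=e["ring_intensity"],
            arc_center_deg=e["arc_center_deg"],
            arc_coverage=e["arc_coverage"],
            arc_intensity=e["arc_intensity"],
        )
        for e in raw.pop("endosomes", [])
    ]
    raw["cell_center"] = tuple(raw["cell_center"])
    raw["image_shape"] = tuple(raw["image_shape"])
    return SceneSpec(endosomes=tuple(endosomes), **raw)
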