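"""Run configuration for the orchestrated pipeline.

Every analysis number (threshold, cutoff, residue range) is a config
default here, never a hard-coded literal in the pipeline, so robustness
experiments are one-line edits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .hbonds import HBondCriteria
from .states import StateThresholds, TraceConfig
from .synth import FIT_SELECTION


@dataclass
class RunConfig:
    reference: str = ""
    trajectories: list[str] = field(default_factory=list)
    output_dir: str = "results"
    seed: int = 0
    fit_selection: str = FIT_SELECTION
    angle_tip: str = "114:OH"
    angle_base: str = "112:CG"
    distance_a: str = "114:OH"
    distance_b: str = "39:CB"
    icl2_range: tuple[int, int] = (110, 118)
    use_offset_angle: bool = False
    thresholds: dict[str, float] = field(default_factory=dict)
    hbond: dict[str, Any] = field(default_factory=lambda: {"heavy_only": True})
    pairs: list[dict[str, str]] = field(default_factory=list)
    pca_window: tuple[int, int] | None = None
    frame_interval_ps: float = 200.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.icl2_range = tuple(cfg.icl2_range)  # type: ignore[assignment]
        if cfg.pca_window is not None:
            cfg.pca_window = tuple(cfg.pca_window)  # type: ignore[assignment]
        return cfg

    def to_dict(self) -> dict:
        out = dict(self.__dict__)
        out["icl2_range"] = list(self.icl2_range)
        if self.pca_window is not None:
            out["pca_window"] = list(self.pca_window)
        return out

    def trace_config(self) -> TraceConfig:
        from .metrics import parse_atom_spec

        return TraceConfig(
            fit_selection=self.fit_selection,
            angle_tip=parse_atom_spec(self.angle_tip),
            angle_base=parse_atom_spec(self.angle_base),
            distance_a=parse_atom_spec(self.distance_a),
            distance_b=parse_atom_spec(self.distance_b),
            icl2_range=self.icl2_range,
            thresholds=StateThresholds(**self.thresholds),
            hbond=HBondCriteria(**self.hbond),
            use_offset_angle=self.use_offset_angle,
        )
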