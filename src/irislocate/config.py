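"""Pipeline configuration.

All tunable parameters of denoising and the two-stage boundary search live in
one flat dataclass that can be loaded from YAML. Defaults follow the
224-px-image operating point: n=32 sample points for the short inner contour,
n=256 for the outer, radial step 1 px, and two lateral 90-degree arcs for the
outer integration path so that eyelids and lashes stay off the contour.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import yaml

#: outer-boundary integration path: 90 degrees on each lateral side of the iris
LATERAL_ARCS: tuple[tuple[float, float], ...] = ((315.0, 45.0), (135.0, 225.0))
FULL_CIRCLE: tuple[tuple[float, float], ...] = ((0.0, 360.0),)


@dataclass
class PipelineConfig:
    # --- denoising ---
    reflection_threshold: float = 0.90  # normalized gray level; specular spots are near-saturated
    mask_dilate_px: int = 2
    closing_radius_px: int = 3  # disk radius at 224-px scale; lashes are a few px wide
    stages_enabled: tuple[str, ...] = ("reflections", "eyelashes")
    denoise_in_box: bool = True  # restrict denoising to the (padded) detector box
    box_pad_frac: float = 0.10

    # --- operator parameters ---
    n_inner: int = 32
    n_outer: int = 256
    delta_r: float = 1.0
    sigma: float = 1.0  # Gaussian std for the integro-differential objective
    gradient_sign: str = "outward_brighter"
    min_valid_frac: float = 0.5  # candidates with fewer valid contour samples are rejected
    outer_arcs: tuple[tuple[float, float], ...] = LATERAL_ARCS

    # --- search-field geometry ---
    inner_center_window_px: int = 10
    outer_center_window_px: int = 3  # "tiny neighborhood" of the inner center
    r_min_px: int = 8
    r_max_frac: float = 0.35  # inner radius prior as a fraction of min(box side)

    def __post_init__(self) -> None:
        if not 0.0 < self.reflection_threshold < 1.0:
            raise ValueError("reflection_threshold must be in (0,1)")
        if self.n_inner < 8 or self.n_outer < 8:
            raise ValueError("need at least 8 contour sample points")
        if self.delta_r <= 0:
            raise ValueError("delta_r must be positive")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if self.gradient_sign not in ("outward_brighter", "outward_darker"):
            raise ValueError(f"unknown gradient_sign {self.gradient_sign!r}")
        self.stages_enabled = tuple(self.stages_enabled)
        self.outer_arcs = tuple(tuple(a) for a in self.outer_arcs)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["stages_enabled"] = list(self.stages_enabled)
        d["outer_arcs"] = [list(a) for a in self.outer_arcs]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
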