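"""Synthetic eye-image generator with exact ground truth.

Renders the intensity structure the boundary operators rely on — a dark pupil
disk inside a textured iris annulus inside a bright sclera — plus the noise
classes typical of non-cooperative acquisition: near-saturated specular
reflection spots, dark eyelash strokes crossing the upper iris, partial
eyelid occlusion, and a mild off-angle (horizontally compressed, elliptical)
distortion. Every scene carries a ``SceneTruth`` with the ground-truth
circles and a detector-style bounding box, so parameter recovery can be
measured without any external dataset.

Intensities are floats in [0,1] throughout; 8-bit conversion happens only at
the PNG boundary. Boundaries are anti-aliased with a 1-px soft edge by
default; ``hard_edge=True`` renders ideal step edges for analytic tests.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy.ndimage import gaussian_filter
from skimage.draw import line_aa

from .geometry import BoundingBox, Circle, circle_bbox

__all__ = [
    "SceneSpec",
    "SceneTruth",
    "render_scene",
    "generate_batch",
    "sample_spec",
    "DEFAULT_RANGES",
    "STRATA",
]

_EYELID_INTENSITY = 0.72
_EYELASH_INTENSITY = 0.08
_REFLECTION_INTENSITY = 1.0


@dataclass(frozen=True)
class SceneSpec:
    """Full description of one synthetic scene; deterministic given ``seed``."""

    image_height: int = 224
    image_width: int = 224
    pupil: Circle = field(default_factory=lambda: Circle(112.0, 112.0, 22.0))
    iris: Circle = field(default_factory=lambda: Circle(112.0, 112.0, 60.0))
    intensity_pupil: float = 0.10
    intensity_iris: float = 0.45
    intensity_sclera: float = 0.85
    iris_texture_amplitude: float = 0.05
    n_reflections: int = 0
    reflection_radius_range: tuple[float, float] = (2.0, 5.0)
    n_eyelashes: int = 0
    eyelid_coverage_fraction: float = 0.0
    off_angle_axis_ratio: float = 1.0
    blur_sigma: float = 0.0
    max_center_offset: float = 3.0
    seed: int = 0

    def validate(self) -> None:
        if self.pupil.r >= self.iris.r:
            raise ValueError("pupil radius must be smaller than iris radius")
        if self.pupil.center_distance(self.iris) > self.max_center_offset + 1e-9:
            raise ValueError(
                f"pupil/iris center offset exceeds {self.max_center_offset} px"
            )
        if not (self.intensity_pupil < self.intensity_iris < self.intensity_sclera):
            raise ValueError("intensities must increase outward: pupil < iris < sclera")
        for name in ("intensity_pupil", "intensity_iris", "intensity_sclera",
                     "iris_texture_amplitude"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0,1], got {v}")
        if not 0.0 <= self.eyelid_coverage_fraction <= 0.5:
            raise ValueError("eyelid_coverage_fraction must lie in [0, 0.5]")
        if not 0.0 < self.off_angle_axis_ratio <= 1.0:
            raise ValueError("off_angle_axis_ratio must lie in (0, 1]")
        lo, hi = self.reflection_radius_range
        if lo > hi or lo <= 0:
            raise ValueError("invalid reflection_radius_range")
        if self.n_reflections < 0 or self.n_eyelashes < 0:
            raise ValueError("counts must be non-negative")
        # the iris must fit in the frame unless an eyelid hides its top
        a = self.iris.r * self.off_angle_axis_ratio
        out_lr = self.iris.cx - a < 0 or self.iris.cx + a > self.image_width
        out_bottom = self.iris.cy + self.iris.r > self.image_height
        out_top = self.iris.cy - self.iris.r < 0
        if out_lr or out_bottom or (out_top and self.eyelid_coverage_fraction == 0):
            raise ValueError("iris circle exceeds image bounds")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["pupil"] = self.pupil.to_dict()
        d["iris"] = self.iris.to_dict()
        d["reflection_radius_range"] = list(self.reflection_radius_range)
        return d


@dataclass(frozen=True)
class SceneTruth:
    """Ground truth for one rendered scene.

    ``pupil``/``iris`` are the post-distortion best-fit circles: for an
    off-angle scene they are the equal-area circles of the rendered ellipses,
    centered at the ellipse centers. ``bbox`` tightly encloses the rendered
    iris boundary, standing in for a detector's output box.
    """

    spec: SceneSpec
    pupil: Circle
    iris: Circle
    bbox: BoundingBox
    reflection_centers: tuple[tuple[float, float], ...] = ()

    def to_dict(self) -> dict:
        return {
            "pupil": self.pupil.to_dict(),
            "iris": self.iris.to_dict(),
            "bbox": self.bbox.to_dict(),
            "reflection_centers": [list(c) for c in self.reflection_centers],
        }


def _soft_inside(d: np.ndarray, hard: bool) -> np.ndarray:
    """Coverage fraction from a signed distance (negative = inside)."""
    if hard:
        return (d <= 0).astype(float)
    return np.clip(0.5 - d, 0.0, 1.0)


def render_scene(
    spec: SceneSpec, *, hard_edge: bool = False
) -> tuple[np.ndarray, SceneTruth]:
    """Render ``spec`` into a float image in [0,1] and its ground truth.

    Deterministic for a fixed spec (all randomness flows from ``spec.seed``).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    H, W = spec.image_height, spec.image_width
    yy, xx = np.mgrid[0:H, 0:W].astype(float)
    ar = spec.off_angle_axis_ratio

    # elliptical radii: horizontal semi-axis compressed by the axis ratio
    rho_i = np.hypot((xx - spec.iris.cx) / ar, yy - spec.iris.cy)
    rho_p = np.hypot((xx - spec.pupil.cx) / ar, yy - spec.pupil.cy)

    img = np.full((H, W), spec.intensity_sclera)

    # iris annulus with radial sinusoid texture plus smooth seeded noise
    iris_val = np.full((H, W), spec.intensity_iris)
    if spec.iris_texture_amplitude > 0:
        amp = spec.iris_texture_amplitude
        period = 6.0
        phase = rng.uniform(0, 2 * math.pi)
        tex = amp * np.sin(2 * math.pi * rho_i / period + phase)
        noise = rng.normal(0.0, 1.0, (H, W))
        tex = tex + 0.5 * amp * gaussian_filter(noise, 2.0)
        lo = spec.intensity_pupil + 0.08
        hi = spec.intensity_sclera - 0.08
        iris_val = np.clip(iris_val + tex, lo, hi)

    alpha_i = _soft_inside(rho_i - spec.iris.r, hard_edge)
    img = img * (1 - alpha_i) + iris_val * alpha_i
    alpha_p = _soft_inside(rho_p - spec.pupil.r, hard_edge)
    img = img * (1 - alpha_p) + spec.intensity_pupil * alpha_p

    # eyelid: straight occluding edge covering the top fraction of the iris
    if spec.eyelid_coverage_fraction > 0:
        y_lid = spec.iris.cy - spec.iris.r * (1 - 2 * spec.eyelid_coverage_fraction)
        alpha_lid = _soft_inside(yy - y_lid, hard_edge)
        img = img * (1 - alpha_lid) + _EYELID_INTENSITY * alpha_lid
    else:
        y_lid = spec.iris.cy - spec.iris.r

    # eyelashes: dark anti-aliased strokes angling down across the upper iris
    for _ in range(spec.n_eyelashes):
        x0 = spec.iris.cx + rng.uniform(-0.9, 0.9) * spec.iris.r * ar
        y0 = max(0.0, y_lid - rng.uniform(0.0, 3.0))
        length = rng.uniform(0.25, 0.55) * spec.iris.r
        tilt = math.radians(rng.uniform(-25, 25))  # mostly +y with a lateral tilt
        x1 = x0 + length * math.sin(tilt)
        y1 = y0 + length * math.cos(tilt)
        rr, cc, val = line_aa(
            int(round(y0)), int(round(x0)), int(round(y1)), int(round(x1))
        )
        for dc in (0, 1):  # ~2 px wide strokes
            c = np.clip(cc + dc, 0, W - 1)
            r_ = np.clip(rr, 0, H - 1)
            img[r_, c] = img[r_, c] * (1 - val) + _EYELASH_INTENSITY * val

    # specular reflections: near-saturated disks scattered over the iris region
    reflection_centers: list[tuple[float, float]] = []
    for _ in range(spec.n_reflections):
        phi = rng.uniform(0, 2 * math.pi)
        d = rng.uniform(0.3, 1.05) * spec.iris.r
        cx = spec.iris.cx + d * ar * math.cos(phi)
        cy = spec.iris.cy + d * math.sin(phi)
        cy = min(max(cy, 1.0), H - 2.0)
        cx = min(max(cx, 1.0), W - 2.0)
        rad = rng.uniform(*spec.reflection_radius_range)
        rho = np.hypot(xx - cx, yy - cy)
        alpha = _soft_inside(rho - rad, hard_edge)
        img = img * (1 - alpha) + _REFLECTION_INTENSITY * alpha
        reflection_centers.append((float(cx), float(cy)))

    if spec.blur_sigma > 0:
        img = gaussian_filter(img, spec.blur_sigma)
    img = np.clip(img, 0.0, 1.0)

    # post-distortion best-fit circles: equal-area circles of the ellipses
    scale = math.sqrt(ar)
    truth = SceneTruth(
        spec=spec,
        pupil=Circle(spec.pupil.cx, spec.pupil.cy, spec.pupil.r * scale),
        iris=Circle(spec.iris.cx, spec.iris.cy, spec.iris.r * scale),
        bbox=circle_bbox(spec.iris, ar),
        reflection_centers=tuple(reflection_centers),
    )
    return img, truth


# ---------------------------------------------------------------------------
# batch generation

#: default sampling ranges for randomized scenes (224x224 operating point)
DEFAULT_RANGES: dict[str, tuple[float, float]] = {
    "iris_cx": (104.0, 120.0),
    "iris_cy": (104.0, 120.0),
    "iris_r": (50.0, 75.0),
    "pupil_r_frac": (0.25, 0.45),  # pupil radius as a fraction of iris radius
    "center_offset": (0.0, 2.0),  # pupil center offset from iris center
    "intensity_pupil": (0.08, 0.14),
    "intensity_iris": (0.40, 0.50),
    "intensity_sclera": (0.80, 0.88),
    "iris_texture_amplitude": (0.04, 0.06),
    "blur_sigma": (0.4, 0.7),
    "reflection_radius": (2.0, 5.0),
    "eyelid_coverage_fraction": (0.0, 0.0),
    "off_angle_axis_ratio": (1.0, 1.0),
}

#: per-stratum overrides emulating the individual noise classes
STRATA: dict[str, dict] = {
    "clean": {},
    "noiseless": {"iris_texture_amplitude": (0.0, 0.0)},
    "reflections": {"n_reflections": 3},
    "eyelashes": {"n_eyelashes": 12},
    "occlusion": {"eyelid_coverage_fraction": (0.15, 0.25)},
    "off_angle": {"off_angle_axis_ratio": (0.85, 0.95)},
    "combined": {
        "n_reflections": 3,
        "n_eyelashes": 12,
        "eyelid_coverage_fraction": (0.15, 0.25),
    },
}

_COUNT_KEYS = {"n_reflections", "n_eyelashes"}


def _merge_ranges(param_ranges: dict | None) -> tuple[dict, dict]:
    ranges = dict(DEFAULT_RANGES)
    counts = {"n_reflections": 0, "n_eyelashes": 0}
    if param_ranges:
        for k, v in param_ranges.items():
            if k in _COUNT_KEYS:
                counts[k] = int(v)
                continue
            if k not in ranges:
                raise ValueError(f"unknown parameter range {k!r}")
            lo, hi = (v, v) if np.isscalar(v) else (v[0], v[1])
            if lo > hi:
                raise ValueError(f"invalid range for {k}: min {lo} > max {hi}")
            ranges[k] = (float(lo), float(hi))
    return ranges, counts


def sample_spec(rng: np.random.Generator, param_ranges: dict | None = None) -> SceneSpec:
    """Draw one random ``SceneSpec`` from (possibly overridden) default ranges."""
    rg, counts = _merge_ranges(param_ranges)

    def u(key):
        lo, hi = rg[key]
        return float(rng.uniform(lo, hi)) if hi > lo else float(lo)

    icx, icy, ir = u("iris_cx"), u("iris_cy"), u("iris_r")
    pr = ir * u("pupil_r_frac")
    off = u("center_offset")
    ang = rng.uniform(0, 2 * math.pi)
    pupil = Circle(icx + off * math.cos(ang), icy + off * math.sin(ang), pr)
    return SceneSpec(
        pupil=pupil,
        iris=Circle(icx, icy, ir),
        intensity_pupil=u("intensity_pupil"),
        intensity_iris=u("intensity_iris"),
        intensity_sclera=u("intensity_sclera"),
        iris_texture_amplitude=u("iris_texture_amplitude"),
        n_reflections=counts["n_reflections"],
        reflection_radius_range=rg["reflection_radius"],
        n_eyelashes=counts["n_eyelashes"],
        eyelid_coverage_fraction=u("eyelid_coverage_fraction"),
        off_angle_axis_ratio=u("off_angle_axis_ratio"),
        blur_sigma=u("blur_sigma"),
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def generate_batch(
    n: int,
    param_ranges: dict | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> list[tuple[np.ndarray, SceneTruth]]:
    """Generate ``n`` random scenes; reproducible from ``(n, param_ranges, seed)``.

    With ``out_dir`` set, writes ``scene_####.png`` (8-bit grayscale), a JSON
    truth sidecar per image, and a ``manifest.csv`` of all truth fields.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    scenes = [render_scene(sample_spec(rng, param_ranges)) for _ in range(n)]

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        rows = []
        for i, (img, truth) in enumerate(scenes):
            name = f"scene_{i:04d}"
            save_png(img, out / f"{name}.png")
            with open(out / f"{name}.json", "w") as fh:
                json.dump(truth.to_dict(), fh, sort_keys=True, indent=1)
            rows.append(
                {
                    "filename": f"{name}.png",
                    "pupil_cx": truth.pupil.cx,
                    "pupil_cy": truth.pupil.cy,
                    "pupil_r": truth.pupil.r,
                    "iris_cx": truth.iris.cx,
                    "iris_cy": truth.iris.cy,
                    "iris_r": truth.iris.r,
                    "bbox_x": truth.bbox.x,
                    "bbox_y": truth.bbox.y,
                    "bbox_w": truth.bbox.w,
                    "bbox_h": truth.bbox.h,
                }
            )
        pd.DataFrame(rows).to_csv(out / "manifest.csv", index=False)
    return scenes


def save_png(img: np.ndarray, path: str | Path) -> None:
    """Write a [0,1] float image as 8-bit grayscale PNG (lossless)."""
    arr = np.clip(np.rint(img * 255.0), 0, 255).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(path)


def load_png(path: str | Path) -> np.ndarray:
    """Read an image file back into a float array (RGB kept as 3 channels)."""
    arr = np.asarray(Image.open(path))
    return arr.astype(float) / 255.0
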