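"""Two-stage precise iris localization.

Stage 1 finds the pupillary (inner) boundary: a full-circle contour with
n = 32 sample points is scored over a small center window around the
detector-box center and a prior radius range. Stage 2 finds the limbic
(outer) boundary: the contour is restricted to two lateral 90-degree arcs
(eyelids and lashes occlude the top and bottom), n = 256, centers confined
to a tiny neighborhood of the inner center, and radii to the interval

    1.2 * rp  <  r  <  0.5 * max(rows, cols)

where ``rp`` is the recovered pupil radius and rows/cols are the detector
box sides. Both stages maximize the compensated radial-gradient objective;
``locate_iris_daugman`` swaps in the integro-differential objective over the
identical candidate grids for a like-for-like comparison.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .config import PipelineConfig
from .coarse import box_to_search, coarse_pupil_estimate, CoarseEstimateError
from .geometry import BoundingBox
from .operators import (
    OperatorParams,
    ScoredCircle,
    ScoringError,
    SearchGrid,
    search_max,
)
from .preprocess import denoise, to_gray
from .synthgen import load_png

__all__ = [
    "LocalizationResult",
    "locate_inner",
    "outer_radius_range",
    "locate_outer",
    "locate_iris",
    "locate_iris_daugman",
]

STATUS_OK = "ok"
STATUS_INNER_FAILED = "inner_failed"
STATUS_OUTER_FAILED = "outer_failed"


@dataclass(frozen=True)
class LocalizationResult:
    """Outcome of the two-stage search; serializable to JSON."""

    status: str
    inner: ScoredCircle | None
    outer: ScoredCircle | None
    bbox_used: BoundingBox | None
    objective: str = "modified"

    def to_dict(self) -> dict:
        return {
            "status": self.status,
            "objective": self.objective,
            "inner": self.inner.to_dict() if self.inner else None,
            "outer": self.outer.to_dict() if self.outer else None,
            "bbox_used": self.bbox_used.to_dict() if self.bbox_used else None,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)


def _outer_params(cfg: PipelineConfig) -> OperatorParams:
    return OperatorParams(
        n=cfg.n_outer,
        delta_r=cfg.delta_r,
        sigma=cfg.sigma,
        arcs=cfg.outer_arcs,
        gradient_sign=cfg.gradient_sign,
        min_valid_frac=cfg.min_valid_frac,
    )


def locate_inner(
    image: np.ndarray,
    box: BoundingBox,
    config: PipelineConfig | None = None,
    objective: str = "modified",
) -> ScoredCircle:
    """Find the pupillary boundary inside the detector box."""
    cfg = config or PipelineConfig()
    plan = box_to_search(box, image, cfg)
    return search_max(image, plan.inner_grid, objective)


def outer_radius_range(rp: float, box: BoundingBox) -> tuple[float, ...]:
    """Integer radius candidates in the open interval (1.2 rp, 0.5 max(w,h)).

    Empty result signals that no admissible outer radius exists.
    """
    if rp <= 0:
        raise ValueError("rp must be positive")
    lo = 1.2 * rp
    hi = 0.5 * max(box.w, box.h)
    if hi <= lo:
        return ()
    first = math.floor(lo) + 1
    last = math.ceil(hi) - 1
    return tuple(float(r) for r in range(first, last + 1) if lo < r < hi)


def outer_search_grid(
    image: np.ndarray,
    inner: ScoredCircle,
    box: BoundingBox,
    cfg: PipelineConfig,
) -> SearchGrid | None:
    radii = outer_radius_range(inner.circle.r, box)
    if not radii:
        return None
    H, W = image.shape
    w = cfg.outer_center_window_px
    cx0, cy0 = round(inner.circle.cx), round(inner.circle.cy)
    xs = [x for x in range(cx0 - w, cx0 + w + 1) if 0 <= x <= W - 1]
    ys = [y for y in range(cy0 - w, cy0 + w + 1) if 0 <= y <= H - 1]
    centers = tuple((float(x), float(y)) for y in ys for x in xs)
    return SearchGrid(centers=centers, radii=radii, params=_outer_params(cfg))


def locate_outer(
    image: np.ndarray,
    inner: ScoredCircle,
    box: BoundingBox,
    config: PipelineConfig | None = None,
    objective: str = "modified",
) -> ScoredCircle:
    """Find the limbic boundary, constrained by the inner result."""
    cfg = config or PipelineConfig()
    grid = outer_search_grid(image, inner, box, cfg)
    if grid is None:
        raise ScoringError("outer radius range is empty (1.2 rp >= 0.5 max(w,h))")
    return search_max(image, grid, objective)


def _locate(
    image: np.ndarray,
    box: BoundingBox | None,
    cfg: PipelineConfig,
    objective: str,
) -> LocalizationResult:
    gray = to_gray(image)
    if box is None:
        try:
            box = coarse_pupil_estimate(gray, cfg)
        except CoarseEstimateError:
            return LocalizationResult(STATUS_INNER_FAILED, None, None, None, objective)
    clean = denoise(gray, cfg, box)
    try:
        inner = locate_inner(clean, box, cfg, objective)
    except (ScoringError, ValueError):
        return LocalizationResult(STATUS_INNER_FAILED, None, None, box, objective)
    try:
        outer = locate_outer(clean, inner, box, cfg, objective)
    except ScoringError:
        return LocalizationResult(STATUS_OUTER_FAILED, inner, None, box, objective)
    return LocalizationResult(STATUS_OK, inner, outer, box, objective)


def _load_image(image: np.ndarray | str | Path) -> np.ndarray:
    if isinstance(image, (str, Path)):
        return load_png(image)
    return np.asarray(image)


def locate_iris(
    image: np.ndarray | str | Path,
    box: BoundingBox | None = None,
    config: PipelineConfig | None = None,
) -> LocalizationResult:
    """Full pipeline with the compensated radial-gradient objective.

    ``image`` may be a path (PNG/JPEG) or an in-memory array; without a box
    the coarse intensity-based pupil estimate supplies one. The pipeline is
    deterministic: identical inputs give byte-identical JSON results.
    """
    return _locate(_load_image(image), box, config or PipelineConfig(), "modified")


def locate_iris_daugman(
    image: np.ndarray | str | Path,
    box: BoundingBox | None = None,
    config: PipelineConfig | None = None,
) -> LocalizationResult:
    """Same pipeline and identical search grids, integro-differential objective."""
    return _locate(_load_image(image), box, config or PipelineConfig(), "daugman")


def locate_iris_uncompensated(
    image: np.ndarray | str | Path,
    box: BoundingBox | None = None,
    config: PipelineConfig | None = None,
) -> LocalizationResult:
    """Ablation pipeline: plain gradient sum without the compensation factor."""
    return _locate(
        _load_image(image), box, config or PipelineConfig(), "uncompensated"
    )
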