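"""Coarse initialization of the boundary search.

The precise search needs a starting rectangle around the iris. In a full
deployment that comes from an object detector; here it comes either from an
annotation file (JSON/CSV of boxes) or from a simple intensity-based pupil
finder: after reflection inpainting, the largest compact dark component is
taken as the pupil and boxed with a generous margin. The box center seeds
the inner-boundary search field, and the box sides bound the outer radius.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .config import PipelineConfig, FULL_CIRCLE
from .geometry import BoundingBox
from .operators import OperatorParams, SearchGrid
from .preprocess import detect_reflections, inpaint_reflections

__all__ = ["load_boxes", "coarse_pupil_estimate", "box_to_search", "SearchPlan"]

logger = logging.getLogger(__name__)


class CoarseEstimateError(ValueError):
    """No usable dark pupil component found; supply an annotation box."""


def load_boxes(path: str | Path) -> list[tuple[str, BoundingBox]]:
    """Load (image_id, box) pairs from a JSON or CSV annotation file.

    CSV needs columns image, x, y, w, h (extras ignored); JSON is a list of
    objects with the same keys. Malformed rows raise with their position.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        with open(path) as fh:
            records = json.load(fh)
        if not isinstance(records, list):
            raise ValueError("JSON annotation file must contain a list of objects")
        df = pd.DataFrame(records)
    else:
        df = pd.read_csv(path)
    if df.empty:
        logger.warning("annotation file %s is empty", path)
        return []
    missing = {"image", "x", "y", "w", "h"} - set(df.columns)
    if missing:
        raise ValueError(f"annotation file missing columns: {sorted(missing)}")
    out = []
    for i, row in df.iterrows():
        try:
            box = BoundingBox(float(row.x), float(row.y), float(row.w), float(row.h))
        except (TypeError, ValueError) as exc:
            raise ValueError(f"malformed annotation row {i + 1}: {exc}") from exc
        out.append((str(row.image), box))
    return out


def coarse_pupil_estimate(
    image: np.ndarray,
    config: PipelineConfig | None = None,
    quantile: float = 0.05,
    margin: float = 0.05,
    min_area_px: int = 50,
    box_scale: float = 6.0,
) -> BoundingBox:
    """Estimate a pupil-centered search box from image intensities alone.

    Reflections are inpainted first (a bright spot inside the pupil would
    split the dark component), then pixels below the ``quantile`` intensity
    plus ``margin`` are thresholded and the largest connected dark component
    is taken as the pupil. The returned box is a square of side
    ``box_scale x`` the component's equivalent radius, centered on its
    centroid and clipped to the image.
    """
    cfg = config or PipelineConfig()
    work = image
    mask = detect_reflections(work, cfg.reflection_threshold, cfg.mask_dilate_px)
    if mask.any() and not mask.all():
        work = inpaint_reflections(work, mask)
    thr = float(np.quantile(work, quantile)) + margin
    dark = work <= thr
    if not dark.any() or dark.mean() > 0.5:
        # nothing dark, or the "dark region" is most of the frame (flat image)
        raise CoarseEstimateError("no compact dark pupil-like component found")
    labels, nlab = ndimage.label(dark)
    if nlab == 0:
        raise CoarseEstimateError("no dark pupil-like component found")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, np.arange(1, nlab + 1))
    best = int(np.argmax(sizes)) + 1
    area = float(sizes[best - 1])
    if area < min_area_px:
        raise CoarseEstimateError(
            f"largest dark component has area {area:.0f} px < {min_area_px};"
            " provide an annotation box instead"
        )
    cy, cx = ndimage.center_of_mass(labels == best)
    r_eq = float(np.sqrt(area / np.pi))
    side = box_scale * r_eq
    H, W = image.shape
    return BoundingBox(cx - side / 2, cy - side / 2, side, side).clipped(H, W)


@dataclass(frozen=True)
class SearchPlan:
    """Everything the two-stage search needs from the coarse box."""

    initial_center: tuple[float, float]
    inner_grid: SearchGrid
    box: BoundingBox  # carried for the outer-radius bound 0.5 * max(w, h)


def box_to_search(
    box: BoundingBox, image: np.ndarray, config: PipelineConfig | None = None
) -> SearchPlan:
    """Turn a detector box into the inner-boundary search field.

    Center candidates form an integer square window of half-width
    ``inner_center_window_px`` around the box center; radii run from
    ``r_min_px`` to ``r_max_frac * min(w, h)`` at 1-px steps.
    """
    cfg = config or PipelineConfig()
    H, W = image.shape
    cx0, cy0 = box.center
    r_max = int(np.floor(cfg.r_max_frac * min(box.w, box.h)))
    if r_max < cfg.r_min_px:
        raise ValueError(
            f"box too small: inner radius prior [{cfg.r_min_px}, {r_max}] is empty"
        )
    radii = tuple(float(r) for r in range(cfg.r_min_px, r_max + 1))

    w = cfg.inner_center_window_px
    cx_int, cy_int = round(cx0), round(cy0)
    xs = [x for x in range(cx_int - w, cx_int + w + 1) if 0 <= x <= W - 1]
    ys = [y for y in range(cy_int - w, cy_int + w + 1) if 0 <= y <= H - 1]
    centers = tuple((float(x), float(y)) for y in ys for x in xs)

    params = OperatorParams(
        n=cfg.n_inner,
        delta_r=cfg.delta_r,
        sigma=cfg.sigma,
        arcs=FULL_CIRCLE,
        gradient_sign=cfg.gradient_sign,
        min_valid_frac=cfg.min_valid_frac,
    )
    return SearchPlan(
        initial_center=(cx0, cy0),
        inner_grid=SearchGrid(centers=centers, radii=radii, params=params),
        box=box,
    )
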