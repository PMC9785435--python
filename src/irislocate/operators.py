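"""Circle-scoring objectives for iris boundary search.

Two objectives are implemented over candidate circles ``(cx, cy, r)``:

* **Integro-differential operator** (Daugman): the absolute value of the
  Gaussian-smoothed radial derivative of the mean contour intensity
  ``m(r)`` — large where the contour sits on a circular intensity edge.

* **Compensated radial-gradient operator**: ``sum_theta (g_theta - C_theta)``
  where ``g_theta = I(r + dr) - I(r)`` is the radial gradient along the ray
  at angle theta, and the compensation factor
  ``C_theta = 0.5 * (|g_{theta+1} - g_theta| + |g_{theta-1} - g_theta|)``
  penalizes rays whose gradient disagrees with their angular neighbors.
  An isolated interference spot (a specular reflection, a lash) inflates a
  few ``g`` values but inflates their neighbor differences just as much, so
  its contribution is cancelled; a true boundary raises every ``g`` equally
  and pays no penalty.

The uncompensated plain gradient sum (``C`` dropped) is also exposed as the
ablation baseline. ``search_max`` exhaustively evaluates a candidate grid
and returns the global maximizer with deterministic tie-breaking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d, map_coordinates

from .config import FULL_CIRCLE
from .geometry import Circle

__all__ = [
    "OperatorParams",
    "ContourSamples",
    "RadialSamples",
    "SearchGrid",
    "ScoredCircle",
    "ScoringError",
    "arc_angles",
    "sample_on_circle",
    "radial_gradient",
    "compensation",
    "modified_score",
    "uncompensated_score",
    "daugman_score",
    "search_max",
]

OBJECTIVES = ("modified", "uncompensated", "daugman")


class ScoringError(ValueError):
    """No candidate could be scored (out-of-bounds contour, empty grid...)."""


@dataclass(frozen=True)
class OperatorParams:
    """Tuning parameters shared by both objectives.

    ``n`` contour sample points, radial step ``delta_r`` (px), Gaussian std
    ``sigma`` (px) for the integro-differential smoothing, the integration
    arc(s) in degrees, and the expected gradient direction across the
    boundary (``outward_brighter`` for dark-pupil imagery).
    """

    n: int = 32
    delta_r: float = 1.0
    sigma: float = 1.0
    arcs: tuple[tuple[float, float], ...] = FULL_CIRCLE
    gradient_sign: str = "outward_brighter"
    min_valid_frac: float = 0.5

    def __post_init__(self) -> None:
        if self.n < 8:
            raise ValueError("n must be >= 8")
        if self.delta_r <= 0:
            raise ValueError("delta_r must be positive")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.gradient_sign not in ("outward_brighter", "outward_darker"):
            raise ValueError(f"unknown gradient_sign {self.gradient_sign!r}")


@dataclass(frozen=True)
class ContourSamples:
    """Intensities sampled at ``n`` angles on one circle."""

    thetas: np.ndarray  # radians, length n
    intensity: np.ndarray  # bilinear samples; meaningless where invalid
    valid: np.ndarray  # bool; False where the point fell outside the image


@dataclass
class RadialSamples:
    """Per-angle radial gradients ``g`` (and compensation ``C`` once filled)."""

    thetas: np.ndarray
    g: np.ndarray
    valid: np.ndarray
    prev_idx: np.ndarray  # angular neighbor indices; -1 at open arc ends
    next_idx: np.ndarray
    C: np.ndarray | None = None


# ---------------------------------------------------------------------------
# arc geometry

def arc_angles(
    arcs: tuple[tuple[float, float], ...], n: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Distribute ``n`` sample angles uniformly over the arc(s).

    Returns ``(thetas_rad, prev_idx, next_idx)``. Angles are laid out with
    spacing ``total_arc / n`` starting at each interval's start; neighbor
    indices wrap for a full circle and clamp (-1 sentinel) at the open ends
    of partial arcs.
    """
    segs = []
    for start, end in arcs:
        length = (end - start) % 360.0
        if length == 0.0:
            length = 360.0
        segs.append((float(start), length))
    total = sum(length for _, length in segs)
    if total > 360.0 + 1e-9:
        raise ValueError("arc intervals exceed the full circle")

    step = total / n
    t = np.arange(n) * step
    thetas = np.empty(n)
    seg_id = np.empty(n, dtype=int)
    offset = 0.0
    for i, (start, length) in enumerate(segs):
        in_seg = (t >= offset - 1e-12) & (t < offset + length - 1e-12)
        thetas[in_seg] = np.deg2rad((start + (t[in_seg] - offset)) % 360.0)
        seg_id[in_seg] = i
        offset += length

    idx = np.arange(n)
    prev_idx = idx - 1
    next_idx = idx + 1
    full = len(segs) == 1 and abs(total - 360.0) < 1e-9
    if full:
        prev_idx[0] = n - 1
        next_idx[-1] = 0
    else:
        # sever neighbor links across segment boundaries
        same_prev = np.r_[False, seg_id[1:] == seg_id[:-1]]
        same_next = np.r_[seg_id[:-1] == seg_id[1:], False]
        prev_idx = np.where(same_prev, prev_idx, -1)
        next_idx = np.where(same_next, next_idx, -1)
    return thetas, prev_idx, next_idx


# ---------------------------------------------------------------------------
# vectorized sampling core

def _sample_stack(
    image: np.ndarray,
    centers: np.ndarray,
    radii: np.ndarray,
    thetas: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Bilinear samples on rings: output shape (n_centers, n_thetas, n_radii)."""
    H, W = image.shape
    cos = np.cos(thetas)[None, :, None]
    sin = np.sin(thetas)[None, :, None]
    r = np.asarray(radii, dtype=float)[None, None, :]
    xs = centers[:, 0, None, None] + cos * r
    ys = centers[:, 1, None, None] + sin * r
    valid = (xs >= 0) & (xs <= W - 1) & (ys >= 0) & (ys <= H - 1)
    vals = map_coordinates(
        image, [ys.ravel(), xs.ravel()], order=1, mode="nearest"
    ).reshape(xs.shape)
    return vals, valid


def _combine_neighbor_diffs(dp: np.ndarray, dn: np.ndarray) -> np.ndarray:
    """C = mean of the available |neighbor - self| gradient differences.

    With both neighbors present this is the standard half-sum; a missing
    neighbor (arc end or out-of-bounds sample) contributes the remaining
    term alone; with neither, C = 0.
    """
    both_nan = np.isnan(dp) & np.isnan(dn)
    C = np.where(np.isnan(dp), dn, np.where(np.isnan(dn), dp, 0.5 * (dp + dn)))
    return np.where(both_nan, 0.0, C)


def _gradient_fields(
    image: np.ndarray,
    centers: np.ndarray,
    radii: np.ndarray,
    params: OperatorParams,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """g, valid, prev_idx, next_idx over (centers, thetas, radii)."""
    thetas, prev_idx, next_idx = arc_angles(params.arcs, params.n)
    r = np.asarray(radii, dtype=float)
    I0, v0 = _sample_stack(image, centers, r, thetas)
    I1, v1 = _sample_stack(image, centers, r + params.delta_r, thetas)
    g = I1 - I0
    if params.gradient_sign == "outward_darker":
        g = -g
    return g, v0 & v1, prev_idx, next_idx


def _compensation_field(
    g: np.ndarray, valid: np.ndarray, prev_idx: np.ndarray, next_idx: np.ndarray
) -> np.ndarray:
    """Vectorized C over (centers, thetas, radii); 0 where no neighbor exists."""
    gn = np.where(valid, g, np.nan)

    def gather(idx):
        safe = np.where(idx >= 0, idx, 0)
        vals = gn[:, safe, :].copy()
        vals[:, idx < 0, :] = np.nan
        return vals

    dp = np.abs(gather(prev_idx) - gn)
    dn = np.abs(gather(next_idx) - gn)
    return _combine_neighbor_diffs(dp, dn)


def _grad_objective_scores(
    image: np.ndarray,
    centers: np.ndarray,
    radii: np.ndarray,
    params: OperatorParams,
    compensated: bool,
) -> np.ndarray:
    """Scores (n_centers, n_radii) for the (un)compensated gradient sum.

    The sum runs over valid angles and is rescaled by ``n / n_valid`` so that
    partially out-of-frame candidates remain comparable; candidates with
    fewer than ``min_valid_frac * n`` valid rays score ``-inf``.
    """
    g, valid, prev_idx, next_idx = _gradient_fields(image, centers, radii, params)
    if compensated:
        C = _compensation_field(g, valid, prev_idx, next_idx)
        contrib = g - C
    else:
        contrib = g
    contrib = np.where(valid, contrib, 0.0)
    nvalid = valid.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        scores = contrib.sum(axis=1) * (params.n / nvalid)
    scores[nvalid < params.min_valid_frac * params.n] = -np.inf
    return scores


def _daugman_objective_scores(
    image: np.ndarray,
    centers: np.ndarray,
    radii: np.ndarray,
    params: OperatorParams,
) -> np.ndarray:
    """Scores (n_centers, n_radii) for the integro-differential operator.

    Per center: mean contour intensity m(r) over valid arc samples, central
    differences over the (ascending) radii, 1-D Gaussian smoothing with
    reflect padding, absolute value.
    """
    r = np.asarray(radii, dtype=float)
    if len(r) < 3:
        raise ScoringError("integro-differential objective needs >= 3 radii")
    if np.any(np.diff(r) <= 0):
        raise ValueError("radii must be sorted ascending")
    thetas, _, _ = arc_angles(params.arcs, params.n)
    I, valid = _sample_stack(image, centers, r, thetas)
    nvalid = valid.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        m = np.where(valid, I, 0.0).sum(axis=1) / nvalid
    ok = nvalid >= params.min_valid_frac * params.n

    scores = np.full(m.shape, -np.inf)
    for ci in range(m.shape[0]):
        row_ok = ok[ci]
        if row_ok.sum() < 3:
            continue
        mm = m[ci].copy()
        if not row_ok.all():
            # continue m(r) through invalid radii so differentiation stays local
            mm[~row_ok] = np.interp(r[~row_ok], r[row_ok], mm[row_ok])
        dm = np.gradient(mm, r)
        if params.sigma > 0:
            dm = gaussian_filter1d(dm, params.sigma, mode="reflect")
        row = np.abs(dm)
        row[~row_ok] = -np.inf
        scores[ci] = row
    return scores


# ---------------------------------------------------------------------------
# public single-candidate operations

def sample_on_circle(
    image: np.ndarray,
    circle: Circle,
    n: int,
    arcs: tuple[tuple[float, float], ...] = FULL_CIRCLE,
) -> ContourSamples:
    """Sample image intensity at ``n`` uniform angles on ``circle``."""
    if n < 8:
        raise ValueError("n must be >= 8")
    thetas, _, _ = arc_angles(arcs, n)
    centers = np.array([[circle.cx, circle.cy]])
    vals, valid = _sample_stack(image, centers, np.array([circle.r]), thetas)
    return ContourSamples(thetas, vals[0, :, 0], valid[0, :, 0])


def radial_gradient(
    image: np.ndarray, circle: Circle, params: OperatorParams
) -> RadialSamples:
    """Per-angle radial gradient g = I(r + delta_r) - I(r) on ``circle``."""
    centers = np.array([[circle.cx, circle.cy]])
    g, valid, prev_idx, next_idx = _gradient_fields(
        image, centers, np.array([circle.r]), params
    )
    valid = valid[0, :, 0]
    if not valid.any():
        raise ScoringError("no valid contour sample on this circle")
    return RadialSamples(
        thetas=arc_angles(params.arcs, params.n)[0],
        g=g[0, :, 0],
        valid=valid,
        prev_idx=prev_idx,
        next_idx=next_idx,
    )


def compensation(samples: RadialSamples) -> RadialSamples:
    """Fill the compensation factor C from angular-neighbor gradient spread."""
    if samples.valid.sum() < 3:
        raise ScoringError("compensation needs at least 3 valid samples")
    g3 = samples.g[None, :, None]
    v3 = samples.valid[None, :, None]
    C = _compensation_field(g3, v3, samples.prev_idx, samples.next_idx)
    samples.C = np.where(samples.valid, C[0, :, 0], 0.0)
    return samples


@dataclass(frozen=True)
class ScoredCircle:
    circle: Circle
    score: float

    def to_dict(self) -> dict:
        return {"circle": self.circle.to_dict(), "score": float(self.score)}


def modified_score(
    image: np.ndarray, circle: Circle, params: OperatorParams
) -> ScoredCircle:
    """Compensated gradient-sum score of a single candidate circle."""
    centers = np.array([[circle.cx, circle.cy]])
    s = _grad_objective_scores(image, centers, np.array([circle.r]), params, True)
    if not np.isfinite(s[0, 0]):
        raise ScoringError("candidate circle has too few valid samples")
    return ScoredCircle(circle, float(s[0, 0]))


def uncompensated_score(
    image: np.ndarray, circle: Circle, params: OperatorParams
) -> ScoredCircle:
    """Plain radial gradient sum (the ablation baseline without C)."""
    centers = np.array([[circle.cx, circle.cy]])
    s = _grad_objective_scores(image, centers, np.array([circle.r]), params, False)
    if not np.isfinite(s[0, 0]):
        raise ScoringError("candidate circle has too few valid samples")
    return ScoredCircle(circle, float(s[0, 0]))


def daugman_score(
    image: np.ndarray,
    center: tuple[float, float],
    radii: np.ndarray,
    params: OperatorParams,
) -> list[ScoredCircle]:
    """Integro-differential scores for one center across a radius sweep."""
    centers = np.array([center], dtype=float)
    s = _daugman_objective_scores(image, centers, np.asarray(radii, float), params)
    return [
        ScoredCircle(Circle(center[0], center[1], float(r)), float(v))
        for r, v in zip(radii, s[0])
    ]


# ---------------------------------------------------------------------------
# exhaustive search

@dataclass(frozen=True)
class SearchGrid:
    """Candidate centers x radii enumerated by the exhaustive search."""

    centers: tuple[tuple[float, float], ...]
    radii: tuple[float, ...]
    params: OperatorParams

    def __post_init__(self) -> None:
        if len(self.centers) == 0 or len(self.radii) == 0:
            raise ValueError("search grid must not be empty")

    @property
    def n_candidates(self) -> int:
        return len(self.centers) * len(self.radii)


def grid_scores(image: np.ndarray, grid: SearchGrid, objective: str) -> np.ndarray:
    """Score matrix (n_centers, n_radii); -inf marks rejected candidates."""
    if objective not in OBJECTIVES:
        raise ValueError(f"unknown objective {objective!r}")
    centers = np.asarray(grid.centers, dtype=float)
    radii = np.asarray(grid.radii, dtype=float)
    if objective == "daugman":
        return _daugman_objective_scores(image, centers, radii, grid.params)
    return _grad_objective_scores(
        image, centers, radii, grid.params, compensated=(objective == "modified")
    )


def search_max(image: np.ndarray, grid: SearchGrid, objective: str) -> ScoredCircle:
    """Exhaustive maximum over the grid.

    Ties are broken toward the smaller radius, then lexicographically by
    (cy, cx), so the result is deterministic regardless of grid ordering.
    """
    scores = grid_scores(image, grid, objective)
    if not np.isfinite(scores).any():
        raise ScoringError("every candidate in the grid failed scoring")
    centers = np.asarray(grid.centers, dtype=float)
    radii = np.asarray(grid.radii, dtype=float)
    C, R = scores.shape
    flat = scores.ravel()
    rr = np.tile(radii, C)
    cxs = np.repeat(centers[:, 0], R)
    cys = np.repeat(centers[:, 1], R)
    order = np.lexsort((cxs, cys, rr, -flat))
    best = order[0]
    return ScoredCircle(
        Circle(float(cxs[best]), float(cys[best]), float(rr[best])),
        float(flat[best]),
    )
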