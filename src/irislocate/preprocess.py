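"""Denoising of eye images before boundary search.

Two noise classes are handled, in a fixed order:

1. **Specular reflections** — near-saturated bright spots. A binary mask of
   pixels above an intensity threshold (dilated to cover bloom halos) is
   filled by inward interpolation: a harmonic (diffusion) fill that iterates
   neighbor averaging over the masked pixels until convergence, so the filled
   region smoothly continues the surrounding intensities.
2. **Eyelashes** — thin dark strokes. Grayscale morphological closing with a
   disk structuring element raises dark details thinner than the element
   toward the surrounding intensity; it is extensive (output >= input) and
   idempotent.

By default denoising is restricted to the detector bounding box (padded 10%),
since that is the only region the boundary search inspects.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import convolve
from skimage.morphology import closing, dilation, disk

from .config import PipelineConfig
from .geometry import BoundingBox

__all__ = [
    "to_gray",
    "detect_reflections",
    "inpaint_reflections",
    "suppress_eyelashes",
    "denoise",
]

_REC601 = np.array([0.299, 0.587, 0.114])


def to_gray(image: np.ndarray) -> np.ndarray:
    """Convert an 8-bit or float, gray or RGB, image to a [0,1] float grid.

    Color is collapsed with Rec. 601 luma weights (0.299 R + 0.587 G + 0.114 B).
    """
    arr = np.asarray(image)
    if arr.ndim == 3:
        if arr.shape[2] not in (3, 4):
            raise ValueError(f"expected 3 color channels, got shape {arr.shape}")
        arr = arr[..., :3] @ _REC601
    elif arr.ndim != 2:
        raise ValueError(f"expected a 2-D or 3-channel image, got {arr.ndim} dims")
    arr = arr.astype(float)
    if np.issubdtype(np.asarray(image).dtype, np.integer):
        arr = arr / 255.0
    return np.clip(arr, 0.0, 1.0)


def detect_reflections(
    image: np.ndarray, threshold: float = 0.90, dilate_px: int = 2
) -> np.ndarray:
    """Binary mask of near-saturated pixels, dilated to cover bloom halos."""
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must be in (0,1), got {threshold}")
    mask = image >= threshold
    if dilate_px > 0 and mask.any():
        mask = dilation(mask, disk(dilate_px))
    return mask


def inpaint_reflections(
    image: np.ndarray,
    mask: np.ndarray,
    tol: float = 1e-5,
    max_sweeps: int = 500,
) -> np.ndarray:
    """Fill masked pixels by harmonic inward interpolation.

    Masked pixels are repeatedly replaced by the mean of their 4-neighbors
    (Jacobi sweeps over the mask only) until the largest per-pixel change
    drops below ``tol`` or ``max_sweeps`` is reached. Pixels outside the
    mask are returned bit-identical to the input.
    """
    if mask.shape != image.shape:
        raise ValueError("mask shape must equal image shape")
    mask = mask.astype(bool)
    if not mask.any():
        return image.copy()
    if mask.all():
        raise ValueError("all-true mask: no boundary to interpolate from")

    out = image.copy()
    # restrict the sweeps to the mask's bounding window (plus a 1-px rim)
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    r0, r1 = max(rows[0] - 1, 0), min(rows[-1] + 2, image.shape[0])
    c0, c1 = max(cols[0] - 1, 0), min(cols[-1] + 2, image.shape[1])
    win = out[r0:r1, c0:c1]
    m = mask[r0:r1, c0:c1]

    win[m] = win[~m].mean()  # neutral start speeds convergence
    kernel = np.array([[0.0, 1.0, 0.0], [1.0, 0.0, 1.0], [0.0, 1.0, 0.0]])
    counts = convolve(np.ones_like(win), kernel, mode="constant")
    for _ in range(max_sweeps):
        avg = convolve(win, kernel, mode="constant") / counts
        delta = np.abs(avg[m] - win[m]).max()
        win[m] = avg[m]
        if delta < tol:
            break
    out[r0:r1, c0:c1] = win
    out[~mask] = image[~mask]  # locality is exact by construction
    return np.clip(out, 0.0, 1.0)


def suppress_eyelashes(image: np.ndarray, selem_radius: int = 3) -> np.ndarray:
    """Grayscale closing with a disk element; fills thin dark structures."""
    if selem_radius < 1:
        raise ValueError("selem_radius must be >= 1")
    return closing(image, disk(selem_radius))


def denoise(
    image: np.ndarray,
    config: PipelineConfig | None = None,
    box: BoundingBox | None = None,
) -> np.ndarray:
    """Run the full denoising chain: reflections first, then eyelashes.

    With a box (and ``config.denoise_in_box``), only the padded box window is
    processed; the rest of the image is untouched.
    """
    cfg = config or PipelineConfig()
    # closing element radius scales with image size; 3 px at the 224-px reference
    radius = max(1, round(cfg.closing_radius_px * max(image.shape) / 224.0))
    if box is not None and cfg.denoise_in_box:
        H, W = image.shape
        b = box.padded(cfg.box_pad_frac).clipped(H, W)
        r0, r1 = int(np.floor(b.y)), int(np.ceil(b.y + b.h))
        c0, c1 = int(np.floor(b.x)), int(np.ceil(b.x + b.w))
        out = image.copy()
        out[r0:r1, c0:c1] = _denoise_window(image[r0:r1, c0:c1], cfg, radius)
        return out
    return _denoise_window(image, cfg, radius)


def _denoise_window(window: np.ndarray, cfg: PipelineConfig, radius: int) -> np.ndarray:
    out = window
    if "reflections" in cfg.stages_enabled:
        mask = detect_reflections(out, cfg.reflection_threshold, cfg.mask_dilate_px)
        if mask.any() and not mask.all():
            out = inpaint_reflections(out, mask)
    if "eyelashes" in cfg.stages_enabled:
        out = suppress_eyelashes(out, radius)
    return out if out is not window else window.copy()
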