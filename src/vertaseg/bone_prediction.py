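"""Iterative frame-fusion bone-region prediction over sequential slices.

Sequential CT slices of the same bone change slowly, so the segmentation of
frame i is a strong prior for frame i+1.  The loop: the first frame is
enhanced, segmented by an active contour and binarized; each later frame is
enhanced, fused with the previous binary mask,

    I_mod^{i+1} = alpha * (255 * I_b^i) + beta * I_enh^{i+1},

and fusion noise is suppressed in the *suture area* — a narrow band around
the previous contour where the mask prior and the new frame disagree most.
Band pixels whose raw (pre-enhancement) intensity in frame i+1 falls below a
threshold are damped by mu1 (inside the previous mask, band Q1) or mu2
(outside, band Q2), which stops the mask from leaking into tissue that is
actually dark.  After frame n, one final active-contour pass on the last
modified image yields the predicted bone region.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_dilation, binary_erosion

from . import active_contour as ac
from .enhancement import EnhancementParams, enhance_contrast
from .raster_io import as_binary_mask, as_gray_image

__all__ = [
    "FusionParams",
    "SutureRegions",
    "fuse_frames",
    "extract_suture_regions",
    "suture_noise_suppress",
    "predict_segment_sequence",
]


@dataclass
class FusionParams:
    """Fusion weights and suture-suppression parameters.

    weight_prev/weight_next are the convex mixing weights of Eq-style frame
    fusion (they must sum to 1 so fused intensities stay on the 0-255
    scale); mu1/mu2 damp dark band pixels inside/outside the previous
    contour; threshold is the raw-intensity cut; band_radius the Chebyshev
    half-width of the suture band in pixels.
    """

    weight_prev: float = 0.3
    weight_next: float = 0.7
    mu1: float = 0.5
    mu2: float = 0.5
    threshold: float = 0.3 * 255.0
    band_radius: int = 2

    def __post_init__(self) -> None:
        if not (0.0 <= self.weight_prev <= 1.0 and 0.0 <= self.weight_next <= 1.0):
            raise ValueError("fusion weights must lie in [0, 1]")
        if abs(self.weight_prev + self.weight_next - 1.0) > 1e-9:
            raise ValueError("fusion weights must sum to 1")
        if not (0.0 < self.mu1 <= 1.0 and 0.0 < self.mu2 <= 1.0):
            raise ValueError("mu1 and mu2 must lie in (0, 1]")
        if not (0.0 <= self.threshold <= 255.0):
            raise ValueError("threshold must lie in [0, 255]")
        if int(self.band_radius) < 0:
            raise ValueError("band_radius must be >= 0")


@dataclass
class SutureRegions:
    """Disjoint bands around the previous contour: q1 inside, q2 outside."""

    q1: np.ndarray
    q2: np.ndarray


def fuse_frames(prev_mask, next_enhanced, params: FusionParams | None = None) -> np.ndarray:
    """Pixelwise convex mix of the previous mask (lifted to 0-255) with the
    next enhanced frame."""
    params = params or FusionParams()
    mask = as_binary_mask(prev_mask).astype(np.float64)
    enh = as_gray_image(next_enhanced)
    if mask.shape != enh.shape:
        raise ValueError("frame shape mismatch")
    return params.weight_prev * (255.0 * mask) + params.weight_next * enh


def extract_suture_regions(prev_mask, band_radius: int) -> SutureRegions:
    """Chebyshev band of half-width ``band_radius`` around the mask boundary.

    q1: band pixels inside the mask (mask minus its ``band_radius``-fold
    erosion); q2: band pixels outside (dilation minus the mask).  Both via a
    3x3 structuring element, so distance is the Chebyshev metric.  The image
    border is not treated as a boundary.
    """
    mask = as_binary_mask(prev_mask).astype(bool)
    if mask.all() or (~mask).all():
        raise ValueError("no boundary: suture undefined")
    r = int(band_radius)
    if r == 0:
        empty = np.zeros(mask.shape, dtype=np.uint8)
        return SutureRegions(q1=empty, q2=empty.copy())
    selem = np.ones((3, 3), dtype=bool)
    eroded = binary_erosion(mask, selem, iterations=r, border_value=1)
    dilated = binary_dilation(mask, selem, iterations=r, border_value=0)
    q1 = (mask & ~eroded).astype(np.uint8)
    q2 = (dilated & ~mask).astype(np.uint8)
    return SutureRegions(q1=q1, q2=q2)


def suture_noise_suppress(fused, original_next, regions: SutureRegions,
                          params: FusionParams | None = None) -> np.ndarray:
    """Damp fused band pixels that the raw next frame says are dark.

    q1 pixels with original intensity < threshold are multiplied by mu1; q2
    pixels likewise by mu2; everything else passes through unchanged.
    """
    params = params or FusionParams()
    fused = as_gray_image(fused)
    orig = as_gray_image(original_next)
    if fused.shape != orig.shape:
        raise ValueError("frame shape mismatch")
    q1 = as_binary_mask(regions.q1).astype(bool)
    q2 = as_binary_mask(regions.q2).astype(bool)
    if q1.shape != fused.shape or q2.shape != fused.shape:
        raise ValueError("frame shape mismatch")
    out = fused.copy()
    dark = orig < params.threshold
    out[q1 & dark] *= params.mu1
    out[q2 & dark] *= params.mu2
    return out


def _segment(image, method: str, contour_params, init=None):
    init = ac.circle_level_set(image.shape) if init is None else init
    if method == "cv":
        field, hist = ac.cv_evolve(image, init, contour_params)
    elif method == "lbf":
        field, hist = ac.lbf_evolve(image, init, contour_params)
    else:
        raise ValueError(f"unknown contour method: {method!r}")
    return field, hist


def predict_segment_sequence(frames, fusion: FusionParams | None = None,
                             contour_method: str = "cv", contour_params=None,
                             enh: EnhancementParams | None = None):
    """Run the iterative prediction loop over an ordered frame sequence.

    Frame 1 has no predecessor and is processed without fusion.  Each later
    frame is enhanced, fused with the previous binary mask, suppressed in
    the previous mask's suture band (conditioned on the raw frame), then
    segmented and binarized.  After the last frame a final active-contour
    pass on the last modified image produces the sequence-level prediction.

    Returns (per-frame masks in order, final mask).
    """
    frames = list(frames)
    if not frames:
        raise ValueError("no frames")
    shapes = {as_gray_image(f).shape for f in frames}
    if len(shapes) != 1:
        raise ValueError("frame shape mismatch")
    fusion = fusion or FusionParams()
    enh = enh or EnhancementParams()
    if contour_params is None:
        contour_params = ac.CVParams() if contour_method == "cv" else ac.LBFParams()

    masks: list[np.ndarray] = []
    prev_mask = None
    last_modified = None
    for i, frame in enumerate(frames):
        try:
            enhanced = enhance_contrast(frame, enh)
            if prev_mask is None:
                modified = enhanced
            else:
                fused = fuse_frames(prev_mask, enhanced, fusion)
                regions = extract_suture_regions(prev_mask, fusion.band_radius)
                modified = suture_noise_suppress(fused, frame, regions, fusion)
            field, _ = _segment(modified, contour_method, contour_params)
            mask = ac.binarize(field)
        except (ValueError, FloatingPointError) as exc:
            raise type(exc)(f"frame {i}: {exc}") from exc
        masks.append(mask)
        prev_mask = mask
        last_modified = modified

    final_field, _ = _segment(last_modified, contour_method, contour_params)
    return masks, ac.binarize(final_field)
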