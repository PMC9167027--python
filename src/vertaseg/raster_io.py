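"""Raster readers/writers and run configuration.

All images are held in memory as 2-D float64 arrays on the 0-255 intensity
scale; values stay real-valued through the processing chain and are only
quantized to 8-bit when a file is written.  Binary masks are {0,1} uint8
arrays with the same shape as their source image.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import yaml

log = logging.getLogger("vertaseg")

__all__ = [
    "as_gray_image",
    "as_binary_mask",
    "read_gray_image",
    "write_gray_image",
    "write_mask",
    "read_mask",
    "RunConfig",
]


def as_gray_image(pixels) -> np.ndarray:
    """Validate and coerce an array to a GrayImage (2-D finite float64).

    Images must be at least 3x3 so that every pixel has a well-defined 3x3
    neighborhood for the contrast-enhancement stencil.
    """
    arr = np.asarray(pixels, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError("gray image must be 2-D")
    if arr.shape[0] < 3 or arr.shape[1] < 3:
        raise ValueError("gray image must be at least 3x3")
    if not np.all(np.isfinite(arr)):
        raise ValueError("gray image contains non-finite values")
    return arr


def as_binary_mask(pixels) -> np.ndarray:
    """Validate and coerce an array to a BinaryMask ({0,1} uint8)."""
    arr = np.asarray(pixels)
    if arr.ndim != 2:
        raise ValueError("binary mask must be 2-D")
    vals = np.unique(arr)
    if not np.all(np.isin(vals, (0, 1))):
        raise ValueError("binary mask values must be exactly 0 or 1")
    return arr.astype(np.uint8)


def read_gray_image(path) -> np.ndarray:
    """Read a lossless 8- or 16-bit raster as a GrayImage on the 0-255 scale.

    Color inputs are collapsed by the arithmetic mean of their channels.
    16-bit inputs are linearly mapped from their own min/max onto [0, 255];
    8-bit inputs are taken verbatim.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input not found: {path}")
    try:
        raw = iio.imread(path)
    except Exception as exc:  # noqa: BLE001 - any decoder failure is the same to us
        raise ValueError(f"malformed image: {path}") from exc
    if raw.size == 0:
        raise ValueError(f"malformed image: {path}")
    arr = np.asarray(raw)
    if arr.ndim == 3:  # drop alpha, then luminance-average the color channels
        if arr.shape[2] == 4:
            arr = arr[:, :, :3]
        arr = arr.mean(axis=2)
    arr = arr.astype(np.float64)
    if raw.dtype == np.uint16:
        lo, hi = arr.min(), arr.max()
        arr = np.zeros_like(arr) if hi == lo else (arr - lo) * (255.0 / (hi - lo))
    return as_gray_image(arr)


def write_gray_image(image: np.ndarray, path) -> None:
    """Write a GrayImage as an 8-bit raster, clamping and rounding at write."""
    path = Path(path)
    if not path.parent.is_dir():
        raise OSError(f"output not writable: {path}")
    data = np.rint(np.clip(np.asarray(image, dtype=np.float64), 0, 255)).astype(np.uint8)
    iio.imwrite(path, data)


def write_mask(mask: np.ndarray, path) -> None:
    """Write a BinaryMask as an 8-bit raster with 0 -> 0 and 1 -> 255."""
    path = Path(path)
    if not path.parent.is_dir() or not os.access(path.parent, os.W_OK):
        raise OSError(f"output not writable: {path}")
    data = (as_binary_mask(mask) * np.uint8(255))
    iio.imwrite(path, data)


def read_mask(path) -> np.ndarray:
    """Read a mask raster back to {0,1} by thresholding at 128."""
    img = read_gray_image(path)
    return (img >= 128).astype(np.uint8)


@dataclass
class RunConfig:
    """Run configuration shared by the CLI subcommands.

    ``method`` selects the active-contour branch; parameter bundles for each
    branch live in their own modules and are carried here as plain dicts so a
    YAML config file can populate them field by field.  CLI flags override
    file values on conflict.
    """

    method: str = "cv"
    enhancement_iterations: int = 3
    cv_params: dict = field(default_factory=dict)
    lbf_params: dict = field(default_factory=dict)
    fusion_params: dict = field(default_factory=dict)
    seed: int = 0
    output_dir: str = "."

    def __post_init__(self) -> None:
        if self.method not in ("cv", "lbf", "fused"):
            raise ValueError(f"invalid config field 'method': {self.method!r}")
        if int(self.enhancement_iterations) < 1:
            raise ValueError("invalid config field 'enhancement_iterations': must be >= 1")
        if int(self.seed) < 0:
            raise ValueError("invalid config field 'seed': must be >= 0")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        """Load a config file, then apply keyword overrides (CLI flags win)."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError("invalid config file: expected a key-value mapping")
        data.update({k: v for k, v in overrides.items() if v is not None})
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"invalid config field(s): {sorted(unknown)}")
        return cls(**data)
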