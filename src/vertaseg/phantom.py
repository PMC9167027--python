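"""Seeded synthetic vertebra phantoms with ground-truth masks.

A phantom slice emulates a lumbar vertebral cross-section: a bright cortical
ring (outer ellipse minus a concentric inner ellipse at 60% of the axes)
plus a rectangular posterior spinous process, over a darker soft-tissue
background.  Optional degradations mirror CT artifacts: a smooth
multiplicative bias field (gray unevenness), additive Gaussian noise, and
salt impulses.  Generation is a pure function of the spec, seed included, so
every segmentation property is testable without external data.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .raster_io import as_binary_mask

__all__ = ["PhantomSpec", "generate_vertebra_phantom", "generate_slice_stack", "dice"]


@dataclass
class PhantomSpec:
    """Geometry, intensity and degradation parameters for one phantom slice.

    Intensities are on the 0-255 scale; bone must be brighter than background
    (bone is bright on CT).  ``bias_amplitude`` a gives a multiplicative
    field in [1-a, 1+a]; ``noise_sigma`` is the additive Gaussian std;
    ``salt_fraction`` the fraction of pixels replaced by 255 impulses.
    """

    height: int = 128
    width: int = 128
    body_axes: tuple[float, float] = (30.0, 22.0)  # (column, row) semi-axes
    process_length: int = 18
    bone_intensity: float = 200.0
    background_intensity: float = 60.0
    bias_amplitude: float = 0.0
    noise_sigma: float = 0.0
    salt_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bone_intensity <= self.background_intensity:
            raise ValueError("bone_intensity must exceed background_intensity")
        if not (0.0 <= self.bias_amplitude <= 1.0):
            raise ValueError("bias_amplitude must be in [0, 1]")
        if not (0.0 <= self.salt_fraction <= 1.0):
            raise ValueError("salt_fraction must be in [0, 1]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if int(self.seed) < 0:
            raise ValueError("seed must be >= 0")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["body_axes"] = list(self.body_axes)
        return d


_INNER_FRACTION = 0.6  # inner ellipse axes as a fraction of the outer
_PROCESS_WIDTH = 6     # spinous-process width in pixels


def _truth_mask(spec: PhantomSpec, center=None) -> np.ndarray:
    h, w = int(spec.height), int(spec.width)
    a, b = spec.body_axes  # a: column semi-axis, b: row semi-axis
    cy, cx = center if center is not None else ((h - 1) / 2.0, (w - 1) / 2.0)
    if cy - b < 0 or cx - a < 0 or cx + a > w - 1:
        raise ValueError("phantom does not fit")
    proc_r0 = cy + _INNER_FRACTION * b  # overlap the ring so the union is connected
    proc_r1 = proc_r0 + spec.process_length
    if proc_r1 > h - 1:
        raise ValueError("phantom does not fit")
    rr, cc = np.meshgrid(np.arange(h, dtype=float), np.arange(w, dtype=float), indexing="ij")
    q = ((cc - cx) / a) ** 2 + ((rr - cy) / b) ** 2
    ring = (q <= 1.0) & (q > _INNER_FRACTION**2)
    process = (
        (rr >= proc_r0)
        & (rr <= proc_r1)
        & (np.abs(cc - cx) <= _PROCESS_WIDTH / 2.0)
    )
    return (ring | process).astype(np.uint8)


def _bias_field(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    h, w = int(spec.height), int(spec.width)
    if spec.bias_amplitude == 0.0:
        return np.ones((h, w))
    rr, cc = np.meshgrid(np.arange(h, dtype=float), np.arange(w, dtype=float), indexing="ij")
    field = np.zeros((h, w))
    # a few broad Gaussian bumps at seeded random centers: the simplest
    # smooth inhomogeneity resembling CT gray unevenness
    for _ in range(4):
        y0 = rng.uniform(0, h - 1)
        x0 = rng.uniform(0, w - 1)
        s = rng.uniform(0.25, 0.5) * max(h, w)
        field += np.exp(-((rr - y0) ** 2 + (cc - x0) ** 2) / (2.0 * s**2))
    lo, hi = field.min(), field.max()
    if hi - lo < 1e-12:
        return np.ones((h, w))
    a = spec.bias_amplitude
    return (1.0 - a) + (field - lo) * (2.0 * a / (hi - lo))


def generate_vertebra_phantom(spec: PhantomSpec | None = None, center=None):
    """Generate one phantom slice; returns (image, truth mask).

    image = clamp(bias * (bone * truth + background * (1 - truth)) + noise),
    then salt impulses.  Identical specs (seed included) give identical
    output.
    """
    spec = spec or PhantomSpec()
    truth = _truth_mask(spec, center=center)
    rng = np.random.default_rng(spec.seed)
    bias = _bias_field(spec, rng)
    clean = spec.bone_intensity * truth + spec.background_intensity * (1.0 - truth)
    img = bias * clean
    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, img.shape)
    img = np.clip(img, 0.0, 255.0)
    if spec.salt_fraction > 0:
        n = int(round(spec.salt_fraction * img.size))
        if n:
            flat = rng.choice(img.size, size=n, replace=False)
            img.flat[flat] = 255.0
    return img, truth


def generate_slice_stack(spec: PhantomSpec | None = None, n: int = 1, drift: float = 0.0):
    """Generate n sequential slices whose body center drifts along columns.

    Frame i uses seed ``spec.seed + i`` for fresh noise; returns the frame
    list and the per-frame truth masks.
    """
    spec = spec or PhantomSpec()
    if int(n) < 1:
        raise ValueError("n must be >= 1")
    frames, truths = [], []
    cy = (spec.height - 1) / 2.0
    cx0 = (spec.width - 1) / 2.0
    for i in range(int(n)):
        frame_spec = PhantomSpec(**{**spec.to_dict(), "seed": spec.seed + i,
                                    "body_axes": tuple(spec.body_axes)})
        img, truth = generate_vertebra_phantom(frame_spec, center=(cy, cx0 + drift * i))
        frames.append(img)
        truths.append(truth)
    return frames, truths


def dice(a, b) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|); two empty masks score 1."""
    ma = as_binary_mask(a).astype(bool)
    mb = as_binary_mask(b).astype(bool)
    if ma.shape != mb.shape:
        raise ValueError("mask shape mismatch")
    sa, sb = int(ma.sum()), int(mb.sum())
    if sa + sb == 0:
        return 1.0
    return 2.0 * int((ma & mb).sum()) / (sa + sb)
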