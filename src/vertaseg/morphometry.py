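"""Spinal morphometry and clinical-efficacy statistics.

Downstream quantities measured on segmented slices: the protrusion-to-canal
area ratio, disc height (midpoint of the upper vertebra's lower endplate to
the midpoint of the lower vertebra's upper endplate), and vertebral
slippage (the anteroposterior offset between near-parallel endplates,
0 mm when aligned).  Efficacy operations grade per-patient improvement on a
four-level scale, compute a group's total effective rate, and compare
groups with a chi-square test on the responder table and paired /
two-sample t tests on scores.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy import stats

from .raster_io import as_binary_mask

__all__ = [
    "PixelSpacing",
    "EndplateLine",
    "MorphometryResult",
    "EfficacyCounts",
    "Grade",
    "protrusion_ratio",
    "disc_height",
    "vertebral_slippage",
    "grade_improvement",
    "total_effective_rate",
    "compare_rates",
    "compare_scores",
]


@dataclass
class PixelSpacing:
    """Physical pixel size in mm (rows may differ from columns)."""

    mm_per_pixel_row: float = 1.0
    mm_per_pixel_col: float = 1.0

    def __post_init__(self) -> None:
        if self.mm_per_pixel_row <= 0 or self.mm_per_pixel_col <= 0:
            raise ValueError("pixel spacing must be > 0")


@dataclass
class EndplateLine:
    """Endplate edge line as a (row, col) point pair in pixel coordinates."""

    p_start: tuple[float, float]
    p_end: tuple[float, float]

    def __post_init__(self) -> None:
        if tuple(self.p_start) == tuple(self.p_end):
            raise ValueError("endplate line endpoints must differ")


@dataclass
class MorphometryResult:
    protrusion_area_mm2: float = 0.0
    canal_area_mm2: float = 0.0
    protrusion_ratio: float = 0.0
    disc_height_mm: float = 0.0
    slippage_mm: float = 0.0


class Grade(str, Enum):
    CURED = "cured"
    MARKEDLY_EFFECTIVE = "markedly_effective"
    EFFECTIVE = "effective"
    INEFFECTIVE = "ineffective"


@dataclass
class EfficacyCounts:
    """Per-group counts on the four-level efficacy scale."""

    cured: int
    markedly: int
    effective: int
    ineffective: int

    def __post_init__(self) -> None:
        for name in ("cured", "markedly", "effective", "ineffective"):
            if int(getattr(self, name)) < 0:
                raise ValueError(f"{name} count must be >= 0")
        if self.total == 0:
            raise ValueError("empty group")

    @property
    def total(self) -> int:
        return int(self.cured) + int(self.markedly) + int(self.effective) + int(self.ineffective)

    @property
    def responders(self) -> int:
        return int(self.cured) + int(self.markedly) + int(self.effective)


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def _to_mm(point, spacing: PixelSpacing) -> np.ndarray:
    r, c = float(point[0]), float(point[1])
    return np.array([r * spacing.mm_per_pixel_row, c * spacing.mm_per_pixel_col])


def protrusion_ratio(protrusion, canal, spacing: PixelSpacing | None = None) -> MorphometryResult:
    """Areas (mm^2) of the protrusion and spinal-canal masks and their ratio."""
    spacing = spacing or PixelSpacing()
    p = as_binary_mask(protrusion)
    c = as_binary_mask(canal)
    px_mm2 = spacing.mm_per_pixel_row * spacing.mm_per_pixel_col
    canal_area = float(c.sum()) * px_mm2
    if canal_area == 0.0:
        raise ValueError("canal area zero")
    prot_area = float(p.sum()) * px_mm2
    return MorphometryResult(
        protrusion_area_mm2=prot_area,
        canal_area_mm2=canal_area,
        protrusion_ratio=prot_area / canal_area,
    )


def disc_height(upper_mid, lower_mid, spacing: PixelSpacing | None = None) -> float:
    """Euclidean distance in mm between endplate midpoints (anisotropic spacing)."""
    spacing = spacing or PixelSpacing()
    return float(np.linalg.norm(_to_mm(upper_mid, spacing) - _to_mm(lower_mid, spacing)))


def vertebral_slippage(upper_edge: EndplateLine, lower_edge: EndplateLine,
                       spacing: PixelSpacing | None = None,
                       max_angle_deg: float = 30.0,
                       as_percent_of_endplate: bool = False) -> float:
    """Anteroposterior offset between two near-parallel endplate lines.

    Construction: a midline parallel to both edges (direction = mean of the
    two unit directions, through the midpoint between the two line
    midpoints); each edge midpoint is dropped perpendicularly onto the
    midline and the slippage is the distance between the two foot points.
    Exactly aligned endplates give 0; pure perpendicular separation (disc
    space without shear) also gives 0.  With ``as_percent_of_endplate`` the
    offset is normalized by the mean endplate length and returned in %.
    """
    spacing = spacing or PixelSpacing()
    a0 = _to_mm(upper_edge.p_start, spacing)
    a1 = _to_mm(upper_edge.p_end, spacing)
    b0 = _to_mm(lower_edge.p_start, spacing)
    b1 = _to_mm(lower_edge.p_end, spacing)
    da = a1 - a0
    db = b1 - b0
    ua = da / np.linalg.norm(da)
    ub = db / np.linalg.norm(db)
    if ua @ ub < 0:  # align orientations before averaging
        ub = -ub
    cosang = float(np.clip(abs(ua @ ub), -1.0, 1.0))
    if np.degrees(np.arccos(cosang)) > max_angle_deg:
        raise ValueError("endplates not near-parallel")
    d = ua + ub
    d = d / np.linalg.norm(d)
    ma = (a0 + a1) / 2.0
    mb = (b0 + b1) / 2.0
    slip = abs(float((ma - mb) @ d))
    if as_percent_of_endplate:
        mean_len = (np.linalg.norm(da) + np.linalg.norm(db)) / 2.0
        return 100.0 * slip / mean_len
    return slip


# ---------------------------------------------------------------------------
# efficacy
# ---------------------------------------------------------------------------

def grade_improvement(rate: float) -> Grade:
    """Map an improvement rate (%) onto the four-level efficacy scale.

    >= 80 cured; >= 60 markedly effective; >= 25 effective; below 25
    ineffective.  Bands are closed on the left of the better category.
    """
    r = float(rate)
    if not (0.0 <= r <= 100.0):
        raise ValueError("invalid improvement rate")
    if r >= 80.0:
        return Grade.CURED
    if r >= 60.0:
        return Grade.MARKEDLY_EFFECTIVE
    if r >= 25.0:
        return Grade.EFFECTIVE
    return Grade.INEFFECTIVE


def total_effective_rate(counts: EfficacyCounts) -> float:
    """Percentage of responders (cured + markedly + effective), 2 decimals."""
    if counts.total == 0:
        raise ValueError("empty group")
    return round(100.0 * counts.responders / counts.total, 2)


def compare_rates(a: EfficacyCounts, b: EfficacyCounts, correction: bool = False):
    """Pearson chi-square on the 2x2 responders-vs-ineffective table, 1 df.

    No continuity correction by default; pass ``correction=True`` for Yates.
    Returns (statistic, p_value).
    """
    table = np.array([[a.responders, a.ineffective],
                      [b.responders, b.ineffective]], dtype=float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("degenerate table")
    if np.array_equal(table[0] / table[0].sum(), table[1] / table[1].sum()):
        # identical proportions: chi2_contingency handles this fine, but make
        # the exact zero explicit rather than trusting float cancellation
        return 0.0, 1.0
    res = stats.chi2_contingency(table, correction=correction)
    return float(res.statistic), float(res.pvalue)


def compare_scores(before_a, after_a, before_b, after_b, welch: bool = False):
    """Score comparison summary: paired t within groups, two-sample t between.

    Within each group a paired t test contrasts before vs. after; between
    groups a two-sample t test (pooled variance by default, Welch optional)
    contrasts the after-treatment scores.  Returns a dict of means +- SD,
    t statistics and p values.
    """
    arrays = {k: np.asarray(v, dtype=float) for k, v in
              dict(before_a=before_a, after_a=after_a,
                   before_b=before_b, after_b=after_b).items()}
    for k, arr in arrays.items():
        if arr.size == 0:
            raise ValueError(f"{k} is empty")
    if arrays["before_a"].size != arrays["after_a"].size or \
       arrays["before_b"].size != arrays["after_b"].size:
        raise ValueError("unpaired observations")

    def _summ(x):
        return float(x.mean()), float(x.std(ddof=1)) if x.size > 1 else 0.0

    out = {}
    for g in ("a", "b"):
        pre, post = arrays[f"before_{g}"], arrays[f"after_{g}"]
        if np.allclose(pre - post, (pre - post).mean()) and np.isclose((pre - post).mean(), 0):
            t, p = 0.0, 1.0  # all differences zero: no change, degenerate t
        else:
            t, p = stats.ttest_rel(pre, post)
        m0, s0 = _summ(pre)
        m1, s1 = _summ(post)
        out[f"group_{g}"] = {
            "before_mean": m0, "before_sd": s0,
            "after_mean": m1, "after_sd": s1,
            "paired_t": float(t), "paired_p": float(p),
        }
    xa, xb = arrays["after_a"], arrays["after_b"]
    if np.isclose(xa.mean(), xb.mean()) and xa.std() == 0 and xb.std() == 0:
        t, p = 0.0, 1.0  # identical constant groups: degenerate t
    else:
        t, p = stats.ttest_ind(xa, xb, equal_var=not welch)
    out["between_after"] = {"t": float(t), "p": float(p)}
    return out
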