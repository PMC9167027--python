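"""Level-set active contours: Chan-Vese (global) and local-binary-fitting.

The segmenting curve C is carried implicitly as the zero level of a scalar
field phi(x, y); pixels with phi >= 0 are "inside".  Two region-based
energies are provided:

* **Chan-Vese (C-V)**: assumes two approximately constant phases and fits
  global means c1 (inside) and c2 (outside),

      A(c1, c2, phi) = mu * Length + nu * Area
                       + lambda1 * sum (I - c1)^2 H(phi)
                       + lambda2 * sum (I - c2)^2 (1 - H(phi))

* **Local binary fitting (LBF)**: replaces c1, c2 by kernel-weighted local
  mean fields g1(x), g2(x), which tracks smooth intensity inhomogeneity
  (bias fields / "gray unevenness") that defeats a global two-phase fit,

      E = lambda1 * sum_x sum_y K(x-y) (I(y) - g1(x))^2 H(phi(y))
        + lambda2 * sum_x sum_y K(x-y) (I(y) - g2(x))^2 (1 - H(phi(y)))

Both are minimized by explicit gradient descent on phi with a regularized
Heaviside H_eps(t) = 1/2 (1 + 2/pi * arctan(t/eps)) and its derivative
delta_eps(t) = eps / (pi (eps^2 + t^2)); the sharp step indicator is the
eps -> 0 limit.  Discretization: central differences with replicated-edge
(Neumann) boundaries, unit pixel spacing, ties phi == 0 inside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .raster_io import as_gray_image

__all__ = [
    "CVParams",
    "LBFParams",
    "LocalFitting",
    "heaviside",
    "dirac",
    "circle_level_set",
    "checkerboard_level_set",
    "cv_region_means",
    "cv_energy",
    "cv_evolve",
    "lbf_fitting_functions",
    "lbf_energy",
    "lbf_evolve",
    "binarize",
]

_DEGENERATE = 1e-9  # region-weight threshold below which a mean falls back to global
_GRAD_GUARD = 1e-8  # additive guard in |grad phi|


@dataclass
class CVParams:
    """Chan-Vese parameters.

    Intensities live on the 0-255 scale, so the fitting residuals are O(255^2)
    and the length weight mu is quoted in units of 255^2.  The time step must
    balance those magnitudes: with lambda1 = lambda2 = 1 the descent force is
    O(1e4), hence the small default dt.
    """

    mu: float = 0.05 * 255.0**2
    nu: float = 0.0
    lambda1: float = 1.0
    lambda2: float = 1.0
    epsilon: float = 1.0
    dt: float = 1e-3
    max_iters: int = 400
    tol: float = 1e-6

    def __post_init__(self) -> None:
        if self.lambda1 <= 0 or self.lambda2 <= 0:
            raise ValueError("lambda1 and lambda2 must be > 0")
        if self.epsilon <= 0:
            raise ValueError("invalid regularization width")
        if self.dt <= 0 or self.tol <= 0 or int(self.max_iters) < 1:
            raise ValueError("dt, tol must be > 0 and max_iters >= 1")


@dataclass
class LBFParams:
    """LBF parameters (Gaussian kernel width sigma in pixels).

    Defaults follow common LBF practice on the 0-255 scale: sigma = 3,
    length weight 0.003 * 255^2, distance-regularization weight 1, dt = 0.1.
    """

    sigma: float = 3.0
    lambda1: float = 1.0
    lambda2: float = 1.0
    mu_reg: float = 1.0
    nu_len: float = 0.003 * 255.0**2
    epsilon: float = 1.0
    dt: float = 0.05
    max_iters: int = 400
    tol: float = 1e-6

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.lambda1 <= 0 or self.lambda2 <= 0:
            raise ValueError("lambda1 and lambda2 must be > 0")
        if self.epsilon <= 0:
            raise ValueError("invalid regularization width")
        if self.dt <= 0 or self.tol <= 0 or int(self.max_iters) < 1:
            raise ValueError("dt, tol must be > 0 and max_iters >= 1")


@dataclass
class LocalFitting:
    """Local inside/outside mean fields g1, g2 of the LBF model."""

    g1: np.ndarray
    g2: np.ndarray


# ---------------------------------------------------------------------------
# Heaviside / Dirac machinery and level-set initializers
# ---------------------------------------------------------------------------

def heaviside(phi_value, epsilon: float = 1.0):
    """Regularized Heaviside H_eps(t) = 1/2 (1 + 2/pi arctan(t/eps))."""
    if epsilon <= 0:
        raise ValueError("invalid regularization width")
    return 0.5 * (1.0 + (2.0 / np.pi) * np.arctan(np.asarray(phi_value, dtype=np.float64) / epsilon))


def dirac(phi_value, epsilon: float = 1.0):
    """Regularized Dirac delta_eps(t) = eps / (pi (eps^2 + t^2)) = H_eps'."""
    if epsilon <= 0:
        raise ValueError("invalid regularization width")
    t = np.asarray(phi_value, dtype=np.float64)
    return epsilon / (np.pi * (epsilon**2 + t**2))


def circle_level_set(shape, center=None, radius=None) -> np.ndarray:
    """Signed distance to a circle (positive inside); the default initializer.

    Defaults: centered, radius min(h, w) / 4.
    """
    h, w = shape
    if center is None:
        center = ((h - 1) / 2.0, (w - 1) / 2.0)
    if radius is None:
        radius = min(h, w) / 4.0
    rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    return radius - np.sqrt((rr - center[0]) ** 2 + (cc - center[1]) ** 2)


def checkerboard_level_set(shape, period: int = 10) -> np.ndarray:
    """Sinusoidal checkerboard field; many small initial contours."""
    h, w = shape
    rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    return np.sin(np.pi * rr / period) * np.sin(np.pi * cc / period)


def _check_shapes(image: np.ndarray, phi: np.ndarray) -> None:
    if image.shape != np.asarray(phi).shape:
        raise ValueError("image/field shape mismatch")


def _check_init(phi: np.ndarray) -> None:
    if not np.all(np.isfinite(phi)):
        raise ValueError("level-set field contains non-finite values")
    if not ((phi >= 0).any() and (phi < 0).any()):
        raise ValueError("initial field must contain both signs (nonempty contour)")


# Neumann (replicated-edge) central differences; unit pixel spacing.

def _grad(f: np.ndarray):
    p = np.pad(f, 1, mode="edge")
    gy = (p[2:, 1:-1] - p[:-2, 1:-1]) / 2.0
    gx = (p[1:-1, 2:] - p[1:-1, :-2]) / 2.0
    return gy, gx


def _laplacian(f: np.ndarray) -> np.ndarray:
    p = np.pad(f, 1, mode="edge")
    return p[2:, 1:-1] + p[:-2, 1:-1] + p[1:-1, 2:] + p[1:-1, :-2] - 4.0 * f


def _curvature(phi: np.ndarray) -> np.ndarray:
    """div(grad phi / |grad phi|) with the |grad| guard."""
    gy, gx = _grad(phi)
    mag = np.sqrt(gx**2 + gy**2) + _GRAD_GUARD
    ny = gy / mag
    nx = gx / mag
    dyy, _ = _grad(ny)
    _, dxx = _grad(nx)
    return dyy + dxx


def _contour_length(phi: np.ndarray, epsilon: float) -> float:
    gy, gx = _grad(phi)
    return float(np.sum(dirac(phi, epsilon) * np.sqrt(gx**2 + gy**2)))


# ---------------------------------------------------------------------------
# Chan-Vese branch
# ---------------------------------------------------------------------------

def cv_region_means(image, field, epsilon: float = 1.0):
    """Global inside/outside means (c1, c2) under the regularized Heaviside.

    c1 = sum(I H) / sum(H), c2 = sum(I (1-H)) / sum(1-H).  A region whose
    total weight is degenerate (< 1e-9) falls back to the global image mean.
    """
    img = as_gray_image(image)
    phi = np.asarray(field, dtype=np.float64)
    _check_shapes(img, phi)
    H = heaviside(phi, epsilon)
    w1 = float(H.sum())
    w2 = float((1.0 - H).sum())
    gmean = float(img.mean())
    c1 = float((img * H).sum() / w1) if w1 >= _DEGENERATE else gmean
    c2 = float((img * (1.0 - H)).sum() / w2) if w2 >= _DEGENERATE else gmean
    return c1, c2


def cv_energy(image, field, params: CVParams) -> float:
    """Discrete Chan-Vese energy with the regularized H and delta."""
    img = as_gray_image(image)
    phi = np.asarray(field, dtype=np.float64)
    _check_shapes(img, phi)
    H = heaviside(phi, params.epsilon)
    c1, c2 = cv_region_means(img, phi, params.epsilon)
    length = _contour_length(phi, params.epsilon)
    area = float(H.sum())
    fit1 = float(((img - c1) ** 2 * H).sum())
    fit2 = float(((img - c2) ** 2 * (1.0 - H)).sum())
    return params.mu * length + params.nu * area + params.lambda1 * fit1 + params.lambda2 * fit2


def _run_descent(phi, step, energy, max_iters, tol):
    """Shared descent driver: stop at max_iters or when the relative energy
    change stays below tol for 5 consecutive iterations."""
    history: list[float] = []
    calm = 0
    for _ in range(int(max_iters)):
        with np.errstate(over="ignore", invalid="ignore"):
            phi = step(phi)
            if not np.all(np.isfinite(phi)):
                raise FloatingPointError("evolution diverged (reduce dt)")
            e = energy(phi)
        if not np.isfinite(e):
            raise FloatingPointError("evolution diverged (reduce dt)")
        history.append(e)
        if len(history) >= 2:
            prev = history[-2]
            rel = abs(e - prev) / max(abs(prev), 1e-12)
            calm = calm + 1 if rel < tol else 0
            if calm >= 5:
                break
    return phi, history


def cv_evolve(image, init, params: CVParams | None = None):
    """Gradient-descent minimization of the Chan-Vese energy.

    phi <- phi + dt * delta(phi) * (mu*kappa - nu - l1 (I-c1)^2 + l2 (I-c2)^2)

    Returns the final field and the per-iteration energy history.
    """
    params = params or CVParams()
    img = as_gray_image(image)
    phi0 = np.asarray(init, dtype=np.float64).copy()
    _check_shapes(img, phi0)
    _check_init(phi0)

    def step(phi):
        c1, c2 = cv_region_means(img, phi, params.epsilon)
        force = (
            params.mu * _curvature(phi)
            - params.nu
            - params.lambda1 * (img - c1) ** 2
            + params.lambda2 * (img - c2) ** 2
        )
        return phi + params.dt * dirac(phi, params.epsilon) * force

    phi, history = _run_descent(phi0, step, lambda p: cv_energy(img, p, params),
                                params.max_iters, params.tol)
    return _orient(img, phi, lambda p: cv_energy(img, p, params), params.epsilon), history


def _orient(img, phi, energy, epsilon):
    """Resolve the inside/outside labeling ambiguity.

    With lambda1 == lambda2 and nu == 0 the energy is invariant under
    phi -> -phi (the two labelings are equally good minima and the one
    reached depends on the initialization).  Keep whichever labeling has
    lower energy; on a tie, adopt the bright-inside convention (bone is the
    bright phase on CT).
    """
    e, e_flip = energy(phi), energy(-phi)
    if e_flip < e * (1.0 - 1e-12):
        return -phi
    if abs(e_flip - e) <= abs(e) * 1e-9:
        c1, c2 = cv_region_means(img, phi, epsilon)
        if c1 < c2:
            return -phi
    return phi


# ---------------------------------------------------------------------------
# Local-binary-fitting branch
# ---------------------------------------------------------------------------

def _ksmooth(arr: np.ndarray, sigma: float) -> np.ndarray:
    # normalized, truncated Gaussian; replicated edges keep K*1 == 1
    return gaussian_filter(arr, sigma=sigma, mode="nearest")


def lbf_fitting_functions(image, field, params: LBFParams | None = None) -> LocalFitting:
    """Kernel-weighted local mean fields.

    g1 = K*(H I) / K*H and g2 = K*((1-H) I) / K*(1-H); a pixel whose local
    region weight is degenerate (< 1e-9) falls back to the global mean.
    """
    params = params or LBFParams()
    img = as_gray_image(image)
    phi = np.asarray(field, dtype=np.float64)
    _check_shapes(img, phi)
    H = heaviside(phi, params.epsilon)
    gmean = float(img.mean())
    kh = _ksmooth(H, params.sigma)
    kmh = _ksmooth(1.0 - H, params.sigma)
    g1 = np.where(kh >= _DEGENERATE, _ksmooth(img * H, params.sigma) / np.maximum(kh, _DEGENERATE), gmean)
    g2 = np.where(kmh >= _DEGENERATE, _ksmooth(img * (1.0 - H), params.sigma) / np.maximum(kmh, _DEGENERATE), gmean)
    return LocalFitting(g1=g1, g2=g2)


def lbf_energy(image, field, params: LBFParams | None = None,
               fitting: LocalFitting | None = None) -> float:
    """Discrete LBF energy, evaluated through convolution identities.

    The double sum over (x, y) expands, for the inside term, to
    sum_x [K*(I^2 H) - 2 g1 K*(I H) + g1^2 K*H](x); likewise outside.
    Length (nu_len) and distance-regularization (mu_reg) penalties are added
    when their weights are nonzero.
    """
    params = params or LBFParams()
    img = as_gray_image(image)
    phi = np.asarray(field, dtype=np.float64)
    _check_shapes(img, phi)
    if fitting is None:
        fitting = lbf_fitting_functions(img, phi, params)
    g1, g2 = fitting.g1, fitting.g2
    H = heaviside(phi, params.epsilon)
    s = params.sigma
    ki2h = _ksmooth(img**2 * H, s)
    kih = _ksmooth(img * H, s)
    kh = _ksmooth(H, s)
    ki2m = _ksmooth(img**2 * (1.0 - H), s)
    kim = _ksmooth(img * (1.0 - H), s)
    kmh = _ksmooth(1.0 - H, s)
    e_in = float((ki2h - 2.0 * g1 * kih + g1**2 * kh).sum())
    e_out = float((ki2m - 2.0 * g2 * kim + g2**2 * kmh).sum())
    e = params.lambda1 * e_in + params.lambda2 * e_out
    if params.nu_len:
        e += params.nu_len * _contour_length(phi, params.epsilon)
    if params.mu_reg:
        gy, gx = _grad(phi)
        e += params.mu_reg * float((0.5 * (np.sqrt(gx**2 + gy**2) - 1.0) ** 2).sum())
    return e


def lbf_evolve(image, init, params: LBFParams | None = None):
    """Alternating minimization: update g1, g2 in closed form, then descend phi.

    phi <- phi + dt * [ -delta(phi) (l1 e1 - l2 e2)
                        + nu_len delta(phi) kappa
                        + mu_reg (lap phi - kappa) ]

    with e_i(y) = sum_x K(x-y) (I(y) - g_i(x))^2 expanded via convolutions.
    The distance-regularization term keeps phi close to a signed distance
    function, replacing explicit reinitialization.
    """
    params = params or LBFParams()
    img = as_gray_image(image)
    phi0 = np.asarray(init, dtype=np.float64).copy()
    _check_shapes(img, phi0)
    _check_init(phi0)
    s = params.sigma

    def step(phi):
        fit = lbf_fitting_functions(img, phi, params)
        kg1 = _ksmooth(fit.g1, s)
        kg1sq = _ksmooth(fit.g1**2, s)
        kg2 = _ksmooth(fit.g2, s)
        kg2sq = _ksmooth(fit.g2**2, s)
        e1 = img**2 - 2.0 * img * kg1 + kg1sq  # K*1 == 1 (normalized kernel)
        e2 = img**2 - 2.0 * img * kg2 + kg2sq
        d = dirac(phi, params.epsilon)
        kappa = _curvature(phi)
        dphi = (
            -d * (params.lambda1 * e1 - params.lambda2 * e2)
            + params.nu_len * d * kappa
            + params.mu_reg * (_laplacian(phi) - kappa)
        )
        return phi + params.dt * dphi

    phi, history = _run_descent(phi0, step, lambda p: lbf_energy(img, p, params),
                                params.max_iters, params.tol)
    return _orient(img, phi, lambda p: lbf_energy(img, p, params), params.epsilon), history


def binarize(field) -> np.ndarray:
    """Threshold the level-set field at zero: phi >= 0 -> 1, else 0."""
    phi = np.asarray(field, dtype=np.float64)
    if not np.all(np.isfinite(phi)):
        raise ValueError("level-set field contains non-finite values")
    return (phi >= 0).astype(np.uint8)
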