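"""Independent brute-force oracles for the energy and statistics operations.

Everything here is written as direct, loop-based summation from the defining
formulas, deliberately sharing no code with the package implementation.
"""

import math

import numpy as np


def _H(t, eps):
    return 0.5 * (1.0 + (2.0 / math.pi) * math.atan(t / eps))


def _delta(t, eps):
    return eps / (math.pi * (eps * eps + t * t))


def _central_diff(phi, i, j):
    """Replicated-edge central differences at one pixel."""
    h, w = phi.shape
    gy = (phi[min(i + 1, h - 1), j] - phi[max(i - 1, 0), j]) / 2.0
    gx = (phi[i, min(j + 1, w - 1)] - phi[i, max(j - 1, 0)]) / 2.0
    return gy, gx


def region_means(img, phi, eps):
    n1 = d1 = n2 = d2 = 0.0
    h, w = img.shape
    for i in range(h):
        for j in range(w):
            hv = _H(phi[i, j], eps)
            n1 += img[i, j] * hv
            d1 += hv
            n2 += img[i, j] * (1.0 - hv)
            d2 += 1.0 - hv
    g = img.mean()
    c1 = n1 / d1 if d1 >= 1e-9 else g
    c2 = n2 / d2 if d2 >= 1e-9 else g
    return c1, c2


def cv_energy(img, phi, mu, nu, lam1, lam2, eps):
    c1, c2 = region_means(img, phi, eps)
    h, w = img.shape
    e = 0.0
    for i in range(h):
        for j in range(w):
            gy, gx = _central_diff(phi, i, j)
            hv = _H(phi[i, j], eps)
            e += mu * _delta(phi[i, j], eps) * math.sqrt(gx * gx + gy * gy)
            e += nu * hv
            e += lam1 * (img[i, j] - c1) ** 2 * hv
            e += lam2 * (img[i, j] - c2) ** 2 * (1.0 - hv)
    return e


def _gauss_weights(sigma):
    r = int(4.0 * sigma + 0.5)
    wts = np.array([math.exp(-(k * k) / (2.0 * sigma * sigma)) for k in range(-r, r + 1)])
    return wts / wts.sum(), r


def lbf_fitting(img, phi, sigma, eps):
    """Local inside/outside means by direct weighted summation.

    The kernel is the truncated, per-axis-normalized Gaussian with
    replicated edges (out-of-range coordinates clipped per axis).
    """
    wts, r = _gauss_weights(sigma)
    h, w = img.shape
    g1 = np.empty((h, w))
    g2 = np.empty((h, w))
    gmean = img.mean()
    for i in range(h):
        for j in range(w):
            n1 = d1 = n2 = d2 = 0.0
            for dy in range(-r, r + 1):
                for dx in range(-r, r + 1):
                    y = min(max(i + dy, 0), h - 1)
                    x = min(max(j + dx, 0), w - 1)
                    wgt = wts[dy + r] * wts[dx + r]
                    hv = _H(phi[y, x], eps)
                    n1 += wgt * img[y, x] * hv
                    d1 += wgt * hv
                    n2 += wgt * img[y, x] * (1.0 - hv)
                    d2 += wgt * (1.0 - hv)
            g1[i, j] = n1 / d1 if d1 >= 1e-9 else gmean
            g2[i, j] = n2 / d2 if d2 >= 1e-9 else gmean
    return g1, g2


def lbf_energy(img, phi, sigma, lam1, lam2, eps):
    """Quadruple-loop LBF data energy (length/regularization weights zero)."""
    g1, g2 = lbf_fitting(img, phi, sigma, eps)
    wts, r = _gauss_weights(sigma)
    h, w = img.shape
    e = 0.0
    for i in range(h):
        for j in range(w):
            for dy in range(-r, r + 1):
                for dx in range(-r, r + 1):
                    y = min(max(i + dy, 0), h - 1)
                    x = min(max(j + dx, 0), w - 1)
                    wgt = wts[dy + r] * wts[dx + r]
                    hv = _H(phi[y, x], eps)
                    e += lam1 * wgt * (img[y, x] - g1[i, j]) ** 2 * hv
                    e += lam2 * wgt * (img[y, x] - g2[i, j]) ** 2 * (1.0 - hv)
    return e


def chi_square_2x2(table):
    """Pearson chi-square from the four-cell definition sum((O-E)^2 / E)."""
    table = np.asarray(table, dtype=float)
    total = table.sum()
    stat = 0.0
    for i in range(2):
        for j in range(2):
            expected = table[i].sum() * table[:, j].sum() / total
            stat += (table[i, j] - expected) ** 2 / expected
    return stat


def paired_t(before, after):
    d = np.asarray(before, float) - np.asarray(after, float)
    n = d.size
    sd = math.sqrt(((d - d.mean()) ** 2).sum() / (n - 1))
    return d.mean() / (sd / math.sqrt(n))


def pooled_two_sample_t(x, y):
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    nx, ny = x.size, y.size
    vx = ((x - x.mean()) ** 2).sum() / (nx - 1)
    vy = ((y - y.mean()) ** 2).sum() / (ny - 1)
    sp2 = ((nx - 1) * vx + (ny - 1) * vy) / (nx + ny - 2)
    return (x.mean() - y.mean()) / math.sqrt(sp2 * (1.0 / nx + 1.0 / ny))


def max_relative_ascent(history, burn_in=5):
    """Largest relative rise above the running minimum after burn-in."""
    h = np.asarray(history, dtype=float)
    worst = 0.0
    for i in range(burn_in + 1, len(h)):
        run_min = h[burn_in:i + 1].min()
        worst = max(worst, (h[i] - run_min) / abs(run_min))
    return worst
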