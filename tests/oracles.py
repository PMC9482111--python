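"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the library code paths (and vectorised numpy where
feasible): plain double loops with explicit border handling, so agreement
with the package is evidence, not tautology.
"""

from __future__ import annotations

import math

import numpy as np


def _reflect(i: int, n: int) -> int:
    """scipy 'reflect' border index: (d c b a | a b c d | d c b a)."""
    if i < 0:
        return -i - 1
    if i >= n:
        return 2 * n - i - 1
    return i


def naive_nematic_tensor(
    img: np.ndarray, mask: np.ndarray, floor_rel: float = 1e-6
) -> tuple[float, float, float] | None:
    """Double-loop accumulation of the gradient nematic tensor.

    Central differences with reflective borders; fibril direction
    perpendicular to the gradient in a y-up frame; weight = squared gradient
    magnitude; pixels below ``floor_rel`` of the in-mask intensity range are
    skipped.  Returns unit-trace (nxx, nyy, nxy) or None when undefined.
    """
    img = np.asarray(img, dtype=np.float64)
    h, w = img.shape
    vals = img[mask]
    rng = float(vals.max() - vals.min())
    if rng == 0.0:
        return None
    floor2 = (floor_rel * rng) ** 2
    txx = tyy = txy = 0.0
    any_kept = False
    for r in range(h):
        for c in range(w):
            if not mask[r, c]:
                continue
            gx = (img[r, _reflect(c + 1, w)] - img[r, _reflect(c - 1, w)]) / 2.0
            gy_row = (img[_reflect(r + 1, h), c] - img[_reflect(r - 1, h), c]) / 2.0
            gy = -gy_row  # y-up convention
            if gx * gx + gy * gy <= floor2:
                continue
            any_kept = True
            txx += gy * gy
            tyy += gx * gx
            txy += -gx * gy
    if not any_kept:
        return None
    tr = txx + tyy
    return txx / tr, tyy / tr, txy / tr


SOBEL_X = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=np.float64)
SOBEL_Y = SOBEL_X.T


def naive_sobel_magnitude(img: np.ndarray) -> np.ndarray:
    """3x3 Sobel gradient magnitude by explicit convolution, reflect borders.

    Matches scipy.ndimage.sobel's correlation orientation (the derivative
    kernels with positive weights toward increasing index).
    """
    img = np.asarray(img, dtype=np.float64)
    h, w = img.shape
    out = np.zeros((h, w))
    for r in range(h):
        for c in range(w):
            sx = sy = 0.0
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    v = img[_reflect(r + dr, h), _reflect(c + dc, w)]
                    sx += SOBEL_X[dr + 1, dc + 1] * v
                    sy += SOBEL_Y[dr + 1, dc + 1] * v
            out[r, c] = math.hypot(sx, sy)
    return out


def naive_ccp(img: np.ndarray, mask: np.ndarray, threshold: float) -> tuple[int, int]:
    """Brute-force CCP counts: (edge_pixels, area_pixels).

    Erodes the mask by one 8-connected pixel (interior band) and thresholds
    the naive Sobel magnitude relative to the interior maximum.
    """
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    interior = np.zeros_like(mask)
    for r in range(h):
        for c in range(w):
            if not mask[r, c]:
                continue
            ok = True
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    rr, cc = r + dr, c + dc
                    if rr < 0 or rr >= h or cc < 0 or cc >= w or not mask[rr, cc]:
                        ok = False
            interior[r, c] = ok
    mag = naive_sobel_magnitude(img)
    if not interior.any():
        return 0, int(mask.sum())
    mmax = mag[interior].max()
    if mmax == 0:
        return 0, int(mask.sum())
    edges = interior & (mag >= threshold * mmax)
    return int(edges.sum()), int(mask.sum())


def anova_f_and_p(groups: list[np.ndarray]) -> tuple[float, float]:
    """One-way ANOVA by explicit sums of squares plus the F survival function."""
    from scipy.stats import f as f_dist

    all_vals = np.concatenate(groups)
    grand = all_vals.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_b = len(groups) - 1
    df_w = len(all_vals) - len(groups)
    F = (ss_between / df_b) / (ss_within / df_w)
    return float(F), float(f_dist.sf(F, df_b, df_w))
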