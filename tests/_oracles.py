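"""Brute-force set-definition oracles, independent of the package internals.

These deliberately re-derive morphology, flood fill, Otsu thresholding and
OLS from first principles (loops and closed forms) so the vectorised
implementations can be checked against them on small inputs.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


def brute_erode(mask: np.ndarray, selem: np.ndarray) -> np.ndarray:
    """p survives iff every structuring-element offset lands on foreground
    (outside the frame counts as background)."""
    mask = np.asarray(mask, bool)
    h, w = mask.shape
    sh, sw = selem.shape
    oy, ox = sh // 2, sw // 2
    out = np.zeros_like(mask)
    for r in range(h):
        for c in range(w):
            keep = True
            for i in range(sh):
                for j in range(sw):
                    if not selem[i, j]:
                        continue
                    rr, cc = r + i - oy, c + j - ox
                    if not (0 <= rr < h and 0 <= cc < w) or not mask[rr, cc]:
                        keep = False
                        break
                if not keep:
                    break
            out[r, c] = keep
    return out


def brute_dilate(mask: np.ndarray, selem: np.ndarray) -> np.ndarray:
    """p becomes foreground iff some structuring-element offset lands on
    foreground."""
    mask = np.asarray(mask, bool)
    h, w = mask.shape
    sh, sw = selem.shape
    oy, ox = sh // 2, sw // 2
    out = np.zeros_like(mask)
    for r in range(h):
        for c in range(w):
            hit = False
            for i in range(sh):
                for j in range(sw):
                    if not selem[i, j]:
                        continue
                    rr, cc = r + i - oy, c + j - ox
                    if 0 <= rr < h and 0 <= cc < w and mask[rr, cc]:
                        hit = True
                        break
                if hit:
                    break
            out[r, c] = hit
    return out


def brute_flood(allowed: np.ndarray, seed: tuple[int, int], connectivity: int) -> np.ndarray:
    """Breadth-first flood over allowed pixels from a seed."""
    allowed = np.asarray(allowed, bool)
    h, w = allowed.shape
    if connectivity == 4:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        nbrs = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    out = np.zeros_like(allowed)
    if not allowed[seed]:
        raise ValueError("seed not allowed")
    stack = [seed]
    out[seed] = True
    while stack:
        r, c = stack.pop()
        for dr, dc in nbrs:
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w and allowed[rr, cc] and not out[rr, cc]:
                out[rr, cc] = True
                stack.append((rr, cc))
    return out


def brute_otsu_classes(values: np.ndarray) -> np.ndarray:
    """Foreground indicator from an exhaustive intra-class-variance search.

    Tries every midpoint between adjacent distinct values and keeps the
    threshold minimising the weighted within-class variance.
    """
    v = np.asarray(values, float).ravel()
    uniq = np.unique(v)
    best_thr, best_wcv = None, np.inf
    for lo, hi in zip(uniq[:-1], uniq[1:]):
        thr = (lo + hi) / 2.0
        a, b = v[v <= thr], v[v > thr]
        wcv = len(a) * a.var() + len(b) * b.var()
        if wcv < best_wcv:
            best_wcv, best_thr = wcv, thr
    return np.asarray(values) > best_thr


def normal_equations_fit(x: np.ndarray, y: np.ndarray):
    """Closed-form OLS: slope, intercept, R^2, two-sided slope p (t, n-2 df)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    sxx = np.sum((x - x.mean()) ** 2)
    sxy = np.sum((x - x.mean()) * (y - y.mean()))
    slope = sxy / sxx
    intercept = y.mean() - slope * x.mean()
    resid = y - (intercept + slope * x)
    sse = np.sum(resid**2)
    sst = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 - sse / sst if sst > 0 else 1.0
    if n > 2 and sse > 0:
        se = np.sqrt(sse / (n - 2) / sxx)
        t = slope / se
        p = 2 * stats.t.sf(abs(t), n - 2)
    elif n > 2:
        p = 0.0
    else:
        p = np.nan
    return slope, intercept, r2, p


def count_disk_pixels(size: int, center: tuple[float, float], radius: float) -> int:
    """Exhaustive count of pixel centres within ``radius`` of ``center``."""
    n = 0
    for r in range(size):
        for c in range(size):
            if ((r - center[0]) ** 2 + (c - center[1]) ** 2) ** 0.5 <= radius:
                n += 1
    return n
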