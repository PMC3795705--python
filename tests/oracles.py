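"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written as plain per-pixel / per-labeling
loops, independent of the vectorized implementations it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

from discdiff.segmentation import (SCB_GAP_PX, SCB_THICKNESS_PX, LandmarkSet,
                                   ROI_LABELS)


def classify_pixel(lms: LandmarkSet, row: int, col: int) -> str | None:
    """Label of one pixel by direct evaluation of the layering rules.

    Interpolates each border polyline at the pixel's column, computes the
    normalized depth u of the pixel center, and applies the band rules
    (ties on interior edges go to the band nearer the disc center) and
    the SCB gap/thickness offsets.  Returns None outside every ROI.
    """
    c_lo = max(lms.upper[0, 1], lms.lower[0, 1])
    c_hi = min(lms.upper[2, 1], lms.lower[2, 1])
    if col < c_lo or col > c_hi:
        return None

    def border(points):
        (ra, ca), (rb, cb), (rc, cc) = points
        if col <= cb:
            f = (col - ca) / (cb - ca)
            return ra + f * (rb - ra)
        f = (col - cb) / (cc - cb)
        return rb + f * (rc - rb)

    up = border(lms.upper)
    lo = border(lms.lower)
    if up - SCB_GAP_PX - SCB_THICKNESS_PX <= row < up - SCB_GAP_PX:
        return "SCB_upper"
    if lo + SCB_GAP_PX < row <= lo + SCB_GAP_PX + SCB_THICKNESS_PX:
        return "SCB_lower"
    if not (up <= row <= lo):
        return None
    u = (row - up) / (lo - up)
    edges = [0.2, 0.4, 0.6, 0.8]
    names = ["EPZ_upper", "Peripheral_upper", "Central",
             "Peripheral_lower", "EPZ_lower"]
    for k, e in enumerate(edges):
        if u < e:
            return names[k]
        if u == e:
            # tie: band closer to the disc center
            return names[k + 1] if e < 0.5 else names[k]
    return names[4]


def brute_force_masks(lms: LandmarkSet, shape):
    """Full per-pixel classification into the seven ROI masks."""
    masks = {k: np.zeros(shape, dtype=bool) for k in ROI_LABELS}
    for r in range(shape[0]):
        for c in range(shape[1]):
            label = classify_pixel(lms, r, c)
            if label is not None:
                masks[label][r, c] = True
    return masks


def slab_series(x, t, h, D, c0, n_terms=80):
    """Analytic Fourier-series solution of the Dirichlet slab problem.

    c(x, t) for dc/dt = D d2c/dx2 on [0, h], c(x, 0) = 0, both boundaries
    held at c0.
    """
    x = np.asarray(x, dtype=float)
    acc = np.zeros_like(x)
    for n in range(n_terms):
        k = 2 * n + 1
        acc += (4.0 / (k * math.pi)) * np.sin(k * math.pi * x / h) * \
            math.exp(-D * (k * math.pi / h) ** 2 * t)
    return c0 * (1.0 - acc)


def exact_ranksum_p(x, y):
    """Two-sided exact rank-sum p by full enumeration over labelings."""
    x = list(map(float, x))
    y = list(map(float, y))
    pooled = x + y
    order = sorted(range(len(pooled)), key=lambda i: pooled[i])
    ranks = [0.0] * len(pooled)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and pooled[order[j + 1]] == pooled[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    n = len(x)
    t_obs = sum(ranks[:n])
    expect = n * (len(pooled) + 1) / 2.0
    dev = abs(t_obs - expect)
    count = total = 0
    for comb in itertools.combinations(range(len(pooled)), n):
        t = sum(ranks[i] for i in comb)
        total += 1
        if abs(t - expect) >= dev - 1e-9:
            count += 1
    return count / total


def partial_f_tests(y, columns, names):
    """Type-III-style F per variable via nested least squares.

    ``columns`` maps each variable name to its design column(s); the full
    model stacks all of them plus an intercept.  F_j compares the full
    model with the model dropping variable j's columns.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    blocks = [np.atleast_2d(np.asarray(columns[k], dtype=float).T).T
              for k in names]
    intercept = np.ones((n, 1))
    full = np.hstack([intercept] + blocks)
    rss_full = np.sum((y - full @ np.linalg.lstsq(full, y, rcond=None)[0]) ** 2)
    p_full = full.shape[1]
    out = {}
    for j, name in enumerate(names):
        reduced = np.hstack([intercept] + [b for i, b in enumerate(blocks)
                                           if i != j])
        rss_red = np.sum((y - reduced @ np.linalg.lstsq(
            reduced, y, rcond=None)[0]) ** 2)
        q = blocks[j].shape[1]
        f = ((rss_red - rss_full) / q) / (rss_full / (n - p_full))
        out[name] = f
    return out
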