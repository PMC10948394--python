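"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the vectorised code paths of the package: naive
per-pixel loops, explicit flood fill, and a from-scratch convex hull, so
that agreement is evidence rather than tautology.
"""

import math

import numpy as np


def naive_phansalkar(pixels, radius, k=0.25, r=0.5, p=2.0, q=10.0, max_value=None):
    """Per-pixel Phansalkar mask via explicit window loops."""
    arr = np.asarray(pixels, dtype=float)
    if max_value:
        arr = arr / max_value
    padded = np.pad(arr, radius, mode="edge")
    h, w = arr.shape
    mask = np.zeros((h, w), dtype=bool)
    for i in range(h):
        for j in range(w):
            win = padded[i:i + 2 * radius + 1, j:j + 2 * radius + 1]
            m = win.mean()
            s = win.std()  # population SD over the window
            t = m * (1 + p * math.exp(-q * m) + k * (s / r - 1))
            mask[i, j] = arr[i, j] > t
    return mask


def naive_intermodes(hist, centers, max_iters=10_000):
    """Exhaustive histogram re-smoothing with a mode count at every step.

    Returns (threshold, iterations) or raises ValueError when bimodality
    is never reached.
    """
    h = [float(x) for x in hist]

    def peaks(vals):
        out = []
        for i, v in enumerate(vals):
            left = vals[i - 1] if i > 0 else -math.inf
            right = vals[i + 1] if i < len(vals) - 1 else -math.inf
            if v > left and v > right:
                out.append(i)
        return out

    for it in range(max_iters + 1):
        p = peaks(h)
        if len(p) == 2:
            return (centers[p[0]] + centers[p[1]]) / 2.0, it
        if len(p) < 2:
            raise ValueError(f"unimodal after {it} iterations")
        h = [(h[max(i - 1, 0)] + h[i] + h[min(i + 1, len(h) - 1)]) / 3.0
             for i in range(len(h))]
    raise ValueError("iteration budget exhausted")


def flood_fill_count(mask, connectivity=8):
    """Connected components by explicit BFS; returns list of pixel sets."""
    mask = np.asarray(mask, dtype=bool)
    if connectivity == 8:
        steps = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    seen = np.zeros_like(mask)
    comps = []
    h, w = mask.shape
    for si in range(h):
        for sj in range(w):
            if mask[si, sj] and not seen[si, sj]:
                stack = [(si, sj)]
                seen[si, sj] = True
                comp = set()
                while stack:
                    i, j = stack.pop()
                    comp.add((i, j))
                    for di, dj in steps:
                        ni, nj = i + di, j + dj
                        if 0 <= ni < h and 0 <= nj < w and mask[ni, nj] \
                                and not seen[ni, nj]:
                            seen[ni, nj] = True
                            stack.append((ni, nj))
                comps.append(frozenset(comp))
    return comps


def brute_hull_area(points):
    """Convex hull area by Andrew's monotone chain + the shoelace formula."""
    pts = sorted({(float(x), float(y)) for x, y in points})
    if len(pts) < 3:
        return 0.0

    def cross(o, a, b):
        return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])

    lower = []
    for pt in pts:
        while len(lower) >= 2 and cross(lower[-2], lower[-1], pt) <= 0:
            lower.pop()
        lower.append(pt)
    upper = []
    for pt in reversed(pts):
        while len(upper) >= 2 and cross(upper[-2], upper[-1], pt) <= 0:
            upper.pop()
        upper.append(pt)
    hull = lower[:-1] + upper[:-1]
    area = 0.0
    for i in range(len(hull)):
        x1, y1 = hull[i]
        x2, y2 = hull[(i + 1) % len(hull)]
        area += x1 * y2 - x2 * y1
    return abs(area) / 2.0


def pixel_corner_hull_area(coords):
    """Brute hull area of a pixel set expanded to its unit-square corners."""
    corners = []
    for r, c in coords:
        for dr in (-0.5, 0.5):
            for dc in (-0.5, 0.5):
                corners.append((r + dr, c + dc))
    return brute_hull_area(corners)
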