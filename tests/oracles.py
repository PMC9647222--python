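"""Independent brute-force reference implementations.

Everything here is written with plain Python loops directly from the
defining formulas, deliberately sharing no code with the package, so it
can serve as an oracle for the vectorised implementations.
"""

from __future__ import annotations

import math

import numpy as np

DIRS_2D = [(0, 1), (1, 0), (1, 1), (1, -1)]  # (dy, dx) within a slice


def brute_glcm_slice_dir(levels, mask, ng, distance=1):
    """Symmetric normalised GLCM per (slice, direction) by voxel loops."""
    nz, ny, nx = levels.shape
    mats = []
    for dy, dx in DIRS_2D:
        for z in range(nz):
            m = [[0.0] * ng for _ in range(ng)]
            total = 0
            for y in range(ny):
                for x in range(nx):
                    if not mask[z, y, x]:
                        continue
                    y2, x2 = y + dy * distance, x + dx * distance
                    if 0 <= y2 < ny and 0 <= x2 < nx and mask[z, y2, x2]:
                        a, b = levels[z, y, x] - 1, levels[z, y2, x2] - 1
                        m[a][b] += 1.0
                        m[b][a] += 1.0
                        total += 2
            if total:
                mats.append(np.array(m) / total)
    return mats


def brute_imc1(P):
    """Information correlation 1 from its three-entropy definition."""
    ng = P.shape[0]
    px = [sum(P[i][j] for j in range(ng)) for i in range(ng)]
    py = [sum(P[i][j] for i in range(ng)) for j in range(ng)]

    def h(vals):
        return -sum(v * math.log2(v) for v in vals if v > 0)

    hx, hy = h(px), h(py)
    hxy = h([P[i][j] for i in range(ng) for j in range(ng)])
    hxy1 = -sum(
        P[i][j] * math.log2(px[i] * py[j])
        for i in range(ng)
        for j in range(ng)
        if P[i][j] > 0
    )
    hmax = max(hx, hy)
    if hmax == 0:
        return 0.0
    return (hxy - hxy1) / hmax


def brute_runs_slice_dir(levels, mask):
    """Maximal in-mask runs per (slice, direction): list of lists of
    (grey, length) tuples, matching the 2-D direction set."""
    nz, ny, nx = levels.shape
    out = []
    for dy, dx in DIRS_2D:
        for z in range(nz):
            runs = []
            for y in range(ny):
                for x in range(nx):
                    if not mask[z, y, x]:
                        continue
                    yp, xp = y - dy, x - dx
                    prev_same = (
                        0 <= yp < ny and 0 <= xp < nx and mask[z, yp, xp]
                        and levels[z, yp, xp] == levels[z, y, x]
                    )
                    if prev_same:
                        continue  # not a run start
                    length = 1
                    y2, x2 = y + dy, x + dx
                    while (
                        0 <= y2 < ny and 0 <= x2 < nx and mask[z, y2, x2]
                        and levels[z, y2, x2] == levels[z, y, x]
                    ):
                        length += 1
                        y2 += dy
                        x2 += dx
                    runs.append((int(levels[z, y, x]), length))
            if runs:
                out.append(runs)
    return out


def brute_glnun(runs):
    """Normalised grey-level non-uniformity from a run list."""
    ns = len(runs)
    per_grey = {}
    for g, _l in runs:
        per_grey[g] = per_grey.get(g, 0) + 1
    return sum(c * c for c in per_grey.values()) / (ns * ns)


def brute_quantile(values, q):
    """Linear-interpolation quantile between order statistics."""
    v = sorted(values)
    pos = q * (len(v) - 1)
    lo = int(math.floor(pos))
    hi = min(lo + 1, len(v) - 1)
    frac = pos - lo
    return v[lo] * (1 - frac) + v[hi] * frac


def brute_iqr(values):
    return brute_quantile(values, 0.75) - brute_quantile(values, 0.25)


def brute_discretize_fbn(values, ng):
    vmin, vmax = min(values), max(values)
    if vmax == vmin:
        return [1 for _ in values], [vmin - 0.5, vmin + 0.5]
    levels = [
        min(ng, 1 + math.floor(ng * (x - vmin) / (vmax - vmin))) for x in values
    ]
    edges = [vmin + (vmax - vmin) * k / ng for k in range(ng + 1)]
    return levels, edges


def brute_min_grad_intensity(values, ng):
    """Grey level of minimum histogram gradient, as the HU bin centre."""
    levels, edges = brute_discretize_fbn(values, ng)
    ng_eff = 1 if max(values) == min(values) else ng
    counts = [0] * ng_eff
    for lv in levels:
        counts[lv - 1] += 1
    if ng_eff == 1:
        gmin = 0
    else:
        grads = []
        for i in range(ng_eff):
            if i == 0:
                grads.append(counts[1] - counts[0])
            elif i == ng_eff - 1:
                grads.append(counts[-1] - counts[-2])
            else:
                grads.append((counts[i + 1] - counts[i - 1]) / 2.0)
        gmin = min(range(ng_eff), key=lambda i: grads[i])
    return (edges[gmin] + edges[gmin + 1]) / 2.0


def brute_ols_slope(points):
    fs = [p[0] for p in points]
    vs = [p[1] for p in points]
    fbar = sum(fs) / len(fs)
    vbar = sum(vs) / len(vs)
    num = sum((f - fbar) * (v - vbar) for f, v in points)
    den = sum((f - fbar) ** 2 for f in fs)
    return num / den


def brute_threshold_cost(probs, y, cost_ratio):
    """Minimum achievable cost over every possible threshold."""
    cands = sorted(set(probs))
    cands = (
        [cands[0] - 1.0]
        + [(a + b) / 2.0 for a, b in zip(cands, cands[1:])]
        + [cands[-1] + 1.0]
    )
    best = None
    for t in cands:
        fn = sum(1 for p, yy in zip(probs, y) if yy == 1 and p < t)
        fp = sum(1 for p, yy in zip(probs, y) if yy == 0 and p >= t)
        cost = cost_ratio * fn + fp
        if best is None or cost < best:
            best = cost
    return best


def random_masked_volume(rng, shape=(4, 8, 8)):
    """A random HU volume with a random (connected-ish, non-empty) mask."""
    vol = rng.normal(50.0, 30.0, size=shape)
    mask = rng.uniform(size=shape) < 0.7
    if not mask.any():
        mask[tuple(s // 2 for s in shape)] = True
    return vol, mask
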