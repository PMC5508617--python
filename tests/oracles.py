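"""Independent brute-force reference implementations used only by tests.

Everything here is written as plain per-pixel / per-cell loops, deliberately
sharing no code with the package's vectorized builders, so that agreement is
a meaningful check.
"""

from __future__ import annotations

import numpy as np

STEPS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


def glcm_bruteforce(levels: np.ndarray, d: int, theta: int, n_levels: int) -> np.ndarray:
    """Normalized symmetric co-occurrence matrix by explicit pair enumeration.

    ``levels`` uses 0 as the out-of-mask sentinel.
    """
    h, w = levels.shape
    dr, dc = STEPS[theta]
    m = np.zeros((n_levels, n_levels))
    for r in range(h):
        for c in range(w):
            a = levels[r, c]
            if a == 0:
                continue
            for sign in (1, -1):  # direction and its opposite
                rr, cc = r + sign * dr * d, c + sign * dc * d
                if 0 <= rr < h and 0 <= cc < w and levels[rr, cc] > 0:
                    m[a - 1, levels[rr, cc] - 1] += 1
    total = m.sum()
    return m / total if total else m


def glrlm_bruteforce(levels: np.ndarray, theta: int, n_levels: int) -> np.ndarray:
    """Run-length counts by walking every maximal run pixel by pixel."""
    h, w = levels.shape
    dr, dc = STEPS[theta]
    counts = np.zeros((n_levels, max(h, w)), dtype=int)
    for r in range(h):
        for c in range(w):
            v = levels[r, c]
            if v == 0:
                continue
            # run start: predecessor is out of bounds, masked, or different
            pr, pc = r - dr, c - dc
            if 0 <= pr < h and 0 <= pc < w and levels[pr, pc] == v:
                continue
            length = 1
            rr, cc = r + dr, c + dc
            while 0 <= rr < h and 0 <= cc < w and levels[rr, cc] == v:
                length += 1
                rr += dr
                cc += dc
            counts[v - 1, length - 1] += 1
    used = max(1, int(np.max(np.nonzero(counts.any(axis=0))[0])) + 1) if counts.any() else 1
    return counts[:, :used]


def iszm_bruteforce(levels: np.ndarray, n_levels: int, connectivity: int = 8) -> np.ndarray:
    """Zone counts by explicit stack-based flood fill."""
    h, w = levels.shape
    if connectivity == 8:
        nbrs = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    seen = np.zeros((h, w), dtype=bool)
    zones: list[tuple[int, int]] = []  # (level, size)
    for r in range(h):
        for c in range(w):
            if levels[r, c] == 0 or seen[r, c]:
                continue
            v = levels[r, c]
            stack = [(r, c)]
            seen[r, c] = True
            size = 0
            while stack:
                y, x = stack.pop()
                size += 1
                for dy, dx in nbrs:
                    yy, xx = y + dy, x + dx
                    if 0 <= yy < h and 0 <= xx < w and not seen[yy, xx] and levels[yy, xx] == v:
                        seen[yy, xx] = True
                        stack.append((yy, xx))
            zones.append((v, size))
    smax = max((s for _, s in zones), default=1)
    counts = np.zeros((n_levels, smax), dtype=int)
    for v, s in zones:
        counts[v - 1, s - 1] += 1
    return counts


def sobel_bruteforce(image: np.ndarray) -> np.ndarray:
    """3x3 Sobel magnitude with nearest-edge replication, by explicit loops."""
    h, w = image.shape
    kr = np.array([[-1, -2, -1], [0, 0, 0], [1, 2, 1]], dtype=float)  # d/drow
    kc = kr.T
    out = np.zeros((h, w))
    for r in range(h):
        for c in range(w):
            gr = gc = 0.0
            for i in (-1, 0, 1):
                for j in (-1, 0, 1):
                    rr = min(max(r + i, 0), h - 1)
                    cc = min(max(c + j, 0), w - 1)
                    gr += kr[i + 1, j + 1] * image[rr, cc]
                    gc += kc[i + 1, j + 1] * image[rr, cc]
            out[r, c] = np.hypot(gr, gc)
    return out


def quantize_bruteforce(values: np.ndarray, n: int) -> np.ndarray:
    """Eq-style floor min-max discretization of a flat value array to 1..n."""
    lo, hi = values.min(), values.max()
    return np.array([int(np.floor(n * (v - lo) / (hi - lo + 1.0))) + 1 for v in values])


def glgcm_bruteforce(
    levels: np.ndarray, gradient: np.ndarray, mask: np.ndarray, n_levels: int, g_levels: int
) -> np.ndarray:
    """Joint gray/gradient histogram, one count per in-mask pixel."""
    g_in = gradient[mask]
    glev = quantize_bruteforce(g_in, g_levels)
    gray = levels[mask]
    m = np.zeros((n_levels, g_levels))
    for a, g in zip(gray, glev):
        m[a - 1, g - 1] += 1
    return m / m.sum()


# ---------------------------------------------------------------------------
# direct-summation feature oracles
# ---------------------------------------------------------------------------

def glcm_features_bruteforce(p: np.ndarray) -> dict[str, float]:
    n = p.shape[0]
    mu_i = sum((i + 1) * p[i, j] for i in range(n) for j in range(n))
    mu_j = sum((j + 1) * p[i, j] for i in range(n) for j in range(n))
    var_i = sum(((i + 1) - mu_i) ** 2 * p[i, j] for i in range(n) for j in range(n))
    var_j = sum(((j + 1) - mu_j) ** 2 * p[i, j] for i in range(n) for j in range(n))
    out = {
        "Energy": sum(p[i, j] ** 2 for i in range(n) for j in range(n)),
        "Entropy": -sum(
            p[i, j] * np.log2(p[i, j]) for i in range(n) for j in range(n) if p[i, j] > 0
        ),
        "Contrast": sum((i - j) ** 2 * p[i, j] for i in range(n) for j in range(n)),
        "Homogeneity": sum(p[i, j] / (1 + abs(i - j)) for i in range(n) for j in range(n)),
        "InverseDifferenceMoment": sum(
            p[i, j] / (1 + (i - j) ** 2) for i in range(n) for j in range(n)
        ),
        "InverseVariance": sum(
            p[i, j] / (i - j) ** 2 for i in range(n) for j in range(n) if i != j
        ),
        "ClusterShade": sum(
            ((i + 1) + (j + 1) - mu_i - mu_j) ** 3 * p[i, j]
            for i in range(n)
            for j in range(n)
        ),
        "ClusterTendency": sum(
            ((i + 1) + (j + 1) - mu_i - mu_j) ** 2 * p[i, j]
            for i in range(n)
            for j in range(n)
        ),
    }
    if var_i > 0 and var_j > 0:
        out["Correlation"] = sum(
            ((i + 1) - mu_i) * ((j + 1) - mu_j) * p[i, j]
            for i in range(n)
            for j in range(n)
        ) / np.sqrt(var_i * var_j)
    else:
        out["Correlation"] = 0.0
    # sum variance over the distribution of i+j (levels 1-based)
    sum_avg = sum(((i + 1) + (j + 1)) * p[i, j] for i in range(n) for j in range(n))
    out["SumVariance"] = sum(
        ((i + 1) + (j + 1) - sum_avg) ** 2 * p[i, j] for i in range(n) for j in range(n)
    )
    return out


def glrlm_features_bruteforce(counts: np.ndarray, n_pixels: int) -> dict[str, float]:
    ni, nl = counts.shape
    s = counts.sum()
    f = {k: 0.0 for k in ("SRE", "LRE", "GLN", "RLN", "LGRE", "HGRE",
                          "SRLGE", "SRHGE", "LRLGE", "LRHGE")}
    for i in range(ni):
        for j in range(nl):
            c = counts[i, j]
            gi, rj = i + 1, j + 1
            f["SRE"] += c / rj**2
            f["LRE"] += c * rj**2
            f["LGRE"] += c / gi**2
            f["HGRE"] += c * gi**2
            f["SRLGE"] += c / (gi**2 * rj**2)
            f["SRHGE"] += c * gi**2 / rj**2
            f["LRLGE"] += c * rj**2 / gi**2
            f["LRHGE"] += c * gi**2 * rj**2
    for i in range(ni):
        f["GLN"] += counts[i, :].sum() ** 2
    for j in range(nl):
        f["RLN"] += counts[:, j].sum() ** 2
    out = {k: v / s for k, v in f.items()}
    out["RP"] = s / n_pixels
    return out


def iszm_features_bruteforce(counts: np.ndarray, n_pixels: int) -> dict[str, float]:
    ni, ns = counts.shape
    z = counts.sum()
    f = {k: 0.0 for k in (
        "SmallZoneEmphasis", "LargeZoneEmphasis", "LowIntensityEmphasis",
        "HighIntensityEmphasis", "LowIntensitySmallZoneEmphasis",
        "HighIntensitySmallZoneEmphasis", "LowIntensityLargeZoneEmphasis",
        "HighIntensityLargeZoneEmphasis")}
    for i in range(ni):
        for s_ in range(ns):
            c = counts[i, s_]
            gi, sz = i + 1, s_ + 1
            f["SmallZoneEmphasis"] += c / sz**2
            f["LargeZoneEmphasis"] += c * sz**2
            f["LowIntensityEmphasis"] += c / gi**2
            f["HighIntensityEmphasis"] += c * gi**2
            f["LowIntensitySmallZoneEmphasis"] += c / (gi**2 * sz**2)
            f["HighIntensitySmallZoneEmphasis"] += c * gi**2 / sz**2
            f["LowIntensityLargeZoneEmphasis"] += c * sz**2 / gi**2
            f["HighIntensityLargeZoneEmphasis"] += c * gi**2 * sz**2
    out = {k: v / z for k, v in f.items()}
    out["IntensityVariability"] = sum(counts[i, :].sum() ** 2 for i in range(ni)) / z
    out["SizeZoneVariability"] = sum(counts[:, s_].sum() ** 2 for s_ in range(ns)) / z
    out["ZonePercentage"] = z / n_pixels
    return out


def glgcm_features_bruteforce(p: np.ndarray) -> dict[str, float]:
    ni, ng = p.shape
    p_i = p.sum(axis=1)
    p_g = p.sum(axis=0)
    mu_i = sum((i + 1) * p_i[i] for i in range(ni))
    mu_g = sum((g + 1) * p_g[g] for g in range(ng))
    var_i = sum(((i + 1) - mu_i) ** 2 * p_i[i] for i in range(ni))
    var_g = sum(((g + 1) - mu_g) ** 2 * p_g[g] for g in range(ng))

    def ent(q):
        return -sum(x * np.log2(x) for x in q if x > 0)

    corr = 0.0
    if var_i > 0 and var_g > 0:
        corr = sum(
            ((i + 1) - mu_i) * ((g + 1) - mu_g) * p[i, g]
            for i in range(ni)
            for g in range(ng)
        ) / np.sqrt(var_i * var_g)
    return {
        "GLGCM_SmallGradientEmphasis": sum(
            p[i, g] / (g + 1) ** 2 for i in range(ni) for g in range(ng)
        ),
        "GLGCM_LargeGradientEmphasis": sum(
            p[i, g] * (g + 1) ** 2 for i in range(ni) for g in range(ng)
        ),
        "GLGCM_GrayInhomogeneity": sum(x**2 for x in p_i),
        "GLGCM_GradientInhomogeneity": sum(x**2 for x in p_g),
        "GLGCM_GradientEnergy": sum(p[i, g] ** 2 for i in range(ni) for g in range(ng)),
        "GLGCM_MeanGray": mu_i,
        "GLGCM_MeanGradient": mu_g,
        "GLGCM_GrayVariance": var_i,
        "GLGCM_GradientVariance": var_g,
        "GLGCM_GradientCorrelation": corr,
        "GLGCM_GrayEntropy": ent(p_i),
        "GLGCM_GradientEntropy": ent(p_g),
        "GLGCM_MixtureEntropy": ent(p.ravel()),
        "GLGCM_GradientDifferenceMoment": sum(
            ((i + 1) - (g + 1)) ** 2 * p[i, g] for i in range(ni) for g in range(ng)
        ),
        "GLGCM_GradientInverseDifferenceMoment": sum(
            p[i, g] / (1 + ((i + 1) - (g + 1)) ** 2) for i in range(ni) for g in range(ng)
        ),
    }


def random_masked_roi(rng: np.random.Generator, size: int, n_levels: int):
    """A random quantized ROI with a random connected mask, for oracle tests.

    Returns (levels, mask) where levels uses the 0 sentinel outside the mask.
    Mask is grown from a seed pixel so it is always 8-connected.
    """
    mask = np.zeros((size, size), dtype=bool)
    r, c = size // 2, size // 2
    mask[r, c] = True
    frontier = [(r, c)]
    target = rng.integers(max(16, size), size * size // 2 + 16)
    while mask.sum() < target and frontier:
        idx = int(rng.integers(len(frontier)))
        y, x = frontier.pop(idx)
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                yy, xx = y + dy, x + dx
                if 0 <= yy < size and 0 <= xx < size and not mask[yy, xx]:
                    if rng.random() < 0.8:
                        mask[yy, xx] = True
                        frontier.append((yy, xx))
    levels = np.zeros((size, size), dtype=np.int64)
    levels[mask] = rng.integers(1, n_levels + 1, size=int(mask.sum()))
    return levels, mask
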