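"""Texture-matrix construction restricted to the masked ROI.

Four matrices summarize the spatial arrangement of discretized gray levels:

* GLCM  — gray-level co-occurrence: normalized counts of ordered gray-level
  pairs at a fixed pixel offset (distance d, direction theta), symmetrized
  so that each of the four canonical directions also covers its opposite.
* GLGCM — gray-gradient co-occurrence: joint histogram of a pixel's gray
  level and its quantized Sobel gradient magnitude.
* GLRLM — run lengths: counts of maximal same-level pixel runs by level and
  length along one of the four directions; runs never span out-of-mask
  pixels.
* ISZM  — intensity-size-zone: counts of connected iso-level zones by level
  and zone size.

Direction convention: angles are measured with 0 deg = +column axis and
90 deg = image "up" (-row); diagonal steps are unit Chebyshev steps, so
distance d at 45 deg means the pixel offset (-d, +d) in (row, col).
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage

from .io import QuantizedRoi, RoiImage, ValidationError
from .preprocessing import quantize as _quantize_levels  # noqa: F401  (re-export convenience)

__all__ = [
    "Glcm",
    "Glgcm",
    "Glrlm",
    "Iszm",
    "DIRECTIONS",
    "DISTANCES",
    "DIRECTION_STEPS",
    "build_glcm",
    "build_glgcm",
    "build_glrlm",
    "build_iszm",
]

DIRECTIONS = (0, 45, 90, 135)
DISTANCES = (1, 2, 4, 8)

#: unit step (drow, dcol) for each direction angle.
DIRECTION_STEPS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}

DEFAULT_GRADIENT_LEVELS = 16


@dataclasses.dataclass
class Glcm:
    matrix: np.ndarray  # (range, range), sums to 1 when pair_count > 0
    distance: int
    direction: int
    pair_count: int


@dataclasses.dataclass
class Glgcm:
    matrix: np.ndarray  # (range, G), sums to 1
    gradient_levels: int


@dataclasses.dataclass
class Glrlm:
    matrix: np.ndarray  # (range, Lmax) integer run counts
    direction: int
    n_pixels: int

    @property
    def n_runs(self) -> int:
        return int(self.matrix.sum())


@dataclasses.dataclass
class Iszm:
    matrix: np.ndarray  # (range, Smax) integer zone counts
    n_pixels: int

    @property
    def n_zones(self) -> int:
        return int(self.matrix.sum())


def _bbox(mask: np.ndarray) -> tuple[slice, slice]:
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    return slice(rows[0], rows[-1] + 1), slice(cols[0], cols[-1] + 1)


def build_glcm(q: QuantizedRoi, distance: int = 1, direction: int = 0) -> Glcm:
    """Symmetric normalized co-occurrence matrix at one (distance, direction).

    Ordered in-mask pixel pairs ``(x, x + d*u(theta))`` are counted and the
    transpose added, which is equivalent to also scanning the opposite
    direction.  A ROI with no valid pair at this offset yields the flagged
    zero matrix (``pair_count == 0``); feature code substitutes documented
    degenerate values.
    """
    if distance not in DISTANCES:
        raise ValidationError(f"distance must be in {DISTANCES}, got {distance}")
    if direction not in DIRECTIONS:
        raise ValidationError(f"direction must be in {DIRECTIONS}, got {direction}")
    sl = _bbox(q.mask)
    lv = q.levels[sl]
    r = q.range
    dr, dc = DIRECTION_STEPS[direction]
    dr *= distance
    dc *= distance
    h, w = lv.shape
    if abs(dr) >= h or abs(dc) >= w:  # offset larger than the ROI box
        return Glcm(matrix=np.zeros((r, r)), distance=distance,
                    direction=direction, pair_count=0)
    # source block and offset block such that src[i,j] pairs with dst[i,j]
    rs = slice(max(0, -dr), min(h, h - dr))
    cs = slice(max(0, -dc), min(w, w - dc))
    rd = slice(max(0, dr), min(h, h + dr))
    cd = slice(max(0, dc), min(w, w + dc))
    a = lv[rs, cs].ravel()
    b = lv[rd, cd].ravel()
    keep = (a > 0) & (b > 0)
    a = a[keep]
    b = b[keep]
    counts = np.bincount((a - 1) * r + (b - 1), minlength=r * r).reshape(r, r)
    sym = counts + counts.T
    total = int(sym.sum())
    matrix = sym / total if total else sym.astype(float)
    return Glcm(matrix=matrix, distance=distance, direction=direction, pair_count=total)


def sobel_gradient_magnitude(pixels: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """3x3 Sobel gradient magnitude with out-of-mask neighbors replicated
    from the nearest in-mask pixel (so the mask boundary contributes no
    artificial edge)."""
    filled = pixels.astype(float).copy()
    if not mask.all():
        idx = ndimage.distance_transform_edt(
            ~mask, return_distances=False, return_indices=True
        )
        filled = filled[tuple(idx)]
    gr = ndimage.sobel(filled, axis=0, mode="nearest")
    gc = ndimage.sobel(filled, axis=1, mode="nearest")
    return np.hypot(gr, gc)


def build_glgcm(
    q: QuantizedRoi,
    source: RoiImage,
    gradient_levels: int = DEFAULT_GRADIENT_LEVELS,
) -> Glgcm:
    """Joint gray-level / gradient-level histogram over in-mask pixels.

    The gradient magnitude is computed on the (denoised) source intensities
    and discretized to 1..G by the same floor min-max rule used for gray
    levels; each in-mask pixel contributes exactly one count.
    """
    if not np.array_equal(q.mask, source.mask):
        raise ValidationError("quantized ROI and source image have different masks")
    sl = _bbox(q.mask)
    mask = q.mask[sl]
    grad = sobel_gradient_magnitude(source.pixels[sl], mask)
    g_in = grad[mask]
    lo, hi = g_in.min(), g_in.max()
    glev = np.floor(gradient_levels * (g_in - lo) / (hi - lo + 1.0)).astype(np.int64) + 1
    gray = q.levels[sl][mask]
    counts = np.bincount(
        (gray - 1) * gradient_levels + (glev - 1),
        minlength=q.range * gradient_levels,
    ).reshape(q.range, gradient_levels)
    matrix = counts / counts.sum()
    return Glgcm(matrix=matrix, gradient_levels=gradient_levels)


def build_glrlm(q: QuantizedRoi, direction: int = 0) -> Glrlm:
    """Run-length matrix along one direction, runs truncated at mask edges."""
    if direction not in DIRECTIONS:
        raise ValidationError(f"direction must be in {DIRECTIONS}, got {direction}")
    sl = _bbox(q.mask)
    lv = q.levels[sl]
    h, w = lv.shape
    if direction == 0:
        lines = [lv[i, :] for i in range(h)]
    elif direction == 90:
        lines = [lv[:, j] for j in range(w)]
    elif direction == 45:
        # step (-1, +1) keeps row+col constant: anti-diagonals
        flipped = lv[::-1, :]
        lines = [np.diagonal(flipped, offset=k) for k in range(-(h - 1), w)]
    else:  # 135: step (-1, -1) keeps row-col constant: main diagonals
        lines = [np.diagonal(lv, offset=k) for k in range(-(h - 1), w)]

    n_pixels = int((lv > 0).sum())
    max_len = max(h, w)
    counts = np.zeros((q.range, max_len), dtype=np.int64)
    longest = 1
    for line in lines:
        prev = 0
        run = 0
        for v in line:
            if v == prev and v > 0:
                run += 1
            else:
                if prev > 0:
                    counts[prev - 1, run - 1] += 1
                    longest = max(longest, run)
                prev = int(v)
                run = 1
        if prev > 0:
            counts[prev - 1, run - 1] += 1
            longest = max(longest, run)
    return Glrlm(matrix=counts[:, :longest], direction=direction, n_pixels=n_pixels)


def build_iszm(q: QuantizedRoi, connectivity: int = 8) -> Iszm:
    """Intensity-size-zone matrix: connected iso-level zones by level & size."""
    if connectivity not in (4, 8):
        raise ValidationError(f"connectivity must be 4 or 8, got {connectivity}")
    structure = np.ones((3, 3), dtype=bool) if connectivity == 8 else None
    sl = _bbox(q.mask)
    lv = q.levels[sl]
    n_pixels = int((lv > 0).sum())
    per_level: list[np.ndarray] = []
    smax = 1
    for level in range(1, q.range + 1):
        labelled, n = ndimage.label(lv == level, structure=structure)
        if n:
            sizes = np.bincount(labelled.ravel())[1:]
            smax = max(smax, int(sizes.max()))
        else:
            sizes = np.zeros(0, dtype=np.int64)
        per_level.append(sizes)
    counts = np.zeros((q.range, smax), dtype=np.int64)
    for i, sizes in enumerate(per_level):
        for s in sizes:
            counts[i, int(s) - 1] += 1
    return Iszm(matrix=counts, n_pixels=n_pixels)
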