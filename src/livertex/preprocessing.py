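"""Noise filtering and gray-level discretization.

Two preprocessing steps precede all matrix-based texture features:

1. adaptive Wiener denoising of the full slice, and
2. min-max resampling of in-mask intensities to a small number of discrete
   gray levels (the *fixed bin number* convention),

   ``p(x) = floor( Range * (I(x) - min) / (max - min + 1) )``

   with min/max taken over the ROI pixel set only.  Stored levels are
   ``p(x) + 1`` so they span 1..Range; level 0 is reserved as the
   out-of-mask sentinel (run-length / size-zone low-gray-level emphases
   divide by the squared gray level, so a 0 level would be undefined).
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import uniform_filter

from .io import QuantizedRoi, RoiImage, ValidationError

__all__ = ["wiener_denoise", "quantize", "ALLOWED_RANGES", "DEFAULT_RANGE"]

ALLOWED_RANGES = (16, 32, 64, 128)
DEFAULT_RANGE = 32


def wiener_denoise(image: RoiImage, window: int = 3) -> RoiImage:
    """Adaptive (local mean / local variance) Wiener filter of the whole slice.

    The noise power is estimated as the mean of the local variances over
    ``window x window`` neighborhoods, the standard adaptive-Wiener
    convention.  Local statistics use reflected boundaries, so a constant
    image is a fixed point of the filter.  The mask is unchanged.
    """
    if window % 2 == 0 or window < 3:
        raise ValidationError(f"Wiener window must be odd and >= 3, got {window}")
    img = image.pixels.astype(float)
    lmean = uniform_filter(img, window)
    lvar = uniform_filter(img * img, window) - lmean * lmean
    lvar = np.maximum(lvar, 0.0)  # guard tiny negative round-off
    noise = lvar.mean()
    gain = np.where(lvar > noise, (lvar - noise) / np.where(lvar > 0, lvar, 1.0), 0.0)
    filtered = lmean + gain * (img - lmean)
    return RoiImage(
        filtered,
        image.mask,
        subject_id=image.subject_id,
        label=image.label,
        replicate=image.replicate,
    )


def quantize(image: RoiImage, range: int = DEFAULT_RANGE) -> QuantizedRoi:
    """Discretize in-mask intensities to integer gray levels 1..``range``.

    Min and max are taken over in-mask pixels only; a constant ROI maps to
    level 1 everywhere.  The mapping is monotone in intensity and invariant
    under affine intensity rescaling up to floor-boundary ties.
    """
    if range not in ALLOWED_RANGES:
        raise ValidationError(f"range must be one of {ALLOWED_RANGES}, got {range}")
    mask = image.mask
    if not mask.any():
        raise ValidationError(f"subject {image.subject_id!r}: empty mask")
    vals = image.pixels[mask]
    lo = vals.min()
    hi = vals.max()
    levels = np.zeros(image.pixels.shape, dtype=np.int64)
    p = np.floor(range * (image.pixels[mask] - lo) / (hi - lo + 1.0)).astype(np.int64)
    levels[mask] = p + 1
    return QuantizedRoi(levels=levels, mask=mask, range=range, source=image)
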