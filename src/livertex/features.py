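"""The 233-feature texture signature of a masked lesion ROI.

Family breakdown (see docs/formulas.md for every formula):

=======  ====================================================  =====
family   construction                                          count
=======  ====================================================  =====
IHF      histogram variance / skewness / kurtosis                  3
GLCM     10 Haralick statistics x {mean, variance over the 4
         directions} x 4 distances (1, 2, 4, 8)                   80
GLGCM    15 gray-gradient co-occurrence statistics                15
GLRLM    11 run-length statistics x 4 directions                  44
GWTF     Gabor mean square energy + mean amplitude, 5 x 8         80
ISZM     11 size-zone statistics                                  11
=======  ====================================================  =====

IHF + GLCM + GLGCM + GLRLM (142 features) describe local gray-level
variation; GWTF describes frequency-domain structure; ISZM describes
regional homogeneous-zone structure.

Degenerate ROIs (e.g. constant intensity) yield documented limit values
(Energy 1, entropies 0, Contrast 0, Correlation 0, Homogeneity 1,
variances 0) rather than errors, so cohort feature tables stay complete.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np

from . import gabor as _gabor
from .io import FeatureVector, QuantizedRoi, RoiImage, ValidationError
from .matrices import (
    DIRECTIONS,
    DISTANCES,
    Glcm,
    Glgcm,
    Glrlm,
    Iszm,
    build_glcm,
    build_glgcm,
    build_glrlm,
    build_iszm,
)
from .preprocessing import DEFAULT_RANGE, quantize, wiener_denoise

logger = logging.getLogger(__name__)

__all__ = [
    "ExtractionConfig",
    "ihf_features",
    "glcm_matrix_features",
    "glcm_features",
    "glgcm_features",
    "glrlm_features",
    "iszm_features",
    "extract_all",
    "feature_names",
    "FAMILY_COUNTS",
    "LOCAL_FAMILIES",
]

GLCM_BASES = (
    "Energy",
    "Entropy",
    "Contrast",
    "Correlation",
    "Homogeneity",
    "SumVariance",
    "ClusterShade",
    "ClusterTendency",
    "InverseDifferenceMoment",
    "InverseVariance",
)
GLGCM_BASES = (
    "SmallGradientEmphasis",
    "LargeGradientEmphasis",
    "GrayInhomogeneity",
    "GradientInhomogeneity",
    "GradientEnergy",
    "MeanGray",
    "MeanGradient",
    "GrayVariance",
    "GradientVariance",
    "GradientCorrelation",
    "GrayEntropy",
    "GradientEntropy",
    "MixtureEntropy",
    "GradientDifferenceMoment",
    "GradientInverseDifferenceMoment",
)
GLRLM_BASES = (
    "SRE",
    "LRE",
    "GLN",
    "RLN",
    "LGRE",
    "HGRE",
    "SRLGE",
    "SRHGE",
    "LRLGE",
    "LRHGE",
    "RP",
)
ISZM_BASES = (
    "SmallZoneEmphasis",
    "LargeZoneEmphasis",
    "IntensityVariability",
    "SizeZoneVariability",
    "ZonePercentage",
    "LowIntensityEmphasis",
    "HighIntensityEmphasis",
    "LowIntensitySmallZoneEmphasis",
    "HighIntensitySmallZoneEmphasis",
    "LowIntensityLargeZoneEmphasis",
    "HighIntensityLargeZoneEmphasis",
)

FAMILY_COUNTS = {"IHF": 3, "GLCM": 80, "GLGCM": 15, "GLRLM": 44, "GWTF": 80, "ISZM": 11}
LOCAL_FAMILIES = ("IHF", "GLCM", "GLGCM", "GLRLM")


@dataclasses.dataclass
class ExtractionConfig:
    """Everything that parameterizes a feature extraction run."""

    quantization_range: int = DEFAULT_RANGE
    wiener_enabled: bool = True
    wiener_window: int = 3
    gradient_levels: int = 16
    iszm_connectivity: int = 8
    glcm_distances: tuple[int, ...] = DISTANCES
    gabor_f_low: float = _gabor.DEFAULT_F_LOW
    gabor_f_high: float = _gabor.DEFAULT_F_HIGH
    gabor_fill: str = "mean"


def feature_names(config: ExtractionConfig | None = None) -> list[str]:
    """The canonical ordered 233-entry feature-name list."""
    config = config or ExtractionConfig()
    names = ["IHF_Variance", "IHF_Skewness", "IHF_Kurtosis"]
    for d in config.glcm_distances:
        for base in GLCM_BASES:
            for stat in ("mean", "variance"):
                names.append(f"GLCM_{base}_{stat}_d{d}")
    names += [f"GLGCM_{base}" for base in GLGCM_BASES]
    for base in GLRLM_BASES:
        for theta in DIRECTIONS:
            names.append(f"GLRLM_{base}_{theta}deg")
    for kind in ("S", "A"):
        for v in range(_gabor.N_SCALES):
            for mu in range(_gabor.N_ORIENTATIONS):
                names.append(f"GWTF_{kind}_gabor-{v}{mu}")
    names += [f"ISZM_{base}" for base in ISZM_BASES]
    return names


_EXPECTED_TOTAL = sum(FAMILY_COUNTS.values())
assert _EXPECTED_TOTAL == 233, FAMILY_COUNTS
assert len(feature_names()) == 233


# ---------------------------------------------------------------------------
# intensity histogram features
# ---------------------------------------------------------------------------

def ihf_features(image: RoiImage) -> dict[str, float]:
    """Histogram variance (unbiased), skewness (m3/m2^1.5) and excess
    kurtosis (m4/m2^2 - 3) of in-mask intensities.

    These three are kept precisely because they do not move under a global
    intensity shift; a zero-variance ROI returns 0 for the shape statistics.
    """
    vals = image.roi_values()
    if vals.size < 3:
        raise ValidationError(f"subject {image.subject_id!r}: need >= 3 ROI pixels")
    var = float(np.var(vals, ddof=1))
    m2 = float(np.mean((vals - vals.mean()) ** 2))
    if m2 == 0.0:
        logger.warning("subject %r: constant ROI, skewness/kurtosis set to 0", image.subject_id)
        skew = kurt = 0.0
    else:
        m3 = float(np.mean((vals - vals.mean()) ** 3))
        m4 = float(np.mean((vals - vals.mean()) ** 4))
        skew = m3 / m2**1.5
        kurt = m4 / m2**2 - 3.0
    return {"IHF_Variance": var, "IHF_Skewness": skew, "IHF_Kurtosis": kurt}


# ---------------------------------------------------------------------------
# GLCM features
# ---------------------------------------------------------------------------

def glcm_matrix_features(glcm: Glcm) -> dict[str, float]:
    """The 10 per-direction Haralick statistics of one co-occurrence matrix."""
    p = glcm.matrix
    if glcm.pair_count == 0:
        # no valid pair at this offset: documented degenerate limits
        return {
            "Energy": 1.0,
            "Entropy": 0.0,
            "Contrast": 0.0,
            "Correlation": 0.0,
            "Homogeneity": 1.0,
            "SumVariance": 0.0,
            "ClusterShade": 0.0,
            "ClusterTendency": 0.0,
            "InverseDifferenceMoment": 1.0,
            "InverseVariance": 0.0,
        }
    n = p.shape[0]
    i = np.arange(1, n + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    mu_i = float((ii * p).sum())
    mu_j = float((jj * p).sum())
    var_i = float(((ii - mu_i) ** 2 * p).sum())
    var_j = float(((jj - mu_j) ** 2 * p).sum())
    nz = p > 0
    entropy = float(-(p[nz] * np.log2(p[nz])).sum())
    if var_i > 0 and var_j > 0:
        correlation = float(((ii - mu_i) * (jj - mu_j) * p).sum() / np.sqrt(var_i * var_j))
    else:
        correlation = 0.0
    # p_{x+y}: distribution of the level sum i+j over 2..2n
    k = ii + jj
    sums = np.bincount(k.ravel(), weights=p.ravel(), minlength=2 * n + 1)[2:]
    ks = np.arange(2, 2 * n + 1)
    sum_avg = float((ks * sums).sum())
    sum_var = float(((ks - sum_avg) ** 2 * sums).sum())
    off = ii != jj
    return {
        "Energy": float((p**2).sum()),
        "Entropy": entropy,
        "Contrast": float(((ii - jj) ** 2 * p).sum()),
        "Correlation": correlation,
        "Homogeneity": float((p / (1.0 + np.abs(ii - jj))).sum()),
        "SumVariance": sum_var,
        "ClusterShade": float(((ii + jj - mu_i - mu_j) ** 3 * p).sum()),
        "ClusterTendency": float(((ii + jj - mu_i - mu_j) ** 2 * p).sum()),
        "InverseDifferenceMoment": float((p / (1.0 + (ii - jj) ** 2)).sum()),
        "InverseVariance": float((p[off] / (ii - jj)[off] ** 2).sum()),
    }


def glcm_features(glcms: list[Glcm]) -> dict[str, float]:
    """Mean and (population) variance over the four directions at one distance."""
    if len(glcms) != len(DIRECTIONS):
        raise ValidationError(f"need one GLCM per direction {DIRECTIONS}")
    d = glcms[0].distance
    per_dir = [glcm_matrix_features(g) for g in glcms]
    out: dict[str, float] = {}
    for base in GLCM_BASES:
        vals = np.array([f[base] for f in per_dir])
        out[f"GLCM_{base}_mean_d{d}"] = float(vals.mean())
        out[f"GLCM_{base}_variance_d{d}"] = float(vals.var())
    return out


# ---------------------------------------------------------------------------
# GLGCM features
# ---------------------------------------------------------------------------

def glgcm_features(m: Glgcm) -> dict[str, float]:
    p = m.matrix
    ni, ng = p.shape
    i = np.arange(1, ni + 1)
    g = np.arange(1, ng + 1)
    ii, gg = np.meshgrid(i, g, indexing="ij")
    p_i = p.sum(axis=1)  # gray marginal
    p_g = p.sum(axis=0)  # gradient marginal
    mu_i = float((i * p_i).sum())
    mu_g = float((g * p_g).sum())
    var_i = float(((i - mu_i) ** 2 * p_i).sum())
    var_g = float(((g - mu_g) ** 2 * p_g).sum())
    if var_i > 0 and var_g > 0:
        corr = float(((ii - mu_i) * (gg - mu_g) * p).sum() / np.sqrt(var_i * var_g))
    else:
        corr = 0.0

    def _ent(q: np.ndarray) -> float:
        nz = q > 0
        return float(-(q[nz] * np.log2(q[nz])).sum())

    return {
        "GLGCM_SmallGradientEmphasis": float((p / gg**2).sum()),
        "GLGCM_LargeGradientEmphasis": float((p * gg**2).sum()),
        "GLGCM_GrayInhomogeneity": float((p_i**2).sum()),
        "GLGCM_GradientInhomogeneity": float((p_g**2).sum()),
        "GLGCM_GradientEnergy": float((p**2).sum()),
        "GLGCM_MeanGray": mu_i,
        "GLGCM_MeanGradient": mu_g,
        "GLGCM_GrayVariance": var_i,
        "GLGCM_GradientVariance": var_g,
        "GLGCM_GradientCorrelation": corr,
        "GLGCM_GrayEntropy": _ent(p_i),
        "GLGCM_GradientEntropy": _ent(p_g),
        "GLGCM_MixtureEntropy": _ent(p.ravel()),
        "GLGCM_GradientDifferenceMoment": float(((ii - gg) ** 2 * p).sum()),
        "GLGCM_GradientInverseDifferenceMoment": float((p / (1.0 + (ii - gg) ** 2)).sum()),
    }


# ---------------------------------------------------------------------------
# GLRLM features
# ---------------------------------------------------------------------------

def glrlm_features(m: Glrlm) -> dict[str, float]:
    """The 11 run-length statistics of one direction's matrix."""
    counts = m.matrix.astype(float)
    n_runs = counts.sum()
    theta = m.direction
    if n_runs == 0:
        return {f"GLRLM_{b}_{theta}deg": 0.0 for b in GLRLM_BASES}
    ni, nl = counts.shape
    i = np.arange(1, ni + 1)
    j = np.arange(1, nl + 1)
    ii, jj = np.meshgrid(i, j, indexing="ij")
    r_i = counts.sum(axis=1)
    r_j = counts.sum(axis=0)
    s = n_runs
    return {
        f"GLRLM_SRE_{theta}deg": float((counts / jj**2).sum() / s),
        f"GLRLM_LRE_{theta}deg": float((counts * jj**2).sum() / s),
        f"GLRLM_GLN_{theta}deg": float((r_i**2).sum() / s),
        f"GLRLM_RLN_{theta}deg": float((r_j**2).sum() / s),
        f"GLRLM_LGRE_{theta}deg": float((counts / ii**2).sum() / s),
        f"GLRLM_HGRE_{theta}deg": float((counts * ii**2).sum() / s),
        f"GLRLM_SRLGE_{theta}deg": float((counts / (ii**2 * jj**2)).sum() / s),
        f"GLRLM_SRHGE_{theta}deg": float((counts * ii**2 / jj**2).sum() / s),
        f"GLRLM_LRLGE_{theta}deg": float((counts * jj**2 / ii**2).sum() / s),
        f"GLRLM_LRHGE_{theta}deg": float((counts * ii**2 * jj**2).sum() / s),
        f"GLRLM_RP_{theta}deg": float(s / m.n_pixels),
    }


# ---------------------------------------------------------------------------
# ISZM features
# ---------------------------------------------------------------------------

def iszm_features(m: Iszm) -> dict[str, float]:
    """The 11 size-zone statistics (zone-count normalized)."""
    counts = m.matrix.astype(float)
    z = counts.sum()
    if z == 0:
        return {f"ISZM_{b}": 0.0 for b in ISZM_BASES}
    ni, ns = counts.shape
    i = np.arange(1, ni + 1)
    s = np.arange(1, ns + 1)
    ii, ss = np.meshgrid(i, s, indexing="ij")
    z_i = counts.sum(axis=1)
    z_s = counts.sum(axis=0)
    return {
        "ISZM_SmallZoneEmphasis": float((counts / ss**2).sum() / z),
        "ISZM_LargeZoneEmphasis": float((counts * ss**2).sum() / z),
        "ISZM_IntensityVariability": float((z_i**2).sum() / z),
        "ISZM_SizeZoneVariability": float((z_s**2).sum() / z),
        "ISZM_ZonePercentage": float(z / m.n_pixels),
        "ISZM_LowIntensityEmphasis": float((counts / ii**2).sum() / z),
        "ISZM_HighIntensityEmphasis": float((counts * ii**2).sum() / z),
        "ISZM_LowIntensitySmallZoneEmphasis": float((counts / (ii**2 * ss**2)).sum() / z),
        "ISZM_HighIntensitySmallZoneEmphasis": float((counts * ii**2 / ss**2).sum() / z),
        "ISZM_LowIntensityLargeZoneEmphasis": float((counts * ss**2 / ii**2).sum() / z),
        "ISZM_HighIntensityLargeZoneEmphasis": float((counts * ii**2 * ss**2).sum() / z),
    }


# ---------------------------------------------------------------------------
# full extraction
# ---------------------------------------------------------------------------

_BANK_CACHE: dict[tuple[float, float], _gabor.GaborBank] = {}


def _get_bank(config: ExtractionConfig) -> _gabor.GaborBank:
    key = (config.gabor_f_low, config.gabor_f_high)
    if key not in _BANK_CACHE:
        _BANK_CACHE[key] = _gabor.make_bank(f_low=key[0], f_high=key[1])
    return _BANK_CACHE[key]


def extract_all(image: RoiImage, config: ExtractionConfig | None = None) -> FeatureVector:
    """Run preprocessing, every matrix builder and every feature family on
    one ROI and return the canonical 233-entry feature vector."""
    config = config or ExtractionConfig()
    denoised = (
        wiener_denoise(image, config.wiener_window) if config.wiener_enabled else image
    )
    q = quantize(denoised, config.quantization_range)

    values: dict[str, float] = {}
    values.update(ihf_features(denoised))
    for d in config.glcm_distances:
        glcms = [build_glcm(q, d, theta) for theta in DIRECTIONS]
        values.update(glcm_features(glcms))
    values.update(glgcm_features(build_glgcm(q, denoised, config.gradient_levels)))
    per_dir_rl: dict[str, float] = {}
    for theta in DIRECTIONS:
        per_dir_rl.update(glrlm_features(build_glrlm(q, theta)))
    for base in GLRLM_BASES:  # canonical base-major ordering
        for theta in DIRECTIONS:
            key = f"GLRLM_{base}_{theta}deg"
            values[key] = per_dir_rl[key]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # kernel-crop warnings on tiny ROIs
        gset = _gabor.gabor_features(denoised, _get_bank(config), fill=config.gabor_fill)
    for kind, arr in (("S", gset.S), ("A", gset.A)):
        for v in range(arr.shape[0]):
            for mu in range(arr.shape[1]):
                values[f"GWTF_{kind}_gabor-{v}{mu}"] = float(arr[v, mu])
    values.update(iszm_features(build_iszm(q, config.iszm_connectivity)))

    expected = feature_names(config)
    if list(values) != expected:
        raise RuntimeError("feature extraction produced a non-canonical name order")
    return FeatureVector(values=values, subject_id=image.subject_id, label=image.label)
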