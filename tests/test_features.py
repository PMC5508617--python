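import numpy as np
import pytest

import oracles
from conftest import quantized_from_levels
from livertex.features import (
    FAMILY_COUNTS,
    GLCM_BASES,
    LOCAL_FAMILIES,
    ExtractionConfig,
    extract_all,
    feature_names,
    glcm_features,
    glcm_matrix_features,
    glgcm_features,
    glrlm_features,
    ihf_features,
    iszm_features,
)
from livertex.io import RoiImage
from livertex.matrices import DIRECTIONS, build_glcm, build_glgcm, build_glrlm, build_iszm
from livertex.preprocessing import quantize
from livertex.synthetic import PhantomSpec, generate_phantom


# ---------------------------------------------------------------------------
# name/count identities
# ---------------------------------------------------------------------------

def test_feature_name_counts():
    names = feature_names()
    assert len(names) == 233
    by_family = {}
    for n in names:
        by_family[n.split("_")[0]] = by_family.get(n.split("_")[0], 0) + 1
    assert by_family == FAMILY_COUNTS
    assert sum(by_family[f] for f in LOCAL_FAMILIES) == 142
    assert len(set(names)) == 233  # no duplicates


# ---------------------------------------------------------------------------
# IHF
# ---------------------------------------------------------------------------

def test_ihf_worked_values():
    # values {1,2,3,4} each repeated 4 times: mean 2.5, SS = 4*5 = 20,
    # unbiased variance = 20/15 = 4/3 (hand-derived)
    vals = np.array([[1.0, 2.0, 3.0, 4.0]] * 4)
    roi = RoiImage(vals, np.ones_like(vals, bool), subject_id="v")
    f = ihf_features(roi)
    assert f["IHF_Variance"] == pytest.approx(4 / 3)
    assert f["IHF_Skewness"] == pytest.approx(0.0, abs=1e-12)  # symmetric


def test_ihf_symmetric_distribution_zero_skew(rng):
    a = rng.uniform(0, 10, size=200)
    sym = np.concatenate([a, 20.0 - a]).reshape(20, 20)
    roi = RoiImage(sym, np.ones((20, 20), bool), subject_id="s")
    assert ihf_features(roi)["IHF_Skewness"] == pytest.approx(0.0, abs=1e-10)


def test_ihf_gaussian_excess_kurtosis_near_zero(rng):
    vals = rng.standard_normal((100, 100))
    roi = RoiImage(vals, np.ones((100, 100), bool), subject_id="g")
    assert abs(ihf_features(roi)["IHF_Kurtosis"]) < 0.15


def test_ihf_constant_roi_degenerate():
    roi = RoiImage(np.full((6, 6), 9.0), np.ones((6, 6), bool), subject_id="c")
    f = ihf_features(roi)
    assert f["IHF_Variance"] == 0.0
    assert f["IHF_Skewness"] == 0.0
    assert f["IHF_Kurtosis"] == 0.0


# ---------------------------------------------------------------------------
# GLCM features
# ---------------------------------------------------------------------------

def test_glcm_constant_roi_limits():
    q = quantized_from_levels(np.ones((6, 6), dtype=int), 4)
    for d in (1, 2, 4):
        feats = glcm_features([build_glcm(q, d, t) for t in DIRECTIONS])
        assert feats[f"GLCM_Energy_mean_d{d}"] == 1.0
        assert feats[f"GLCM_Entropy_mean_d{d}"] == 0.0
        assert feats[f"GLCM_Contrast_mean_d{d}"] == 0.0
        assert feats[f"GLCM_Homogeneity_mean_d{d}"] == 1.0
        assert feats[f"GLCM_Energy_variance_d{d}"] == 0.0


def test_glcm_alternating_stripe_hand_values():
    q = quantized_from_levels([[1, 2, 1, 2, 1, 2, 1, 2]], 2)
    g = build_glcm(q, 1, 0)
    f = glcm_matrix_features(g)
    assert f["Contrast"] == pytest.approx(1.0)
    assert f["Energy"] == pytest.approx(0.5)


def test_glcm_features_match_bruteforce(rng):
    for _ in range(10):
        levels, _ = oracles.random_masked_roi(rng, 10, 6)
        q = quantized_from_levels(levels, 6)
        for theta in DIRECTIONS:
            g = build_glcm(q, 1, theta)
            if g.pair_count == 0:
                continue
            got = glcm_matrix_features(g)
            want = oracles.glcm_features_bruteforce(g.matrix)
            for k in GLCM_BASES:
                assert got[k] == pytest.approx(want[k], rel=1e-10), k


def test_glcm_direction_aggregation_population_variance(rng):
    levels, _ = oracles.random_masked_roi(rng, 10, 4)
    q = quantized_from_levels(levels, 4)
    glcms = [build_glcm(q, 1, t) for t in DIRECTIONS]
    feats = glcm_features(glcms)
    per_dir = [glcm_matrix_features(g)["Contrast"] for g in glcms]
    assert feats["GLCM_Contrast_mean_d1"] == pytest.approx(np.mean(per_dir))
    assert feats["GLCM_Contrast_variance_d1"] == pytest.approx(np.var(per_dir))  # ddof=0


# ---------------------------------------------------------------------------
# GLGCM features
# ---------------------------------------------------------------------------

def test_glgcm_constant_image_limits():
    img = RoiImage(np.full((8, 8), 5.0), np.ones((8, 8), bool), subject_id="c")
    q = quantize(img, 16)
    f = glgcm_features(build_glgcm(q, img))
    assert f["GLGCM_GradientVariance"] == 0.0
    assert f["GLGCM_MixtureEntropy"] == 0.0


def test_glgcm_ramp_vs_shuffled_gradients(rng):
    """Shuffling a smooth ramp raises raw gradient magnitudes, and the
    ramp's gradient distribution is far more concentrated.

    Gradient levels are discretized per ROI (relative scale), so the
    cross-image comparison is made on raw Sobel magnitudes; within the
    GLGCM the ramp shows the higher gradient-marginal energy.
    """
    from livertex.matrices import sobel_gradient_magnitude

    wins_raw = wins_conc = 0
    for s in range(10):
        r = np.random.default_rng(s)
        ramp = np.tile(np.arange(16, dtype=float) * 10, (16, 1))
        shuffled = ramp.copy().ravel()
        r.shuffle(shuffled)
        shuffled = shuffled.reshape(16, 16)
        mask = np.ones((16, 16), bool)
        if sobel_gradient_magnitude(ramp, mask).mean() < sobel_gradient_magnitude(
            shuffled, mask
        ).mean():
            wins_raw += 1

        def feats(arr):
            img = RoiImage(arr, mask, subject_id="x")
            return glgcm_features(build_glgcm(quantize(img, 16), img))

        if (
            feats(ramp)["GLGCM_GradientInhomogeneity"]
            > feats(shuffled)["GLGCM_GradientInhomogeneity"]
        ):
            wins_conc += 1
    assert wins_raw == 10
    assert wins_conc >= 8


def test_glgcm_features_match_bruteforce(rng):
    for _ in range(8):
        arr = rng.uniform(0, 100, size=(10, 10))
        img = RoiImage(arr, np.ones((10, 10), bool), subject_id="g")
        q = quantize(img, 16)
        m = build_glgcm(q, img, gradient_levels=8)
        got = glgcm_features(m)
        want = oracles.glgcm_features_bruteforce(m.matrix)
        for k, v in want.items():
            assert got[k] == pytest.approx(v, rel=1e-10, abs=1e-12), k


# ---------------------------------------------------------------------------
# GLRLM features
# ---------------------------------------------------------------------------

def test_glrlm_all_length_one_runs():
    levels = np.arange(1, 26).reshape(5, 5)
    q = quantized_from_levels(levels, 25)
    for theta in DIRECTIONS:
        f = glrlm_features(build_glrlm(q, theta))
        assert f[f"GLRLM_SRE_{theta}deg"] == 1.0
        assert f[f"GLRLM_LRE_{theta}deg"] == 1.0
        assert f[f"GLRLM_RP_{theta}deg"] == 1.0


def test_glrlm_sre_worked_value():
    q = quantized_from_levels([[1, 1, 1, 2, 2]], 2)
    f = glrlm_features(build_glrlm(q, 0))
    assert f["GLRLM_SRE_0deg"] == pytest.approx(13 / 72)


def test_glrlm_features_match_bruteforce(rng):
    for _ in range(10):
        levels, mask = oracles.random_masked_roi(rng, 10, 4)
        q = quantized_from_levels(levels, 4)
        for theta in DIRECTIONS:
            m = build_glrlm(q, theta)
            got = glrlm_features(m)
            want = oracles.glrlm_features_bruteforce(m.matrix, int(mask.sum()))
            for k, v in want.items():
                assert got[f"GLRLM_{k}_{theta}deg"] == pytest.approx(v, rel=1e-10), k


# ---------------------------------------------------------------------------
# ISZM features
# ---------------------------------------------------------------------------

def test_iszm_single_zone_zone_percentage():
    for side in (3, 4, 5):
        q = quantized_from_levels(np.full((side, side), 2, dtype=int), 4)
        f = iszm_features(build_iszm(q))
        assert f["ISZM_ZonePercentage"] == pytest.approx(1.0 / side**2)


def test_iszm_constant_lowest_level_low_intensity_emphasis():
    q = quantized_from_levels(np.ones((4, 4), dtype=int), 8)
    f = iszm_features(build_iszm(q))
    assert f["ISZM_LowIntensityEmphasis"] == 1.0


def test_iszm_features_match_bruteforce(rng):
    for _ in range(10):
        levels, mask = oracles.random_masked_roi(rng, 10, 4)
        q = quantized_from_levels(levels, 4)
        m = build_iszm(q)
        got = iszm_features(m)
        want = oracles.iszm_features_bruteforce(m.matrix, int(mask.sum()))
        for k, v in want.items():
            assert got[f"ISZM_{k}"] == pytest.approx(v, rel=1e-10), k


# ---------------------------------------------------------------------------
# full extraction
# ---------------------------------------------------------------------------

def test_extract_all_233_finite_features(spec):
    roi = generate_phantom(spec, "classB", seed=5)
    fv = extract_all(roi)
    assert len(fv.values) == 233
    assert fv.names() == feature_names()
    assert np.all(np.isfinite(fv.as_array()))


def test_extract_all_constant_roi_completes():
    mask = np.zeros((64, 64), bool)
    mask[20:45, 20:45] = True
    roi = RoiImage(np.full((64, 64), 100.0), mask, subject_id="const")
    fv = extract_all(roi, ExtractionConfig(wiener_enabled=False))
    assert len(fv.values) == 233
    assert np.all(np.isfinite(fv.as_array()))
    assert fv.values["GLCM_Energy_mean_d1"] == 1.0


def test_extract_all_invariant_to_out_of_mask_pixels(spec):
    roi = generate_phantom(spec, "classA", seed=9)
    altered = RoiImage(
        np.where(roi.mask, roi.pixels, 12345.0), roi.mask, subject_id=roi.subject_id
    )
    cfg = ExtractionConfig(wiener_enabled=False)  # the filter itself spans the slice
    a = extract_all(roi, cfg).as_array()
    b = extract_all(altered, cfg).as_array()
    np.testing.assert_allclose(a, b, rtol=1e-12)


def test_discretization_sensitivity_regional_vs_local():
    """Between 16 and 128 gray levels, ISZM regional features shift more
    than the local-family features do (paired over 20 phantoms)."""
    from scipy.stats import wilcoxon

    spec = PhantomSpec(seed=21)
    local, regional = [], []
    iszm_sensitive = [
        "ISZM_LowIntensityLargeZoneEmphasis",
        "ISZM_LargeZoneEmphasis",
        "ISZM_LowIntensityEmphasis",
        "ISZM_LowIntensitySmallZoneEmphasis",
    ]
    local_feats = [
        n for n in feature_names()
        if n.startswith(("GLCM_", "GLRLM_")) and "variance" not in n
    ]
    for s in range(20):
        label = ["classA", "classB", "classC"][s % 3]
        roi = generate_phantom(spec, label, seed=3000 + s)
        f16 = extract_all(roi, ExtractionConfig(quantization_range=16)).values
        f128 = extract_all(roi, ExtractionConfig(quantization_range=128)).values

        def mard(names):
            diffs = []
            for n in names:
                denom = max(abs(f16[n]), abs(f128[n]), 1e-12)
                diffs.append(abs(f128[n] - f16[n]) / denom)
            return float(np.mean(diffs))

        local.append(mard(local_feats))
        regional.append(mard(iszm_sensitive))
    local = np.array(local)
    regional = np.array(regional)
    assert regional.mean() > local.mean()
    assert wilcoxon(regional - local, alternative="greater").pvalue < 0.05
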