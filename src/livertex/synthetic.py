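"""Synthetic lesion-phantom cohorts.

No liver-MRI cohort ships with the package, so every downstream stage is
exercised on phantoms: 256 x 256 axial-slice look-alikes containing one
elliptical lesion ROI on a darker background.  In-ROI texture is a sum of
interpretable ingredients, each of which a specific feature family must
detect:

* ``base_intensity``  — mean ROI signal;
* a smoothed Gaussian random field (``blur_sigma``, amplitude
  ``intensity_sd``) — local heterogeneity for GLCM/GLRLM;
* a Voronoi blob field — piecewise-constant zones with mean cell diameter
  ``blob_scale`` and i.i.d. per-cell offsets — regional structure for ISZM;
* an optional linear ramp (``gradient_slope``) — gradient structure for
  GLGCM;
* i.i.d. Gaussian pixel noise (``noise_sd``).

The default three classes emulate the study geometry (three texture-distinct
lesion types, cohort 55/67/40 split into 112 training / 50 validation
subjects, and 15 paired test-retest acquisitions).  A retest replicate
shares its subject's texture field and mask and differs only by fresh noise
of ``retest_noise_sd``.

Randomness: one root seed per cohort; per-subject sub-streams are derived
with ``numpy.random.SeedSequence.spawn`` so adding subjects never perturbs
earlier ones.  Pixels are rounded to integers, making generation
deterministic across platforms and PNG round-trips exact.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .io import Manifest, RoiImage, ValidationError

__all__ = [
    "ClassParams",
    "PhantomSpec",
    "SyntheticCohort",
    "generate_phantom",
    "generate_cohort",
    "generate_test_retest",
    "null_class_params",
    "write_cohort",
    "DEFAULT_COUNTS",
    "DEFAULT_SPLIT",
]

#: study cohort geometry: class counts and training/validation sizes
DEFAULT_COUNTS = {"classA": 55, "classB": 67, "classC": 40}
DEFAULT_SPLIT = (112, 50)
DEFAULT_N_RETEST = 15


@dataclasses.dataclass
class ClassParams:
    base_intensity: float
    intensity_sd: float
    blur_sigma: float
    blob_scale: float
    gradient_slope: float = 0.0


def _default_classes() -> dict[str, ClassParams]:
    # Three strongly texture-distinct classes: A nearly homogeneous and
    # bright (hemangioma-like), B moderately heterogeneous with mid-size
    # zones and a mild ramp, C coarse with large zones and a strong ramp.
    return {
        "classA": ClassParams(180.0, 8.0, 2.5, 0.0, 0.0),
        "classB": ClassParams(140.0, 25.0, 1.0, 4.0, 0.6),
        "classC": ClassParams(120.0, 40.0, 0.0, 10.0, 1.5),
    }


def null_class_params() -> dict[str, ClassParams]:
    """Three *identical* classes — the no-signal control condition."""
    p = ClassParams(150.0, 20.0, 1.0, 4.0, 0.5)
    return {"classA": dataclasses.replace(p), "classB": dataclasses.replace(p),
            "classC": dataclasses.replace(p)}


@dataclasses.dataclass
class PhantomSpec:
    image_size: tuple[int, int] = (256, 256)
    roi_radius_range: tuple[float, float] = (8.0, 30.0)
    class_params: dict[str, ClassParams] = dataclasses.field(default_factory=_default_classes)
    noise_sd: float = 5.0
    retest_noise_sd: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.class_params) != 3:
            raise ValidationError("exactly three lesion classes must be defined")
        for name, cp in self.class_params.items():
            if cp.intensity_sd < 0 or cp.blur_sigma < 0 or cp.blob_scale < 0:
                raise ValidationError(f"class {name!r}: sd/sigma/scale must be >= 0")
        if self.noise_sd < 0 or self.retest_noise_sd < 0:
            raise ValidationError("noise sd must be >= 0")

    @classmethod
    def from_json(cls, path: str | Path) -> "PhantomSpec":
        raw = json.loads(Path(path).read_text())
        if "class_params" in raw:
            raw["class_params"] = {
                k: ClassParams(**v) for k, v in raw["class_params"].items()
            }
        for key in ("image_size", "roi_radius_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclasses.dataclass
class SyntheticCohort:
    rois: list[RoiImage]
    cohorts: list[str]  # "training"/"validation" per roi
    spec: PhantomSpec

    def __len__(self) -> int:
        return len(self.rois)


def _ellipse_mask(shape: tuple[int, int], center, radii, angle: float) -> np.ndarray:
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    dr = rr - center[0]
    dc = cc - center[1]
    u = dc * np.cos(angle) + dr * np.sin(angle)
    v = -dc * np.sin(angle) + dr * np.cos(angle)
    return (u / radii[1]) ** 2 + (v / radii[0]) ** 2 <= 1.0


def _texture_field(
    shape: tuple[int, int], cp: ClassParams, rng: np.random.Generator
) -> np.ndarray:
    """Deterministic (given rng state) noiseless texture over a bounding box."""
    field = np.full(shape, cp.base_intensity, dtype=float)
    if cp.intensity_sd > 0:
        wn = rng.standard_normal(shape)
        if cp.blur_sigma > 0:
            wn = ndimage.gaussian_filter(wn, cp.blur_sigma)
        sd = wn.std()
        if sd > 0:
            field += cp.intensity_sd * wn / sd
    if cp.blob_scale > 0:
        area = shape[0] * shape[1]
        n_cells = max(2, int(round(area / cp.blob_scale**2)))
        centers = rng.uniform([0, 0], shape, size=(n_cells, 2))
        offsets = rng.normal(0.0, cp.intensity_sd, size=n_cells)
        rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
        pts = np.column_stack([rr.ravel(), cc.ravel()])
        _, cell = cKDTree(centers).query(pts)
        field += offsets[cell].reshape(shape)
    if cp.gradient_slope != 0.0:
        phi = rng.uniform(0, np.pi)
        rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
        ramp = (cc - shape[1] / 2) * np.cos(phi) + (rr - shape[0] / 2) * np.sin(phi)
        field += cp.gradient_slope * ramp
    return field


def _phantom_from_streams(
    spec: PhantomSpec,
    label: str,
    geom_rng: np.random.Generator,
    noise_rng: np.random.Generator,
    noise_sd: float,
    subject_id: str,
    replicate: str | None = None,
) -> RoiImage:
    """Render one phantom; geometry+texture and noise use separate streams
    so test/retest replicates can share the former."""
    if label not in spec.class_params:
        raise ValidationError(f"unknown class label {label!r}")
    cp = spec.class_params[label]
    h, w = spec.image_size
    rmin, rmax = spec.roi_radius_range
    margin = rmax + 2
    center = geom_rng.uniform([margin, margin], [h - margin, w - margin])
    radii = geom_rng.uniform(rmin, rmax, size=2)
    angle = geom_rng.uniform(0, np.pi)
    mask = _ellipse_mask((h, w), center, radii, angle)

    background = 0.5 * min(c.base_intensity for c in spec.class_params.values())
    image = np.full((h, w), background, dtype=float)

    r0, r1 = np.flatnonzero(mask.any(axis=1))[[0, -1]]
    c0, c1 = np.flatnonzero(mask.any(axis=0))[[0, -1]]
    box = (slice(r0, r1 + 1), slice(c0, c1 + 1))
    field = _texture_field((r1 - r0 + 1, c1 - c0 + 1), cp, geom_rng)
    sub = image[box]
    sub[mask[box]] = field[mask[box]]

    if noise_sd > 0:
        image = image + noise_rng.normal(0.0, noise_sd, size=image.shape)
    image = np.clip(np.rint(image), 0, None)
    return RoiImage(image, mask, subject_id=subject_id, label=label, replicate=replicate)


def generate_phantom(
    spec: PhantomSpec, label: str, seed: int | np.random.SeedSequence | None = None
) -> RoiImage:
    """Generate a single labelled phantom ROI image (deterministic per seed)."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(
        spec.seed if seed is None else seed
    )
    geom_ss, noise_ss = ss.spawn(2)
    return _phantom_from_streams(
        spec,
        label,
        np.random.Generator(np.random.PCG64(geom_ss)),
        np.random.Generator(np.random.PCG64(noise_ss)),
        spec.noise_sd,
        subject_id=f"{label}_s{ss.entropy}",
    )


def _split_counts(n_per_class: dict[str, int], n_train: int) -> dict[str, int]:
    """Largest-remainder stratified apportionment of n_train across classes."""
    total = sum(n_per_class.values())
    exact = {k: n_train * v / total for k, v in n_per_class.items()}
    base = {k: int(np.floor(e)) for k, e in exact.items()}
    short = n_train - sum(base.values())
    order = sorted(exact, key=lambda k: exact[k] - base[k], reverse=True)
    for k in order[:short]:
        base[k] += 1
    return base


def generate_cohort(
    spec: PhantomSpec,
    n_per_class: dict[str, int] | None = None,
    split: float | tuple[int, int] = DEFAULT_SPLIT,
) -> SyntheticCohort:
    """Generate a labelled cohort with a stratified training/validation split.

    ``split`` is either a train fraction in (0, 1) or explicit
    ``(n_train, n_validation)`` sizes summing to the cohort size.
    """
    n_per_class = dict(n_per_class or DEFAULT_COUNTS)
    for name, n in n_per_class.items():
        if name not in spec.class_params:
            raise ValidationError(f"unknown class {name!r}")
        if n < 2:
            raise ValidationError(f"class {name!r}: need >= 2 subjects, got {n}")
    total = sum(n_per_class.values())
    if isinstance(split, tuple):
        n_train, n_val = split
        if n_train + n_val != total:
            raise ValidationError(
                f"split {split} does not sum to cohort size {total}"
            )
    else:
        if not (0.0 < split < 1.0):
            raise ValidationError(f"split fraction must be in (0,1), got {split}")
        n_train = int(round(split * total))
    train_per_class = _split_counts(n_per_class, n_train)

    root = np.random.SeedSequence(spec.seed)
    subject_streams = root.spawn(total)
    rois: list[RoiImage] = []
    cohorts: list[str] = []
    idx = 0
    for label in n_per_class:  # deterministic class order
        for j in range(n_per_class[label]):
            ss = subject_streams[idx]
            geom_ss, noise_ss = ss.spawn(2)
            roi = _phantom_from_streams(
                spec,
                label,
                np.random.Generator(np.random.PCG64(geom_ss)),
                np.random.Generator(np.random.PCG64(noise_ss)),
                spec.noise_sd,
                subject_id=f"{label}_{j:03d}",
            )
            rois.append(roi)
            cohorts.append("training" if j < train_per_class[label] else "validation")
            idx += 1
    return SyntheticCohort(rois=rois, cohorts=cohorts, spec=spec)


def generate_test_retest(
    spec: PhantomSpec, n_subjects: int = DEFAULT_N_RETEST
) -> list[tuple[RoiImage, RoiImage]]:
    """Paired test/retest phantoms: same texture field and mask per subject,
    independent pixel noise of ``retest_noise_sd`` in each replicate."""
    if n_subjects < 2:
        raise ValidationError(f"need >= 2 retest subjects, got {n_subjects}")
    labels = sorted(spec.class_params)
    root = np.random.SeedSequence([spec.seed, 0x7E57])  # dedicated retest stream
    pairs: list[tuple[RoiImage, RoiImage]] = []
    for i, ss in enumerate(root.spawn(n_subjects)):
        label = labels[i % len(labels)]
        geom_ss, n1_ss, n2_ss = ss.spawn(3)
        sid = f"retest_{i:02d}"
        # replicate shares the geometry/texture stream state: regenerate it
        test = _phantom_from_streams(
            spec, label,
            np.random.Generator(np.random.PCG64(geom_ss)),
            np.random.Generator(np.random.PCG64(n1_ss)),
            spec.retest_noise_sd, subject_id=sid, replicate="test",
        )
        retest = _phantom_from_streams(
            spec, label,
            np.random.Generator(np.random.PCG64(geom_ss)),
            np.random.Generator(np.random.PCG64(n2_ss)),
            spec.retest_noise_sd, subject_id=sid, replicate="retest",
        )
        pairs.append((test, retest))
    return pairs


def write_cohort(
    cohort: SyntheticCohort,
    out_dir: str | Path,
    retest_pairs: list[tuple[RoiImage, RoiImage]] | None = None,
) -> Manifest:
    """Write PNG images + masks + a manifest CSV for a generated cohort."""
    import pandas as pd

    from .io import write_manifest, write_roi_png

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records = []

    def _write(roi: RoiImage, cohort_tag: str) -> None:
        rep = roi.replicate or ""
        stem = roi.subject_id + (f"_{rep}" if rep else "")
        img = f"{stem}.png"
        msk = f"{stem}_mask.png"
        write_roi_png(roi, out / img, out / msk)
        records.append(
            {
                "subject_id": roi.subject_id,
                "image": img,
                "mask": msk,
                "label": roi.label or "",
                "cohort": cohort_tag,
                "replicate": rep,
            }
        )

    for roi, coh in zip(cohort.rois, cohort.cohorts, strict=True):
        _write(roi, coh)
    for test, retest in retest_pairs or []:
        _write(test, "retest")
        _write(retest, "retest")
    manifest = Manifest(pd.DataFrame(records))
    write_manifest(manifest, out / "manifest.csv")
    return manifest
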