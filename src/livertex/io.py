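"""Domain types and file I/O: ROI images, feature tables, cohort manifests.

The pipeline's unit of analysis is a single 2-D image slice together with a
binary lesion mask (the ROI).  All texture features are computed strictly on
the masked pixel set; nothing outside the mask ever enters a feature value.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "RoiImage",
    "QuantizedRoi",
    "FeatureVector",
    "FeatureTable",
    "Manifest",
    "ValidationError",
    "FormatError",
    "read_roi",
    "read_image",
    "write_roi_png",
    "write_feature_table",
    "read_feature_table",
    "read_manifest",
    "write_manifest",
]

MIN_ROI_PIXELS = 16

#: 8-connectivity structuring element used to decide ROI contiguity.
_STRUCT8 = np.ones((3, 3), dtype=bool)


class ValidationError(ValueError):
    """An input violates a domain invariant (empty mask, bad label, ...)."""


class FormatError(IOError):
    """A file could not be read as any supported image format."""


@dataclasses.dataclass
class RoiImage:
    """A 2-D intensity slice plus a binary lesion mask.

    Parameters
    ----------
    pixels : 2-D float array of intensities, arbitrary units.
    mask : same-shape boolean array; True marks the lesion ROI.
    subject_id : subject identifier.
    label : optional class label (e.g. ``"classA"``).
    replicate : optional ``"test"``/``"retest"`` tag for reproducibility scans.
    """

    pixels: np.ndarray
    mask: np.ndarray
    subject_id: str = ""
    label: str | None = None
    replicate: str | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        self.mask = np.asarray(self.mask).astype(bool)
        if self.pixels.ndim != 2:
            raise ValidationError(
                f"subject {self.subject_id!r}: image must be 2-D, got shape {self.pixels.shape}"
            )
        if self.mask.shape != self.pixels.shape:
            raise ValidationError(
                f"subject {self.subject_id!r}: mask shape {self.mask.shape} "
                f"!= image shape {self.pixels.shape}"
            )
        if not np.all(np.isfinite(self.pixels)):
            raise ValidationError(f"subject {self.subject_id!r}: non-finite pixel values")
        n = int(self.mask.sum())
        if n < MIN_ROI_PIXELS:
            raise ValidationError(
                f"subject {self.subject_id!r}: ROI has {n} pixels, need >= {MIN_ROI_PIXELS}"
            )
        _, n_comp = ndimage.label(self.mask, structure=_STRUCT8)
        if n_comp != 1:
            raise ValidationError(
                f"subject {self.subject_id!r}: ROI mask has {n_comp} 8-connected "
                "components, expected exactly 1"
            )

    @property
    def n_roi_pixels(self) -> int:
        return int(self.mask.sum())

    def roi_values(self) -> np.ndarray:
        """In-mask intensities as a flat array."""
        return self.pixels[self.mask]


@dataclasses.dataclass
class QuantizedRoi:
    """ROI gray levels after min-max discretization to integers 1..range.

    ``levels`` holds the discrete gray level for in-mask pixels and the
    sentinel 0 outside the mask; matrix builders never count sentinel pixels.
    """

    levels: np.ndarray
    mask: np.ndarray
    range: int
    source: RoiImage | None = None

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=np.int64)
        self.mask = np.asarray(self.mask).astype(bool)
        inside = self.levels[self.mask]
        if inside.size and (inside.min() < 1 or inside.max() > self.range):
            raise ValidationError(
                f"quantized levels outside [1, {self.range}]: "
                f"[{inside.min()}, {inside.max()}]"
            )
        if np.any(self.levels[~self.mask] != 0):
            raise ValidationError("out-of-mask level entries must be the sentinel 0")


@dataclasses.dataclass
class FeatureVector:
    """An ordered named feature record for one ROI."""

    values: dict[str, float]
    subject_id: str = ""
    label: str | None = None

    def __post_init__(self) -> None:
        bad = [k for k, v in self.values.items() if not np.isfinite(v)]
        if bad:
            raise ValidationError(
                f"subject {self.subject_id!r}: non-finite feature values: {bad[:5]}"
            )

    def names(self) -> list[str]:
        return list(self.values)

    def as_array(self) -> np.ndarray:
        return np.array(list(self.values.values()), dtype=float)


class FeatureTable:
    """A cohort of feature vectors with labels and a train/validation split.

    Thin wrapper around a pandas DataFrame whose columns are
    ``subject_id, label, cohort, <feature...>``.
    """

    META_COLUMNS = ("subject_id", "label", "cohort")

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in self.META_COLUMNS if c not in frame.columns]
        if missing:
            raise ValidationError(f"feature table missing columns {missing}")
        self.frame = frame.reset_index(drop=True)

    @classmethod
    def from_vectors(
        cls,
        vectors: Sequence[FeatureVector],
        cohorts: Sequence[str] | None = None,
    ) -> "FeatureTable":
        if not vectors:
            raise ValidationError("cannot build a feature table from zero vectors")
        names = vectors[0].names()
        for v in vectors[1:]:
            if v.names() != names:
                raise ValidationError(
                    f"subject {v.subject_id!r} has a mismatched feature-name set"
                )
        if cohorts is None:
            cohorts = ["training"] * len(vectors)
        rows = []
        for v, coh in zip(vectors, cohorts, strict=True):
            row = {"subject_id": v.subject_id, "label": v.label, "cohort": coh}
            row.update(v.values)
            rows.append(row)
        return cls(pd.DataFrame(rows))

    @property
    def feature_names(self) -> list[str]:
        return [c for c in self.frame.columns if c not in self.META_COLUMNS]

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def __len__(self) -> int:
        return len(self.frame)

    def features(self) -> pd.DataFrame:
        return self.frame[self.feature_names]

    def labels(self) -> pd.Series:
        return self.frame["label"]

    def subset(self, mask: np.ndarray) -> "FeatureTable":
        return FeatureTable(self.frame.loc[np.asarray(mask)].reset_index(drop=True))

    def cohort(self, which: str) -> "FeatureTable":
        return self.subset((self.frame["cohort"] == which).to_numpy())

    def select(self, names: Sequence[str]) -> "FeatureTable":
        cols = list(self.META_COLUMNS) + list(names)
        return FeatureTable(self.frame[cols].copy())


@dataclasses.dataclass
class Manifest:
    """Per-subject image/mask/label bookkeeping for a cohort on disk."""

    records: pd.DataFrame

    COLUMNS = ("subject_id", "image", "mask", "label", "cohort", "replicate")

    def __post_init__(self) -> None:
        missing = [c for c in self.COLUMNS if c not in self.records.columns]
        if missing:
            raise ValidationError(f"manifest missing columns {missing}")
        key = self.records[["subject_id", "replicate"]].astype(str).agg("/".join, axis=1)
        if key.duplicated().any():
            dup = key[key.duplicated()].iloc[0]
            raise ValidationError(f"duplicate subject/replicate in manifest: {dup}")

    def __len__(self) -> int:
        return len(self.records)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_image(path: str | Path, slice_index: int = 0) -> np.ndarray:
    """Read a single 2-D grayscale frame from PNG/TIFF, DICOM or NIfTI.

    NIfTI volumes yield slice ``slice_index`` along the last axis.  DICOM
    intensities are rescaled only by the format-mandated slope/intercept.
    """
    path = Path(path)
    suffix = "".join(path.suffixes).lower()
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        if suffix.endswith((".dcm", ".dicom")):
            import pydicom

            ds = pydicom.dcmread(str(path))
            arr = ds.pixel_array.astype(float)
            slope = float(getattr(ds, "RescaleSlope", 1.0))
            intercept = float(getattr(ds, "RescaleIntercept", 0.0))
            arr = arr * slope + intercept
        elif ".nii" in suffix:
            import nibabel as nib

            vol = np.asanyarray(nib.load(str(path)).dataobj).astype(float)
            if vol.ndim == 2:
                arr = vol
            else:
                arr = vol[..., slice_index]
        else:
            import imageio.v3 as iio

            arr = np.asarray(iio.imread(str(path))).astype(float)
            if arr.ndim == 3:  # collapse RGB(A) to luminance-free mean
                arr = arr[..., :3].mean(axis=-1)
    except FormatError:
        raise
    except Exception as exc:  # noqa: BLE001 - wrap any backend failure
        raise FormatError(f"could not read {path} as an image: {exc}") from exc
    if arr.ndim != 2:
        raise FormatError(f"{path}: expected a single 2-D frame, got shape {arr.shape}")
    return arr


def read_roi(
    image_path: str | Path,
    mask_path: str | Path,
    subject_id: str = "",
    label: str | None = None,
    replicate: str | None = None,
    slice_index: int = 0,
) -> RoiImage:
    """Load an image and its mask into a validated :class:`RoiImage`.

    Any nonzero mask pixel counts as in-ROI.
    """
    pixels = read_image(image_path, slice_index=slice_index)
    mask = read_image(mask_path, slice_index=slice_index) != 0
    if mask.shape != pixels.shape:
        raise ValidationError(
            f"subject {subject_id!r}: mask shape {mask.shape} != image shape {pixels.shape}"
        )
    if not subject_id:
        subject_id = Path(image_path).stem
    return RoiImage(pixels, mask, subject_id=subject_id, label=label, replicate=replicate)


def write_roi_png(roi: RoiImage, image_path: str | Path, mask_path: str | Path) -> None:
    """Write image and mask as 16-bit / 8-bit grayscale PNGs.

    Intensities are rounded to the nearest integer and clipped to the uint16
    range; the synthetic generator emits integer-valued pixels, so phantoms
    round-trip bit-identically.
    """
    import imageio.v3 as iio

    img = np.clip(np.rint(roi.pixels), 0, 65535).astype(np.uint16)
    iio.imwrite(str(image_path), img)
    iio.imwrite(str(mask_path), (roi.mask.astype(np.uint8)) * 255)


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    """Write a feature table to CSV (comma, UTF-8, '.' decimal, 17 sig digits)."""
    table.frame.to_csv(path, index=False, float_format="%.17g", encoding="utf-8")


def read_feature_table(path: str | Path) -> FeatureTable:
    return FeatureTable(pd.read_csv(path, encoding="utf-8"))


def read_manifest(path: str | Path) -> Manifest:
    frame = pd.read_csv(path, encoding="utf-8", dtype=str).fillna("")
    return Manifest(frame)


def write_manifest(manifest: Manifest, path: str | Path) -> None:
    manifest.records.to_csv(path, index=False, encoding="utf-8")


def load_manifest_rois(manifest: Manifest, base_dir: str | Path = ".") -> list[RoiImage]:
    """Read every ROI referenced by a manifest, resolving relative paths."""
    base = Path(base_dir)
    rois = []
    for rec in manifest.records.itertuples(index=False):
        rois.append(
            read_roi(
                base / rec.image,
                base / rec.mask,
                subject_id=rec.subject_id,
                label=rec.label or None,
                replicate=rec.replicate or None,
            )
        )
    return rois
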