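"""Raw-volume preprocessing: masking, truncation, 16-bit encoding.

The pipeline takes co-registered MR/CT volumes to the normalized,
trimmed, resized 16-bit slice corpus the trainer consumes, keeping an
invertible record per volume so evaluation can return to Hounsfield
units.

Order of operations: ``mask_background`` -> ``truncate_intensities``
-> ``normalize_to_uint16`` -> ``trim_and_resize`` -> ``split_by_site``.

Normalisation conventions
-------------------------
CT uses the fixed global range [-1024, 1400] HU so that one HU maps to
the same 16-bit code in every volume and denormalisation is consistent
across patients.  MR has no absolute scale, so each volume is min-max
normalised after truncation at its own in-body 99th percentile.
Quantisation rounds half to even; a normalize -> denormalize round
trip is exact to within one quantisation step (~0.037 HU for CT).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skimage.transform import resize as _sk_resize

from .config import (ConfigurationError, DegenerateInputError,
                     StructuralError)

__all__ = ["RawVolume", "NormalizationRecord", "NormalizedVolume",
           "mask_background", "truncate_intensities", "normalize_to_uint16",
           "denormalize", "trim_and_resize", "split_by_site",
           "otsu_body_mask", "prepare_volume", "load_raw_volume",
           "save_normalized_volume", "load_normalized_volume"]

CT_BACKGROUND = -1024.0
CT_TRUNCATION_UPPER = 1400.0
CT_RANGE = (-1024.0, 1400.0)
MR_PERCENTILE = 99.0
U16_MAX = 65535
TARGET_SIZE = 256


@dataclass
class RawVolume:
    """A single-modality 3-D scan with body mask and provenance."""

    voxels: np.ndarray            # (Z, H, W); HU for CT, raw units for MR
    modality: str                 # {"CT", "MR"}
    body_mask: np.ndarray         # binary, same shape
    patient_id: str
    site_id: int
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        self.body_mask = np.asarray(self.body_mask)
        if self.modality not in ("CT", "MR"):
            raise StructuralError(f"unknown modality {self.modality!r}")
        if self.voxels.ndim != 3:
            raise StructuralError("voxels must be a (Z, H, W) array")
        if self.body_mask.shape != self.voxels.shape:
            raise StructuralError(
                f"body mask shape {self.body_mask.shape} does not match "
                f"voxels {self.voxels.shape}")
        if self.voxels.shape[0] < 5:
            raise StructuralError("volumes need >= 5 axial slices")
        if self.modality == "CT" and not np.all(np.isfinite(self.voxels)):
            raise StructuralError("CT intensities must be finite")

    def copy_with(self, voxels: np.ndarray) -> "RawVolume":
        return dataclasses.replace(self, voxels=voxels,
                                   body_mask=self.body_mask.copy())


@dataclass
class NormalizationRecord:
    """Invertible account of the truncation + 16-bit min-max mapping."""

    modality: str
    truncation_upper: float
    source_min: float | None = None
    source_max: float | None = None
    target_bits: int = 16

    def __post_init__(self):
        if (self.source_min is not None and self.source_max is not None
                and not self.source_max > self.source_min):
            raise DegenerateInputError("source_max must exceed source_min")

    @property
    def step(self) -> float:
        """HU (or raw-unit) width of one 16-bit quantisation step."""
        return (self.source_max - self.source_min) / U16_MAX

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "NormalizationRecord":
        data = json.loads(text)
        fields = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in data.items() if k in fields})


@dataclass
class NormalizedVolume:
    """16-bit slice stack plus the record needed to recover HU."""

    slices: np.ndarray            # (Z, H, W) uint16
    record: NormalizationRecord
    body_mask: np.ndarray
    patient_id: str
    site_id: int

    def __post_init__(self):
        self.slices = np.asarray(self.slices)
        if self.slices.dtype != np.uint16:
            raise StructuralError("normalized slices must be uint16")
        if self.body_mask.shape != self.slices.shape:
            raise StructuralError("body mask / slices shape mismatch")


def mask_background(v: RawVolume) -> RawVolume:
    """Zero out-of-body voxels: 0 for MR, -1024 HU (air floor) for CT.

    Idempotent; in-body voxels are untouched.
    """
    fill = CT_BACKGROUND if v.modality == "CT" else 0.0
    out = v.voxels.copy()
    out[v.body_mask == 0] = fill
    return v.copy_with(out)


def truncate_intensities(v: RawVolume) -> tuple[RawVolume,
                                                NormalizationRecord]:
    """Clip the upper intensity tail and open the normalisation record.

    CT clips at the fixed 1400 HU cap (values above it occur only in
    the densest bone and are irrelevant to dose); MR clips at the 99th
    percentile of its own in-body intensities (linear-interpolation
    percentile; background excluded so it cannot drag the quantile
    down).
    """
    if v.modality == "CT":
        upper = CT_TRUNCATION_UPPER
    else:
        in_body = v.voxels[v.body_mask != 0]
        if in_body.size == 0:
            raise DegenerateInputError("MR volume has an empty body mask")
        if np.ptp(in_body) == 0:
            raise DegenerateInputError(
                "constant-valued MR volume: percentile truncation is "
                "undefined")
        upper = float(np.percentile(in_body, MR_PERCENTILE))
    out = np.minimum(v.voxels, upper)
    return v.copy_with(out), NormalizationRecord(v.modality, upper)


def normalize_to_uint16(v: RawVolume,
                        rec: NormalizationRecord) -> NormalizedVolume:
    """Linear map of the source range onto [0, 65535], half-to-even.

    CT maps the fixed global range [-1024, 1400]; MR maps the volume's
    own (truncated) min-max.  The completed record allows
    ``denormalize`` to recover intensities to within one quantisation
    step.
    """
    if v.modality == "CT":
        smin, smax = CT_RANGE
    else:
        smin = float(v.voxels.min())
        smax = float(v.voxels.max())
    if not smax > smin:
        raise DegenerateInputError("degenerate intensity range: "
                                   f"[{smin}, {smax}]")
    rec = dataclasses.replace(rec, source_min=smin, source_max=smax)
    scaled = (v.voxels - smin) * (U16_MAX / (smax - smin))
    codes = np.rint(np.clip(scaled, 0, U16_MAX)).astype(np.uint16)
    return NormalizedVolume(codes, rec, v.body_mask.copy(),
                            v.patient_id, v.site_id)


def denormalize(slices: np.ndarray, rec: NormalizationRecord) -> np.ndarray:
    """Invert the 16-bit encoding back to HU / raw units (float64)."""
    if rec.source_min is None or rec.source_max is None:
        raise ConfigurationError("record has no source range; run "
                                 "normalize_to_uint16 first")
    return np.asarray(slices, dtype=np.float64) * rec.step + rec.source_min


def trim_and_resize(v: NormalizedVolume,
                    size: int = TARGET_SIZE) -> NormalizedVolume:
    """Drop the first/last two axial slices, resample to size x size.

    Slices are resampled bicubically (values re-clipped to the 16-bit
    range afterwards: cubic interpolation can overshoot); the body
    mask uses nearest-neighbour so it stays binary.
    """
    if v.slices.shape[0] < 5:
        raise DegenerateInputError("need >= 5 slices to trim two per end")
    kept = v.slices[2:-2]
    kept_mask = v.body_mask[2:-2]
    Z = kept.shape[0]
    out = np.empty((Z, size, size), dtype=np.uint16)
    out_mask = np.empty((Z, size, size), dtype=kept_mask.dtype)
    for k in range(Z):
        if kept.shape[1:] == (size, size):
            out[k] = kept[k]
            out_mask[k] = kept_mask[k]
            continue
        r = _sk_resize(kept[k].astype(np.float64), (size, size), order=3,
                       mode="edge", anti_aliasing=False, preserve_range=True)
        out[k] = np.rint(np.clip(r, 0, U16_MAX)).astype(np.uint16)
        m = _sk_resize(kept_mask[k].astype(np.float64), (size, size),
                       order=0, mode="edge", anti_aliasing=False,
                       preserve_range=True)
        out_mask[k] = (m > 0.5).astype(kept_mask.dtype)
    return NormalizedVolume(out, v.record, out_mask, v.patient_id, v.site_id)


def split_by_site(volumes: list) -> tuple[list, list]:
    """Sites 2 and 3 train, site 1 tests (the cross-scanner split)."""
    train, test = [], []
    for v in volumes:
        site = getattr(v, "site_id")
        if site in (2, 3):
            train.append(v)
        elif site == 1:
            test.append(v)
        else:
            raise ConfigurationError(f"unknown site_id {site!r}")
    return train, test


def otsu_body_mask(voxels: np.ndarray) -> np.ndarray:
    """Fallback body mask for unmasked data (convenience extension).

    Otsu threshold per volume, then the largest connected component
    with holes filled, per slice.  Prefer a provided delineation when
    one exists.
    """
    from scipy import ndimage
    from skimage.filters import threshold_otsu

    vol = np.asarray(voxels, dtype=np.float64)
    thr = threshold_otsu(vol)
    fg = vol > thr
    labels, n = ndimage.label(fg)
    if n == 0:
        return np.zeros_like(vol, dtype=np.uint8)
    largest = np.argmax(ndimage.sum_labels(fg, labels, range(1, n + 1))) + 1
    mask = labels == largest
    for k in range(mask.shape[0]):
        mask[k] = ndimage.binary_fill_holes(mask[k])
    return mask.astype(np.uint8)


def prepare_volume(v: RawVolume, size: int = TARGET_SIZE
                   ) -> tuple[NormalizedVolume, NormalizationRecord]:
    """Full preprocessing chain for one raw volume."""
    masked = mask_background(v)
    truncated, rec = truncate_intensities(masked)
    normalized = normalize_to_uint16(truncated, rec)
    trimmed = trim_and_resize(normalized, size=size)
    return trimmed, trimmed.record


# ---------------------------------------------------------------------
# NIfTI interchange
# ---------------------------------------------------------------------

def load_raw_volume(path: str | Path, modality: str, mask_path=None,
                    patient_id: str = "", site_id: int = 1,
                    axial_axis: int = -1) -> RawVolume:
    """Read a NIfTI volume (+ optional mask) into a RawVolume.

    The axial slice axis (NIfTI's last dimension by default) is moved
    to the front; without a mask an Otsu-based body mask is estimated.
    """
    import nibabel as nib

    img = nib.load(str(path))
    vox = np.moveaxis(np.asanyarray(img.dataobj).astype(np.float64),
                      axial_axis, 0)
    if mask_path is not None:
        m = nib.load(str(mask_path))
        mask = np.moveaxis(np.asanyarray(m.dataobj), axial_axis, 0)
        mask = (mask > 0).astype(np.uint8)
    else:
        mask = otsu_body_mask(vox)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return RawVolume(vox, modality, mask, patient_id or Path(path).stem,
                     site_id, spacing)


def save_normalized_volume(v: NormalizedVolume, out_dir: str | Path,
                           stem: str | None = None) -> Path:
    """Write slices + mask as NIfTI and the record as a JSON sidecar."""
    import nibabel as nib

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stem = stem or f"{v.patient_id}_{v.record.modality.lower()}"
    arr = np.moveaxis(v.slices, 0, -1)
    nib.save(nib.Nifti1Image(arr.astype(np.uint16), np.eye(4)),
             out / f"{stem}.nii")
    nib.save(nib.Nifti1Image(
        np.moveaxis(v.body_mask, 0, -1).astype(np.uint8), np.eye(4)),
        out / f"{stem}_mask.nii")
    meta = dataclasses.asdict(v.record)
    meta.update(patient_id=v.patient_id, site_id=v.site_id)
    (out / f"{stem}.json").write_text(json.dumps(meta, indent=2))
    return out / f"{stem}.nii"


def load_normalized_volume(nii_path: str | Path) -> NormalizedVolume:
    import nibabel as nib

    nii_path = Path(nii_path)
    meta = json.loads(nii_path.with_suffix(".json").read_text())
    patient_id = meta.pop("patient_id")
    site_id = meta.pop("site_id")
    rec = NormalizationRecord(**meta)
    vol = np.moveaxis(np.asanyarray(nib.load(str(nii_path)).dataobj), -1, 0)
    mask_file = nii_path.with_name(nii_path.stem + "_mask.nii")
    mask = np.moveaxis(np.asanyarray(nib.load(str(mask_file)).dataobj),
                       -1, 0).astype(np.uint8)
    return NormalizedVolume(vol.astype(np.uint16), rec, mask,
                            patient_id, site_id)
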