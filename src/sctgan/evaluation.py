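"""HU-space evaluation of synthetic CT: ME, MAE and PSNR per region.

ME and MAE are computed in Hounsfield units after denormalising the
16-bit volumes; PSNR stays on the 16-bit scale with MAX_I = 65535.
Metrics are restricted to the body contour and, when organ
delineations are given, to each organ mask; volume-level reports are
aggregated across test volumes as mean +/- population SD.

Two PSNR conventions are provided.  ``standard`` is the usual
20 log10(MAX_I / RMSE).  ``paper`` divides by the MSE itself rather
than its square root, matching the printed formula of the model
family's publication; the literal form cannot produce ~57 dB at
~40 HU MAE, which is why ``standard`` is the default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import DegenerateInputError, StructuralError
from .preprocess import NormalizationRecord, denormalize

__all__ = ["RegionMetrics", "MetricsReport", "mean_error",
           "mean_absolute_error", "psnr", "evaluate_volume", "aggregate",
           "interframe_residual"]

PSNR_MAX = 65535.0


def _masked(ct, sct, mask, name: str) -> tuple[np.ndarray, np.ndarray]:
    ct = np.asarray(ct, dtype=np.float64)
    sct = np.asarray(sct, dtype=np.float64)
    mask = np.asarray(mask)
    if ct.shape != sct.shape or ct.shape != mask.shape:
        raise StructuralError(f"{name}: shapes {ct.shape}/{sct.shape}/"
                              f"{mask.shape} do not align")
    sel = mask != 0
    if not sel.any():
        raise DegenerateInputError(f"{name}: empty mask")
    return ct[sel], sct[sel]


def mean_error(ct, sct, mask) -> float:
    """Signed mean of CT - sCT over the mask (positive: sCT reads low)."""
    a, b = _masked(ct, sct, mask, "mean_error")
    return float(np.mean(a - b))


def mean_absolute_error(ct, sct, mask) -> float:
    """Mean |CT - sCT| over the mask."""
    a, b = _masked(ct, sct, mask, "mean_absolute_error")
    return float(np.mean(np.abs(a - b)))


def psnr(ct_u16, sct_u16, mask, mode: str = "standard") -> float:
    """Peak signal-to-noise ratio on the 16-bit scale, in dB.

    mode 'standard': 20 log10(65535 / sqrt(MSE));
    mode 'paper':    20 log10(65535 / MSE), the literal printed form.
    Identical inputs give +inf (sentinel for a zero-error volume).
    """
    if mode not in ("standard", "paper"):
        raise ValueError(f"unknown PSNR mode {mode!r}")
    a, b = _masked(ct_u16, sct_u16, mask, "psnr")
    mse = float(np.mean((a - b) ** 2))
    if mse == 0.0:
        return float("inf")
    denom = np.sqrt(mse) if mode == "standard" else mse
    return float(20.0 * np.log10(PSNR_MAX / denom))


@dataclass
class RegionMetrics:
    me_hu: float
    mae_hu: float
    psnr_db: float
    n_voxels: int


@dataclass
class MetricsReport:
    """Per-region metric triples for one evaluated volume."""

    patient_id: str
    regions: dict[str, RegionMetrics] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"region": name, "ME_HU": m.me_hu, "MAE_HU": m.mae_hu,
                 "PSNR_dB": m.psnr_db, "n_voxels": m.n_voxels}
                for name, m in self.regions.items()]
        return pd.DataFrame(rows)


def evaluate_volume(ct_u16, sct_u16, body_mask, organs=None,
                    rec: NormalizationRecord | None = None,
                    psnr_mode: str = "standard") -> MetricsReport:
    """Score one synthetic CT against ground truth, region by region.

    ``ct_u16``/``sct_u16`` are 16-bit encoded volumes; ME/MAE are
    computed after denormalising through ``rec``, PSNR on the 16-bit
    codes.  ``organs`` maps region names to binary masks; a mask empty
    in this volume is skipped with a warning.
    """
    if rec is None:
        raise StructuralError("evaluate_volume needs the normalization "
                              "record for HU recovery")
    ct_u16 = np.asarray(ct_u16)
    sct_u16 = np.asarray(sct_u16)
    ct_hu = denormalize(ct_u16, rec)
    sct_hu = denormalize(sct_u16, rec)
    report = MetricsReport(patient_id="")
    regions = {"body": np.asarray(body_mask)}
    for name, m in (organs or {}).items():
        regions[name] = np.asarray(m)
    for name, mask in regions.items():
        if not (mask != 0).any():
            warnings.warn(f"region {name!r} is empty in this volume; "
                          f"skipped", stacklevel=2)
            continue
        report.regions[name] = RegionMetrics(
            me_hu=mean_error(ct_hu, sct_hu, mask),
            mae_hu=mean_absolute_error(ct_hu, sct_hu, mask),
            psnr_db=psnr(ct_u16, sct_u16, mask, mode=psnr_mode),
            n_voxels=int((mask != 0).sum()))
    return report


def aggregate(reports: list[MetricsReport]) -> pd.DataFrame:
    """Across-volume mean +/- population SD per region and metric.

    Output rows: region; columns: <metric>_mean, <metric>_sd,
    n_volumes.  Regions missing from some volumes aggregate over the
    volumes that have them.
    """
    if not reports:
        raise StructuralError("aggregate needs at least one report")
    names: list[str] = []
    for r in reports:
        for name in r.regions:
            if name not in names:
                names.append(name)
    rows = []
    for name in names:
        triples = [r.regions[name] for r in reports if name in r.regions]
        row = {"region": name, "n_volumes": len(triples)}
        for metric in ("me_hu", "mae_hu", "psnr_db"):
            vals = np.array([getattr(t, metric) for t in triples])
            row[f"{metric}_mean"] = float(vals.mean())
            row[f"{metric}_sd"] = float(vals.std(ddof=0))
        rows.append(row)
    return pd.DataFrame(rows)


def interframe_residual(slices_u16, cache, rec: NormalizationRecord,
                        body_mask=None) -> float:
    """Mean HU residual of flow-warped adjacent slices of one volume.

    For every slice n, warps it through the cached ground-truth flow
    f_{n,n+1} (which reconstructs slice n+1 from slice n) and takes the
    mean |warped - slice_{n+1}| in HU.  Low values mean the stack is
    consistent with the anatomy's interslice motion; a synthetic volume
    with flickering axial content scores high even when each individual
    slice looks plausible.
    """
    from .flow import warp

    hu = denormalize(np.asarray(slices_u16), rec)
    Z = hu.shape[0]
    if Z < 2:
        raise DegenerateInputError("interframe residual needs >= 2 slices")
    residuals = []
    for n in range(Z - 1):
        f = cache.get(n, "to_next")
        if f is None:
            raise StructuralError(f"cache has no to_next flow for slice {n}")
        diff = np.abs(warp(hu[n], f) - hu[n + 1])
        if body_mask is not None:
            sel = np.asarray(body_mask[n + 1]) != 0
            if not sel.any():
                continue
            diff = diff[sel]
        residuals.append(float(diff.mean()))
    return float(np.mean(residuals))
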