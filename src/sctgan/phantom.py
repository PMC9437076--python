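"""Paired pseudo-MR / pseudo-CT pelvis phantoms.

Each phantom emulates the features of a co-registered MR/CT pelvis
pair that the pipeline actually exercises: an elliptical body contour
surrounded by air, two bone-like high-HU discs (femoral heads), a
bladder-like near-water ellipse, a rectum-like ellipse enclosing an
air core, a small prostate-like ellipse, textured soft tissue, and a
smooth slice-to-slice drift of all structures so adjacent slices
differ by small, flow-recoverable displacements.  The MR channel is a
monotone nonlinear remap of the CT tissue map (bone dark, as in
T2-weighted imaging) with its own texture, multiplicative bias field
and noise, so the MR->CT translation task is non-trivial but has an
exact voxel-wise ground truth.

These phantoms are deliberately schematic: no scanner physics, no
air-pocket mismatch between modalities, no anatomical variability
beyond ellipse geometry.  Everything derives from one seed through a
hierarchical `numpy` SeedSequence, so cohorts are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .config import ConfigurationError
from .preprocess import RawVolume

__all__ = ["PhantomSpec", "PhantomPatient", "generate_phantom",
           "generate_cohort", "save_patient_nifti"]

HU_AIR = -1000.0
HU_BONE = 1000.0
HU_SOFT = 50.0
HU_BLADDER = 15.0
HU_RECTAL_AIR = -900.0
HU_PROSTATE = 45.0


@dataclass
class PhantomSpec:
    """Geometry, drift and noise of one synthetic patient."""

    n_slices: int = 12
    height: int = 64
    width: int = 64
    drift_step: float = 1.0        # max per-slice structure drift, px
    noise_sigma_ct: float = 10.0   # HU
    noise_sigma_mr: float = 15.0   # arbitrary MR units
    body_scale: float = 1.0        # relative body ellipse size
    seed: int = 0

    def __post_init__(self):
        if self.n_slices < 5:
            raise ConfigurationError("phantoms need >= 5 slices (trimming "
                                     "removes four)")
        if min(self.height, self.width) < 32:
            raise ConfigurationError("phantom slices must be >= 32 px")


@dataclass
class PhantomPatient:
    """One co-registered pair with masks, as produced by the generator."""

    ct: RawVolume
    mr: RawVolume
    organs: dict[str, np.ndarray]
    patient_id: str = "phantom"
    site_id: int = 1


def _soft_ellipse(H, W, cy, cx, ry, rx, edge: float = 1.5):
    """Anti-aliased ellipse coverage in [0, 1] with an ``edge``-px ramp.

    Soft edges make sub-pixel structure drift appear as smooth
    intensity change, the kind of interslice motion dense optical flow
    can actually track (hard binary edges would flicker instead).
    """
    yy, xx = np.mgrid[0:H, 0:W]
    r = np.sqrt(((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2)
    scale = np.sqrt(ry * rx) / edge
    return np.clip((1.0 - r) * scale + 0.5, 0.0, 1.0)


def _smooth_noise(rng, H, W, sigma, amplitude):
    return ndimage.gaussian_filter(rng.normal(0.0, 1.0, (H, W)), sigma) \
        * amplitude


def _drift_offsets(rng, n_slices: int, step: float, limit: float):
    """Smooth 2-D drift: per-slice displacement of magnitude ~``step``
    with a slowly turning direction, reflected off the ``limit`` box."""
    off = np.zeros((n_slices, 2))
    theta = rng.uniform(0.0, 2.0 * np.pi)
    for k in range(1, n_slices):
        theta += rng.normal(0.0, 0.6)
        mag = step * rng.uniform(0.7, 1.0)
        v = mag * np.array([np.cos(theta), np.sin(theta)])
        nxt = off[k - 1] + v
        for d in range(2):
            if abs(nxt[d]) > limit:          # bounce back into frame
                v[d] = -v[d]
                nxt[d] = off[k - 1][d] + v[d]
        off[k] = nxt
    return off


def _mr_remap(hu: np.ndarray) -> np.ndarray:
    """Monotone decreasing HU -> MR map (bone dark, fluid bright)."""
    u = np.clip((hu - HU_AIR) / 2400.0, 0.0, 1.0)
    return 900.0 * (1.0 - u) ** 1.5 + 60.0


def generate_phantom(spec: PhantomSpec) -> PhantomPatient:
    """Build one paired phantom volume from its spec, deterministically."""
    rng = np.random.default_rng(spec.seed)
    Z, H, W = spec.n_slices, spec.height, spec.width
    limit = 0.12 * min(H, W)
    offsets = _drift_offsets(rng, Z, spec.drift_step, limit)
    body_ry = 0.40 * H * spec.body_scale
    body_rx = 0.45 * W * spec.body_scale
    # static anchor positions, relative to the (drifting) body centre
    bone_dx = 0.26 * W
    bone_r = 0.085 * min(H, W)

    ct = np.empty((Z, H, W))
    mr = np.empty((Z, H, W))
    body = np.empty((Z, H, W), dtype=np.uint8)
    organs = {name: np.zeros((Z, H, W), dtype=np.uint8)
              for name in ("bladder", "rectum", "prostate",
                           "femoral_head_l", "femoral_head_r")}
    # one shared texture field, shifted sub-pixel with the drift so the
    # whole slice content moves coherently and interslice flow is
    # recoverable
    tex_ct = _smooth_noise(rng, H, W, 4.0, 30.0)
    tex_mr = _smooth_noise(rng, H, W, 3.0, 60.0)
    bias = 1.0 + _smooth_noise(rng, H, W, 12.0, 1.5)

    for k in range(Z):
        cy = H / 2.0 + offsets[k, 0]
        cx = W / 2.0 + offsets[k, 1]
        a_body = _soft_ellipse(H, W, cy, cx, body_ry, body_rx)
        tex_k = ndimage.shift(tex_ct, offsets[k], order=3, mode="reflect")

        a_bl = _soft_ellipse(H, W, cy - 0.14 * H, cx, 0.12 * H, 0.11 * W)
        a_re = _soft_ellipse(H, W, cy + 0.20 * H, cx, 0.08 * H, 0.07 * W)
        a_ra = _soft_ellipse(H, W, cy + 0.20 * H, cx, 0.04 * H, 0.035 * W)
        a_pr = _soft_ellipse(H, W, cy + 0.03 * H, cx, 0.06 * H, 0.07 * W)
        a_fl = _soft_ellipse(H, W, cy, cx - bone_dx, bone_r, bone_r)
        a_fr = _soft_ellipse(H, W, cy, cx + bone_dx, bone_r, bone_r)

        # layered alpha blend, innermost last
        hu = np.full((H, W), HU_AIR)
        hu = hu + a_body * (HU_SOFT + tex_k - hu)
        for alpha, value, tex_w in ((a_bl, HU_BLADDER, 0.2),
                                    (a_re, 40.0, 0.2),
                                    (a_ra, HU_RECTAL_AIR, 0.0),
                                    (a_pr, HU_PROSTATE, 0.2),
                                    (a_fl, HU_BONE, 2.0),
                                    (a_fr, HU_BONE, 2.0)):
            a = alpha * a_body
            hu = hu + a * (value + tex_w * tex_k - hu)

        body_k = a_body > 0.5
        mr_k = _mr_remap(hu) * bias
        mr_k += ndimage.shift(tex_mr, offsets[k], order=3, mode="reflect")
        mr_k[~body_k] = 5.0

        hu[body_k] += rng.normal(0.0, spec.noise_sigma_ct,
                                 int(body_k.sum()))
        mr_k[body_k] += rng.normal(0.0, spec.noise_sigma_mr,
                                   int(body_k.sum()))
        np.clip(mr_k, 0.0, None, out=mr_k)

        ct[k], mr[k] = hu, mr_k
        body[k] = body_k
        # priority order keeps organ masks pairwise disjoint
        taken = np.zeros((H, W), dtype=bool)
        for name, m in (("bladder", a_bl > 0.5),
                        ("rectum", a_re > 0.5),
                        ("prostate", a_pr > 0.5),
                        ("femoral_head_l", a_fl > 0.5),
                        ("femoral_head_r", a_fr > 0.5)):
            m = m & body_k
            organs[name][k] = (m & ~taken)
            taken |= m

    spacing = (2.5, 1.0, 1.0)
    pid = f"phantom-{spec.seed}"
    return PhantomPatient(
        ct=RawVolume(ct, "CT", body, pid, 1, spacing),
        mr=RawVolume(mr, "MR", body.copy(), pid, 1, spacing),
        organs=organs, patient_id=pid, site_id=1)


def generate_cohort(n_patients: int, site_assignment=None, seed: int = 0,
                    size: int = 64, n_slices: int = 12,
                    drift_step: float = 1.0) -> list[PhantomPatient]:
    """A multi-patient, multi-site phantom cohort from one seed.

    ``site_assignment`` is a per-patient sequence of site ids; with 19
    patients and no assignment the 8/7/4 split over sites 1/2/3 of the
    emulated public cohort is used, otherwise sites cycle 1, 2, 3.
    Patient seeds derive hierarchically from the cohort seed, so every
    patient differs but the cohort is reproducible.
    """
    if n_patients < 1:
        raise ConfigurationError("n_patients must be >= 1")
    if site_assignment is None:
        if n_patients == 19:
            site_assignment = [1] * 8 + [2] * 7 + [3] * 4
        else:
            site_assignment = [(i % 3) + 1 for i in range(n_patients)]
    if len(site_assignment) != n_patients:
        raise ConfigurationError("site_assignment length must equal "
                                 "n_patients")
    master = np.random.SeedSequence(seed)
    cohort = []
    for i, child in enumerate(master.spawn(n_patients)):
        sub = np.random.default_rng(child)
        pseed = int(sub.integers(0, 2 ** 31 - 1))
        scale = float(sub.uniform(0.88, 1.05))
        spec = PhantomSpec(n_slices=n_slices, height=size, width=size,
                           drift_step=drift_step, body_scale=scale,
                           seed=pseed)
        patient = generate_phantom(spec)
        patient.patient_id = f"phantom-{seed}-{i:02d}"
        patient.site_id = int(site_assignment[i])
        patient.ct.patient_id = patient.mr.patient_id = patient.patient_id
        patient.ct.site_id = patient.mr.site_id = patient.site_id
        cohort.append(patient)
    return cohort


def save_patient_nifti(patient: PhantomPatient, out_dir: str | Path) -> None:
    """Write CT/MR/body/organ volumes as NIfTI files (axial axis last)."""
    import nibabel as nib

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pid = patient.patient_id

    def save(arr, name):
        data = np.moveaxis(np.asarray(arr), 0, -1).astype(np.float32)
        nib.save(nib.Nifti1Image(data, np.eye(4)), out / f"{pid}_{name}.nii")

    save(patient.ct.voxels, "ct")
    save(patient.mr.voxels, "mr")
    save(patient.ct.body_mask, "body")
    for organ, mask in patient.organs.items():
        save(mask, f"organ_{organ}")
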