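"""Masking, truncation, 16-bit encoding, trimming and the site split."""

import numpy as np
import pytest

from sctgan import (ConfigurationError, DegenerateInputError,
                    NormalizationRecord, RawVolume, StructuralError,
                    denormalize, generate_cohort, mask_background,
                    normalize_to_uint16, prepare_volume, split_by_site,
                    trim_and_resize, truncate_intensities)

RNG = np.random.default_rng(5)


def make_volume(modality="CT", z=6, hw=16, fill=100.0, mask=None):
    vox = np.full((z, hw, hw), fill)
    if mask is None:
        mask = np.ones((z, hw, hw), dtype=np.uint8)
    return RawVolume(vox, modality, mask, "p0", 1)


# ----------------------------------------------------------------- masking

def test_background_set_to_minus_1024_for_ct_and_zero_for_mr():
    mask = np.ones((6, 16, 16), dtype=np.uint8)
    mask[:, :4] = 0
    ct = RawVolume(np.full((6, 16, 16), 312.0), "CT", mask, "p", 1)
    out = mask_background(ct)
    assert np.all(out.voxels[:, :4] == -1024.0)
    assert np.all(out.voxels[:, 4:] == 312.0)
    mr = RawVolume(np.full((6, 16, 16), 87.0), "MR", mask, "p", 1)
    out = mask_background(mr)
    assert np.all(out.voxels[:, :4] == 0.0)
    assert np.all(out.voxels[:, 4:] == 87.0)


def test_mask_background_full_mask_is_identity_and_idempotent():
    v = make_volume(fill=55.0)
    once = mask_background(v)
    assert np.array_equal(once.voxels, v.voxels)
    mask = np.ones((6, 16, 16), dtype=np.uint8)
    mask[:, ::2] = 0
    v2 = RawVolume(RNG.normal(0, 100, (6, 16, 16)), "CT", mask, "p", 1)
    assert np.array_equal(mask_background(mask_background(v2)).voxels,
                          mask_background(v2).voxels)


def test_mask_shape_mismatch_rejected():
    with pytest.raises(StructuralError):
        RawVolume(np.zeros((6, 16, 16)), "CT",
                  np.ones((6, 16, 15), dtype=np.uint8), "p", 1)


# -------------------------------------------------------------- truncation

def test_ct_caps_at_1400_and_leaves_lower_values():
    v = make_volume("CT")
    v.voxels[0, 0, 0] = 2100.0
    v.voxels[0, 0, 1] = 900.0
    out, rec = truncate_intensities(v)
    assert out.voxels[0, 0, 0] == 1400.0
    assert out.voxels[0, 0, 1] == 900.0
    assert rec.truncation_upper == 1400.0


def test_mr_caps_at_99th_percentile_with_sort_oracle():
    vals = np.arange(1000, dtype=float)  # 0..999 uniformly
    vox = np.resize(vals, (5, 16, 16)).astype(float)
    v = RawVolume(vox, "MR", np.ones_like(vox, dtype=np.uint8), "p", 1)
    out, rec = truncate_intensities(v)
    # sort-based linear-interpolation percentile oracle
    s = np.sort(vox.ravel())
    pos = 0.99 * (s.size - 1)
    lo, hi = int(np.floor(pos)), int(np.ceil(pos))
    expect = s[lo] + (pos - lo) * (s[hi] - s[lo])
    assert rec.truncation_upper == pytest.approx(expect, abs=1e-9)
    assert out.voxels.max() == pytest.approx(expect, abs=1e-9)


def test_mr_percentile_ignores_background():
    vox = RNG.uniform(100, 200, (5, 16, 16))
    mask = np.zeros_like(vox, dtype=np.uint8)
    mask[:, 8:] = 1
    vox[mask == 0] = 0.0
    v = RawVolume(vox, "MR", mask, "p", 1)
    _, rec = truncate_intensities(v)
    assert rec.truncation_upper >= 100.0  # zeros did not drag it down


def test_constant_mr_volume_is_degenerate():
    with pytest.raises(DegenerateInputError):
        truncate_intensities(make_volume("MR", fill=7.0))


# ------------------------------------------------------------ quantisation

def test_ct_endpoints_and_midpoint_map():
    v = make_volume("CT")
    v.voxels[0, 0, :3] = [-1024.0, 1400.0, 188.0]  # 188 = midpoint
    out = normalize_to_uint16(v, NormalizationRecord("CT", 1400.0))
    assert out.slices[0, 0, 0] == 0
    assert out.slices[0, 0, 1] == 65535
    assert out.slices[0, 0, 2] in (32767, 32768)
    # round-half-to-even: 32767.5 rounds to 32768
    assert out.slices[0, 0, 2] == 32768


def test_normalization_is_order_preserving():
    v = make_volume("CT")
    v.voxels[:] = RNG.uniform(-1024, 1400, v.voxels.shape)
    out = normalize_to_uint16(v, NormalizationRecord("CT", 1400.0))
    flat_v = v.voxels.ravel()
    flat_n = out.slices.ravel()
    order = np.argsort(flat_v, kind="stable")
    assert np.all(np.diff(flat_n[order].astype(np.int64)) >= 0)


def test_round_trip_within_one_quantisation_step():
    v = make_volume("CT", z=5, hw=10)
    v.voxels[:] = RNG.uniform(-1024, 1400, v.voxels.shape)
    out = normalize_to_uint16(v, NormalizationRecord("CT", 1400.0))
    back = denormalize(out.slices, out.record)
    step = 2424.0 / 65535.0
    # brute-force per-voxel check against the original values
    assert np.abs(back - v.voxels).max() <= step


def test_degenerate_range_rejected():
    v = make_volume("MR", fill=3.0)
    with pytest.raises(DegenerateInputError):
        normalize_to_uint16(v, NormalizationRecord("MR", 3.0))


# ---------------------------------------------------------- trim and resize

def test_trim_removes_two_slices_each_end():
    v = make_volume("CT", z=60, hw=16)
    v.voxels[:] = RNG.uniform(-1024, 1400, v.voxels.shape)
    nv = normalize_to_uint16(v, NormalizationRecord("CT", 1400.0))
    out = trim_and_resize(nv, size=16)
    assert out.slices.shape[0] == 56


def test_trim_keeps_interior_slices_in_order():
    v = make_volume("CT", z=10, hw=16)
    v.voxels[:] = RNG.uniform(-1024, 1400, v.voxels.shape)
    nv = normalize_to_uint16(v, NormalizationRecord("CT", 1400.0))
    out = trim_and_resize(nv, size=16)  # same size: no resampling
    assert out.slices.shape[0] == 6
    assert np.array_equal(out.slices[0], nv.slices[2])


def test_bicubic_preserves_constant_slices():
    v = make_volume("CT", z=6, hw=20, fill=200.0)
    nv = normalize_to_uint16(v, NormalizationRecord("CT", 1400.0))
    out = trim_and_resize(nv, size=32)
    for k in range(out.slices.shape[0]):
        assert np.all(out.slices[k] == nv.slices[0, 0, 0])
    assert out.slices.shape[1:] == (32, 32)


def test_resize_values_stay_in_uint16_range():
    v = make_volume("CT", z=6, hw=20)
    v.voxels[:] = RNG.choice([-1024.0, 1400.0], size=v.voxels.shape)
    nv = normalize_to_uint16(v, NormalizationRecord("CT", 1400.0))
    out = trim_and_resize(nv, size=40)
    assert out.slices.min() >= 0 and out.slices.max() <= 65535


def test_too_few_slices_rejected():
    v = make_volume("CT", z=5, hw=16)
    nv = normalize_to_uint16(
        truncate_intensities(v.copy_with(
            RNG.uniform(-1024, 1400, (5, 16, 16))))[0],
        NormalizationRecord("CT", 1400.0))
    nv.slices = nv.slices[:4]
    nv.body_mask = nv.body_mask[:4]
    with pytest.raises(DegenerateInputError):
        trim_and_resize(nv, size=16)


# ----------------------------------------------------------------- split

class _Tagged:
    def __init__(self, site):
        self.site_id = site


def test_site_split_partition():
    vols = [_Tagged(s) for s in (1, 2, 3, 1, 2, 3, 3)]
    train, test = split_by_site(vols)
    assert all(v.site_id in (2, 3) for v in train)
    assert all(v.site_id == 1 for v in test)
    assert len(train) + len(test) == len(vols)
    assert not (set(map(id, train)) & set(map(id, test)))


def test_site_split_empty_and_unknown():
    assert split_by_site([]) == ([], [])
    with pytest.raises(ConfigurationError):
        split_by_site([_Tagged(4)])


def test_nineteen_patient_cohort_splits_11_train_8_test():
    cohort = generate_cohort(19, seed=2, size=32, n_slices=5)
    train, test = split_by_site([p.ct for p in cohort])
    assert len(train) == 11
    assert len(test) == 8


def test_prepare_volume_chains_all_stages():
    patient = generate_cohort(1, site_assignment=[2], seed=9, size=48,
                              n_slices=8)[0]
    vol, rec = prepare_volume(patient.ct, size=64)
    assert vol.slices.shape == (4, 64, 64)
    assert vol.slices.dtype == np.uint16
    assert rec.source_min == -1024.0 and rec.source_max == 1400.0
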