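"""Every loss term against an independent brute-force oracle, plus the
variant presets and net-objective arithmetic."""

import numpy as np
import pytest

from sctgan import (ConfigurationError, LossWeights, SSIMConstants,
                    StructuralError, VARIANT_PRESETS, cycle_loss,
                    discriminator_loss, discriminator_net_loss, flow_loss,
                    generator_net_loss, lsgan_generator_loss, ssim_index,
                    ssim_loss)
from sctgan import autodiff as ad

RNG = np.random.default_rng(123)


# ------------------------------------------------------------------ oracles

def ssim_oracle(x, y, c):
    """Double-loop windowed SSIM: the definition, computed naively."""
    k = c.window
    H, W = x.shape
    vals = []
    for i in range(H - k + 1):
        for j in range(W - k + 1):
            wx = x[i:i + k, j:j + k]
            wy = y[i:i + k, j:j + k]
            mx, my = wx.mean(), wy.mean()
            vx, vy = wx.var(), wy.var()
            cov = ((wx - mx) * (wy - my)).mean()
            vals.append((2 * mx * my + c.c1) * (2 * cov + c.c2)
                        / ((mx ** 2 + my ** 2 + c.c1) * (vx + vy + c.c2)))
    return float(np.mean(vals))


def warp_oracle(img, flow):
    """Per-pixel bilinear backward warp with border clamping."""
    H, W = img.shape
    out = np.empty_like(img, dtype=float)
    for i in range(H):
        for j in range(W):
            r = min(max(i + flow[i, j, 0], 0), H - 1)
            cc = min(max(j + flow[i, j, 1], 0), W - 1)
            r0, c0 = int(np.floor(r)), int(np.floor(cc))
            r1, c1 = min(r0 + 1, H - 1), min(c0 + 1, W - 1)
            fr, fc = r - r0, cc - c0
            out[i, j] = (img[r0, c0] * (1 - fr) * (1 - fc)
                         + img[r0, c1] * (1 - fr) * fc
                         + img[r1, c0] * fr * (1 - fc)
                         + img[r1, c1] * fr * fc)
    return out


# ------------------------------------------------------------- adversarial

def test_lsgan_generator_perfect_fooling_is_zero():
    assert float(lsgan_generator_loss(np.ones(4), np.ones(4))) == 0.0


def test_lsgan_generator_all_zero_scores_is_two():
    assert float(lsgan_generator_loss(np.zeros(4), np.zeros(3))) == 2.0


def test_lsgan_generator_matches_mean_square_oracle():
    a, b = np.array([0.5, 0.7]), np.array([0.2])
    expect = np.mean((a - 1) ** 2) + np.mean((b - 1) ** 2)
    assert float(lsgan_generator_loss(a, b)) == pytest.approx(expect,
                                                              abs=1e-12)


def test_discriminator_perfect_and_fooled():
    assert float(discriminator_loss(np.ones(4), np.zeros(4))) == 0.0
    assert float(discriminator_loss(np.zeros(4), np.ones(4))) == 2.0


def test_discriminator_net_is_modality_average():
    assert float(discriminator_net_loss(0.4, 0.8)) == pytest.approx(0.6)


def test_empty_score_batch_rejected():
    with pytest.raises(StructuralError):
        lsgan_generator_loss(np.ones(0), np.ones(2))
    with pytest.raises(StructuralError):
        discriminator_loss(np.ones(2), np.ones(0))


# -------------------------------------------------------------------- cycle

def test_cycle_loss_perfect_reconstruction_zero():
    x = RNG.normal(0, 1, (4, 16, 16))
    assert float(cycle_loss(x, x, x, x)) == 0.0


def test_cycle_loss_constant_offset():
    x = RNG.normal(0, 1, (4, 16, 16))
    assert float(cycle_loss(x, x + 0.1, x, x + 0.1)) == pytest.approx(
        0.2, abs=1e-6)


def test_cycle_loss_matches_loop_oracle():
    ct, rct = RNG.normal(0, 1, (2, 4, 4)), RNG.normal(0, 1, (2, 4, 4))
    mr, rmr = RNG.normal(0, 1, (2, 4, 4)), RNG.normal(0, 1, (2, 4, 4))
    expect = sum(abs(rct[i, r, c] - ct[i, r, c])
                 for i in range(2) for r in range(4)
                 for c in range(4)) / 32 + \
        sum(abs(rmr[i, r, c] - mr[i, r, c])
            for i in range(2) for r in range(4) for c in range(4)) / 32
    assert float(cycle_loss(ct, rct, mr, rmr)) == pytest.approx(expect,
                                                                abs=1e-9)


def test_cycle_loss_shape_mismatch_rejected():
    with pytest.raises(StructuralError):
        cycle_loss(np.ones((2, 4, 4)), np.ones((2, 5, 4)),
                   np.ones((2, 4, 4)), np.ones((2, 4, 4)))


# --------------------------------------------------------------------- ssim

def test_ssim_self_similarity_is_one():
    x = RNG.uniform(0, 1, (16, 16))
    assert float(ssim_index(x, x)) == pytest.approx(1.0, abs=1e-6)


def test_ssim_constant_images_closed_form():
    c = SSIMConstants()
    a, b = 0.3, 0.7
    x = np.full((16, 16), a)
    y = np.full((16, 16), b)
    expect = (2 * a * b + c.c1) / (a ** 2 + b ** 2 + c.c1)
    assert float(ssim_index(x, y, c)) == pytest.approx(expect, abs=1e-12)


def test_ssim_matches_double_loop_oracle():
    c = SSIMConstants()
    x = RNG.uniform(0, 1, (32, 32))
    y = np.clip(x + RNG.normal(0, 0.1, (32, 32)), 0, 1)
    assert float(ssim_index(x, y, c)) == pytest.approx(
        ssim_oracle(x, y, c), abs=1e-9)


def test_ssim_symmetry():
    x = RNG.uniform(0, 1, (16, 16))
    y = RNG.uniform(0, 1, (16, 16))
    assert abs(float(ssim_index(x, y)) - float(ssim_index(y, x))) < 1e-12


def test_ssim_bounded_and_loss_range():
    for _ in range(5):
        x = RNG.uniform(0, 1, (16, 16))
        y = RNG.uniform(0, 1, (16, 16))
        s = float(ssim_index(x, y))
        assert -1.0 <= s <= 1.0
        lo = float(ssim_loss(x, x + 0 * y, y, y))
        assert 0.0 <= lo <= 2.0


def test_ssim_rejects_images_smaller_than_window():
    with pytest.raises(StructuralError):
        ssim_index(np.ones((8, 8)), np.ones((8, 8)))


def test_ssim_loss_arithmetic_and_batch_vs_loop():
    # SSIM_CT = 0.8, SSIM_MR = 0.6 -> loss 0.3 by direct arithmetic
    assert 1.0 - (0.8 + 0.6) / 2 == pytest.approx(0.3)
    c = SSIMConstants()
    ct = RNG.uniform(0, 1, (3, 16, 16))
    sct = np.clip(ct + RNG.normal(0, 0.05, ct.shape), 0, 1)
    mr = RNG.uniform(0, 1, (3, 16, 16))
    smr = np.clip(mr + RNG.normal(0, 0.05, mr.shape), 0, 1)
    per_item = np.mean([ssim_oracle(ct[i], sct[i], c) for i in range(3)])
    per_item_mr = np.mean([ssim_oracle(mr[i], smr[i], c) for i in range(3)])
    expect = 1.0 - (per_item + per_item_mr) / 2.0
    assert float(ssim_loss(ct, sct, mr, smr, c)) == pytest.approx(expect,
                                                                  abs=1e-9)


def test_identical_pairs_give_zero_ssim_loss():
    x = RNG.uniform(0, 1, (2, 16, 16))
    y = RNG.uniform(0, 1, (2, 16, 16))
    assert float(ssim_loss(x, x, y, y)) == pytest.approx(0.0, abs=1e-6)


# --------------------------------------------------------------------- flow

def test_flow_loss_identical_slices_zero_flow_is_zero():
    s = RNG.normal(0, 1, (16, 16))
    z = np.zeros((16, 16, 2))
    assert float(flow_loss(s, s, s, z, z)) == 0.0


def test_flow_loss_one_sided_at_boundary():
    s = RNG.normal(0, 1, (16, 16))
    z = np.zeros((16, 16, 2))
    only_next = float(flow_loss(s, None, s + 1.0, None, z))
    assert only_next == pytest.approx(1.0, abs=1e-6)
    with pytest.raises(StructuralError):
        flow_loss(s)  # no neighbour at all


def test_flow_loss_matches_warp_oracle():
    s = RNG.normal(0, 1, (12, 12))
    prev = RNG.normal(0, 1, (12, 12))
    nxt = RNG.normal(0, 1, (12, 12))
    fp = RNG.uniform(-1.5, 1.5, (12, 12, 2))
    fn = RNG.uniform(-1.5, 1.5, (12, 12, 2))
    expect = np.abs(warp_oracle(s, fp) - prev).mean() \
        + np.abs(warp_oracle(s, fn) - nxt).mean()
    assert float(flow_loss(s, prev, nxt, fp, fn)) == pytest.approx(
        expect, abs=1e-9)


# ------------------------------------------------------------ net objective

def test_variant_presets_exact():
    assert VARIANT_PRESETS == {"cyclegan": (10.0, 0.0, 0.0),
                               "structcgan": (8.0, 2.0, 0.0),
                               "flowcgan": (8.0, 0.0, 2.0),
                               "sfcgan": (6.0, 2.0, 2.0)}


@pytest.mark.parametrize("variant", ["cyclegan", "sfcgan"])
def test_unit_terms_give_eleven(variant):
    w = LossWeights.for_variant(variant)
    assert float(generator_net_loss((1.0, 1.0, 1.0, 1.0), w)) == \
        pytest.approx(11.0)


def test_net_loss_weighted_sums_per_variant():
    terms = dict(gan=0.5, cycle=0.25, ssim=0.125, flow=0.0625)
    expect = {"cyclegan": 0.5 + 10 * 0.25,
              "structcgan": 0.5 + 8 * 0.25 + 2 * 0.125,
              "flowcgan": 0.5 + 8 * 0.25 + 2 * 0.0625,
              "sfcgan": 0.5 + 6 * 0.25 + 2 * 0.125 + 2 * 0.0625}
    for variant, val in expect.items():
        w = LossWeights.for_variant(variant)
        assert float(generator_net_loss(terms, w)) == pytest.approx(val)


def test_net_loss_zero_terms_zero():
    w = LossWeights.for_variant("sfcgan")
    assert float(generator_net_loss((0, 0, 0, 0), w)) == 0.0


def test_net_loss_linearity_in_each_term():
    w = LossWeights.for_variant("sfcgan")
    base = dict(gan=1.0, cycle=1.0, ssim=1.0, flow=1.0)
    f0 = float(generator_net_loss(base, w))
    for key, lam in (("gan", 1.0), ("cycle", 6.0), ("ssim", 2.0),
                     ("flow", 2.0)):
        bumped = dict(base)
        bumped[key] = 2.0
        assert float(generator_net_loss(bumped, w)) - f0 == \
            pytest.approx(lam)


def test_missing_required_term_rejected():
    w = LossWeights.for_variant("sfcgan")
    with pytest.raises(ConfigurationError):
        generator_net_loss(dict(gan=1.0, cycle=1.0, ssim=1.0), w)


def test_inconsistent_weights_rejected():
    with pytest.raises(ConfigurationError):
        LossWeights(variant="cyclegan", lambda_cycle=10.0, lambda_ssim=2.0,
                    lambda_flow=0.0)
    with pytest.raises(ConfigurationError):
        LossWeights(variant="flowcgan", lambda_cycle=8.0, lambda_ssim=1.0,
                    lambda_flow=2.0)


# ---------------------------------------------------------------- gradients

@pytest.mark.parametrize("loss_of_syn", [
    lambda s: cycle_loss(ad.Tensor(np.zeros((2, 8, 8))), s,
                         ad.Tensor(np.zeros((2, 8, 8))), s),
    lambda s: ssim_loss((s + 1.0) * 0.5, (s * 0.0 + 0.4),
                        (s + 1.0) * 0.5, (s * 0.0 + 0.6),
                        SSIMConstants(window=5)),
])
def test_losses_have_nonzero_gradients_off_minimum(loss_of_syn):
    s = ad.Tensor(RNG.normal(0, 0.3, (2, 8, 8)), requires_grad=True)
    loss_of_syn(s).backward()
    assert s.grad is not None and np.abs(s.grad).max() > 0


def test_loss_gradient_vanishes_at_global_minimum():
    target = RNG.normal(0, 1, (2, 8, 8))
    s = ad.Tensor(target.copy(), requires_grad=True)
    cycle_loss(ad.Tensor(target), s, ad.Tensor(target), s).backward()
    assert np.abs(s.grad).max() == 0.0
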