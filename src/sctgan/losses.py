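"""Objective terms for the four cycle-GAN variants.

Every function is a pure, differentiable map from `autodiff.Tensor`
batches (plain NumPy arrays are wrapped transparently) to a scalar
Tensor, so the same code path serves training and closed-form unit
tests.  Expectations are realised as batch means.

Terms
-----
adversarial (least squares)
    generator side  E[(D_MR(sMR) - 1)^2] + E[(D_CT(sCT) - 1)^2];
    discriminator side, per modality, E[(D(real) - 1)^2] + E[D(fake)^2],
    with the net discriminator loss the average over the two modalities.
cycle consistency
    mean L1 of each input against its double translation.
windowed SSIM
    local structural-similarity index on uniform windows, compared pair
    by pair and averaged over the two modality directions; the loss is
    one minus the net index.
optical-flow consistency
    a synthesized slice is warped through the precomputed ground-truth
    interslice flow towards each axial neighbour and penalised by mean
    L1 against the real neighbour; both directions when available,
    the single available side at volume boundaries.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .config import (ConfigurationError, LossWeights, SSIMConstants,
                     StructuralError)

__all__ = ["lsgan_generator_loss", "cycle_loss", "discriminator_loss",
           "discriminator_net_loss", "ssim_index", "ssim_loss",
           "flow_loss", "generator_net_loss"]


def _scores(x, name: str) -> Tensor:
    t = ad.as_tensor(x)
    if t.data.size == 0:
        raise StructuralError(f"{name}: empty score batch")
    return t


def _pair(a, b, name: str) -> tuple[Tensor, Tensor]:
    ta, tb = ad.as_tensor(a), ad.as_tensor(b)
    if ta.shape != tb.shape:
        raise StructuralError(f"{name}: shape mismatch {ta.shape} vs "
                              f"{tb.shape}")
    if ta.data.size == 0:
        raise StructuralError(f"{name}: empty input")
    return ta, tb


def lsgan_generator_loss(d_mr_on_smr, d_ct_on_sct) -> Tensor:
    """Least-squares adversarial term pushing both fakes towards label 1."""
    a = _scores(d_mr_on_smr, "lsgan_generator_loss")
    b = _scores(d_ct_on_sct, "lsgan_generator_loss")
    return ((a - 1.0) ** 2).mean() + ((b - 1.0) ** 2).mean()


def cycle_loss(ct, rec_ct, mr, rec_mr) -> Tensor:
    """Mean L1 reconstruction error of both translation cycles."""
    ct, rec_ct = _pair(ct, rec_ct, "cycle_loss(ct)")
    mr, rec_mr = _pair(mr, rec_mr, "cycle_loss(mr)")
    return (rec_ct - ct).abs().mean() + (rec_mr - mr).abs().mean()


def discriminator_loss(d_real, d_fake) -> Tensor:
    """One modality's discriminator loss: real -> 1, synthetic -> 0."""
    r = _scores(d_real, "discriminator_loss")
    f = _scores(d_fake, "discriminator_loss")
    return ((r - 1.0) ** 2).mean() + (f ** 2).mean()


def discriminator_net_loss(loss_ct, loss_mr) -> Tensor:
    """Net discriminator objective: the average of the two modalities."""
    return (ad.as_tensor(loss_ct) + ad.as_tensor(loss_mr)) * 0.5


def ssim_index(x, y, c: SSIMConstants = SSIMConstants()) -> Tensor:
    """Mean local structural-similarity index of two 2-D images.

    Window statistics (mean, variance, covariance) use a uniform
    ``c.window``-sized kernel at valid positions only; the per-window
    index

        (2 mu_x mu_y + C1)(2 cov + C2)
        ------------------------------------------
        (mu_x^2 + mu_y^2 + C1)(var_x + var_y + C2)

    is averaged over all window positions.  Inputs are expected on a
    common [0, 1] intensity scale.
    """
    x, y = _pair(x, y, "ssim_index")
    if x.ndim != 2:
        raise StructuralError("ssim_index expects 2-D images")
    k = c.window
    if x.shape[0] < k or x.shape[1] < k:
        raise StructuralError(f"image {x.shape} smaller than SSIM window {k}")
    mx = ad.box_filter_valid(x, k)
    my = ad.box_filter_valid(y, k)
    mxx = ad.box_filter_valid(x * x, k)
    myy = ad.box_filter_valid(y * y, k)
    mxy = ad.box_filter_valid(x * y, k)
    vx = mxx - mx * mx
    vy = myy - my * my
    cov = mxy - mx * my
    num = (mx * my * 2.0 + c.c1) * (cov * 2.0 + c.c2)
    den = (mx * mx + my * my + c.c1) * (vx + vy + c.c2)
    return (num / den).mean()


def _batched(x: Tensor) -> list[Tensor]:
    """View a (B,1,H,W)/(B,H,W)/(H,W) tensor as a list of 2-D tensors."""
    if x.ndim == 2:
        return [x]
    if x.ndim == 3:
        return [x[i] for i in range(x.shape[0])]
    if x.ndim == 4:
        if x.shape[1] != 1:
            raise StructuralError("expected single-channel slices")
        return [x[i, 0] for i in range(x.shape[0])]
    raise StructuralError(f"cannot interpret shape {x.shape} as image batch")


def ssim_loss(ct, sct, mr, smr, c: SSIMConstants = SSIMConstants()) -> Tensor:
    """1 - net SSIM, the net index averaging the CT and MR directions.

    Batched inputs are scored item by item and averaged.
    """
    ct_s, sct_s = _batched(ad.as_tensor(ct)), _batched(ad.as_tensor(sct))
    mr_s, smr_s = _batched(ad.as_tensor(mr)), _batched(ad.as_tensor(smr))
    if len(ct_s) != len(sct_s) or len(mr_s) != len(smr_s):
        raise StructuralError("ssim_loss: batch size mismatch")
    s_ct = _mean_of([ssim_index(a, b, c) for a, b in zip(ct_s, sct_s)])
    s_mr = _mean_of([ssim_index(a, b, c) for a, b in zip(mr_s, smr_s)])
    return 1.0 - (s_ct + s_mr) * 0.5


def _mean_of(terms: Sequence[Tensor]) -> Tensor:
    total = terms[0]
    for t in terms[1:]:
        total = total + t
    return total * (1.0 / len(terms))


def flow_loss(s_syn_n, gt_prev=None, gt_next=None,
              f_to_prev=None, f_to_next=None) -> Tensor:
    """Interslice consistency of one synthesized slice.

    The slice is warped through the precomputed ground-truth flow
    towards each available axial neighbour and compared by mean L1.
    Interior slices contribute both directions; boundary slices only
    the side that exists.  Flows come from the flow cache as fixed
    displacement fields (gradients flow through the image only).
    """
    s = ad.as_tensor(s_syn_n)
    if s.ndim != 2:
        raise StructuralError("flow_loss expects a 2-D synthesized slice")
    terms: list[Tensor] = []
    for gt, f, tag in ((gt_prev, f_to_prev, "prev"),
                       (gt_next, f_to_next, "next")):
        if gt is None and f is None:
            continue
        if gt is None or f is None:
            raise StructuralError(f"flow_loss: neighbour and flow for "
                                  f"'{tag}' must be given together")
        flow = f.displacements if hasattr(f, "displacements") else np.asarray(f)
        warped = ad.warp_bilinear(s, flow)
        gt_t = ad.as_tensor(gt)
        if gt_t.shape != s.shape:
            raise StructuralError("flow_loss: neighbour shape mismatch")
        terms.append((warped - gt_t).abs().mean())
    if not terms:
        raise StructuralError("flow_loss: no neighbour available")
    total = terms[0]
    for t in terms[1:]:
        total = total + t
    return total


def generator_net_loss(terms: Mapping[str, object] | Sequence,
                       w: LossWeights) -> Tensor:
    """Weighted generator objective for the configured variant.

    ``terms`` maps {'gan', 'cycle', 'ssim', 'flow'} to scalars/Tensors
    (a 4-sequence in that order is also accepted).  Terms whose weight
    is zero for the variant are ignored; a term required by the variant
    but missing raises a configuration error.
    """
    if not isinstance(terms, Mapping):
        vals = list(terms)
        if len(vals) != 4:
            raise ConfigurationError(
                "sequence form of terms must be (gan, cycle, ssim, flow)")
        terms = dict(zip(("gan", "cycle", "ssim", "flow"), vals))
    if "gan" not in terms or "cycle" not in terms:
        raise ConfigurationError("generator loss needs 'gan' and 'cycle'")
    total = ad.as_tensor(terms["gan"]) + w.lambda_cycle * \
        ad.as_tensor(terms["cycle"])
    if w.uses_ssim:
        if terms.get("ssim") is None:
            raise ConfigurationError(f"{w.variant} requires an 'ssim' term")
        total = total + w.lambda_ssim * ad.as_tensor(terms["ssim"])
    if w.uses_flow:
        if terms.get("flow") is None:
            raise ConfigurationError(f"{w.variant} requires a 'flow' term")
        total = total + w.lambda_flow * ad.as_tensor(terms["flow"])
    return total
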