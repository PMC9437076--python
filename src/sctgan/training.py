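"""Alternating generator/discriminator optimisation.

One training step updates the two generators jointly on the variant's
net objective (adversarial + cycle, plus SSIM and/or flow terms), then
updates both discriminators on the averaged least-squares loss, feeding
them fakes through a 50-image history buffer per modality rather than
the latest generator outputs (the standard oscillation damper).

The published schedule — 200 epochs, batch 4, Adam(lr 2e-4, betas
0.5/0.999), learning rate constant for 100 epochs then linearly decayed
to zero — is the default `TrainConfig`.  Everything is seeded and runs
on the CPU deterministically: repeating a step with frozen weights, or
resuming from a checkpoint, reproduces losses bit-identically.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from . import autodiff as ad
from . import losses as L
from .config import ConfigurationError, StructuralError, TrainConfig
from .flow import FlowCache
from .networks import (Adam, DiscriminatorSpec, GeneratorSpec,
                       PatchDiscriminator, ResNetGenerator,
                       build_discriminator, build_generator, net_to_u16,
                       u16_to_net)
from .preprocess import NormalizedVolume

__all__ = ["lr_at_epoch", "ImageBuffer", "Sample", "build_slice_dataset",
           "GanState", "init_state", "train_step", "train",
           "save_checkpoint", "load_checkpoint", "synthesize_volume"]


def lr_at_epoch(e: int, c: TrainConfig) -> float:
    """Learning rate for 1-based epoch ``e``.

    Constant at ``c.lr`` through ``lr_constant_epochs``; thereafter
    lr * (1 - (e - constant)/decay), a straight line hitting zero at
    the final epoch.
    """
    if not 1 <= e <= c.epochs:
        raise StructuralError(f"epoch {e} outside 1..{c.epochs}")
    if e <= c.lr_constant_epochs:
        return c.lr
    return c.lr * (1.0 - (e - c.lr_constant_epochs) / c.lr_decay_epochs)


class ImageBuffer:
    """History buffer of previously generated images.

    Until ``capacity`` images have been seen, fresh images are stored
    and returned unchanged.  Afterwards each fresh image is either
    (probability 1/2) swapped with a uniformly drawn stored image —
    returning the old one — or returned directly.
    """

    def __init__(self, capacity: int = 50,
                 rng: np.random.Generator | None = None):
        if capacity < 1:
            raise ConfigurationError("buffer capacity must be >= 1")
        self.capacity = capacity
        self.rng = rng if rng is not None else np.random.default_rng()
        self.images: list[np.ndarray] = []

    def __len__(self) -> int:
        return len(self.images)

    def query(self, fresh: np.ndarray) -> np.ndarray:
        """Route a batch (B, ...) of fresh fakes through the buffer."""
        out = []
        for img in np.asarray(fresh):
            if len(self.images) < self.capacity:
                self.images.append(img.copy())
                out.append(img)
            elif self.rng.random() < 0.5:
                idx = int(self.rng.integers(self.capacity))
                out.append(self.images[idx])
                self.images[idx] = img.copy()
            else:
                out.append(img)
        return np.stack(out)


@dataclass
class Sample:
    """One paired axial slice with its neighbours and cached flows."""

    mr: np.ndarray                 # (H, W) uint16
    ct: np.ndarray
    ct_prev: np.ndarray | None = None
    ct_next: np.ndarray | None = None
    mr_prev: np.ndarray | None = None
    mr_next: np.ndarray | None = None
    f_ct_prev: np.ndarray | None = None   # flow fields for warping sCT/sMR
    f_ct_next: np.ndarray | None = None
    f_mr_prev: np.ndarray | None = None
    f_mr_next: np.ndarray | None = None
    patient_id: str = ""
    index: int = 0


def build_slice_dataset(pairs, flow_caches=None) -> list[Sample]:
    """Flatten prepared volume pairs into paired slice samples.

    ``pairs`` is a sequence of (mr: NormalizedVolume, ct:
    NormalizedVolume); ``flow_caches`` (optional) a parallel sequence
    of (ct_cache, mr_cache).  Neighbours and flows travel with each
    sample, so the flow loss needs no cross-batch lookups; boundary
    slices keep their single available side.
    """
    samples: list[Sample] = []
    for i, (mr, ct) in enumerate(pairs):
        if mr.slices.shape != ct.slices.shape:
            raise StructuralError(f"pair {i}: MR/CT shape mismatch")
        if mr.patient_id != ct.patient_id:
            raise StructuralError(f"pair {i}: MR/CT are from different "
                                  "patients")
        cache_ct = cache_mr = None
        if flow_caches is not None:
            cache_ct, cache_mr = flow_caches[i]
        Z = ct.slices.shape[0]
        for n in range(Z):
            s = Sample(mr=mr.slices[n], ct=ct.slices[n],
                       patient_id=ct.patient_id, index=n)
            if n > 0:
                s.ct_prev, s.mr_prev = ct.slices[n - 1], mr.slices[n - 1]
                if cache_ct is not None:
                    s.f_ct_prev = cache_ct.get(n, "to_prev").displacements
                    s.f_mr_prev = cache_mr.get(n, "to_prev").displacements
            if n < Z - 1:
                s.ct_next, s.mr_next = ct.slices[n + 1], mr.slices[n + 1]
                if cache_ct is not None:
                    s.f_ct_next = cache_ct.get(n, "to_next").displacements
                    s.f_mr_next = cache_mr.get(n, "to_next").displacements
            samples.append(s)
    return samples


@dataclass
class GanState:
    """All mutable training state: networks, optimisers, buffers, RNGs."""

    g_ct: ResNetGenerator
    g_mr: ResNetGenerator
    d_ct: PatchDiscriminator
    d_mr: PatchDiscriminator
    opt_g: Adam
    opt_d: Adam
    buffer_ct: ImageBuffer
    buffer_mr: ImageBuffer
    epoch: int = 0

    def zero_grads(self) -> None:
        for net in (self.g_ct, self.g_mr, self.d_ct, self.d_mr):
            net.zero_grad()


def init_state(config: TrainConfig) -> GanState:
    """Seeded construction of generators, discriminators and buffers."""
    rng = np.random.default_rng(config.seed)
    seeds = rng.integers(0, 2 ** 31 - 1, size=6)
    gspec = dict(ngf=config.ngf, n_res=config.n_res)
    g_ct = build_generator(GeneratorSpec(role="G_CT", **gspec),
                           int(seeds[0]))
    g_mr = build_generator(GeneratorSpec(role="G_MR", **gspec),
                           int(seeds[1]))
    d_ct = build_discriminator(DiscriminatorSpec(role="D_CT",
                                                 ndf=config.ndf),
                               int(seeds[2]))
    d_mr = build_discriminator(DiscriminatorSpec(role="D_MR",
                                                 ndf=config.ndf),
                               int(seeds[3]))
    opt_g = Adam(g_ct.parameters() + g_mr.parameters(), lr=config.lr)
    opt_d = Adam(d_ct.parameters() + d_mr.parameters(), lr=config.lr)
    return GanState(
        g_ct=g_ct, g_mr=g_mr, d_ct=d_ct, d_mr=d_mr,
        opt_g=opt_g, opt_d=opt_d,
        buffer_ct=ImageBuffer(config.buffer_capacity,
                              np.random.default_rng(int(seeds[4]))),
        buffer_mr=ImageBuffer(config.buffer_capacity,
                              np.random.default_rng(int(seeds[5]))))


def _stack_net(images) -> np.ndarray:
    """(B, 1, H, W) float32 batch in [-1, 1] from uint16 slices."""
    return u16_to_net(np.stack(images))[:, None, :, :]


def train_step(batch: list[Sample], state: GanState, config: TrainConfig,
               lr: float | None = None) -> dict[str, float]:
    """One generator update followed by one update of each discriminator.

    Returns the loss record with every component term of the variant.
    """
    if not batch:
        raise ConfigurationError("empty batch")
    w = config.weights
    if w.uses_flow:
        for s in batch:
            if s.f_ct_prev is None and s.f_ct_next is None:
                raise ConfigurationError(
                    f"variant {w.variant} needs precomputed flows; sample "
                    f"{s.patient_id}[{s.index}] has none")
    if lr is not None:
        state.opt_g.lr = state.opt_d.lr = lr

    mr = ad.Tensor(_stack_net([s.mr for s in batch]))
    ct = ad.Tensor(_stack_net([s.ct for s in batch]))

    # -- generator update (discriminators frozen: their params get no step)
    state.zero_grads()
    sct = state.g_ct(mr)
    smr = state.g_mr(ct)
    rec_ct = state.g_ct(smr)
    rec_mr = state.g_mr(sct)

    gan = L.lsgan_generator_loss(state.d_mr(smr), state.d_ct(sct))
    cyc = L.cycle_loss(ct, rec_ct, mr, rec_mr)
    terms: dict[str, object] = {"gan": gan, "cycle": cyc}
    if w.uses_ssim:
        terms["ssim"] = L.ssim_loss((ct + 1.0) * 0.5, (sct + 1.0) * 0.5,
                                    (mr + 1.0) * 0.5, (smr + 1.0) * 0.5,
                                    config.ssim)
    if w.uses_flow:
        ct_terms, mr_terms = [], []
        for i, s in enumerate(batch):
            ct_terms.append(L.flow_loss(
                sct[i, 0],
                None if s.ct_prev is None else u16_to_net(s.ct_prev),
                None if s.ct_next is None else u16_to_net(s.ct_next),
                s.f_ct_prev, s.f_ct_next))
            mr_terms.append(L.flow_loss(
                smr[i, 0],
                None if s.mr_prev is None else u16_to_net(s.mr_prev),
                None if s.mr_next is None else u16_to_net(s.mr_next),
                s.f_mr_prev, s.f_mr_next))
        flow_ct = L._mean_of(ct_terms)
        flow_mr = L._mean_of(mr_terms)
        terms["flow"] = (flow_ct + flow_mr) * 0.5

    g_net = L.generator_net_loss(terms, w)
    g_net.backward()
    state.opt_g.step()

    # -- discriminator update with buffer-mediated fakes
    state.zero_grads()
    fake_ct = state.buffer_ct.query(sct.data)
    fake_mr = state.buffer_mr.query(smr.data)
    d_ct_loss = L.discriminator_loss(state.d_ct(ct.detach()),
                                     state.d_ct(ad.Tensor(fake_ct)))
    d_mr_loss = L.discriminator_loss(state.d_mr(mr.detach()),
                                     state.d_mr(ad.Tensor(fake_mr)))
    d_net = L.discriminator_net_loss(d_ct_loss, d_mr_loss)
    d_net.backward()
    state.opt_d.step()
    state.zero_grads()

    record = {"gan": float(gan), "cycle": float(cyc),
              "g_net": float(g_net), "d_ct": float(d_ct_loss),
              "d_mr": float(d_mr_loss), "d_net": float(d_net)}
    if w.uses_ssim:
        record["ssim"] = float(terms["ssim"])
    if w.uses_flow:
        record["flow"] = float(terms["flow"])
    return record


def train(config: TrainConfig, dataset: list[Sample],
          out_dir: str | Path | None = None,
          state: GanState | None = None,
          log_file: str | Path | None = None
          ) -> tuple[GanState, list[dict]]:
    """Run the full schedule over a slice dataset.

    Shuffling is epoch-seeded from the config seed; per-epoch means of
    every loss term are returned (and appended to ``log_file`` as JSON
    lines when given).  Checkpoints go to ``out_dir`` every
    ``checkpoint_every`` epochs plus at the end.  Passing a ``state``
    restored by `load_checkpoint` resumes mid-run bit-identically.
    """
    if not dataset:
        raise ConfigurationError("empty dataset")
    if state is None:
        state = init_state(config)
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    history: list[dict] = []
    for epoch in range(state.epoch + 1, config.epochs + 1):
        lr = lr_at_epoch(epoch, config)
        order = np.random.default_rng(
            [config.seed, epoch]).permutation(len(dataset))
        sums: dict[str, float] = {}
        n_steps = 0
        for start in range(0, len(order), config.batch_size):
            batch = [dataset[i] for i in order[start:start
                                               + config.batch_size]]
            record = train_step(batch, state, config, lr=lr)
            for k, v in record.items():
                sums[k] = sums.get(k, 0.0) + v
            n_steps += 1
        epoch_log = {k: v / n_steps for k, v in sums.items()}
        epoch_log.update(epoch=epoch, lr=lr, n_steps=n_steps)
        history.append(epoch_log)
        state.epoch = epoch
        if log_file is not None:
            with open(log_file, "a") as fh:
                fh.write(json.dumps(epoch_log) + "\n")
        if out is not None and config.checkpoint_every and \
                epoch % config.checkpoint_every == 0:
            save_checkpoint(state, config, out / f"epoch_{epoch:04d}.npz")
    if out is not None:
        save_checkpoint(state, config, out / "final.npz")
    return state, history


# ---------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------

def _config_hash(config: TrainConfig) -> str:
    from .config import _to_plain
    return hashlib.sha256(
        yaml.safe_dump(_to_plain(config)).encode()).hexdigest()[:16]


def save_checkpoint(state: GanState, config: TrainConfig,
                    path: str | Path) -> None:
    arrays: dict[str, np.ndarray] = {}
    for name, net in (("g_ct", state.g_ct), ("g_mr", state.g_mr),
                      ("d_ct", state.d_ct), ("d_mr", state.d_mr)):
        for k, v in net.state_dict().items():
            arrays[f"{name}.{k}"] = v
    for name, opt in (("opt_g", state.opt_g), ("opt_d", state.opt_d)):
        for k, v in opt.state_dict().items():
            arrays[f"{name}.{k}"] = np.asarray(v)
    for name, buf in (("buf_ct", state.buffer_ct),
                      ("buf_mr", state.buffer_mr)):
        if buf.images:
            arrays[f"{name}.images"] = np.stack(buf.images)
        arrays[f"{name}.rng"] = np.frombuffer(
            json.dumps(buf.rng.bit_generator.state).encode(), dtype=np.uint8)
    arrays["epoch"] = np.asarray(state.epoch)
    arrays["config_hash"] = np.frombuffer(
        _config_hash(config).encode(), dtype=np.uint8)
    np.savez_compressed(path, **arrays)


def load_checkpoint(path: str | Path, config: TrainConfig,
                    strict_hash: bool = True) -> GanState:
    """Rebuild a GanState from a checkpoint written by `save_checkpoint`."""
    state = init_state(config)
    with np.load(path) as data:
        stored_hash = bytes(data["config_hash"]).decode()
        if strict_hash and stored_hash != _config_hash(config):
            raise ConfigurationError(
                "checkpoint was written under a different configuration")
        for name, net in (("g_ct", state.g_ct), ("g_mr", state.g_mr),
                          ("d_ct", state.d_ct), ("d_mr", state.d_mr)):
            sd = {k.split(".", 1)[1]: data[k] for k in data.files
                  if k.startswith(name + ".")}
            net.load_state_dict(sd)
        for name, opt in (("opt_g", state.opt_g), ("opt_d", state.opt_d)):
            sd = {k.split(".", 1)[1]: data[k] for k in data.files
                  if k.startswith(name + ".")}
            opt.load_state_dict(sd)
        for name, buf in (("buf_ct", state.buffer_ct),
                          ("buf_mr", state.buffer_mr)):
            key = f"{name}.images"
            buf.images = [img for img in data[key]] if key in data.files \
                else []
            buf.rng.bit_generator.state = json.loads(
                bytes(data[f"{name}.rng"]).decode())
        state.epoch = int(data["epoch"])
    return state


def synthesize_volume(generator: ResNetGenerator,
                      v: NormalizedVolume) -> np.ndarray:
    """Translate a normalized volume slice-by-slice; returns uint16."""
    out = np.empty_like(v.slices)
    for n in range(v.slices.shape[0]):
        x = u16_to_net(v.slices[n])[None, None]
        out[n] = net_to_u16(generator(ad.Tensor(x)).data[0, 0])
    return out
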