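"""Generator and discriminator architectures for MR<->CT translation.

Both directions share one design: the generator is the canonical
residual translation network (7x7 stem, two stride-2 downsamplings,
`n_res` residual blocks at 4x base width, two upsamplings, 7x7 head,
tanh output), and the discriminator is a stack of five 4x4 stride-2
convolutional blocks (64 -> 128 -> 256 -> 512 channels, instance norm +
leaky ReLU slope 0.2 after every block but the last) whose final
1-channel map is squashed through a sigmoid and spatially averaged to
one real/synthetic score per image in [0, 1].

Networks operate on slices rescaled from the 16-bit data range
[0, 65535] to [-1, 1]; `u16_to_net` / `net_to_u16` perform that
(invertible, affine) change of scale.

All weights are zero-mean Gaussian (sigma = 0.02) draws from a seeded
generator, so construction is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = ["GeneratorSpec", "DiscriminatorSpec", "build_generator",
           "build_discriminator", "ResNetGenerator", "PatchDiscriminator",
           "Adam", "u16_to_net", "net_to_u16"]

U16_MAX = 65535.0


def u16_to_net(x: np.ndarray) -> np.ndarray:
    """[0, 65535] -> [-1, 1] (float32)."""
    return (np.asarray(x, dtype=np.float32) / (U16_MAX / 2.0)) - 1.0


def net_to_u16(x: np.ndarray) -> np.ndarray:
    """[-1, 1] -> [0, 65535], clipped and rounded to integers."""
    return np.rint(np.clip((np.asarray(x) + 1.0) * (U16_MAX / 2.0),
                           0.0, U16_MAX)).astype(np.uint16)


@dataclass(frozen=True)
class GeneratorSpec:
    """Residual encoder-decoder generator: role is MR->sCT or CT->sMR."""

    role: str = "G_CT"          # {"G_CT": MR->sCT, "G_MR": CT->sMR}
    in_channels: int = 1
    out_channels: int = 1
    ngf: int = 64
    n_res: int = 9

    def __post_init__(self):
        if self.role not in ("G_CT", "G_MR"):
            raise ValueError(f"unknown generator role {self.role!r}")
        if self.ngf < 1 or self.n_res < 1:
            raise ValueError("ngf and n_res must be positive")


@dataclass(frozen=True)
class DiscriminatorSpec:
    """Five-block convolutional discriminator with scalar [0, 1] output."""

    role: str = "D_CT"
    in_channels: int = 1
    ndf: int = 64
    n_blocks: int = 5
    negative_slope: float = 0.2
    patch_output: bool = False  # True: return the score map unaveraged

    def __post_init__(self):
        if self.role not in ("D_CT", "D_MR"):
            raise ValueError(f"unknown discriminator role {self.role!r}")


class Conv2d:
    def __init__(self, rng: np.random.Generator, c_in: int, c_out: int,
                 k: int, stride: int = 1, padding: int = 0,
                 dtype=np.float32):
        self.w = Tensor(rng.normal(0.0, 0.02, (c_out, c_in, k, k))
                        .astype(dtype), requires_grad=True)
        self.b = Tensor(np.zeros(c_out, dtype=dtype), requires_grad=True)
        self.stride, self.padding = stride, padding

    def __call__(self, x: Tensor) -> Tensor:
        return ad.conv2d(x, self.w, self.b, self.stride, self.padding)

    @property
    def params(self):
        return [self.w, self.b]


class ResBlock:
    """Two 3x3 convolutions with instance norm; identity skip."""

    def __init__(self, rng, channels: int):
        self.c1 = Conv2d(rng, channels, channels, 3, 1, 1)
        self.c2 = Conv2d(rng, channels, channels, 3, 1, 1)

    def __call__(self, x: Tensor) -> Tensor:
        h = ad.relu(ad.instance_norm(self.c1(x)))
        h = ad.instance_norm(self.c2(h))
        return x + h

    @property
    def params(self):
        return self.c1.params + self.c2.params


class _Module:
    """Minimal parameter container with named state for checkpoints."""

    def parameters(self) -> list[Tensor]:
        raise NotImplementedError

    def state_dict(self) -> dict[str, np.ndarray]:
        return {f"p{i}": p.data for i, p in enumerate(self.parameters())}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        if len(state) != len(params):
            raise ValueError("checkpoint parameter count mismatch")
        for i, p in enumerate(params):
            arr = np.asarray(state[f"p{i}"])
            if arr.shape != p.data.shape:
                raise ValueError(f"parameter {i} shape mismatch")
            p.data = arr.astype(p.data.dtype)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()


class ResNetGenerator(_Module):
    def __init__(self, spec: GeneratorSpec, seed: int):
        rng = np.random.default_rng(seed)
        self.spec = spec
        g = spec.ngf
        self.stem = Conv2d(rng, spec.in_channels, g, 7, 1, 3)
        self.down1 = Conv2d(rng, g, 2 * g, 3, 2, 1)
        self.down2 = Conv2d(rng, 2 * g, 4 * g, 3, 2, 1)
        self.res_blocks = [ResBlock(rng, 4 * g) for _ in range(spec.n_res)]
        self.up1 = Conv2d(rng, 4 * g, 2 * g, 3, 1, 1)
        self.up2 = Conv2d(rng, 2 * g, g, 3, 1, 1)
        self.head = Conv2d(rng, g, spec.out_channels, 7, 1, 3)

    def __call__(self, x) -> Tensor:
        x = ad.as_tensor(x)
        if x.ndim != 4:
            raise ValueError("generator expects (B, C, H, W) input")
        h = ad.relu(ad.instance_norm(self.stem(x)))
        h = ad.relu(ad.instance_norm(self.down1(h)))
        h = ad.relu(ad.instance_norm(self.down2(h)))
        for block in self.res_blocks:
            h = block(h)
        h = ad.relu(ad.instance_norm(self.up1(ad.upsample2x(h))))
        h = ad.relu(ad.instance_norm(self.up2(ad.upsample2x(h))))
        return ad.tanh(self.head(h))

    def parameters(self):
        out = (self.stem.params + self.down1.params + self.down2.params)
        for b in self.res_blocks:
            out += b.params
        return out + self.up1.params + self.up2.params + self.head.params


class PatchDiscriminator(_Module):
    def __init__(self, spec: DiscriminatorSpec, seed: int):
        rng = np.random.default_rng(seed)
        self.spec = spec
        self.blocks: list[Conv2d] = []
        self.channel_progression: list[int] = []
        c_in = spec.in_channels
        c_out = spec.ndf
        for _ in range(spec.n_blocks - 1):
            self.blocks.append(Conv2d(rng, c_in, c_out, 4, 2, 1))
            self.channel_progression.append(c_out)
            c_in, c_out = c_out, 2 * c_out
        self.final = Conv2d(rng, c_in, 1, 4, 1, 1)

    def __call__(self, x) -> Tensor:
        x = ad.as_tensor(x)
        if x.ndim != 4:
            raise ValueError("discriminator expects (B, C, H, W) input")
        h = x
        for block in self.blocks:
            h = ad.leaky_relu(ad.instance_norm(block(h)),
                              self.spec.negative_slope)
        score_map = ad.sigmoid(self.final(h))          # (B, 1, h, w)
        if self.spec.patch_output:
            return score_map
        return _mean_axis1(score_map.reshape(score_map.shape[0], -1))

    def parameters(self):
        out: list[Tensor] = []
        for b in self.blocks:
            out += b.params
        return out + self.final.params


def _mean_axis1(flat: Tensor) -> Tensor:
    """Row-wise mean of a (B, N) tensor, returning shape (B,)."""
    B, n = flat.shape
    out = flat.data.mean(axis=1)

    def bwd(g):
        ad._acc(flat, np.repeat((g / n)[:, None], n, axis=1))
    return Tensor(out, parents=(flat,), backward=bwd)


def build_generator(spec: GeneratorSpec, seed: int) -> ResNetGenerator:
    """Seeded construction of a generator; same seed -> same weights."""
    return ResNetGenerator(spec, seed)


def build_discriminator(spec: DiscriminatorSpec,
                        seed: int) -> PatchDiscriminator:
    """Seeded construction of a discriminator."""
    return PatchDiscriminator(spec, seed)


class Adam:
    """Adam with the beta_1 = 0.5 convention common to this GAN family."""

    def __init__(self, params: list[Tensor], lr: float = 2e-4,
                 betas: tuple[float, float] = (0.5, 0.999),
                 eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad.astype(p.data.dtype, copy=False)
            m *= self.b1; m += (1 - self.b1) * g
            v *= self.b2; v += (1 - self.b2) * g * g
            p.data = p.data - self.lr * (m / b1t) / (np.sqrt(v / b2t)
                                                     + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def state_dict(self) -> dict:
        out = {"t": np.asarray(self.t)}
        for i, (m, v) in enumerate(zip(self.m, self.v)):
            out[f"m{i}"] = m
            out[f"v{i}"] = v
        return out

    def load_state_dict(self, state: dict) -> None:
        self.t = int(state["t"])
        self.m = [np.asarray(state[f"m{i}"]) for i in range(len(self.m))]
        self.v = [np.asarray(state[f"v{i}"]) for i in range(len(self.v))]
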