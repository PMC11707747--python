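"""Network modules for the virtual stainer: U-Net generator, discriminators.

All weights are Glorot-uniform initialized from a seeded generator, so a
(config, seed) pair fully determines the network.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor


class Module:
    """Base: tracks parameter tensors for the optimizer and checkpoints."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def state_arrays(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.parameters()]

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError("state array count mismatch")
        for p, a in zip(params, arrays):
            if p.value.shape != a.shape:
                raise ValueError("state shape mismatch")
            p.value = a.astype(np.float64).copy()

    def weight_sq_norm(self) -> Tensor:
        terms = [ad.total(ad.square(p)) for p in self.parameters()]
        out = terms[0]
        for t in terms[1:]:
            out = out + t
        return out


class Conv(Module):
    def __init__(self, rng, cin, cout, k=3, stride=1, padding="same"):
        self.w = Tensor(ad.glorot_uniform(rng, (k, k, cin, cout)), requires_grad=True)
        self.b = Tensor(np.zeros(cout), requires_grad=True)
        self.stride = stride
        self.padding = padding

    def __call__(self, x):
        return ad.conv2d(x, self.w, self.b, stride=self.stride, padding=self.padding)


class UNetGenerator(Module):
    """Small U-Net: conv/downsample encoder, skip connections, upsample decoder.

    ``depth`` pooling stages; spatial dims must be divisible by 2**depth.
    The output is a linear (unbounded) map with ``out_channels`` planes —
    the regression losses operate on pIHC/H&E intensities directly.
    """

    def __init__(
        self,
        rng: np.random.Generator,
        in_channels: int = 20,
        out_channels: int = 3,
        base_filters: int = 16,
        depth: int = 2,
        kernel: int = 3,
    ):
        self.depth = depth
        self.enc = []
        cin = in_channels
        f = base_filters
        for _ in range(depth):
            self.enc.append(Conv(rng, cin, f, kernel))
            cin = f
            f *= 2
        self.bottleneck = Conv(rng, cin, f, kernel)
        self.dec = []
        cup = f
        for d in reversed(range(depth)):
            skip_c = base_filters * (2**d)
            self.dec.append(Conv(rng, cup + skip_c, skip_c, kernel))
            cup = skip_c
        self.head = Conv(rng, cup, out_channels, 1)

    def __call__(self, x) -> Tensor:
        x = ad.as_tensor(x)
        skips = []
        h = x
        for conv in self.enc:
            h = ad.leaky_relu(conv(h))
            skips.append(h)
            h = ad.avg_pool2(h)
        h = ad.leaky_relu(self.bottleneck(h))
        for conv, skip in zip(self.dec, reversed(skips)):
            h = ad.upsample_nearest2(h)
            h = ad.leaky_relu(conv(ad.concat([h, skip], axis=-1)))
        return self.head(h)


class PatchDiscriminator(Module):
    """Strided conv stack ending in a single real/fake logit per image."""

    def __init__(
        self,
        rng: np.random.Generator,
        in_channels: int,
        base_filters: int = 8,
        n_layers: int = 2,
        kernel: int = 3,
    ):
        self.convs = []
        cin = in_channels
        f = base_filters
        for _ in range(n_layers):
            self.convs.append(Conv(rng, cin, f, kernel, stride=2))
            cin = f
            f *= 2
        self.head = Conv(rng, cin, 1, 1)

    def __call__(self, x) -> Tensor:
        h = ad.as_tensor(x)
        for conv in self.convs:
            h = ad.leaky_relu(conv(h))
        logits = self.head(h)  # (N, h', w', 1)
        return ad.mean(logits)  # scalar mean logit over batch and patches
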