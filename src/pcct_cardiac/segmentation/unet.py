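"""A compact 2D U-Net in numpy.

Encoder-decoder with skip connections: two 3x3 conv + ReLU per level, 2x2
max pooling on the way down, nearest-neighbor upsampling plus 3x3 conv and
channel concatenation on the way up, and a 1x1 sigmoid output head.  Default
desk scale is 3 resolution levels and 8 base channels on 64x64 inputs;
depth/width are configurable.  Forward stores the caches needed for the
manual backward pass, which returns gradients for all parameters given the
gradient of the loss with respect to the output probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn

__all__ = ["UNetConfig", "UNet2D"]


@dataclass(frozen=True)
class UNetConfig:
    in_channels: int = 1
    base_channels: int = 8
    levels: int = 3  # encoder levels incl. bottleneck
    image_size: int = 64

    def __post_init__(self):
        if self.image_size % (2 ** (self.levels - 1)):
            raise ValueError("image size must be divisible by 2^(levels-1)")


class UNet2D:
    def __init__(self, config: UNetConfig = UNetConfig(), seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        p: dict[str, np.ndarray] = {}
        ch = [config.in_channels] + [
            config.base_channels * 2**i for i in range(config.levels)
        ]
        # encoder (last entry acts as bottleneck)
        for i in range(config.levels):
            p[f"e{i}_w1"] = nn.he_init(rng, ch[i + 1], ch[i], 3)
            p[f"e{i}_b1"] = np.zeros(ch[i + 1])
            p[f"e{i}_w2"] = nn.he_init(rng, ch[i + 1], ch[i + 1], 3)
            p[f"e{i}_b2"] = np.zeros(ch[i + 1])
        # decoder
        for i in range(config.levels - 2, -1, -1):
            p[f"u{i}_w"] = nn.he_init(rng, ch[i + 1], ch[i + 2], 3)
            p[f"u{i}_b"] = np.zeros(ch[i + 1])
            p[f"d{i}_w1"] = nn.he_init(rng, ch[i + 1], 2 * ch[i + 1], 3)
            p[f"d{i}_b1"] = np.zeros(ch[i + 1])
            p[f"d{i}_w2"] = nn.he_init(rng, ch[i + 1], ch[i + 1], 3)
            p[f"d{i}_b2"] = np.zeros(ch[i + 1])
        p["out_w"] = nn.he_init(rng, 1, ch[1], 1)
        p["out_b"] = np.zeros(1)
        self.params = p
        self._cache = None

    # -- forward -----------------------------------------------------------
    def _double_conv(self, x, prefix, caches):
        p = self.params
        z1, c1 = nn.conv2d(x, p[f"{prefix}_w1"], p[f"{prefix}_b1"])
        a1 = nn.relu(z1)
        z2, c2 = nn.conv2d(a1, p[f"{prefix}_w2"], p[f"{prefix}_b2"])
        a2 = nn.relu(z2)
        caches[prefix] = (c1, z1, c2, z2)
        return a2

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        """(B, C, H, W) -> per-voxel probabilities (B, 1, H, W)."""
        L = self.config.levels
        caches: dict = {}
        skips = []
        h = x
        for i in range(L):
            h = self._double_conv(h, f"e{i}", caches)
            if i < L - 1:
                skips.append(h)
                h, pc = nn.maxpool2(h)
                caches[f"pool{i}"] = pc
        for i in range(L - 2, -1, -1):
            up = nn.upsample2(h)
            z, c = nn.conv2d(up, self.params[f"u{i}_w"], self.params[f"u{i}_b"])
            a = nn.relu(z)
            caches[f"u{i}"] = (c, z, up.shape)
            h = np.concatenate([skips[i], a], axis=1)
            caches[f"cat{i}"] = skips[i].shape[1]
            h = self._double_conv(h, f"d{i}", caches)
        z, c = nn.conv2d(h, self.params["out_w"], self.params["out_b"])
        caches["out"] = c
        probs = np.where(z >= 0, 1.0 / (1.0 + np.exp(-np.abs(z))),
                         np.exp(-np.abs(z)) / (1.0 + np.exp(-np.abs(z))))
        if train:
            self._cache = (caches, probs)
        return probs

    # -- backward ----------------------------------------------------------
    def _double_conv_back(self, d, prefix, caches, grads):
        c1, z1, c2, z2 = caches[prefix]
        d = nn.relu_backward(d, z2)
        d, dw2, db2 = nn.conv2d_backward(d, c2, self.params[f"{prefix}_w2"])
        grads[f"{prefix}_w2"] = dw2
        grads[f"{prefix}_b2"] = db2
        d = nn.relu_backward(d, z1)
        d, dw1, db1 = nn.conv2d_backward(d, c1, self.params[f"{prefix}_w1"])
        grads[f"{prefix}_w1"] = dw1
        grads[f"{prefix}_b1"] = db1
        return d

    def backward(self, dprobs: np.ndarray) -> dict:
        """Parameter gradients given dLoss/dprobs from the last forward."""
        if self._cache is None:
            raise RuntimeError("forward(train=True) must precede backward")
        caches, probs = self._cache
        L = self.config.levels
        grads: dict[str, np.ndarray] = {}
        dz = dprobs * probs * (1 - probs)
        d, dw, db = nn.conv2d_backward(dz, caches["out"], self.params["out_w"])
        grads["out_w"] = dw
        grads["out_b"] = db
        dskips = {}
        for i in range(0, L - 1):
            d = self._double_conv_back(d, f"d{i}", caches, grads)
            ns = caches[f"cat{i}"]
            dskip, da = d[:, :ns], d[:, ns:]
            dskips[i] = dskip
            c, z, upshape = caches[f"u{i}"]
            da = nn.relu_backward(da, z)
            da, dw, db = nn.conv2d_backward(da, c, self.params[f"u{i}_w"])
            grads[f"u{i}_w"] = dw
            grads[f"u{i}_b"] = db
            d = nn.upsample2_backward(da)
        for i in range(L - 1, -1, -1):
            if i < L - 1:
                d = nn.maxpool2_backward(d, caches[f"pool{i}"])
                d = d + dskips[i]
            d = self._double_conv_back(d, f"e{i}", caches, grads)
        return grads

    # -- persistence -------------------------------------------------------
    def state_dict(self) -> dict:
        return {k: v.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict):
        for k in self.params:
            self.params[k] = state[k].copy()

    def save(self, path):
        np.savez(path, **self.params,
                 _config=np.array([self.config.in_channels,
                                   self.config.base_channels,
                                   self.config.levels,
                                   self.config.image_size]))

    @classmethod
    def load(cls, path) -> "UNet2D":
        data = np.load(path)
        cin, base, levels, size = (int(v) for v in data["_config"])
        model = cls(UNetConfig(cin, base, levels, size))
        model.load_state_dict({k: data[k] for k in model.params})
        return model
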