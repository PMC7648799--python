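"""Configurable U-Net-style encoder-decoder backbone.

Each encoding unit is two 3x3 convolutions (padding 1, stride 1), each
followed by batch normalization and a rectifying activation, and ends in
2x2 max pooling; the number of feature channels doubles per level from
``base_channels`` (32 at the defaults, giving 32..1024 over six levels).
Each decoding unit bilinearly upsamples its input, concatenates the skip
connection from the encoding unit of the same level, and applies three
3x3 convolutions down to that level's channel count.  A final 1x1
convolution maps the first level's channels to the prediction classes
and a sigmoid yields independent per-class probability maps (no softmax:
mutual exclusivity is imposed only at postprocessing).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .layers import BatchNorm2d, BilinearUp2, Conv2d, MaxPool2, ReLU, Sigmoid

__all__ = ["NetConfig", "UNet", "build_network"]


@dataclass(frozen=True)
class NetConfig:
    levels: int = 6
    base_channels: int = 32
    n_classes: int = 1
    in_channels: int = 1

    def __post_init__(self) -> None:
        if self.levels < 1:
            raise ValueError("levels must be >= 1")
        if self.base_channels < 1 or self.n_classes < 1:
            raise ValueError("base_channels and n_classes must be >= 1")

    def channels(self, level: int) -> int:
        """Feature channels of the encoding/decoding unit at ``level`` (1-based)."""
        return self.base_channels * 2 ** (level - 1)


def _conv_bn_relu(cin: int, cout: int, rng: np.random.Generator, name: str,
                  needs_input_grad: bool = True):
    return [
        Conv2d(cin, cout, 3, rng, name, needs_input_grad=needs_input_grad),
        BatchNorm2d(cout, name=name),
        ReLU(),
    ]


class UNet:
    def __init__(self, cfg: NetConfig, rng: np.random.Generator | int = 0) -> None:
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        self.cfg = cfg
        L = cfg.levels
        self.enc_blocks: list[list] = []
        self.pools: list[MaxPool2] = []
        cin = cfg.in_channels
        for lvl in range(1, L + 1):
            c = cfg.channels(lvl)
            # the very first convolution never needs a gradient for its input
            block = _conv_bn_relu(
                cin, c, rng, f"enc{lvl}a", needs_input_grad=lvl > 1
            ) + _conv_bn_relu(c, c, rng, f"enc{lvl}b")
            self.enc_blocks.append(block)
            self.pools.append(MaxPool2())
            cin = c
        # decoder level lvl consumes the running feature map (channels of
        # level lvl+1, or of level L for the first decoder which consumes
        # the pooled bottom) upsampled + the level-lvl skip
        self.ups: list[BilinearUp2] = []
        self.dec_blocks: list[list] = []
        prev = cfg.channels(L)
        for lvl in range(L, 0, -1):
            c = cfg.channels(lvl)
            block = (
                _conv_bn_relu(prev + c, c, rng, f"dec{lvl}a")
                + _conv_bn_relu(c, c, rng, f"dec{lvl}b")
                + _conv_bn_relu(c, c, rng, f"dec{lvl}c")
            )
            self.ups.append(BilinearUp2())
            self.dec_blocks.append(block)
            prev = c
        self.head = Conv2d(cfg.base_channels, cfg.n_classes, 1, rng, "head")
        # start the sigmoid outputs low (~0.12): organ classes cover a
        # small fraction of each slice, and a large initial sum of
        # probabilities drowns the soft-Dice gradient of small classes
        self.head.bias.value[...] = -2.0
        self.sigmoid = Sigmoid()
        self._cache_splits: list[int] = []

    # -- parameter access ------------------------------------------------
    def params(self):
        out = []
        for block in self.enc_blocks + self.dec_blocks:
            for layer in block:
                out.extend(layer.params())
        out.extend(self.head.params())
        return out

    def n_parameters(self) -> int:
        return int(sum(p.value.size for p in self.params()))

    def zero_grad(self) -> None:
        for p in self.params():
            p.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {f"p{i}": p.value.copy() for i, p in enumerate(self.params())}
        for i, block in enumerate(self.enc_blocks + self.dec_blocks):
            for j, layer in enumerate(block):
                if isinstance(layer, BatchNorm2d):
                    state[f"rm{i}_{j}"] = layer.running_mean.copy()
                    state[f"rv{i}_{j}"] = layer.running_var.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.params()):
            p.value[...] = state[f"p{i}"]
        for i, block in enumerate(self.enc_blocks + self.dec_blocks):
            for j, layer in enumerate(block):
                if isinstance(layer, BatchNorm2d):
                    layer.running_mean[...] = state[f"rm{i}_{j}"]
                    layer.running_var[...] = state[f"rv{i}_{j}"]

    # -- forward / backward ----------------------------------------------
    def _check_shape(self, x: np.ndarray) -> None:
        div = 2 ** self.cfg.levels
        h, w = x.shape[2], x.shape[3]
        if h % div or w % div:
            raise ValueError(
                f"input spatial dims {h}x{w} must be divisible by 2^levels = "
                f"{div}; pad the input (e.g. with pad_to_divisible)"
            )

    def forward(self, x: np.ndarray, train: bool = False,
                return_logits: bool = False) -> np.ndarray:
        """Map (N, 1, H, W) images to (N, n_classes, H, W) probabilities
        (or pre-sigmoid logits with ``return_logits``; the sigmoid is
        monotone, so ranking logits avoids float saturation at p = 1)."""
        x = np.asarray(x, dtype=np.float32)
        if x.ndim != 4 or x.shape[1] != self.cfg.in_channels:
            raise ValueError(f"expected (N, {self.cfg.in_channels}, H, W) input")
        self._check_shape(x)
        feats = x
        skips = []
        for block, pool in zip(self.enc_blocks, self.pools):
            for layer in block:
                feats = layer.forward(feats, train)
            skips.append(feats)
            feats = pool.forward(feats, train)
        self._cache_splits = []
        for up, block, skip in zip(self.ups, self.dec_blocks, reversed(skips)):
            feats = up.forward(feats, train)
            self._cache_splits.append(feats.shape[1])
            feats = np.concatenate([feats, skip], axis=1)
            for layer in block:
                feats = layer.forward(feats, train)
        logits = self.head.forward(feats, train)
        if return_logits:
            return logits
        return self.sigmoid.forward(logits, train)

    def backward(self, gprobs: np.ndarray) -> None:
        """Accumulate parameter gradients for d(loss)/d(probabilities)."""
        g = self.sigmoid.backward(gprobs)
        g = self.head.backward(g)
        skip_grads: list[np.ndarray] = []
        for up, block, split in zip(
            reversed(self.ups), reversed(self.dec_blocks), reversed(self._cache_splits)
        ):
            for layer in reversed(block):
                g = layer.backward(g)
            gup, gskip = g[:, :split], g[:, split:]
            skip_grads.append(gskip)
            g = up.backward(np.ascontiguousarray(gup))
        # skip_grads[k] belongs to encoder level k+1 (they were collected
        # walking decoders from level 1 upward)
        for block, pool, gskip in zip(
            reversed(self.enc_blocks), reversed(self.pools), reversed(skip_grads)
        ):
            g = pool.backward(g) + gskip
            for layer in reversed(block):
                g = layer.backward(g)


def build_network(cfg: NetConfig, rng: np.random.Generator | int = 0) -> UNet:
    return UNet(cfg, rng)
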