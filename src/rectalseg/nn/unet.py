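"""3D encoder-decoder segmentation network (U-Net style), pure NumPy.

Structure per resolution level (channel width doubles per level):

* encoder: a convolution block (conv + batch norm + ReLU; kernel 3x3x3 or
  1x3x3, configurable per level) preceded, below the top level, by a
  strided 3x3x3 convolution block (stride 2) for downsampling;
* decoder: a 4x4x4 transposed-convolution block (stride 2) for
  upsampling, a 1x1x1 convolution block on the skip connection, channel
  concatenation, and a fusing convolution block;
* head: a 1x1x1 convolution to 3 channels followed by a per-channel
  sigmoid (multi-label: tumor and rectum overlap by design).

Output channel order is fixed: ``(tumor, rectum, mesorectum)``.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np

from ..core import ProbMaps, ValidationError, VoxelGrid
from . import functional as F
from .layers import Conv3d, ConvBlock, DeconvBlock, _Sequential

__all__ = ["NetworkConfig", "UNet3D", "build_network", "forward_volume"]

Kernel = tuple[int, int, int]


def _default_kernels(levels: int) -> tuple[Kernel, ...]:
    # Thin through-plane kernel at the top (full-resolution) level, cubic below.
    return ((1, 3, 3),) + ((3, 3, 3),) * (levels - 1)


@dataclass
class NetworkConfig:
    """Architecture hyperparameters.

    ``conv_kernel_per_level`` selects 1x3x3 or 3x3x3 for the stride-1
    convolution blocks of each level; downsampling convolutions are always
    3x3x3 (stride 2) and upsampling kernels fixed at 4x4x4.
    """

    levels: int = 4
    base_channels: int = 16
    conv_kernel_per_level: Optional[tuple[Kernel, ...]] = None
    deconv_kernel: int = 4
    in_channels: int = 1
    out_channels: int = 3
    bn_momentum: float = 0.1
    bn_eps: float = 1e-5

    def __post_init__(self) -> None:
        if self.levels < 2:
            raise ValidationError(f"levels must be >= 2, got {self.levels}")
        if self.base_channels < 1:
            raise ValidationError(f"base_channels must be >= 1, got {self.base_channels}")
        if self.out_channels != 3:
            raise ValidationError("out_channels is fixed at 3 (tumor, rectum, mesorectum)")
        if self.deconv_kernel != 4:
            raise ValidationError("deconv_kernel is fixed at 4")
        if self.conv_kernel_per_level is None:
            self.conv_kernel_per_level = _default_kernels(self.levels)
        else:
            self.conv_kernel_per_level = tuple(
                tuple(k) for k in self.conv_kernel_per_level  # type: ignore[arg-type]
            )
            if len(self.conv_kernel_per_level) != self.levels:
                raise ValidationError(
                    f"need one kernel per level ({self.levels}), got "
                    f"{len(self.conv_kernel_per_level)}"
                )
            for k in self.conv_kernel_per_level:
                if tuple(k) not in ((1, 3, 3), (3, 3, 3)):
                    raise ValidationError(f"conv kernels must be 1x3x3 or 3x3x3, got {k}")

    @property
    def channels(self) -> tuple[int, ...]:
        return tuple(self.base_channels * 2**l for l in range(self.levels))

    def to_dict(self) -> dict:
        return {
            "levels": self.levels,
            "base_channels": self.base_channels,
            "conv_kernel_per_level": [list(k) for k in self.conv_kernel_per_level],
            "deconv_kernel": self.deconv_kernel,
            "in_channels": self.in_channels,
            "out_channels": self.out_channels,
            "bn_momentum": self.bn_momentum,
            "bn_eps": self.bn_eps,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        d = dict(d)
        if d.get("conv_kernel_per_level") is not None:
            d["conv_kernel_per_level"] = tuple(tuple(k) for k in d["conv_kernel_per_level"])
        return cls(**d)


class UNet3D:
    """Encoder-decoder network; see the module docstring for the layout."""

    def __init__(self, config: NetworkConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        ch = config.channels
        kw = dict(rng=rng, bn_momentum=config.bn_momentum, bn_eps=config.bn_eps)
        kernels = config.conv_kernel_per_level

        self.blocks: dict[str, _Sequential] = {}
        self.blocks["enc0"] = ConvBlock(config.in_channels, ch[0], kernels[0], **kw)
        for l in range(1, config.levels):
            self.blocks[f"down{l}"] = ConvBlock(ch[l - 1], ch[l], (3, 3, 3), stride=2, **kw)
            self.blocks[f"enc{l}"] = ConvBlock(ch[l], ch[l], kernels[l], **kw)
        for l in range(config.levels - 2, -1, -1):
            self.blocks[f"up{l}"] = DeconvBlock(ch[l + 1], ch[l], kernel=config.deconv_kernel, **kw)
            self.blocks[f"skip{l}"] = ConvBlock(ch[l], ch[l], (1, 1, 1), **kw)
            self.blocks[f"fuse{l}"] = ConvBlock(2 * ch[l], ch[l], kernels[l], **kw)
        self.blocks["head"] = _Sequential(
            Conv3d(ch[0], config.out_channels, (1, 1, 1), rng=rng)
        )
        self._probs = None

    # -- parameter plumbing -------------------------------------------------
    def _leaf_layers(self):
        for bname, block in self.blocks.items():
            parts = block.parts if isinstance(block, _Sequential) else (block,)
            for i, layer in enumerate(parts):
                if layer.param_names:
                    yield f"{bname}.{i}", layer

    def named_params(self) -> dict[str, np.ndarray]:
        out = {}
        for lname, layer in self._leaf_layers():
            for pname, arr in layer.params().items():
                out[f"{lname}.{pname}"] = arr
        return out

    def named_grads(self) -> dict[str, np.ndarray]:
        out = {}
        for lname, layer in self._leaf_layers():
            for pname in layer.param_names:
                out[f"{lname}.{pname}"] = getattr(layer, "g_" + pname)
        return out

    def num_params(self) -> int:
        return sum(a.size for a in self.named_params().values())

    def state_dict(self) -> dict[str, np.ndarray]:
        out = {}
        for lname, layer in self._leaf_layers():
            for sname, arr in layer.state().items():
                out[f"{lname}.{sname}"] = arr.copy()
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for lname, layer in self._leaf_layers():
            sub = {
                sname: state[f"{lname}.{sname}"]
                for sname in layer.state()
            }
            layer.load_state(sub)

    # -- forward / backward -------------------------------------------------
    def _check_input(self, x: np.ndarray) -> None:
        div = 2 ** (self.config.levels - 1)
        for axis, n in enumerate(x.shape[2:]):
            if n % div:
                raise ValidationError(
                    f"input axis {axis} has length {n}, not divisible by "
                    f"2^(levels-1) = {div}"
                )

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """Map ``(B, 1, D, H, W)`` to per-voxel probabilities ``(B, 3, D, H, W)``."""
        x = np.asarray(x, dtype=np.float32)
        if x.ndim != 5 or x.shape[1] != self.config.in_channels:
            raise ValidationError(f"expected (B, {self.config.in_channels}, D, H, W), got {x.shape}")
        self._check_input(x)
        L = self.config.levels
        feats = [self.blocks["enc0"].forward(x, training)]
        for l in range(1, L):
            d = self.blocks[f"down{l}"].forward(feats[-1], training)
            feats.append(self.blocks[f"enc{l}"].forward(d, training))
        y = feats[-1]
        self._skip_channels = []
        for l in range(L - 2, -1, -1):
            u = self.blocks[f"up{l}"].forward(y, training)
            s = self.blocks[f"skip{l}"].forward(feats[l], training)
            self._skip_channels.append(u.shape[1])
            y = np.concatenate([u, s], axis=1)
            y = self.blocks[f"fuse{l}"].forward(y, training)
        logits = self.blocks["head"].forward(y, training)
        probs = F.sigmoid_forward(logits)
        if training:
            self._probs = probs
        return probs

    def backward(self, gprobs: np.ndarray) -> None:
        """Backpropagate a gradient w.r.t. the output probabilities."""
        if self._probs is None:
            raise RuntimeError("backward called without a training-mode forward")
        gy = F.sigmoid_backward(gprobs.astype(np.float32), self._probs)
        gy = self.blocks["head"].backward(gy)
        L = self.config.levels
        genc = [None] * L  # gradient w.r.t. each encoder feature
        for i, l in enumerate(range(0, L - 1)):
            gy = self.blocks[f"fuse{l}"].backward(gy)
            cu = self._skip_channels[L - 2 - l]
            gu, gs = gy[:, :cu], gy[:, cu:]
            genc[l] = self.blocks[f"skip{l}"].backward(np.ascontiguousarray(gs))
            gy = self.blocks[f"up{l}"].backward(np.ascontiguousarray(gu))
        # gy is now the gradient w.r.t. the bottleneck feature
        for l in range(L - 1, 0, -1):
            gy = self.blocks[f"enc{l}"].backward(gy)
            gy = self.blocks[f"down{l}"].backward(gy)
            gy = gy + genc[l - 1]
        self.blocks["enc0"].backward(gy)
        self._probs = None

    # -- persistence ---------------------------------------------------------
    def save(self, path: Union[str, os.PathLike]) -> None:
        """Checkpoint: weights, BN statistics and the embedded config."""
        arrays = self.state_dict()
        arrays["__config__"] = np.frombuffer(
            json.dumps(self.config.to_dict()).encode(), dtype=np.uint8
        )
        np.savez(os.fspath(path), **arrays)

    @classmethod
    def load(cls, path: Union[str, os.PathLike]) -> "UNet3D":
        with np.load(os.fspath(path)) as data:
            cfg = NetworkConfig.from_dict(json.loads(bytes(data["__config__"]).decode()))
            net = cls(cfg, seed=0)
            net.load_state_dict({k: data[k] for k in data.files if k != "__config__"})
        return net


def build_network(config: Optional[NetworkConfig] = None, seed: int = 0) -> UNet3D:
    """Construct a randomly initialized network from a config."""
    return UNet3D(config or NetworkConfig(), seed=seed)


def forward_volume(net: UNet3D, grid: VoxelGrid) -> ProbMaps:
    """Run inference on one volume; returns (tumor, rectum, mesorectum) maps."""
    x = np.asarray(grid.values, dtype=np.float32)[None, None]
    probs = net.forward(x, training=False)[0]
    return ProbMaps.from_stack(np.clip(probs.astype(np.float64), 0.0, 1.0))
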