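"""Layer objects with explicit forward/backward and in-place parameters."""

from __future__ import annotations

import numpy as np

from . import functional as F

__all__ = ["Conv3d", "ConvTranspose3d", "BatchNorm3d", "ReLU", "ConvBlock", "DeconvBlock"]


class Layer:
    """Base: parameters and their gradients are attributes of matching names."""

    param_names: tuple[str, ...] = ()

    def params(self) -> dict[str, np.ndarray]:
        return {n: getattr(self, n) for n in self.param_names}

    def grads(self) -> dict[str, np.ndarray]:
        return {"g_" + n: getattr(self, "g_" + n) for n in self.param_names}

    def state(self) -> dict[str, np.ndarray]:
        """Everything needed to restore the layer (params + buffers)."""
        return self.params()

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        for n, v in state.items():
            getattr(self, n)[...] = v


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


class Conv3d(Layer):
    param_names = ("w", "b")

    def __init__(self, cin: int, cout: int, kernel, stride=1, rng: np.random.Generator = None):
        kernel = (kernel,) * 3 if np.isscalar(kernel) else tuple(kernel)
        self.stride = stride
        self.pad = tuple(k // 2 for k in kernel)  # "same" padding for stride 1
        fan_in = cin * int(np.prod(kernel))
        self.w = _he_init(rng, (cout, cin, *kernel), fan_in)
        self.b = np.zeros(cout, dtype=np.float32)
        self.g_w = np.zeros_like(self.w)
        self.g_b = np.zeros_like(self.b)
        self._x = None

    def forward(self, x, training: bool):
        if training:
            self._x = x
        return F.conv3d_forward(x, self.w, self.b, self.stride, self.pad)

    def backward(self, gy):
        gx, gw, gb = F.conv3d_backward(self._x, self.w, gy, self.stride, self.pad)
        self.g_w[...] = gw
        self.g_b[...] = gb
        self._x = None
        return gx


class ConvTranspose3d(Layer):
    param_names = ("w", "b")

    def __init__(self, cin: int, cout: int, kernel=4, stride=2, pad=1, rng=None):
        kernel = (kernel,) * 3 if np.isscalar(kernel) else tuple(kernel)
        self.stride = stride
        self.pad = pad
        fan_in = cin * int(np.prod(kernel))
        self.w = _he_init(rng, (cin, cout, *kernel), fan_in)
        self.b = np.zeros(cout, dtype=np.float32)
        self.g_w = np.zeros_like(self.w)
        self.g_b = np.zeros_like(self.b)
        self._x = None

    def forward(self, x, training: bool):
        if training:
            self._x = x
        return F.convtranspose3d_forward(x, self.w, self.b, self.stride, self.pad)

    def backward(self, gy):
        gx, gw, gb = F.convtranspose3d_backward(self._x, self.w, gy, self.stride, self.pad)
        self.g_w[...] = gw
        self.g_b[...] = gb
        self._x = None
        return gx


class BatchNorm3d(Layer):
    param_names = ("gamma", "beta")

    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = np.ones(c, dtype=np.float32)
        self.beta = np.zeros(c, dtype=np.float32)
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps
        self.g_gamma = np.zeros_like(self.gamma)
        self.g_beta = np.zeros_like(self.beta)
        self._cache = None

    def forward(self, x, training: bool):
        y, cache = F.batchnorm_forward(
            x, self.gamma, self.beta, self.running_mean, self.running_var,
            training, self.momentum, self.eps,
        )
        if training:
            self._cache = cache
        return y

    def backward(self, gy):
        gx, ggamma, gbeta = F.batchnorm_backward(gy, self._cache)
        self.g_gamma[...] = ggamma
        self.g_beta[...] = gbeta
        self._cache = None
        return gx

    def state(self):
        return {**self.params(), "running_mean": self.running_mean, "running_var": self.running_var}


class ReLU(Layer):
    def __init__(self):
        self._mask = None

    def forward(self, x, training: bool):
        y, mask = F.relu_forward(x)
        if training:
            self._mask = mask
        return y

    def backward(self, gy):
        gx = F.relu_backward(gy, self._mask)
        self._mask = None
        return gx


class _Sequential(Layer):
    def __init__(self, *parts):
        self.parts = parts

    def forward(self, x, training: bool):
        for p in self.parts:
            x = p.forward(x, training)
        return x

    def backward(self, gy):
        for p in reversed(self.parts):
            gy = p.backward(gy)
        return gy


class ConvBlock(_Sequential):
    """Convolution + batch normalization + ReLU."""

    def __init__(self, cin, cout, kernel, stride=1, rng=None, bn_momentum=0.1, bn_eps=1e-5):
        super().__init__(
            Conv3d(cin, cout, kernel, stride=stride, rng=rng),
            BatchNorm3d(cout, momentum=bn_momentum, eps=bn_eps),
            ReLU(),
        )


class DeconvBlock(_Sequential):
    """Transposed convolution (4x4x4, stride 2) + batch normalization + ReLU."""

    def __init__(self, cin, cout, kernel=4, rng=None, bn_momentum=0.1, bn_eps=1e-5):
        super().__init__(
            ConvTranspose3d(cin, cout, kernel=kernel, stride=2, pad=1, rng=rng),
            BatchNorm3d(cout, momentum=bn_momentum, eps=bn_eps),
            ReLU(),
        )
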