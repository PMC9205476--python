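"""Shape contracts, determinism, gradient correctness and equivariance."""

import numpy as np
import pytest

from rectalseg.core import SegLabels, StageLabel, ValidationError
from rectalseg.losses import LossConfig, combined_loss_grad
from rectalseg.nn import NetworkConfig, UNet3D, build_network


def _promote_to_float64(net: UNet3D) -> None:
    for _, layer in net._leaf_layers():
        for attr, v in list(vars(layer).items()):
            if isinstance(v, np.ndarray) and v.dtype == np.float32:
                setattr(layer, attr, v.astype(np.float64))


class TestArchitecture:
    @pytest.mark.parametrize(
        "levels,base,size",
        [(2, 4, 8), (3, 8, 16)],
    )
    def test_output_shape_matches_input(self, levels, base, size, rng):
        net = build_network(NetworkConfig(levels=levels, base_channels=base), seed=0)
        x = rng.normal(size=(1, 1, size, size, size)).astype(np.float32)
        y = net.forward(x)
        assert y.shape == (1, 3, size, size, size)
        assert 0.0 <= y.min() and y.max() <= 1.0

    def test_deterministic_inference(self, rng):
        net = build_network(NetworkConfig(levels=2, base_channels=4), seed=1)
        x = rng.normal(size=(1, 1, 8, 8, 8)).astype(np.float32)
        np.testing.assert_array_equal(net.forward(x), net.forward(x))

    def test_parameter_count_increases_with_width(self):
        n_small = build_network(NetworkConfig(levels=2, base_channels=2)).num_params()
        n_large = build_network(NetworkConfig(levels=2, base_channels=4)).num_params()
        assert n_large > n_small

    def test_indivisible_input_names_axis(self):
        net = build_network(NetworkConfig(levels=3, base_channels=2))
        with pytest.raises(ValidationError, match="axis 0"):
            net.forward(np.zeros((1, 1, 10, 16, 16), dtype=np.float32))

    def test_invalid_configs(self):
        with pytest.raises(ValidationError):
            NetworkConfig(levels=1)
        with pytest.raises(ValidationError):
            NetworkConfig(out_channels=2)
        with pytest.raises(ValidationError):
            NetworkConfig(levels=2, conv_kernel_per_level=((5, 5, 5), (3, 3, 3)))

    def test_checkpoint_round_trip(self, tmp_path, rng):
        net = build_network(NetworkConfig(levels=2, base_channels=3), seed=5)
        x = rng.normal(size=(1, 1, 8, 8, 8)).astype(np.float32)
        y = net.forward(x)
        path = tmp_path / "weights.npz"
        net.save(path)
        net2 = UNet3D.load(path)
        assert net2.config == net.config
        np.testing.assert_array_equal(net2.forward(x), y)


class TestGradients:
    def test_gradient_reaches_every_parameter(self, rng):
        net = build_network(NetworkConfig(levels=2, base_channels=2), seed=2)
        x = rng.normal(size=(2, 1, 8, 8, 8)).astype(np.float32)
        y = net.forward(x, training=True)
        net.backward(rng.normal(size=y.shape).astype(np.float32))
        for name, g in net.named_grads().items():
            if name.endswith(".b") and ".head" not in name:
                continue  # conv bias feeding batch norm: gradient is exactly zero
            assert np.linalg.norm(g) > 0, f"dead parameter tensor: {name}"

    def test_backprop_matches_finite_differences(self, rng):
        """End-to-end gradient check of the full network + combined loss."""
        net = build_network(NetworkConfig(levels=2, base_channels=2), seed=3)
        _promote_to_float64(net)
        x = rng.normal(size=(1, 1, 4, 4, 4))
        labels = SegLabels.from_stack(rng.random((3, 4, 4, 4)) > 0.5)
        stage = StageLabel.t3()
        cfg = LossConfig(lam=0.1)

        def loss_and_grad():
            p = net.forward(x, training=True)
            v, g = combined_loss_grad(p[0], labels, stage, cfg)
            return v, g[None]

        _, gout = loss_and_grad()
        net.backward(gout)
        analytic = {k: v.copy() for k, v in net.named_grads().items()}
        eps = 1e-4
        checked = 0
        for name, arr in net.named_params().items():
            flat = arr.ravel()
            for i in rng.choice(flat.size, size=min(3, flat.size), replace=False):
                orig = flat[i]
                flat[i] = orig + eps
                vp, _ = loss_and_grad()
                flat[i] = orig - eps
                vm, _ = loss_and_grad()
                flat[i] = orig
                numeric = (vp - vm) / (2 * eps)
                assert analytic[name].ravel()[i] == pytest.approx(
                    numeric, abs=2e-4, rel=2e-2
                ), f"gradient mismatch in {name}"
                checked += 1
        assert checked > 30


class TestEquivariance:
    def test_translation_consistency_on_constant_background(self, rng):
        """Shifting the input by the downsampling factor shifts the output."""
        cfg = NetworkConfig(levels=2, base_channels=4)
        net = build_network(cfg, seed=4)
        shift = 2 ** (cfg.levels - 1)
        size = 40
        x1 = np.zeros((1, 1, size, size, size), dtype=np.float32)
        x1[0, 0, 12:18, 16:22, 16:22] = 1.0
        x2 = np.roll(x1, shift, axis=2)
        y1 = net.forward(x1)
        y2 = net.forward(x2)
        m = 14  # margin excludes boundary effects of zero padding
        np.testing.assert_allclose(
            y2[:, :, m + shift : size - m, m:-m, m:-m],
            y1[:, :, m : size - m - shift, m:-m, m:-m],
            atol=1e-5,
        )
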