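"""U-Net structure, gradients, training behavior and inference wrapper."""

import numpy as np
import pytest

from radcine.dealias import (
    TrainConfig,
    UNetConfig,
    build_unet,
    complex_to_plane,
    count_parameters,
    dealias,
    learning_rate,
    load_checkpoint,
    plane_to_complex,
    save_checkpoint,
    train_unet,
)
from radcine.synthsim import TrainingPair


class TestPlaneRepresentation:
    def test_round_trip_exact(self, rng):
        z = (
            rng.standard_normal((6, 6, 4)) + 1j * rng.standard_normal((6, 6, 4))
        ).astype(np.complex64)
        back = plane_to_complex(complex_to_plane(z))
        assert np.array_equal(back.astype(np.complex64), z)

    def test_purely_real_input_has_zero_lower_half(self, rng):
        z = rng.standard_normal((4, 4, 2)).astype(complex)
        p = complex_to_plane(z)
        assert np.all(p[4:] == 0)

    def test_published_shape(self):
        z = np.zeros((144, 144, 20), dtype=complex)
        assert complex_to_plane(z).shape == (288, 144, 20)

    def test_odd_first_extent_rejected(self):
        with pytest.raises(ValueError):
            plane_to_complex(np.zeros((7, 4, 2), dtype=np.float32))


class TestSchedule:
    def test_published_learning_rates(self):
        cfg = TrainConfig()
        assert learning_rate(0, cfg) == pytest.approx(0.001)
        assert learning_rate(100, cfg) == pytest.approx(0.00095)
        assert learning_rate(2900, cfg) == pytest.approx(0.001 * 0.95**29)

    def test_piecewise_constant(self):
        cfg = TrainConfig()
        assert learning_rate(99, cfg) == learning_rate(0, cfg)
        assert learning_rate(101, cfg) == learning_rate(100, cfg)


class TestArchitecture:
    def test_shape_preservation(self, rng):
        net = build_unet(UNetConfig(base_channels=4), seed=0)
        x = rng.standard_normal((1, 1, 32, 16, 8)).astype(np.float32)
        assert net.forward(x).shape == x.shape

    def test_parameter_count_matches_symbolic_oracle(self):
        net = build_unet(UNetConfig(base_channels=4), seed=0)
        assert net.n_parameters() == count_parameters(4)

    def test_indivisible_extent_rejected(self):
        net = build_unet(UNetConfig(base_channels=4), seed=0)
        with pytest.raises(ValueError):
            net.forward(np.zeros((1, 1, 30, 16, 8), dtype=np.float32))

    def test_analytic_gradients_match_finite_differences(self, rng):
        # dropout off so the forward pass is deterministic in training mode
        net = build_unet(UNetConfig(base_channels=2, dropout_rate=0.0), seed=1)
        x = rng.standard_normal((2, 1, 8, 8, 4)).astype(np.float32)
        target = rng.standard_normal((2, 1, 8, 8, 4)).astype(np.float32)

        def loss():
            return float(np.mean((net.forward(x, training=True) - target) ** 2))

        resid = net.forward(x, training=True) - target
        net.backward((2.0 / resid.size) * resid)
        checked = 0
        for _, layer, name in net.parameters():
            par = layer.params[name]
            idx = tuple(rng.integers(0, s) for s in par.shape)
            grad = float(layer.grads[name][idx])
            if abs(grad) < 1e-4:
                continue  # conv biases are absorbed by batch-norm
            eps = 1e-2
            old = float(par[idx])
            par[idx] = old + eps
            f1 = loss()
            par[idx] = old - eps
            f2 = loss()
            par[idx] = old
            fd = (f1 - f2) / (2 * eps)
            assert grad == pytest.approx(fd, rel=0.15, abs=1e-4)
            checked += 1
            if checked >= 6:
                break
        assert checked >= 3


def _toy_pairs(rng, n_pairs=4, n=8, nt=4):
    pairs = []
    for _ in range(n_pairs):
        target = rng.standard_normal((n, n, nt)) + 1j * rng.standard_normal((n, n, nt))
        noise = 0.3 * (
            rng.standard_normal((n, n, nt)) + 1j * rng.standard_normal((n, n, nt))
        )
        pairs.append(
            TrainingPair(input=target + noise, target=target, norm_constant=1.0)
        )
    return pairs


class TestTraining:
    def test_overfit_single_pair_loss_decreases(self, rng):
        pairs = _toy_pairs(rng, n_pairs=1)
        net, trace = train_unet(
            pairs,
            UNetConfig(base_channels=4, dropout_rate=0.0),
            TrainConfig(batch_size=1, iterations=150, lr0=1e-3, seed=0),
        )
        losses = np.array([t[2] for t in trace])
        windows = losses.reshape(3, 50).mean(axis=1)
        assert windows[1] < windows[0]
        assert windows[2] < windows[1]

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            train_unet([], UNetConfig(base_channels=2), TrainConfig(batch_size=1))

    def test_batch_larger_than_sources_rejected(self, rng):
        with pytest.raises(ValueError):
            train_unet(
                _toy_pairs(rng, n_pairs=2),
                UNetConfig(base_channels=2),
                TrainConfig(batch_size=4, iterations=1),
            )

    def test_training_is_seeded(self, rng):
        pairs = _toy_pairs(rng, n_pairs=2)
        cfg = TrainConfig(batch_size=2, iterations=5, seed=42)
        _, tr1 = train_unet(pairs, UNetConfig(base_channels=2), cfg)
        _, tr2 = train_unet(pairs, UNetConfig(base_channels=2), cfg)
        assert tr1 == tr2


class TestInference:
    def test_deterministic_and_shape_preserving(self, rng):
        net = build_unet(UNetConfig(base_channels=2), seed=0)
        cine = rng.standard_normal((8, 8, 4)) + 1j * rng.standard_normal((8, 8, 4))
        a = dealias(cine, net)
        b = dealias(cine, net)
        assert a.shape == cine.shape
        assert np.array_equal(a, b)

    def test_pads_indivisible_extents(self, rng):
        net = build_unet(UNetConfig(base_channels=2), seed=0)
        cine = rng.standard_normal((10, 10, 5)) + 1j * rng.standard_normal((10, 10, 5))
        out = dealias(cine, net)
        assert out.shape == cine.shape

    def test_output_phase_nontrivial(self, rng):
        net = build_unet(UNetConfig(base_channels=2), seed=0)
        cine = np.exp(1j * rng.uniform(-3, 3, (8, 8, 4))) * rng.uniform(
            0.5, 2.0, (8, 8, 4)
        )
        out = dealias(cine, net)
        assert np.angle(out[np.abs(out) > 1e-9]).std() > 1e-3

    def test_zero_input_rejected(self):
        net = build_unet(UNetConfig(base_channels=2), seed=0)
        with pytest.raises(ValueError):
            dealias(np.zeros((8, 8, 4), dtype=complex), net)


class TestCheckpoint:
    def test_round_trip_preserves_outputs(self, rng, tmp_path):
        pairs = _toy_pairs(rng, n_pairs=2)
        net, _ = train_unet(
            pairs,
            UNetConfig(base_channels=2),
            TrainConfig(batch_size=2, iterations=10, seed=0),
        )
        path = str(tmp_path / "ckpt.npz")
        save_checkpoint(path, net, extra={"note": 1})
        loaded, extra = load_checkpoint(path)
        assert extra == {"note": 1}
        x = rng.standard_normal((1, 1, 8, 8, 4)).astype(np.float32)
        assert np.array_equal(net.forward(x), loaded.forward(x))
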