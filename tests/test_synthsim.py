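"""Training-pair synthesis: resampling, aliasing, cropping, normalization."""

import json

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from radcine.phantom import PhantomConfig, make_cardiac_phantom
from radcine.synthsim import (
    build_training_set,
    crop_or_pad,
    load_training_set,
    make_training_pair,
    norm_constant_of,
    normalize_pair,
    resample_cine,
    simulate_aliasing,
)


class TestResample:
    def test_identity(self, rng):
        x = rng.standard_normal((16, 16, 5)) + 1j * rng.standard_normal((16, 16, 5))
        out = resample_cine(x, 2.0, 37.7, 2.0, 37.7)
        assert np.abs(out - x).max() < 1e-10

    def test_constant_in_time_unchanged_by_temporal_resampling(self, rng):
        frame = rng.standard_normal((16, 16)) + 0j
        x = np.repeat(frame[..., None], 6, axis=-1)
        out = resample_cine(x, 2.0, 20.0, 2.0, 33.0)
        assert np.allclose(out, frame[..., None])

    def test_downsample_matches_fourier_truncation_oracle(self, rng):
        # band-limited input: random spectrum supported on the coarse band
        n_src, n_dst = 32, 16
        spectrum = np.zeros((n_src, n_src), dtype=complex)
        lo = n_src // 2 - n_dst // 2
        band = rng.standard_normal((n_dst, n_dst)) + 1j * rng.standard_normal(
            (n_dst, n_dst)
        )
        spectrum[lo : lo + n_dst, lo : lo + n_dst] = band
        img = np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(spectrum)))
        # oracle: direct truncation of the k-space to the destination grid
        oracle = np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(band))) * (
            n_dst**2 / n_src**2
        )
        out = resample_cine(img[..., None], 1.0, 37.7, 2.0, 37.7)[..., 0]
        assert np.abs(out - oracle).max() < 1e-8

    def test_bad_spacing_rejected(self, rng):
        with pytest.raises(ValueError):
            resample_cine(np.zeros((8, 8, 2)), -1.0, 37.7)


class TestSimulateAliasing:
    def test_fully_sampled_limit(self, small_phantom):
        mc = small_phantom.multicoil[..., :2]
        n = mc.shape[1]
        dense = simulate_aliasing(mc, spokes_per_frame=101, psi=180 / 101)
        nrmse = np.linalg.norm(np.abs(dense) - np.abs(mc)) / np.linalg.norm(mc)
        assert nrmse < 0.05

    def test_twelve_spokes_produce_visible_streaks(self, small_phantom):
        mc = small_phantom.multicoil[..., :2]
        aliased = simulate_aliasing(mc, spokes_per_frame=12)
        nrmse = np.linalg.norm(np.abs(aliased) - np.abs(mc)) / np.linalg.norm(mc)
        assert nrmse > 0.15

    def test_linearity(self, rng):
        x = rng.standard_normal((24, 24, 2)) + 1j * rng.standard_normal((24, 24, 2))
        y = rng.standard_normal((24, 24, 2)) + 1j * rng.standard_normal((24, 24, 2))
        fa = simulate_aliasing(2.0 * x + 1j * y, 6)
        fb = 2.0 * simulate_aliasing(x, 6) + 1j * simulate_aliasing(y, 6)
        assert np.linalg.norm(fa - fb) / np.linalg.norm(fb) < 1e-10

    def test_shape_preserved(self, small_phantom):
        mc = small_phantom.multicoil[..., :2]
        assert simulate_aliasing(mc, 12).shape == mc.shape


class TestCropOrPad:
    def test_exact_length_forces_zero_offset(self, rng):
        x = np.zeros((150, 150, 20), dtype=complex)
        out, start = crop_or_pad(x, 144, 20, rng)
        assert out.shape == (144, 144, 20)
        assert start == 0

    def test_offset_uniform_over_seeds(self):
        starts = {
            crop_or_pad(
                np.zeros((8, 8, 30)), 8, 20, np.random.default_rng(seed)
            )[1]
            for seed in range(200)
        }
        assert starts == set(range(11))  # all offsets 0..10 reachable

    def test_cyclic_padding(self):
        x = np.arange(15, dtype=float).reshape(1, 1, 15) * np.ones((8, 8, 1))
        out, _ = crop_or_pad(x, 8, 20)
        assert np.array_equal(out[0, 0, :15], np.arange(15))
        assert np.array_equal(out[0, 0, 15:], np.arange(5))

    def test_small_grid_zero_padded(self):
        x = np.ones((8, 8, 4), dtype=complex)
        out, _ = crop_or_pad(x, 12, 4)
        assert out.shape == (12, 12, 4)
        assert out[0, 0, 0] == 0 and out[6, 6, 0] == 1

    @given(n_t=st.integers(1, 40))
    @settings(max_examples=20, deadline=None)
    def test_output_always_target_length(self, n_t):
        out, _ = crop_or_pad(
            np.ones((8, 8, n_t)), 8, 20, np.random.default_rng(0)
        )
        assert out.shape[-1] == 20


class TestNormalize:
    def test_constant_magnitude(self):
        x = 3.0 * np.exp(1j * 0.4) * np.ones((64, 64, 4))
        pair = normalize_pair(x, x.copy())
        assert pair.norm_constant == pytest.approx(3.0)
        assert np.abs(np.abs(pair.input) - 1.0).max() < 1e-12

    def test_only_central_region_counts(self, rng):
        x = rng.uniform(0.5, 1.0, (64, 64, 3)) + 0j
        c1 = norm_constant_of(x)
        y = x.copy()
        y[:5, :, :] = 100.0  # far outside the central 48x48
        assert norm_constant_of(y) == pytest.approx(c1)

    def test_percentile_interpolation_oracle(self):
        # central region holds exactly the values 1..100 -> 95.05
        x = np.zeros((10, 10, 1))
        x[...] = np.arange(1.0, 101.0).reshape(10, 10, 1)
        assert norm_constant_of(x) == pytest.approx(95.05)

    def test_idempotent_at_pair_level(self, small_phantom):
        pair = make_training_pair(
            PhantomConfig(matrix_size=48, n_frames=8, n_coils=2, seed=5),
            target_xy=48,
            target_t=8,
        )
        again = normalize_pair(pair.input, pair.target)
        assert again.norm_constant == pytest.approx(1.0, abs=0.05)

    def test_zero_input_rejected(self):
        with pytest.raises(ValueError):
            normalize_pair(np.zeros((8, 8, 2)), np.zeros((8, 8, 2)))


class TestTrainingSet:
    def test_pair_input_converges_to_target_with_dense_spokes(self):
        cfg = PhantomConfig(matrix_size=48, n_frames=4, n_coils=2, seed=5, noise_sd=0.0)
        pair = make_training_pair(
            cfg, spokes_per_frame=80, psi=180 / 80, target_xy=48, target_t=4
        )
        err = np.linalg.norm(pair.input - pair.target) / np.linalg.norm(pair.target)
        assert err < 0.06

    def test_build_persists_manifest_and_is_deterministic(self, tmp_path):
        cfgs = [
            PhantomConfig(matrix_size=48, n_frames=4, n_coils=2, seed=s)
            for s in (1, 2)
        ]
        d1, d2 = str(tmp_path / "a"), str(tmp_path / "b")
        m1 = build_training_set(cfgs, d1, target_xy=48, target_t=4, seed=3)
        m2 = build_training_set(cfgs, d2, target_xy=48, target_t=4, seed=3)
        with open(m1) as fh:
            man1 = json.load(fh)
        with open(m2) as fh:
            man2 = json.load(fh)
        assert man1 == man2
        pairs = load_training_set(d1)
        assert len(pairs) == 2
        assert pairs[0].input.shape == (48, 48, 4)
        again = load_training_set(d2)
        assert np.array_equal(pairs[0].input, again[0].input)

    def test_empty_source_list_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            build_training_set([], str(tmp_path / "x"))
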