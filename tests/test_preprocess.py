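import numpy as np
import pytest

from gliadyn import preprocess as pp
from gliadyn import segment as seg
from gliadyn import simulate as sim
from gliadyn.io_blind import GREEN, RED, TwoChannelStack
from tests.conftest import layer_config


def _stack(green, red, **cal):
    data = np.stack([green, red], axis=-1).astype(np.float64)
    return TwoChannelStack(data, **cal)


class TestBackground:
    def test_constant_frame_becomes_zero(self):
        g = np.full((2, 2, 8, 8), 37.0)
        out = pp.subtract_background(_stack(g, g), GREEN)
        assert np.all(out.data[..., GREEN] == 0)

    def test_object_preserved(self):
        g = np.full((1, 1, 16, 16), 10.0)
        g[0, 0, 5:8, 5:8] = 10.0 + 123.0
        out = pp.subtract_background(_stack(g, g), GREEN)
        assert np.allclose(out.data[0, 0, 5:8, 5:8, GREEN], 123.0)

    def test_output_nonnegative(self, rng):
        g = rng.random((2, 3, 10, 10)) * 100
        out = pp.subtract_background(_stack(g, g), GREEN, percentile=50)
        assert out.data[..., GREEN].min() >= 0

    def test_bad_channel(self):
        g = np.zeros((1, 1, 4, 4))
        with pytest.raises(ValueError):
            pp.subtract_background(_stack(g, g), 2)


class TestBleedthrough:
    def test_exact_proportional_green_goes_to_zero(self, rng):
        red = rng.random((2, 2, 32, 32)) * 1000
        green = 0.3 * red
        out, beta = pp.correct_bleedthrough(_stack(green, red))
        assert beta == pytest.approx(0.3, abs=1e-6)
        assert np.allclose(out.data[..., GREEN], 0, atol=1e-6)

    def test_zero_bleed_estimates_near_zero(self):
        cfg = layer_config(seed=1, n_t=2, bleed_coeff=0.0)
        _, stack = sim.simulate_animal(cfg)
        work = pp.subtract_background(stack, GREEN)
        work = pp.subtract_background(work, RED)
        _, beta = pp.correct_bleedthrough(work)
        assert beta == pytest.approx(0.0, abs=0.02)

    def test_simulated_bleed_recovered_noiseless(self):
        cfg = layer_config(seed=2, n_t=2, bleed_coeff=0.2, gaussian_sd=0.0,
                           poisson_scale=0.0)
        gt, stack = sim.simulate_animal(cfg)
        work = pp.subtract_background(stack, GREEN)
        work = pp.subtract_background(work, RED)
        out, beta = pp.correct_bleedthrough(work)
        assert 0.18 <= beta <= 0.22
        true_green = (
            gt.masks["mg_process"] * sim.I_MG_PROCESS
            + gt.masks["mg_soma"] * sim.I_MG_SOMA
        )
        corr = np.corrcoef(out.data[..., GREEN].ravel(), true_green.ravel())[0, 1]
        assert corr >= 0.99

    def test_red_channel_never_modified(self, rng):
        red = rng.random((1, 2, 16, 16)) * 500
        green = 0.2 * red + rng.random((1, 2, 16, 16))
        stack = _stack(green, red)
        out, _ = pp.correct_bleedthrough(stack)
        assert np.array_equal(out.data[..., RED], stack.data[..., RED])

    def test_all_zero_red_warns_and_passes_through(self):
        green = np.random.default_rng(0).random((1, 1, 8, 8))
        red = np.zeros((1, 1, 8, 8))
        with pytest.warns(UserWarning, match="red channel"):
            out, beta = pp.correct_bleedthrough(_stack(green, red))
        assert beta == 0.0
        assert np.array_equal(out.data[..., GREEN], green)


class TestPcaDenoise:
    def test_identity_at_full_variance(self, rng):
        g = rng.random((2, 3, 8, 8)) * 100
        stack = _stack(g, g)
        out, k = pp.pca_denoise(stack, GREEN, variance_keep=1.0)
        assert np.allclose(out.data[..., GREEN], g, atol=1e-8)

    def test_rank1_movie_mse_decreases(self, rng):
        base = rng.random((16, 16))
        weights = np.linspace(1, 2, 12)
        truth = weights[:, None, None] * base[None] * 50
        noisy = truth + rng.normal(0, 3, truth.shape)
        noisy = np.clip(noisy, 0, None)
        stack = _stack(noisy[:, None], noisy[:, None])
        out, k = pp.pca_denoise(stack, GREEN, variance_keep=0.9)
        den = out.data[:, 0, :, :, GREEN]
        assert np.mean((den - truth) ** 2) < np.mean((noisy - truth) ** 2)

    def test_k_monotone_in_variance_keep(self, rng):
        g = rng.random((4, 3, 10, 10)) * 10
        stack = _stack(g, g)
        ks = [pp.pca_denoise(stack, GREEN, vk)[1] for vk in (1.0, 0.9, 0.5, 0.2)]
        assert all(a >= b for a, b in zip(ks, ks[1:]))

    def test_constant_stack_returned_unchanged(self):
        g = np.full((2, 2, 6, 6), 5.0)
        out, k = pp.pca_denoise(_stack(g, g), GREEN, 0.9)
        assert k == 0
        assert np.array_equal(out.data[..., GREEN], g)

    def test_invalid_variance_keep(self):
        g = np.zeros((2, 2, 4, 4))
        with pytest.raises(ValueError):
            pp.pca_denoise(_stack(g, g), GREEN, 0.0)


class TestLayerSeparation:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_simulated_boundary_within_two_slices(self, seed):
        cfg = layer_config(seed=seed)
        gt, stack = sim.simulate_animal(cfg)
        r_px = 5.0 / cfg.pixel_size_um
        areas = seg.soma_area_profile(
            stack.data[0, ..., RED], min_size=int(0.5 * np.pi * r_px**2)
        )
        la = pp.separate_layers(
            soma_area_per_z=areas, soma_radius_um=5.0,
            pixel_size_um=cfg.pixel_size_um,
        )
        assert abs(la.pcl_start_z - gt.layer_boundary_z) <= 2

    def test_manual_override_exact(self):
        la = pp.separate_layers(manual_pcl_start=50, n_z=101)
        assert la.pcl_start_z == 50
        assert la.ml_slices() == slice(0, 50)
        assert la.pcl_slices() == slice(50, 101)

    def test_harmonization_takes_minimum(self):
        mk = lambda start, nz: pp.LayerAssignment(start, 0, nz)
        arr = [mk(55, 100), mk(60, 100), mk(58, 100)]
        pp.harmonize_layers(arr)
        assert all(a.harmonized_ml_n == 55 for a in arr)
        assert arr[1].ml_slices() == slice(5, 60)

    def test_no_somas_instructs_override(self):
        with pytest.raises(ValueError, match="manual_pcl_start"):
            pp.separate_layers(soma_area_per_z=np.zeros(30))

    def test_harmonized_count_cannot_exceed_available(self):
        with pytest.raises(ValueError):
            pp.LayerAssignment(10, 0, 20, harmonized_ml_n=11)
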