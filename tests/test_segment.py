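import numpy as np
import pytest
from scipy import ndimage

from gliadyn import preprocess as pp
from gliadyn import segment as seg
from gliadyn import simulate as sim
from gliadyn.io_blind import GREEN, RED
from tests.conftest import jaccard, layer_config

EIGHT = np.ones((3, 3), dtype=bool)


class TestBinarize:
    def test_size_exclusion_keeps_large_blob(self):
        vol = np.zeros((10, 20, 20))
        vol[1:6, 1:11, 1:11] = 100.0  # 500 voxels
        vol[8, 15:19, 15:20] = 100.0  # 20 voxels
        mask = seg.binarize(vol, min_size=50, threshold=50.0)
        _, n = ndimage.label(mask, structure=np.ones((3, 3, 3)))
        assert n == 1
        assert mask[1:6, 1:11, 1:11].all()

    def test_uniform_zero_gives_empty(self):
        assert not seg.binarize(np.zeros((4, 8, 8))).any()

    def test_otsu_splits_two_delta_peaks(self):
        vol = np.zeros((1, 10, 10))
        vol[0, :5] = 10.0
        vol[0, 5:] = 200.0
        mask = seg.binarize(vol)
        assert mask[0, 5:].all() and not mask[0, :5].any()

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            seg.binarize(np.array([[-1.0, 2.0]]))


class TestSplitSomaProcess:
    def test_sphere_and_filament(self):
        mask = np.zeros((64, 64), bool)
        yy, xx = np.ogrid[-12:13, -12:13]
        mask[20:45, 20:45][(yy**2 + xx**2) <= 144] = True  # soma disk
        mask[32, 45:60] = True  # 1-px filament
        soma, proc = seg.split_soma_process(mask, r_soma_px=6)
        assert soma[32, 32]
        assert proc[32, 48:60].all()
        assert not soma[32, 50:].any()

    def test_thin_only_empty_soma(self):
        mask = np.zeros((32, 32), bool)
        mask[5:30, 10] = True
        mask[16, 5:30] = True
        soma, proc = seg.split_soma_process(mask, r_soma_px=4)
        assert not soma.any()
        assert np.array_equal(proc, mask)

    @pytest.mark.parametrize("ndim", [2, 3])
    def test_partition_contract_random(self, rng, ndim):
        shape = (24, 24) if ndim == 2 else (6, 24, 24)
        for _ in range(5):
            mask = rng.random(shape) < 0.4
            soma, proc = seg.split_soma_process(mask, r_soma_px=3)
            assert np.array_equal(soma | proc, mask)
            assert not (soma & proc).any()


class TestBranchPoints:
    def test_straight_line_no_branches(self):
        mask = np.zeros((64, 64), bool)
        mask[10:50, 20] = True
        assert not seg.detect_branch_points(mask).any()

    def test_y_shape_single_cluster(self):
        mask = np.zeros((64, 64), bool)
        mask[10:50, 32] = True
        for i in range(20):
            mask[30 + i, 32 + i] = True
        branch = seg.detect_branch_points(mask)
        _, n = ndimage.label(branch, structure=EIGHT)
        assert n == 1

    def test_containment_random(self, rng):
        for _ in range(5):
            mask = rng.random((48, 48)) < 0.35
            branch = seg.detect_branch_points(mask)
            assert not (branch & ~mask).any()

    def test_3d_dispatch(self):
        mask = np.zeros((2, 64, 64), bool)
        mask[0, 10:50, 32] = True
        for i in range(20):
            mask[0, 30 + i, 32 + i] = True
        out = seg.detect_branch_points(mask)
        assert out.shape == mask.shape
        assert out[0].any() and not out[1].any()


class TestPcSomas:
    def test_simulated_soma_count(self):
        cfg = layer_config(seed=4, gaussian_sd=0.0, poisson_scale=0.0)
        gt, stack = sim.simulate_animal(cfg)
        pcl = stack.data[0, cfg.layer_boundary_z:, :, :, RED]
        mask = seg.detect_pc_somas(pcl, min_size=200)
        _, n = ndimage.label(mask, structure=np.ones((3, 3, 3)))
        assert n == cfg.n_purkinje

    def test_ml_slices_are_empty_of_somas(self):
        """Per-slice detection (as layer separation uses it) finds no
        soma-sized component in the molecular layer."""
        from skimage.filters import threshold_otsu

        cfg = layer_config(seed=4)
        gt, stack = sim.simulate_animal(cfg)
        min_size = int(0.5 * np.pi * (5.0 / cfg.pixel_size_um) ** 2)
        thr = threshold_otsu(stack.data[0, ..., RED])
        for z in range(cfg.layer_boundary_z - 2):
            mask = seg.detect_pc_somas(
                stack.data[0, z, :, :, RED][None], min_size=min_size, threshold=thr
            )
            assert mask.sum() == 0, f"slice {z}"

    def test_min_size_larger_than_somas(self):
        cfg = layer_config(seed=4)
        _, stack = sim.simulate_animal(cfg)
        pcl = stack.data[0, cfg.layer_boundary_z:, :, :, RED]
        assert not seg.detect_pc_somas(pcl, min_size=10**6).any()


class TestEndToEndSegmentation:
    def test_jaccard_against_ground_truth(self):
        """Regression: component masks overlap truth at fixed seed and noise."""
        cfg = layer_config(seed=7, n_t=2, n_microglia_per_layer=2)
        gt, stack = sim.simulate_animal(cfg)
        raw_red = stack.data[..., RED].copy()
        work = pp.subtract_background(stack, GREEN)
        work = pp.subtract_background(work, RED)
        work, _ = pp.correct_bleedthrough(work)
        la = pp.LayerAssignment(cfg.layer_boundary_z, 0, cfg.n_z)
        masks = seg.build_component_masks(
            work, la, raw_red=raw_red, r_soma_um=1.5,
            mg_min_size=20, pc_min_size=10, pc_soma_min_size=100,
        )
        zml, zpcl = la.ml_slices(), la.pcl_slices()
        checks = {
            ("ML", "mg_whole"): gt.mg_whole[:, zml],
            ("PCL", "mg_whole"): gt.mg_whole[:, zpcl],
            ("ML", "pc_dendrite_whole"): gt.pc_dendrite_whole[:, zml],
            ("PCL", "pc_soma"): gt.masks["pc_soma"][:, zpcl],
        }
        for (layer, name), truth in checks.items():
            j = jaccard(masks.get(layer, name), truth)
            assert j >= 0.6, f"{layer}/{name}: jaccard {j:.3f}"

    def test_component_identities(self):
        cfg = layer_config(seed=7, n_t=1)
        _, stack = sim.simulate_animal(cfg)
        la = pp.LayerAssignment(cfg.layer_boundary_z, 0, cfg.n_z)
        masks = seg.build_component_masks(stack, la)
        for layer in ("ML", "PCL"):
            mg_whole = masks.get(layer, "mg_whole")
            assert np.array_equal(
                mg_whole,
                masks.get(layer, "mg_soma") | masks.get(layer, "mg_process"),
            )
            assert not (
                masks.get(layer, "mg_soma") & masks.get(layer, "mg_process")
            ).any()
        assert not (
            masks.get("ML", "pc_dendrite") & masks.get("ML", "pc_branch")
        ).any()
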