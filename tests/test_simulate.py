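import numpy as np
import pytest
from scipy import ndimage
from scipy.stats import spearmanr
from skimage.morphology import skeletonize
from skimage.registration import phase_cross_correlation

from gliadyn import simulate as sim
from tests.conftest import cal_config

EIGHT = np.ones((3, 3), dtype=bool)


class TestConfig:
    def test_invalid_boundary(self):
        with pytest.raises(ValueError):
            sim.SimConfig(n_z=10, layer_boundary_z=10)

    @pytest.mark.parametrize(
        "field,value",
        [
            ("process_turnover", 1.5),
            ("interaction_bias", -0.1),
            ("bleed_coeff", 1.0),
        ],
    )
    def test_range_checks(self, field, value):
        with pytest.raises(ValueError):
            sim.reduced_config(**{field: value})


class TestPurkinje:
    def test_empty_case(self):
        cfg = cal_config(n_purkinje=0)
        frag = sim.build_purkinje_layer(cfg, np.random.default_rng(0))
        assert not frag["pc_soma"].any()
        assert not frag["pc_dendrite"].any()
        assert cfg.layer_boundary_z == 4  # boundary defined regardless

    def test_component_count(self):
        cfg = cal_config(n_purkinje=3, n_z=16, layer_boundary_z=6)
        frag = sim.build_purkinje_layer(cfg, np.random.default_rng(1))
        # somas hang below the boundary; count components in the soma slab
        _, n = ndimage.label(frag["pc_soma"], structure=np.ones((3, 3, 3)))
        assert n == 3

    def test_overcrowded_raises(self):
        with pytest.raises(ValueError, match="overlap"):
            cfg = cal_config(n_purkinje=30)
            sim.build_purkinje_layer(cfg, np.random.default_rng(0))

    def test_branch_pixels_near_skeleton_junctions(self):
        """Every branch component sits within 2 px of a slice-skeleton junction."""
        cfg = cal_config(seed=5, n_z=16, layer_boundary_z=10)
        frag = sim.build_purkinje_layer(cfg, np.random.default_rng(5))
        dendrite_whole = frag["pc_dendrite"] | frag["pc_branch"]
        assert frag["pc_branch"].any()
        labels, n = ndimage.label(frag["pc_branch"], structure=np.ones((3, 3, 3)))
        kernel = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]])
        for i in range(1, n + 1):
            comp = labels == i
            zs = np.unique(np.nonzero(comp)[0])
            found = False
            for z in zs:
                skel = skeletonize(dendrite_whole[z])
                junctions = skel & (
                    ndimage.convolve(skel.astype(np.uint8), kernel, mode="constant")
                    >= 3
                )
                near = ndimage.binary_dilation(
                    comp[z], structure=EIGHT, iterations=2
                )
                if (junctions & near).any():
                    found = True
                    break
            assert found, f"branch component {i} far from any skeleton junction"

    def test_layer_confinement(self):
        cfg = cal_config(seed=2)
        frag = sim.build_purkinje_layer(cfg, np.random.default_rng(2))
        zb = cfg.layer_boundary_z
        dend_z = np.nonzero(frag["pc_dendrite"] | frag["pc_branch"])[0]
        soma_z = np.nonzero(frag["pc_soma"])[0]
        assert dend_z.size and (dend_z < zb).all()
        assert soma_z.size and (soma_z >= zb).all()


class TestMicroglia:
    def test_static_at_zero_turnover(self):
        gt, _ = sim.simulate_animal(cal_config(seed=3, process_turnover=0.0),
                                    render=False)
        mp = gt.masks["mg_process"]
        for t in range(1, len(mp)):
            assert np.array_equal(mp[0], mp[t])

    def test_turnover_increases_symmetric_difference(self):
        def mean_symdiff(turnover):
            vals = []
            for s in range(5):
                gt, _ = sim.simulate_animal(
                    cal_config(seed=s, process_turnover=turnover), render=False
                )
                mp = gt.masks["mg_process"]
                vals.append(
                    np.mean([(mp[t] ^ mp[t + 1]).sum() for t in range(len(mp) - 1)])
                )
            return np.mean(vals)

        assert mean_symdiff(1.0) > mean_symdiff(0.1)

    def test_bias_increases_pc_overlap(self):
        def overlap_frac(bias):
            vals = []
            for s in range(8):
                gt, _ = sim.simulate_animal(
                    cal_config(seed=s, interaction_bias=bias), render=False
                )
                mp = np.asarray(gt.masks["mg_process"])
                pc = np.asarray(gt.pc_any())
                vals.append((mp & pc).sum() / max(mp.sum(), 1))
            return np.mean(vals)

        assert overlap_frac(0.9) > overlap_frac(0.0)

    def test_soma_process_disjoint(self):
        gt, _ = sim.simulate_animal(cal_config(seed=4), render=False)
        assert not (gt.masks["mg_soma"] & gt.masks["mg_process"]).any()

    def test_turnover_monotone_rank(self):
        """Per-level mean mask turnover is rank-monotone in process_turnover
        (5 levels x 20 replicates)."""
        levels = [0.0, 0.25, 0.5, 0.75, 1.0]
        means = []
        for lev in levels:
            vals = []
            for s in range(20):
                gt, _ = sim.simulate_animal(
                    cal_config(seed=s, process_turnover=lev), render=False
                )
                mp = gt.masks["mg_process"]
                vals.append(
                    np.mean([(mp[t] ^ mp[t + 1]).sum() for t in range(len(mp) - 1)])
                )
            means.append(np.mean(vals))
        rho = spearmanr(levels, means).statistic
        assert rho > 0.9


class TestRender:
    def test_no_bleed_no_noise_green_only_on_microglia(self):
        cfg = cal_config(seed=6, bleed_coeff=0.0, gaussian_sd=0.0, poisson_scale=0.0)
        gt, stack = sim.simulate_animal(cfg)
        green = stack.data[..., 0].astype(float)
        off_mg = ~(gt.mg_whole)
        assert np.all(green[off_mg] == sim.BG_GREEN)
        assert np.all(green[gt.mg_whole] > sim.BG_GREEN)

    def test_bleed_arithmetic_on_pc_only_pixels(self):
        cfg = cal_config(seed=6, bleed_coeff=0.2, gaussian_sd=0.0, poisson_scale=0.0)
        gt, stack = sim.simulate_animal(cfg)
        green = stack.data[..., 0].astype(float)
        red = stack.data[..., 1].astype(float)
        pc_only = gt.pc_any() & ~gt.mg_whole
        expected = sim.BG_GREEN + 0.2 * red[pc_only]
        assert np.max(np.abs(green[pc_only] - expected)) <= 1.0  # uint16 rounding

    def test_drift_offset_recovered_by_registration(self):
        cfg = cal_config(seed=8, drift_per_t_um=2.0, gaussian_sd=0.0,
                         poisson_scale=0.0)
        gt, stack = sim.simulate_animal(cfg)
        n_t = cfg.n_t
        p0 = stack.data[0, :, :, :, 0].max(axis=0).astype(float)
        p1 = stack.data[-1, :, :, :, 0].max(axis=0).astype(float)
        shift, _, _ = phase_cross_correlation(p0, p1, upsample_factor=1)
        expected_px = (n_t - 1) * 2.0 / cfg.pixel_size_um
        assert abs(-shift[1] - expected_px) <= 1.0
        assert abs(shift[0]) <= 1.0


class TestDeterminismAndCohort:
    def test_identical_seed_identical_output(self):
        g1, s1 = sim.simulate_animal(cal_config(seed=9))
        g2, s2 = sim.simulate_animal(cal_config(seed=9))
        assert np.array_equal(s1.data, s2.data)
        for k in g1.masks:
            assert np.array_equal(np.asarray(g1.masks[k]), np.asarray(g2.masks[k]))

    def test_cohort_metadata_balanced(self):
        meta, truths, stacks = sim.simulate_cohort(
            2, None, 0, base_config=cal_config(), render=False
        )
        assert len(meta) == 8
        assert meta.groupby(["treatment", "sex"]).size().eq(2).all()
        assert len(truths) == 8 and all(s is None for s in stacks)

    def test_cohort_effect_raises_true_overlap(self):
        def group_overlap(effect, seed):
            meta, truths, _ = sim.simulate_cohort(
                3, effect, seed, base_config=cal_config(), render=False
            )
            out = {}
            for treat in ("Saline", "EtOH"):
                idx = meta.index[meta.treatment == treat]
                fracs = []
                for i in idx:
                    mp = np.asarray(truths[i].masks["mg_process"])
                    pc = np.asarray(truths[i].pc_any())
                    fracs.append((mp & pc).sum() / max(mp.sum(), 1))
                out[treat] = np.mean(fracs)
            return out

        res = group_overlap({"EtOH": {"interaction_bias": 0.3}}, seed=0)
        assert res["EtOH"] > res["Saline"]

    def test_cohort_too_small(self):
        with pytest.raises(ValueError, match="n_per_group"):
            sim.simulate_cohort(1, None, 0, base_config=cal_config())

    def test_cohort_outputs_byte_identical(self, tmp_path):
        cfg = cal_config(n_t=2, frame_shape=(64, 64))
        for d in ("r1", "r2"):
            sim.simulate_cohort(2, None, 5, base_config=cfg, out_dir=tmp_path / d)
        for f in sorted((tmp_path / "r1").iterdir()):
            assert f.read_bytes() == (tmp_path / "r2" / f.name).read_bytes(), f.name
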