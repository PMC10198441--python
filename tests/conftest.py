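import numpy as np
import pytest

from gliadyn import simulate as sim


def jaccard(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    union = (a | b).sum()
    return float((a & b).sum() / union) if union else 1.0


# shallow, fast geometry used for calibration-style tests (8 z x 6 t x 128^2)
CAL_KW = dict(
    frame_shape=(128, 128),
    n_z=8,
    n_t=6,
    layer_boundary_z=4,
    pc_soma_radius_um=(1.8, 2.4),
    mg_soma_radius_um=(1.2, 1.8),
    n_purkinje=2,
    n_microglia_per_layer=2,
)

# taller geometry with clearly soma-sized Purkinje somas, for layer detection
LAYER_KW = dict(
    frame_shape=(160, 160),
    n_z=30,
    n_t=1,
    layer_boundary_z=15,
    pc_soma_radius_um=(4.5, 5.5),
    n_purkinje=3,
)


def cal_config(**overrides) -> sim.SimConfig:
    kw = dict(CAL_KW)
    kw.update(overrides)
    return sim.reduced_config(**kw)


def layer_config(**overrides) -> sim.SimConfig:
    kw = dict(LAYER_KW)
    kw.update(overrides)
    return sim.reduced_config(**kw)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def rendered_animal():
    """One rendered reduced-scale animal shared across read-only tests."""
    cfg = sim.reduced_config(seed=11, bleed_coeff=0.2)
    gt, stack = sim.simulate_animal(cfg)
    return cfg, gt, stack
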