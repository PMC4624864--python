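import numpy as np
import pytest

from gctfm import TractionMap, make_grid


def gaussian_focus_map(
    centers,
    amplitudes,
    directions,
    field_size=(30.0, 30.0),
    spacing=0.75,
    width=2.0,
    t=0.0,
):
    """Traction map from Gaussian stress foci (test helper)."""
    x, y = make_grid(field_size, spacing)
    xx, yy = np.meshgrid(x, y)
    tx = np.zeros_like(xx)
    ty = np.zeros_like(xx)
    for (cx, cy), a, (dx, dy) in zip(centers, amplitudes, directions):
        norm = np.hypot(dx, dy)
        if norm == 0:
            raise ValueError("zero direction")
        blob = a * np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * width ** 2))
        tx += blob * dx / norm
        ty += blob * dy / norm
    return TractionMap(x=x, y=y, t=t, tx=tx, ty=ty)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def lowres_cone():
    """Low-time-resolution advancing growth cone (shared across tests)."""
    from gctfm import SimulationConfig, simulate_traction_series

    cfg = SimulationConfig(
        field_size=(180.0, 50.0), dt=120.0, n_frames=60, seed=11
    )
    maps, truth = simulate_traction_series(cfg)
    return cfg, maps, truth
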