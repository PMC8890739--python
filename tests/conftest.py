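import numpy as np
import pytest

import aneupiv as ap


@pytest.fixture(scope="session")
def model():
    """Untreated default phantom (no scenario applied)."""
    return ap.default_model(seed=0)


@pytest.fixture(scope="session")
def geometry(model):
    return ap.build_geometry(model.geometry)


@pytest.fixture(scope="session")
def coarse_grid():
    """Coarse evaluation grid for model-level statistics (0.5 mm pitch)."""
    x = np.arange(-11.75, 12.0, 0.5)
    y = np.arange(-4.75, 20.0, 0.5)
    X, Y = np.meshgrid(x, y)
    return x, y, X, Y


def sample_cycle_fields(scenario_model, X, Y, n_cycles, n_phases):
    """Phase-locked recordings of the analytic model on a grid."""
    pts = np.column_stack([X.ravel(), Y.ravel(), np.zeros(X.size)])
    rec = np.empty((n_cycles, n_phases, X.shape[0], X.shape[1], 3), dtype=float)
    T = scenario_model.waveform.cycle_duration_s
    for c in range(n_cycles):
        for m in range(n_phases):
            vel, _ = scenario_model.sample_velocity(pts, m / n_phases * T, cycle=c)
            rec[c, m] = vel.reshape(X.shape[0], X.shape[1], 3)
    return rec


@pytest.fixture(scope="session")
def model_pacs(coarse_grid):
    """Model-level phase averages for noFD / FDC1 / FDC3 (16 cycles, 64 phases)."""
    x, y, X, Y = coarse_grid
    out = {}
    for scn in ("noFD", "FDC1", "FDC3"):
        m = ap.default_model(seed=0).apply_scenario(scn)
        rec = sample_cycle_fields(m, X, Y, n_cycles=16, n_phases=64)
        out[scn] = ap.phase_average(rec, 1.0, x, y)
    return out


@pytest.fixture(scope="session")
def coarse_roi(coarse_grid):
    x, y, X, Y = coarse_grid
    cfg = ap.GeometryConfig()
    cx, cy = cfg.sac_center_mm
    er = cfg.roi_erosion_mm
    return ((X - cx) ** 2 + (Y - cy) ** 2 < (cfg.sac_radius_mm - er) ** 2) & (Y > er)
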