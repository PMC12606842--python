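import numpy as np
import pandas as pd
import pytest

import dispersr as d


def make_track(xy, t0="2023-03-01T00:00:00Z", interval_h=3.0, ind="a"):
    """Track from a coordinate list at a regular interval."""
    xy = np.asarray(xy, dtype=float)
    t = pd.Timestamp(t0) + pd.to_timedelta(np.arange(len(xy)) * interval_h,
                                           unit="h")
    fixes = pd.DataFrame({"t": t, "x": xy[:, 0], "y": xy[:, 1],
                          "imputed": False, "segment": 0})
    return d.build_steps(d.Track(ind, fixes))


def make_steps(lengths, interval_h=3.0, segment=0):
    """Minimal step table with consistent speeds (for phase tests)."""
    lengths = np.asarray(lengths, dtype=float)
    n = len(lengths)
    x = np.r_[0.0, np.cumsum(lengths)]
    return make_track(np.c_[x, np.zeros(n + 1)], interval_h=interval_h).steps


@pytest.fixture(scope="session")
def small_landscape():
    cfg = d.SimulationConfig(seed=11, extent_m=20_000.0, n_steps=10,
                             n_roads=2, n_rivers=2, n_lakes=1)
    return d.make_landscape(cfg)


@pytest.fixture(scope="session")
def two_state_sim(small_landscape):
    """A 400-step two-state track with well-separated kernels."""
    cfg = d.SimulationConfig(
        seed=11, extent_m=20_000.0, n_steps=400,
        kernels=(d.MovementKernel(1.0, 100.0, 0.0, 0.0),
                 d.MovementKernel(2.0, 1000.0, 0.0, 1.0)))
    return d.simulate_track(cfg, small_landscape,
                            rng=np.random.default_rng(42))
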