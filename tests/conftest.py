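import numpy as np
import pytest

from strainsync import (
    SEGMENTS,
    CycleWindow,
    FrameGrid,
    Layer,
    PointTrace,
    StrainStudy,
    scenario_preset,
    simulate_study,
)
from strainsync.strain_io import POINTS_PER_SEGMENT


def make_grid(n_frames=24, frame_rate=230.0):
    times = np.arange(n_frames) * 1000.0 / frame_rate
    return FrameGrid(frame_times=times, frame_rate=frame_rate)


def make_study(strain_fn, layers=(Layer.ENDO,), n_frames=24, frame_rate=230.0,
               cycles=(), with_positions=False):
    """Build a study whose trace strain is strain_fn(segment, layer, point, times)."""
    grid = make_grid(n_frames, frame_rate)
    traces = []
    for layer in layers:
        for si, seg in enumerate(SEGMENTS):
            for p in range(POINTS_PER_SEGMENT):
                strain = np.asarray(
                    strain_fn(seg, layer, p, grid.frame_times), dtype=float
                )
                pos = None
                if with_positions:
                    idx = si * POINTS_PER_SEGMENT + p
                    pos = np.column_stack([
                        np.full(n_frames, float(idx)),
                        np.full(n_frames, float(idx) * 0.5),
                    ])
                traces.append(PointTrace(seg, layer, p, strain, position=pos))
    return StrainStudy(grid=grid, traces=traces, cycles=list(cycles))


def uniform_study(value=-10.0, **kw):
    return make_study(lambda s, l, p, t: np.full(t.size, value), **kw)


@pytest.fixture
def sham_study():
    return simulate_study(scenario_preset("sham", seed=11))


@pytest.fixture
def noiseless_sham_study():
    cfg = scenario_preset("sham", seed=11)
    cfg.noise_sd = 0.0
    return simulate_study(cfg)


@pytest.fixture
def one_cycle():
    return CycleWindow(0, 21)
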