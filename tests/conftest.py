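import numpy as np
import pytest

from divnoise import (
    CellTrace,
    DivisionEvent,
    MeasurementModel,
    PartitionSpec,
    SimConfig,
    synth_cytometry_timecourse,
    synth_microscopy_events,
)

ACQUISITION_TIMES = [0.0, 24.0, 36.0, 48.0, 60.0, 72.0, 84.0]


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260919)


@pytest.fixture(scope="session")
def small_timecourse():
    """Seeded uncoupled dye-dilution course at sigma_f = 0.07 with labels."""
    cfg = SimConfig(
        n_lineages=1200, partition=PartitionSpec.gaussian(0.07), mode="uncoupled", seed=12
    )
    meas = MeasurementModel(events_per_acquisition=6000)
    return synth_cytometry_timecourse(cfg, meas, ACQUISITION_TIMES)


@pytest.fixture(scope="session")
def noisy_trace_events():
    """500 division events, gaussian Pi (sigma_f = 0.1), 3% frame noise."""
    return synth_microscopy_events(
        500, PartitionSpec.gaussian(0.1), noise_cv=0.03, frames_per_side=7, seed=7
    )


def make_event(
    f: float = 0.5,
    frames_per_side: int = 7,
    frame_interval_h: float = 1.0 / 3.0,
    decay: float = -0.02,
    mother_intensity: float = 1000.0,
    area_r: float | None = None,
    base_area: float = 400.0,
    rng: np.random.Generator | None = None,
) -> DivisionEvent:
    """Deterministic noiseless event; optionally force an exact
    intensity-area Pearson correlation ``area_r`` on every trace."""
    dt = frame_interval_h
    tm = -dt * np.arange(frames_per_side - 1, -1, -1.0)
    td = dt * np.arange(1, frames_per_side + 1, dtype=float)
    im = mother_intensity * np.exp(decay * tm)
    i1 = f * mother_intensity * np.exp(decay * td)
    i2 = (1 - f) * mother_intensity * np.exp(decay * td)

    def area_for(inten: np.ndarray) -> np.ndarray:
        if area_r is None:
            return np.full_like(inten, base_area)
        if rng is None:
            raise ValueError("need rng to build a correlated area trace")
        # Gram-Schmidt: area with exact empirical corr area_r to intensity
        z = (inten - inten.mean()) / inten.std()
        e = rng.normal(size=inten.size)
        e -= e.mean() + z * (e @ z) / inten.size * 0  # center
        e = e - z * (e @ z) / (z @ z)
        e /= np.linalg.norm(e) / np.sqrt(inten.size)
        mix = area_r * z + np.sqrt(1 - area_r**2) * e
        return base_area * (1.0 + 0.05 * mix)

    return DivisionEvent(
        mother=CellTrace(tm, im, area_for(im)),
        daughter1=CellTrace(td, i1, area_for(i1)),
        daughter2=CellTrace(td, i2, area_for(i2)),
        division_time=0.0,
    )


@pytest.fixture()
def qc_fixture_events(rng):
    """10 constructed events: 4 short-window, 2 correlation r=0.95, 4 clean."""
    events = []
    for _ in range(4):  # daughters observed 5 frames at 20 min = 100 min < 2 h
        events.append(make_event(f=0.5, frames_per_side=5))
    for _ in range(2):
        events.append(make_event(f=0.5, area_r=0.95, rng=rng))
    for _ in range(4):
        events.append(make_event(f=0.45))
    return events
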