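"""Stochastic lineage simulation under partitioning noise.

Two modes are provided.  In the *uncoupled* mode cells divide after
independent lognormal cycle times and the dye fraction ``f`` drawn at
each division is independent of everything else — the regime the moment
dynamics assume.  In the *sizer* mode cells grow exponentially and divide
on reaching a (jittered) threshold size, and a single ``f`` per division
splits both size and dye; a small daughter then needs longer to reach the
threshold, maximally coupling partitioning noise to cycle-length noise.

On top of the lineage engine sit the synthetic-data generators: dye
dilution flow-cytometry time courses (narrow sorted founder peak,
per-generation lognormal intensity peaks spaced ~1 in log2, occupancies
evolving over the acquisition grid) and time-lapse microscopy division
events (exponentially decaying mother/daughter traces sampled every
20 min with per-frame multiplicative noise and pixel-area traces).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .partition import PartitionSpec

__all__ = [
    "SimConfig",
    "MeasurementModel",
    "CellRecord",
    "LineagePopulation",
    "simulate_dilution",
    "simulate_sizer",
    "synth_cytometry_timecourse",
    "synth_microscopy_events",
]

_MAX_GENERATION = 25


@dataclass(frozen=True)
class SimConfig:
    """Configuration of a lineage simulation.

    Cycle-time parameters apply to the uncoupled mode; growth rate,
    division size and threshold noise to the sizer mode.  The defaults
    mimic a colon carcinoma line with an ~18 h doubling time followed for
    up to 84 h, founders sorted to a narrow (0.05 log2-units) dye peak.
    """

    n_lineages: int = 1000
    max_generation: int = 10
    partition: PartitionSpec = field(default_factory=PartitionSpec.delta_half)
    mode: str = "uncoupled"
    seed: int = 0
    # founders (sorted population)
    founder_marker_mean: float = 100.0
    founder_log2_sd: float = 0.05
    # uncoupled mode: lognormal cycle times
    cycle_time_mean_h: float = 18.0
    cycle_time_cv: float = 0.2
    # sizer mode
    growth_rate: float = np.log(2.0) / 18.0  # 1/h
    division_size: float = 2.0
    threshold_cv: float = 0.05

    def __post_init__(self) -> None:
        if self.n_lineages < 1:
            raise ValueError("n_lineages must be >= 1")
        if self.mode not in ("uncoupled", "sizer"):
            raise ValueError("mode must be 'uncoupled' or 'sizer'")
        if self.max_generation > _MAX_GENERATION:
            raise ValueError(
                f"max_generation > {_MAX_GENERATION} would overflow the lineage tree"
            )
        if self.mode == "sizer" and (self.growth_rate <= 0 or self.division_size <= 0):
            raise ValueError("sizer mode needs positive growth_rate and division_size")
        if self.seed is None:
            raise ValueError("seed is mandatory")


@dataclass(frozen=True)
class MeasurementModel:
    """Map dye amounts to measured fluorescence intensities.

    intensity = m * F * exp(noise) + background, with mean-one lognormal
    multiplicative noise of the given CV, then subsampling to the number
    of events one acquisition records.
    """

    brightness: float = 500.0
    noise_cv: float = 0.05
    background: float = 0.0
    events_per_acquisition: int = 10000

    def __post_init__(self) -> None:
        if self.brightness <= 0:
            raise ValueError("brightness must be positive")
        if self.noise_cv < 0:
            raise ValueError("noise CV must be non-negative")


@dataclass
class CellRecord:
    id: int
    parent_id: int  # -1 for founders
    generation: int
    marker: float
    birth_size: float
    birth_time: float
    division_time: float  # inf if never divides within the run


@dataclass
class LineagePopulation:
    """Flat arrays over every cell ever alive in a time-resolved run."""

    parent: np.ndarray
    generation: np.ndarray
    marker: np.ndarray
    birth_size: np.ndarray
    birth_time: np.ndarray
    division_time: np.ndarray

    def alive_at(self, t: float) -> np.ndarray:
        """Indices of cells alive at wall-clock time t."""
        return np.flatnonzero((self.birth_time <= t) & (t < self.division_time))

    def records(self) -> list[CellRecord]:
        return [
            CellRecord(
                i,
                int(self.parent[i]),
                int(self.generation[i]),
                float(self.marker[i]),
                float(self.birth_size[i]),
                float(self.birth_time[i]),
                float(self.division_time[i]),
            )
            for i in range(len(self.parent))
        ]


@dataclass
class DilutionResult:
    """Per-generation marker arrays of a pure-dilution run.

    ``markers[g]`` holds the dye amounts of the 2^g * n_lineages cells of
    generation g, ordered so that cells 2i and 2i+1 of generation g+1 are
    the daughters of cell i of generation g.
    """

    markers: list[np.ndarray]

    def mean(self, g: int) -> float:
        return float(self.markers[g].mean())

    def variance(self, g: int) -> float:
        return float(self.markers[g].var())


def _founder_markers(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Sorted founders: lognormal with the configured width in log2 units."""
    s = config.founder_log2_sd * np.log(2.0)
    if s == 0.0:
        return np.full(config.n_lineages, config.founder_marker_mean)
    return config.founder_marker_mean * np.exp(
        rng.normal(-s**2 / 2.0, s, size=config.n_lineages)
    )


def simulate_dilution(config: SimConfig) -> DilutionResult:
    """Generation-indexed dilution: every division draws f ~ Pi independently.

    Daughters receive f*m and m - f*m, so the dye is conserved exactly at
    every division and generation g holds 2^g cells per founder.
    """
    rng = np.random.default_rng(config.seed)
    m = _founder_markers(config, rng)
    markers = [m]
    for _ in range(config.max_generation):
        f = config.partition.sample(m.size, rng)
        a = f * m
        b = m - a  # exact conservation
        children = np.empty(2 * m.size)
        children[0::2] = a
        children[1::2] = b
        markers.append(children)
        m = children
    return DilutionResult(markers=markers)


def _simulate_time_resolved(config: SimConfig, t_end: float) -> LineagePopulation:
    """Breadth-first lineage run to wall-clock time t_end (either mode)."""
    rng = np.random.default_rng(config.seed)
    n0 = config.n_lineages
    m0 = _founder_markers(config, rng)

    parent = [np.full(n0, -1, dtype=np.int64)]
    generation = [np.zeros(n0, dtype=np.int64)]
    marker = [m0]
    if config.mode == "sizer":
        birth_size = [np.full(n0, config.division_size / 2.0)]
    else:
        birth_size = [np.full(n0, np.nan)]
    birth_time = [np.zeros(n0)]

    def cycle_times(k: int) -> np.ndarray:
        mean, cv = config.cycle_time_mean_h, config.cycle_time_cv
        if cv == 0:
            return np.full(k, mean)
        s = np.sqrt(np.log1p(cv**2))
        return mean * np.exp(rng.normal(-s**2 / 2.0, s, size=k))

    def sizer_division_times(bt: np.ndarray, bs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        thr = np.full(bs.size, config.division_size)
        if config.threshold_cv > 0:
            s = np.sqrt(np.log1p(config.threshold_cv**2))
            thr = thr * np.exp(rng.normal(-s**2 / 2.0, s, size=bs.size))
        thr = np.maximum(thr, bs)  # already past threshold: divide now
        return bt + np.log(thr / bs) / config.growth_rate, thr

    division_time: list[np.ndarray] = []
    div_size: list[np.ndarray] = []
    if config.mode == "sizer":
        dt0, ds0 = sizer_division_times(birth_time[0], birth_size[0])
    else:
        dt0 = birth_time[0] + cycle_times(n0)
        ds0 = np.full(n0, np.nan)
    division_time.append(dt0)
    div_size.append(ds0)

    offset = 0
    g = 0
    while g < config.max_generation:
        bt, dt = birth_time[g], division_time[g]
        divides = dt <= t_end
        idx = np.flatnonzero(divides)
        if idx.size == 0:
            break
        f = config.partition.sample(idx.size, rng)
        pm = marker[g][idx]
        ma, mb = f * pm, pm - f * pm
        if config.mode == "sizer":
            ps = div_size[g][idx]
            sa, sb = f * ps, ps - f * ps
        else:
            sa = sb = np.full(idx.size, np.nan)
        k = idx.size
        cp = np.empty(2 * k, dtype=np.int64)
        cp[0::2] = idx + offset
        cp[1::2] = idx + offset
        cm = np.empty(2 * k)
        cm[0::2], cm[1::2] = ma, mb
        cs = np.empty(2 * k)
        cs[0::2], cs[1::2] = sa, sb
        cbt = np.repeat(dt[idx], 2)
        parent.append(cp)
        generation.append(np.full(2 * k, g + 1, dtype=np.int64))
        marker.append(cm)
        birth_size.append(cs)
        birth_time.append(cbt)
        if g + 1 < config.max_generation:
            if config.mode == "sizer":
                cdt, cds = sizer_division_times(cbt, cs)
            else:
                cdt = cbt + cycle_times(2 * k)
                cds = np.full(2 * k, np.nan)
        else:
            cdt = np.full(2 * k, np.inf)
            cds = np.full(2 * k, np.nan)
        division_time.append(cdt)
        div_size.append(cds)
        # cells that never divide within the run keep division_time as drawn
        # (> t_end) so alive_at() works without modification
        offset += bt.size
        g += 1

    return LineagePopulation(
        parent=np.concatenate(parent),
        generation=np.concatenate(generation),
        marker=np.concatenate(marker),
        birth_size=np.concatenate(birth_size),
        birth_time=np.concatenate(birth_time),
        division_time=np.concatenate(division_time),
    )


def simulate_sizer(config: SimConfig, t_end: float) -> LineagePopulation:
    """Time-resolved sizer run: one f per division splits size AND dye."""
    if config.mode != "sizer":
        config = replace(config, mode="sizer")
    return _simulate_time_resolved(config, t_end)


def simulate_uncoupled_timecourse(config: SimConfig, t_end: float) -> LineagePopulation:
    """Time-resolved run with cycle times independent of partitioning."""
    if config.mode != "uncoupled":
        config = replace(config, mode="uncoupled")
    return _simulate_time_resolved(config, t_end)


def synth_cytometry_timecourse(
    config: SimConfig,
    meas: MeasurementModel,
    times: list[float],
):
    """Synthetic dye-dilution flow-cytometry time course with ground truth.

    Returns a list of (CytometrySnapshot, true_generation_labels), one per
    acquisition time.  Intensities are marker * brightness with mean-one
    lognormal measurement noise plus background, subsampled to the
    configured events per acquisition.
    """
    from .cytometry import CytometrySnapshot  # local import: avoid cycle

    if not times or any(b <= a for a, b in zip(times, times[1:])):
        raise ValueError("times must be a non-empty strictly increasing list")
    pop = _simulate_time_resolved(config, t_end=max(times))
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xC1]))
    out = []
    for t in times:
        idx = pop.alive_at(t)
        if idx.size == 0:
            raise ValueError(f"no cells alive at t={t} h")
        if idx.size > meas.events_per_acquisition:
            idx = rng.choice(idx, size=meas.events_per_acquisition, replace=False)
        m = pop.marker[idx]
        intensity = m * meas.brightness
        if meas.noise_cv > 0:
            s = np.sqrt(np.log1p(meas.noise_cv**2))
            intensity = intensity * np.exp(rng.normal(-s**2 / 2.0, s, size=m.size))
        intensity = intensity + meas.background
        snap = CytometrySnapshot(time_h=float(t), channel="CTV", intensities=intensity)
        out.append((snap, pop.generation[idx].copy()))
    return out


def synth_microscopy_events(
    n_events: int,
    spec: PartitionSpec,
    decay_rate_per_h: float = -0.02,
    noise_cv: float = 0.03,
    frames_per_side: int = 7,
    frame_interval_h: float = 1.0 / 3.0,
    seed: int = 0,
    mother_intensity: float = 1000.0,
    area_px: float = 400.0,
    area_noise_cv: float = 0.05,
    area_intensity_corr: float = 0.0,
    couple_area_to_fraction: bool = True,
):
    """Synthetic time-lapse division events with known partition fractions.

    The mother's total fluorescence decays exponentially at
    ``decay_rate_per_h`` up to the division frame; the daughters' traces
    start at f and (1-f) of the mother's division-frame intensity and
    decay at the same rate.  Every frame carries mean-one lognormal
    multiplicative noise of CV ``noise_cv``.  Pixel-area traces are flat
    up to noise; ``area_intensity_corr`` mixes the intensity's frame
    noise into the area to exercise the Pearson QC filter, and
    ``couple_area_to_fraction`` makes daughter areas proportional to the
    inherited fraction (as for cytoplasm).

    Returns (events, true_f) with true_f the fraction inherited by the
    first daughter of each event.
    """
    from .microscopy import CellTrace, DivisionEvent  # local import: avoid cycle

    if frames_per_side < 2:
        raise ValueError("need at least 2 frames per side")
    rng = np.random.default_rng(seed)
    dt = frame_interval_h
    t_mother = -dt * np.arange(frames_per_side - 1, -1, -1.0)
    t_daughter = dt * np.arange(1, frames_per_side + 1, dtype=float)

    def noisy(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(noisy trace, the frame noise factors used)."""
        if noise_cv == 0:
            return x.copy(), np.ones_like(x)
        s = np.sqrt(np.log1p(noise_cv**2))
        fac = np.exp(rng.normal(-s**2 / 2.0, s, size=x.size))
        return x * fac, fac

    def area_trace(base: float, ifac: np.ndarray) -> np.ndarray:
        eta = rng.normal(0.0, area_noise_cv, size=ifac.size)
        rho = area_intensity_corr
        # share the intensity trace's relative frame noise with weight rho
        rel = (ifac - ifac.mean()) / max(ifac.std(), 1e-12) if ifac.std() > 0 else 0.0
        return base * (1.0 + rho * area_noise_cv * rel * 3.0 + np.sqrt(max(1 - rho**2, 0.0)) * eta)

    events, true_f = [], np.empty(n_events)
    f_all = spec.sample(n_events, rng)
    for i in range(n_events):
        f = float(f_all[i])
        true_f[i] = f
        i_div = mother_intensity
        im = i_div * np.exp(decay_rate_per_h * t_mother)
        i1 = f * i_div * np.exp(decay_rate_per_h * t_daughter)
        i2 = (1.0 - f) * i_div * np.exp(decay_rate_per_h * t_daughter)
        im_n, fm = noisy(im)
        i1_n, f1 = noisy(i1)
        i2_n, f2 = noisy(i2)
        if couple_area_to_fraction:
            a1b, a2b = f * area_px, (1.0 - f) * area_px
        else:
            a1b = a2b = area_px / 2.0
        ev = DivisionEvent(
            mother=CellTrace(t_mother.copy(), im_n, area_trace(area_px, fm)),
            daughter1=CellTrace(t_daughter.copy(), i1_n, area_trace(a1b, f1)),
            daughter2=CellTrace(t_daughter.copy(), i2_n, area_trace(a2b, f2)),
            division_time=0.0,
        )
        events.append(ev)
    return events, true_f
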