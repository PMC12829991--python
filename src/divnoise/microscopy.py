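"""Inherited-fraction estimation from time-lapse division traces.

Cytoplasm-stained cells are followed through division; the total
fluorescence of each daughter decays exponentially (photobleaching /
slow dye loss), so fitting both daughters' log-intensity traces with a
shared slope and free intercepts,

    log I_1(t) = m t + q_1,    log I_2(t) = m t + q_2,

gives the fraction inherited by the first daughter as
f = e^{q_1} / (e^{q_1} + e^{q_2}).  Events are quality-filtered (enough
frames on each side of the division; low |Pearson| between intensity and
pixel area, since a strong coupling of total fluorescence to projected
size indicates segmentation noise), the empirical Pi(f) is fitted with a
symmetric double Gaussian, and the daughter size share is compared to f.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats
from scipy.special import logsumexp

from .partition import PartitionNoiseEstimate, cv_percent

__all__ = [
    "CellTrace",
    "DivisionEvent",
    "EventFit",
    "PiFit",
    "fit_division_event",
    "qc_filter",
    "fit_pi_double_gaussian",
    "correlate_size_fraction",
    "asymmetry_from_events",
]


@dataclass
class CellTrace:
    """Per-frame (time, total fluorescence, pixel area) of one cell."""

    times: np.ndarray
    intensity: np.ndarray
    area: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.area is not None:
            self.area = np.asarray(self.area, dtype=float)
            if self.area.size != self.times.size:
                raise ValueError("area and time arrays differ in length")
        if self.intensity.size != self.times.size:
            raise ValueError("intensity and time arrays differ in length")
        if self.times.size > 1 and not (np.diff(self.times) > 0).all():
            raise ValueError("times must be strictly increasing")

    @property
    def span_h(self) -> float:
        return float(self.times[-1] - self.times[0])

    def intensity_area_r(self) -> float:
        """|Pearson r| between intensity and area (nan if unavailable)."""
        if self.area is None or self.times.size < 3:
            return float("nan")
        if np.ptp(self.intensity) == 0 or np.ptp(self.area) == 0:
            return 0.0
        return float(abs(stats.pearsonr(self.intensity, self.area)[0]))


@dataclass
class DivisionEvent:
    mother: CellTrace
    daughter1: CellTrace
    daughter2: CellTrace
    division_time: float
    event_id: str | int = ""


@dataclass
class EventFit:
    slope: float  # shared decay rate m (1/h)
    q1: float  # log-intensity intercepts at t = 0
    q2: float
    f: float  # fraction inherited by daughter 1; daughter 2 gets 1 - f
    r_mother: float
    r_d1: float
    r_d2: float
    frames_d1: int
    frames_d2: int
    conservation_ratio: float = float("nan")  # (d1+d2 first frames)/mother last


def fit_division_event(event: DivisionEvent) -> EventFit:
    """Shared-slope log-linear fit of the two daughter traces.

    Minimizes sum over both daughters of (log I - m t - q_k)^2 with a
    single slope m; the intercept ratio gives f.  The mother trace is not
    used in the fit (only for QC and the conservation diagnostic).
    """
    d1, d2 = event.daughter1, event.daughter2
    if d1.times.size < 2 or d2.times.size < 2:
        raise ValueError("need at least 2 frames per daughter")
    if (d1.intensity <= 0).any() or (d2.intensity <= 0).any():
        raise ValueError("non-positive daughter intensities cannot be log-fitted")
    t = np.concatenate([d1.times, d2.times])
    if np.ptp(t) == 0:
        raise ValueError("singular design: all frame times equal")
    y = np.concatenate([np.log(d1.intensity), np.log(d2.intensity)])
    ind1 = np.concatenate([np.ones(d1.times.size), np.zeros(d2.times.size)])
    X = np.column_stack([t, ind1, 1.0 - ind1])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    m, q1, q2 = (float(b) for b in beta)
    f = 1.0 / (1.0 + np.exp(q2 - q1))  # e^q1 / (e^q1 + e^q2), stable

    cons = float("nan")
    if event.mother.intensity.size:
        cons = float(
            (d1.intensity[0] + d2.intensity[0]) / event.mother.intensity[-1]
        )
    return EventFit(
        slope=m,
        q1=q1,
        q2=q2,
        f=float(f),
        r_mother=event.mother.intensity_area_r(),
        r_d1=d1.intensity_area_r(),
        r_d2=d2.intensity_area_r(),
        frames_d1=d1.times.size,
        frames_d2=d2.times.size,
        conservation_ratio=cons,
    )


def qc_filter(
    events: list[DivisionEvent],
    min_hours: float = 2.0,
    r_max: float = 0.9,
) -> tuple[list[DivisionEvent], list[tuple[DivisionEvent, list[str]]]]:
    """Keep events observed long enough with low intensity-area coupling.

    An event is kept iff the mother and both daughters each span at least
    ``min_hours`` of elapsed time on their side of the division AND each
    of the three traces has |Pearson(intensity, area)| <= ``r_max``.
    Missing area data rejects the event (logged, not raised).
    """
    kept, rejected = [], []
    for ev in events:
        reasons = []
        for name, tr in (("mother", ev.mother), ("d1", ev.daughter1), ("d2", ev.daughter2)):
            if tr.span_h < min_hours - 1e-9:  # tolerate fp frame arithmetic
                reasons.append(f"{name}: observed {tr.span_h:.2f} h < {min_hours} h")
            if tr.area is None:
                reasons.append(f"{name}: no area trace")
            else:
                r = tr.intensity_area_r()
                if np.isfinite(r) and r > r_max:
                    reasons.append(f"{name}: |r(I, area)| = {r:.3f} > {r_max}")
        if reasons:
            rejected.append((ev, reasons))
        else:
            kept.append(ev)
    return kept, rejected


@dataclass
class PiFit:
    """Symmetric double-Gaussian fit of the empirical Pi(f)."""

    f_peak: float
    sigma_prime: float
    sigma_f: float
    model: str  # "double" or "single"
    bic_double: float
    bic_single: float
    n_samples: int

    @property
    def variance(self) -> float:
        return self.sigma_prime**2 + (self.f_peak - 0.5) ** 2


def _double_gauss_nll(theta: np.ndarray, x: np.ndarray) -> float:
    f0, s = theta
    lp = np.stack(
        [stats.norm.logpdf(x, f0, s), stats.norm.logpdf(x, 1.0 - f0, s)], axis=1
    )
    return -float(np.sum(logsumexp(lp, axis=1) - np.log(2.0)))


def fit_pi_double_gaussian(
    f_samples: np.ndarray,
    bic_margin: float = 2.0,
) -> PiFit:
    """Maximum-likelihood symmetric mixture (N(f, s') + N(1-f, s'))/2.

    ``f_peak`` is canonicalized to <= 1/2 (daughter labels are
    exchangeable).  A single central Gaussian N(1/2, s) is compared by
    BIC and preferred when within ``bic_margin`` of the double-peak
    model.  The partition variance follows the exact mixture identity
    sigma_f^2 = s'^2 + (f_peak - 1/2)^2.
    """
    x = np.asarray(f_samples, dtype=float)
    if x.size < 20:
        raise ValueError("need at least 20 fraction samples")
    if ((x <= 0) | (x >= 1)).any():
        raise ValueError("fraction samples must lie in (0, 1)")
    n = x.size
    if np.allclose(x, x[0]):
        warnings.warn("degenerate identical samples; sigma' = 0", stacklevel=2)
        f0 = min(float(x[0]), 1.0 - float(x[0]))
        sf = abs(f0 - 0.5)
        return PiFit(f0, 0.0, sf, "double", float("nan"), float("nan"), n)

    # single central Gaussian: MLE sigma about the fixed mean 1/2
    s_single = float(np.sqrt(np.mean((x - 0.5) ** 2)))
    s_single = max(s_single, 1e-9)
    nll_single = -float(np.sum(stats.norm.logpdf(x, 0.5, s_single)))
    bic_single = 2.0 * nll_single + 1.0 * np.log(n)

    spread = max(float(np.std(x)), 1e-3)
    starts = [(0.5 - d, max(spread / 2, 1e-3)) for d in (0.0, spread / 2, spread, 2 * spread)]
    best = None
    for f0_0, s0 in starts:
        res = optimize.minimize(
            _double_gauss_nll,
            x0=np.array([np.clip(f0_0, 1e-3, 0.5), s0]),
            args=(x,),
            method="L-BFGS-B",
            bounds=[(1e-6, 0.5), (1e-6, 1.0)],
        )
        if best is None or res.fun < best.fun:
            best = res
    f0, sp = float(best.x[0]), float(best.x[1])
    bic_double = 2.0 * float(best.fun) + 2.0 * np.log(n)

    if bic_single <= bic_double + bic_margin:
        model, f0, sp = "single", 0.5, s_single
        # with f_peak = 1/2 the mixture collapses and sigma' is the full SD
    else:
        model = "double"
    sf = float(np.sqrt(sp**2 + (f0 - 0.5) ** 2))
    return PiFit(f0, sp, sf, model, bic_double, bic_single, n)


def correlate_size_fraction(
    fits: list[EventFit],
    events: list[DivisionEvent],
) -> tuple[float, int]:
    """Pearson r between daughter-1 final-frame area share and fitted f."""
    shares, fs = [], []
    for fit, ev in zip(fits, events):
        if ev.daughter1.area is None or ev.daughter2.area is None:
            continue
        a1, a2 = ev.daughter1.area[-1], ev.daughter2.area[-1]
        if a1 + a2 <= 0:
            continue
        shares.append(a1 / (a1 + a2))
        fs.append(fit.f)
    if len(fs) < 3:
        raise ValueError("need at least 3 events with area data")
    if np.std(shares) == 0 or np.std(fs) == 0:
        return 0.0, len(fs)
    r = float(stats.pearsonr(shares, fs)[0])
    return r, len(fs)


def asymmetry_from_events(
    events: list[DivisionEvent],
    min_hours: float = 2.0,
    r_max: float = 0.9,
    n_bootstrap: int = 500,
    seed: int | None = 0,
) -> tuple[PartitionNoiseEstimate, PiFit, list[EventFit]]:
    """QC, fit every event, fit Pi(f), report the division-asymmetry CV%.

    The standard error of sigma_f comes from a bootstrap over events.
    """
    kept, _ = qc_filter(events, min_hours=min_hours, r_max=r_max)
    if not kept:
        raise ValueError("no events pass QC")
    fits = [fit_division_event(ev) for ev in kept]
    f = np.array([fit.f for fit in fits])
    pi = fit_pi_double_gaussian(f)

    stderr = float("nan")
    if n_bootstrap > 0 and f.size >= 20:
        rng = np.random.default_rng(seed)
        boots = np.empty(n_bootstrap)
        for b in range(n_bootstrap):
            xb = f[rng.integers(0, f.size, size=f.size)]
            if np.allclose(xb, xb[0]):
                boots[b] = abs(float(xb[0]) - 0.5)
                continue
            boots[b] = fit_pi_double_gaussian(xb).sigma_f
        stderr = float(np.std(boots, ddof=1))

    est = PartitionNoiseEstimate(
        sigma_f=pi.sigma_f,
        E_f2=pi.sigma_f**2 + 0.25,
        cv_percent=cv_percent(pi.sigma_f),
        stderr_sigma_f=stderr,
        mean_slope_log2=float("nan"),
        n_entries=len(fits),
    )
    return est, pi, fits
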