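"""Synthetic DAM activity and fluorescence time-courses with known truth.

The activity generator draws per-minute beam-crossing counts from an
inhomogeneous Poisson process whose rate carries the features the analysis
assumes: exponential morning/evening anticipation ramps terminating at the
light transitions, clock-independent startle (masking) spikes just after
each transition, a rectified-cosine free-running oscillation of period τ in
DD, flat arrhythmic flies, and death (all-zero tail).  The fluorescence
generator produces per-brain intensities following a damped 24-h cosine plus
Gaussian noise on a 6-h collection grid.

Every generator is a pure function of its parameters and seed; populations
derive per-fly streams from a single seed via ``SeedSequence`` spawning, so
results are reproducible and independent of fly order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .schedule import MINUTES_PER_DAY, LightSchedule
from .dam_io import MonitorData, N_CHANNELS
from .cycling import IntensityTimecourse

__all__ = [
    "FlySimParams",
    "CyclingSimParams",
    "rate_profile",
    "simulate_fly",
    "simulate_population",
    "mixture_specs",
    "simulate_timecourse",
    "render_spot_image",
]


@dataclass(frozen=True)
class FlySimParams:
    """Rate-model parameters for one simulated fly.

    Rates are in beam crossings per minute.  ``ramp_tau_h`` is the e-folding
    time of the anticipation ramps; ``tau_h`` the free-running period used in
    DD when ``rhythmic``; ``death_day`` (experiment day index) silences the
    fly from that day's first minute onward.
    """

    baseline_rate: float = 2.0
    morning_amp: float = 4.0
    evening_amp: float = 4.0
    ramp_tau_h: float = 3.0
    startle_amp: float = 10.0
    startle_width_min: int = 10
    dd_amplitude: float = 4.0
    tau_h: float = 24.0
    phase0_h: float = 0.0
    rhythmic: bool = True
    death_day: int | None = None
    seed: int | None = None
    genotype: str = "sim"

    def __post_init__(self) -> None:
        for name in ("baseline_rate", "morning_amp", "evening_amp",
                     "startle_amp", "dd_amplitude"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.ramp_tau_h <= 0:
            raise ValueError("ramp_tau_h must be > 0")
        if self.rhythmic and not 14.0 < self.tau_h < 34.0:
            raise ValueError("tau_h must lie in (14, 34) h for rhythmic flies")


@dataclass(frozen=True)
class CyclingSimParams:
    """Damped-cosine model for fluorescence intensity time-courses (a.u.)."""

    mesor: float = 100.0
    amplitude: float = 50.0
    acrophase_h: float = 0.0
    damping_per_day: float = 0.0
    noise_sd: float = 10.0
    n_brains_per_timepoint: int = 5
    timepoints_h: tuple[float, ...] = (0.0, 6.0, 12.0, 18.0)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_brains_per_timepoint < 1:
            raise ValueError("n_brains_per_timepoint must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0.0 <= self.damping_per_day <= 1.0:
            raise ValueError("damping_per_day must lie in [0, 1]")


def rate_profile(params: FlySimParams, schedule: LightSchedule, n_days: int) -> np.ndarray:
    """Per-minute Poisson rate λ(t) for the fly model (exposed for testing
    the generator's analytic mean)."""
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    if schedule.n_days < n_days:
        raise ValueError("schedule shorter than requested n_days")
    t_min = np.arange(n_days * MINUTES_PER_DAY)
    h = t_min / 60.0
    zt = h % 24.0
    day = t_min // MINUTES_PER_DAY
    regimes = np.array([schedule.regime_of_day(int(d)) for d in range(n_days)])
    ld = regimes[day] == "LD"
    dd = ~ld

    lam = np.full(t_min.size, params.baseline_rate, dtype=float)
    if params.rhythmic:
        # anticipation ramps rise toward lights-on (ZT24) and lights-off
        lam[ld] += params.morning_amp * np.exp((zt[ld] - 24.0) / params.ramp_tau_h)
        ev = ld & (zt < 12.0)
        lam[ev] += params.evening_amp * np.exp((zt[ev] - 12.0) / params.ramp_tau_h)
        if dd.any():
            lam[dd] += params.dd_amplitude * np.maximum(
                0.0, np.cos(2 * np.pi * (h[dd] - params.phase0_h) / params.tau_h)
            )
    # masking startles are clock-independent: present even in arrhythmic flies
    w_h = params.startle_width_min / 60.0
    for d in np.flatnonzero(regimes == "LD"):
        p = schedule.phase_of_day(int(d))
        on, off = 0.0, p.light_hours
        day_sel = day == d
        lam[day_sel & (zt >= on) & (zt < on + w_h)] += params.startle_amp
        lam[day_sel & (zt >= off) & (zt < off + w_h)] += params.startle_amp
    if params.death_day is not None:
        lam[t_min >= params.death_day * MINUTES_PER_DAY] = 0.0
    return lam


def simulate_fly(
    params: FlySimParams,
    schedule: LightSchedule,
    n_days: int,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Draw a fly's per-minute counts; deterministic given (params, seed)."""
    if rng is None:
        rng = np.random.default_rng(params.seed if params.seed is not None else 0)
    lam = rate_profile(params, schedule, n_days)
    return rng.poisson(lam).astype(np.int64)


def mixture_specs(
    n: int,
    frac_rhythmic: float,
    rhythmic_params: FlySimParams | None = None,
    arrhythmic_params: FlySimParams | None = None,
) -> list[FlySimParams]:
    """Deterministic rhythmic/arrhythmic mixture: exactly ``round(n * frac)``
    rhythmic flies, assigned to the first slots."""
    if not 0.0 <= frac_rhythmic <= 1.0:
        raise ValueError("frac_rhythmic must lie in [0, 1]")
    rp = rhythmic_params or FlySimParams(rhythmic=True)
    ap = arrhythmic_params or FlySimParams(
        rhythmic=False, morning_amp=0.0, evening_amp=0.0, dd_amplitude=0.0
    )
    k = int(round(n * frac_rhythmic))
    return [rp] * k + [ap] * (n - k)


def simulate_population(
    specs: Sequence[FlySimParams],
    schedule: LightSchedule,
    n_days: int,
    seed: int = 0,
    start: str | pd.Timestamp = "2025-01-05",
) -> MonitorData:
    """Simulate one fly per spec entry into a :class:`MonitorData`.

    Ground truth (rhythmic flag, τ, death day) is recorded in the fly
    metadata as ``true_*`` columns.  Fly *i* draws from the *i*-th child of
    ``SeedSequence(seed)`` unless its spec pins an explicit seed.
    """
    if not specs:
        raise ValueError("empty population spec")
    children = np.random.SeedSequence(seed).spawn(len(specs))
    counts = np.empty((len(specs), n_days * MINUTES_PER_DAY), dtype=float)
    for i, sp in enumerate(specs):
        rng = (
            np.random.default_rng(sp.seed)
            if sp.seed is not None
            else np.random.default_rng(children[i])
        )
        counts[i] = simulate_fly(sp, schedule, n_days, rng=rng)
    t0 = pd.Timestamp(start).normalize() + pd.Timedelta(
        hours=schedule.reference_lights_on
    )
    timestamps = pd.date_range(t0, periods=n_days * MINUTES_PER_DAY, freq="min")
    monitors = [i // N_CHANNELS + 1 for i in range(len(specs))]
    channels = [i % N_CHANNELS + 1 for i in range(len(specs))]
    ids = [f"M{m:02d}C{c:02d}" for m, c in zip(monitors, channels)]
    flies = pd.DataFrame(
        {
            "monitor": monitors,
            "channel": channels,
            "genotype": [sp.genotype for sp in specs],
            "sex": "male",
            "true_rhythmic": [sp.rhythmic for sp in specs],
            "true_tau_h": [sp.tau_h if sp.rhythmic else np.nan for sp in specs],
            "true_death_day": [
                -1 if sp.death_day is None else sp.death_day for sp in specs
            ],
        },
        index=pd.Index(ids, name="fly_id"),
    )
    return MonitorData(counts, timestamps, flies, schedule)


def simulate_timecourse(
    params: CyclingSimParams,
    n_days: int = 1,
    cluster: str = "sLNv",
    genotype: str = "sim",
) -> IntensityTimecourse:
    """Per-brain intensities on the collection grid, repeated over ``n_days``:

    ``I(b, t) = mesor + amplitude * (1 - damping)^(t/24) * cos(2π(t - acrophase)/24)
    + N(0, noise_sd)``.
    """
    rng = np.random.default_rng(params.seed if params.seed is not None else 0)
    times = np.concatenate(
        [np.asarray(params.timepoints_h, dtype=float) + 24.0 * d for d in range(n_days)]
    )
    records = []
    for t in times:
        mean = params.mesor + params.amplitude * (
            (1.0 - params.damping_per_day) ** (t / 24.0)
        ) * np.cos(2 * np.pi * (t - params.acrophase_h) / 24.0)
        vals = mean + rng.normal(0.0, params.noise_sd, params.n_brains_per_timepoint)
        for b, v in enumerate(vals):
            records.append((f"b{int(round(t)):03d}_{b:02d}", float(t), float(v)))
    data = pd.DataFrame(records, columns=["brain_id", "timepoint_h", "intensity"])
    return IntensityTimecourse(data=data, cluster=cluster, genotype=genotype)


def render_spot_image(
    width: int,
    height: int,
    spots: Sequence[tuple[float, float, float, float]],
    background_level: float = 0.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Render Gaussian spots onto a flat background (fixture generator for
    ROI quantification): returns (image[height, width], truth table)."""
    rng = np.random.default_rng(seed if seed is not None else 0)
    img = np.full((height, width), float(background_level))
    yy, xx = np.mgrid[0:height, 0:width]
    truth = []
    for (x, y, peak, sigma) in spots:
        if not (0 <= x < width and 0 <= y < height):
            raise ValueError(f"spot center ({x}, {y}) outside {width}x{height} frame")
        img += peak * np.exp(-(((xx - x) ** 2) + ((yy - y) ** 2)) / (2.0 * sigma**2))
        truth.append({"x": x, "y": y, "peak": peak, "sigma": sigma})
    if noise_sd > 0:
        img += rng.normal(0.0, noise_sd, img.shape)
    return img, pd.DataFrame(truth, columns=["x", "y", "peak", "sigma"])
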