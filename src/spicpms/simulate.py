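"""Synthetic paired sample/blank traces with known ground truth.

The generator reproduces the phenomenology the correction method assumes:

* background counts in each window are Poisson with mean proportional to
  the dwell time (rate ``background_rate`` counts per ms of dissolved
  analyte plus interferents);
* particle events arrive as a Poisson process in time; each event carries
  a whole-particle ion count that is Poisson around the calibration
  response to the particle's Ti mass;
* the event's ions arrive over a rectangular transient of duration tau
  placed uniformly in time, and are split multinomially across the dwell
  windows the transient overlaps — at short dwell times single particles
  therefore fragment into several windows, at long dwell times several
  particles can coincide in one window (counts add);
* particle sizes follow a lognormal or monodisperse model, and dilution
  scales the event rate without touching the background.

All randomness flows from a single seed through a documented
stream-splitting scheme (``numpy`` ``SeedSequence.spawn``): child 0 drives
the blank trace, child 1 the sample background, child 2 the particle
process, and further children the per-dwell backgrounds of a dwell sweep.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence, Union

import numpy as np

from .calibration import (
    CalibrationModel,
    default_calibration,
    particle_mass,
    sensitivity_for_lod,
)
from .trace_io import TimeTrace

#: expected particle events per window above which coincidence is likely
COINCIDENCE_DENSITY = 0.1


class CoincidenceWarning(UserWarning):
    """Raised when the particle density makes multi-particle windows likely."""


@dataclass
class LognormalSizes:
    """Lognormal diameter model: median (nm) and geometric sd."""

    median: float
    gsd: float

    def __post_init__(self) -> None:
        if self.median <= 0 or self.gsd < 1.0:
            raise ValueError("median must be > 0 and gsd >= 1")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return np.exp(rng.normal(np.log(self.median), np.log(self.gsd), n))


@dataclass
class MonodisperseSizes:
    """Single-diameter model."""

    diameter: float

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError("diameter must be > 0")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return np.full(n, self.diameter, dtype=float)


SizeModel = Union[LognormalSizes, MonodisperseSizes]


@dataclass
class SimulationConfig:
    background_rate: float = 4.0  # counts per ms
    n_windows: int = 6000
    dwell_time: float = 10.0  # ms
    particle_rate: float = 8.0  # expected particle events per second
    size_model: SizeModel = field(
        default_factory=lambda: LognormalSizes(median=150.0, gsd=1.3)
    )
    transient_duration: float = 0.5  # ms
    calibration: CalibrationModel = field(default_factory=default_calibration)
    dilution_factor: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.background_rate < 0:
            raise ValueError("background_rate must be >= 0")
        if self.transient_duration <= 0:
            raise ValueError("transient_duration must be > 0")
        if self.particle_rate < 0:
            raise ValueError("particle_rate must be >= 0")
        if self.dilution_factor < 1.0:
            raise ValueError("dilution_factor must be >= 1")
        if self.n_windows < 1:
            raise ValueError("n_windows must be >= 1")

    @property
    def total_time(self) -> float:
        """Acquisition length in seconds."""
        return self.n_windows * self.dwell_time / 1000.0


@dataclass
class GroundTruth:
    """Per-particle truth recorded by the generator."""

    diameters: np.ndarray  # nm
    total_counts: np.ndarray  # whole-particle ion counts
    arrival_times: np.ndarray  # s, transient start
    windows: list  # array of window indices touched, per particle
    split_counts: list  # counts deposited in each touched window

    @property
    def n_particles(self) -> int:
        return int(self.diameters.size)


def _rngs(seed: int, n_extra: int = 0) -> list[np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(3 + n_extra)
    return [np.random.default_rng(c) for c in children]


def simulate_background(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> TimeTrace:
    """Pure background trace: independent Poisson(lambda * t_dt) counts."""
    if rng is None:
        rng = _rngs(config.seed)[0]
    lam = config.background_rate * config.dwell_time
    counts = rng.poisson(lam, config.n_windows)
    return TimeTrace(
        counts=counts, dwell_time=config.dwell_time, label="background"
    )


def _draw_events(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw (arrival_times s, diameters nm, whole-particle counts)."""
    expected = config.particle_rate * config.total_time / config.dilution_factor
    n_events = rng.poisson(expected)
    tau_s = config.transient_duration / 1000.0
    t0 = rng.uniform(0.0, max(config.total_time - tau_s, 0.0), n_events)
    diameters = config.size_model.sample(rng, n_events)
    cal = config.calibration
    cal.require_complete()
    mass_ti = np.array(
        [particle_mass(d, cal.particle_density) for d in diameters]
    ) / cal.molar_ratio
    total_counts = rng.poisson(cal.sensitivity * mass_ti)
    return t0, diameters, total_counts


def _deposit_events(
    config: SimulationConfig,
    rng: np.random.Generator,
    t0: np.ndarray,
    total_counts: np.ndarray,
) -> tuple[np.ndarray, list, list]:
    """Split each event's counts multinomially across overlapped windows."""
    dwell_s = config.dwell_time / 1000.0
    tau_s = config.transient_duration / 1000.0
    signal = np.zeros(config.n_windows, dtype=np.int64)
    windows_per_event: list = []
    splits_per_event: list = []
    for start, q in zip(t0, total_counts):
        first = int(start / dwell_s)
        last = min(int((start + tau_s) / dwell_s), config.n_windows - 1)
        idx = np.arange(first, last + 1)
        lo = np.maximum(idx * dwell_s, start)
        hi = np.minimum((idx + 1) * dwell_s, start + tau_s)
        overlap = np.clip(hi - lo, 0.0, None)
        frac = overlap / overlap.sum()
        split = rng.multinomial(q, frac)
        signal[idx] += split
        touched = split > 0
        windows_per_event.append(idx[touched])
        splits_per_event.append(split[touched])
    return signal, windows_per_event, splits_per_event


def simulate_sample(config: SimulationConfig) -> tuple[TimeTrace, GroundTruth]:
    """Sample trace = background plus particle transients, with truth."""
    _, rng_bg, rng_events = _rngs(config.seed)
    expected = config.particle_rate * config.total_time / config.dilution_factor
    if expected / config.n_windows > COINCIDENCE_DENSITY:
        warnings.warn(
            f"expected {expected / config.n_windows:.3f} particle events per "
            "window; time-unresolved coincidence of several particles is likely",
            CoincidenceWarning,
        )
    t0, diameters, total_counts = _draw_events(config, rng_events)
    signal, windows, splits = _deposit_events(config, rng_events, t0, total_counts)
    background = rng_bg.poisson(
        config.background_rate * config.dwell_time, config.n_windows
    )
    trace = TimeTrace(
        counts=background + signal, dwell_time=config.dwell_time, label="sample"
    )
    truth = GroundTruth(
        diameters=diameters,
        total_counts=total_counts,
        arrival_times=t0,
        windows=windows,
        split_counts=splits,
    )
    return trace, truth


def simulate_pair(
    config: SimulationConfig,
) -> tuple[TimeTrace, TimeTrace, GroundTruth]:
    """Matched (sample, blank, truth) triple sharing one seed."""
    rng_blank = _rngs(config.seed)[0]
    blank = simulate_background(config, rng_blank)
    blank.label = "blank"
    sample, truth = simulate_sample(config)
    return sample, blank, truth


def simulate_dilution_series(
    config: SimulationConfig, factors: Sequence[float]
) -> list[tuple[TimeTrace, TimeTrace, GroundTruth]]:
    """One matched pair per dilution factor.

    A single blank trace is shared by the whole series — the experimental
    situation of correcting every dilution against the same deionized-water
    distribution — while each dilution gets its own sample background and a
    particle process whose expected event count scales as 1/factor.
    """
    if any(f < 1.0 for f in factors):
        raise ValueError("dilution factors must be >= 1")
    rngs = _rngs(config.seed, n_extra=2 * len(factors))
    blank = simulate_background(config, rngs[0])
    blank.label = "blank"
    out = []
    for k, f in enumerate(factors):
        sub = replace(config, dilution_factor=f)
        rng_bg, rng_events = rngs[3 + 2 * k], rngs[4 + 2 * k]
        t0, diameters, total_counts = _draw_events(sub, rng_events)
        signal, windows, splits = _deposit_events(sub, rng_events, t0, total_counts)
        sample = TimeTrace(
            counts=rng_bg.poisson(
                sub.background_rate * sub.dwell_time, sub.n_windows
            )
            + signal,
            dwell_time=sub.dwell_time,
            label=f"sample-dilution{f:g}",
        )
        truth = GroundTruth(
            diameters=diameters,
            total_counts=total_counts,
            arrival_times=t0,
            windows=windows,
            split_counts=splits,
        )
        out.append((sample, blank, truth))
    return out


def simulate_dwell_sweep(
    config: SimulationConfig, dwell_times: Sequence[float]
) -> list[tuple[TimeTrace, TimeTrace, GroundTruth]]:
    """Re-bin a single fixed particle population at several dwell times.

    The particle events (arrival times, sizes, whole-particle counts) are
    drawn once for the acquisition length implied by ``config`` and then
    deposited onto each dwell-time grid, so differences across the sweep
    reflect only window-splitting and the dwell-scaled background — the
    physical situation of re-acquiring the same suspension at different
    dwell settings.
    """
    rngs = _rngs(config.seed, n_extra=3 * len(dwell_times))
    rng_events = rngs[2]
    t0, diameters, total_counts = _draw_events(config, rng_events)
    out = []
    for k, dt in enumerate(dwell_times):
        n_win = int(round(config.total_time * 1000.0 / dt))
        sub = replace(config, dwell_time=dt, n_windows=n_win)
        rng_split, rng_bg, rng_blank = rngs[3 + 3 * k : 6 + 3 * k]
        signal, windows, splits = _deposit_events(sub, rng_split, t0, total_counts)
        lam = config.background_rate * dt
        sample = TimeTrace(
            counts=rng_bg.poisson(lam, n_win) + signal,
            dwell_time=dt,
            label=f"sample-{dt}ms",
        )
        blank = TimeTrace(
            counts=rng_blank.poisson(lam, n_win),
            dwell_time=dt,
            label=f"blank-{dt}ms",
        )
        truth = GroundTruth(
            diameters=diameters,
            total_counts=total_counts,
            arrival_times=t0,
            windows=windows,
            split_counts=splits,
        )
        out.append((sample, blank, truth))
    return out


def high_sensitivity_calibration(dwell_time: float = 16.0) -> CalibrationModel:
    """A collision-cell-grade TiO2 setup with LOD_size ~ 41.5 nm (five times
    the reference-instrument response), used by the polydisperse scenarios so that the
    whole size population is resolvable above the dissolved background."""
    return CalibrationModel(
        transport_efficiency=0.057,
        flow_rate=0.28,
        dwell_time=dwell_time,
        sensitivity=5.0 * sensitivity_for_lod(71.0),
    )


#: Named study scenarios.  ``dilution-series`` pairs with factors
#: (1, 2, 5, 10) and ``dwell-sweep`` with dwell times (4, 10, 16, 20) ms.
PRESET_DILUTION_FACTORS = (1.0, 2.0, 5.0, 10.0)
PRESET_DWELL_TIMES = (4.0, 10.0, 16.0, 20.0)


def preset(name: str, seed: int = 0) -> SimulationConfig:
    """Build the :class:`SimulationConfig` of a named scenario.

    * ``blank-only``       — 60 s of pure background at 10 ms dwell.
    * ``monodisperse``     — 150 nm particles, ~500 events in 60 s, 10 ms.
    * ``polydisperse``     — lognormal(150 nm, GSD 1.3), ~500 events in
      100 s at 16 ms dwell, high-sensitivity response.
    * ``dilution-series``  — polydisperse stock, ~600 events in 60 s at
      10 ms; run through :func:`simulate_dilution_series`.
    * ``dwell-sweep``      — fixed polydisperse population over 100 s; run
      through :func:`simulate_dwell_sweep`.
    """
    common = dict(background_rate=4.0, transient_duration=0.5, seed=seed)
    if name == "blank-only":
        return SimulationConfig(
            n_windows=6000, dwell_time=10.0, particle_rate=0.0, **common
        )
    if name == "monodisperse":
        return SimulationConfig(
            n_windows=6000,
            dwell_time=10.0,
            particle_rate=500.0 / 60.0,
            size_model=MonodisperseSizes(150.0),
            calibration=high_sensitivity_calibration(10.0),
            **common,
        )
    if name == "polydisperse":
        return SimulationConfig(
            n_windows=6250,
            dwell_time=16.0,
            particle_rate=5.0,
            size_model=LognormalSizes(150.0, 1.3),
            calibration=high_sensitivity_calibration(16.0),
            **common,
        )
    if name == "dilution-series":
        return SimulationConfig(
            n_windows=6000,
            dwell_time=10.0,
            particle_rate=10.0,
            size_model=LognormalSizes(150.0, 1.3),
            calibration=high_sensitivity_calibration(10.0),
            **common,
        )
    if name == "dwell-sweep":
        return SimulationConfig(
            n_windows=10000,
            dwell_time=10.0,
            particle_rate=5.0,
            size_model=LognormalSizes(150.0, 1.3),
            calibration=high_sensitivity_calibration(10.0),
            **common,
        )
    raise ValueError(f"unknown preset {name!r}")
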