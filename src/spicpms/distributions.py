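"""Frequency-intensity distributions and classical background thresholds.

The central data structure of millisecond SP-ICP-MS processing: a histogram
of how many dwell-time windows registered each integer count value.  Bin
width is fixed at 1 count because detector counts are integers.  Difference
histograms produced by the background correction carry ``signed=True`` and
may hold negative (and fractional) frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, NamedTuple

import numpy as np
from scipy import stats

from .trace_io import TimeTrace

_SUM_TOL = 1e-9


@dataclass
class IntensityDistribution:
    """Mapping intensity (integer counts) -> frequency, with window total N."""

    frequencies: dict[int, float]
    n: float
    dwell_time: float
    signed: bool = False

    def __post_init__(self) -> None:
        self.frequencies = {int(i): float(f) for i, f in self.frequencies.items()}
        if any(i < 0 for i in self.frequencies):
            raise ValueError("intensity keys must be >= 0")
        if not self.signed:
            if any(f < 0 for f in self.frequencies.values()):
                raise ValueError("unsigned distribution with negative frequency")
            total = sum(self.frequencies.values())
            if abs(total - self.n) > _SUM_TOL * max(1.0, self.n):
                raise ValueError(
                    f"frequencies sum to {total}, expected N = {self.n}"
                )

    @property
    def intensities(self) -> np.ndarray:
        return np.array(sorted(self.frequencies), dtype=np.int64)

    def freq(self, intensity: int) -> float:
        return self.frequencies.get(int(intensity), 0.0)

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            fh.write("intensity\tfrequency\n")
            for i in sorted(self.frequencies):
                fh.write(f"{i}\t{self.frequencies[i]!r}\n")
        return path


class DistributionSummary(NamedTuple):
    mean: float
    sd: float
    mode: int
    min: int
    max: int
    width: int


def build_distribution(trace: TimeTrace) -> IntensityDistribution:
    """Histogram a trace into frequency-intensity coordinates.

    ``frequencies[i]`` is the number of windows that registered exactly
    ``i`` counts; the frequencies sum to the window total N.
    """
    values, counts = np.unique(trace.counts, return_counts=True)
    freqs = {int(v): float(c) for v, c in zip(values, counts)}
    return IntensityDistribution(
        frequencies=freqs, n=float(trace.n), dwell_time=trace.dwell_time
    )


def _check_unsigned(dist: IntensityDistribution) -> None:
    if dist.signed:
        raise ValueError("operation requires an unsigned distribution")
    if not dist.frequencies or dist.n <= 0:
        raise ValueError("empty distribution")


def summary_stats(dist: IntensityDistribution) -> DistributionSummary:
    """Frequency-weighted mean, population sd, mode (smallest on ties),
    min, max and width of an unsigned distribution."""
    _check_unsigned(dist)
    intens = dist.intensities.astype(float)
    freqs = np.array([dist.frequencies[int(i)] for i in intens])
    total = freqs.sum()
    mean = float(np.dot(intens, freqs) / total)
    var = float(np.dot((intens - mean) ** 2, freqs) / total)
    mode = modal_intensity(dist)
    lo, hi = int(intens.min()), int(intens.max())
    return DistributionSummary(mean, np.sqrt(var), mode, lo, hi, hi - lo)


def modal_intensity(dist: IntensityDistribution) -> int:
    """Intensity of the maximum frequency; smallest such intensity on ties."""
    _check_unsigned(dist)
    best = max(dist.frequencies.values())
    return min(i for i, f in dist.frequencies.items() if f == best)


def nsigma_threshold(dist: IntensityDistribution, n: float) -> float:
    """Classical particle/background discriminator: mean + n * sd.

    Returned real-valued (not rounded); signals *strictly above* the
    threshold are candidate particles.
    """
    if n <= 0:
        raise ValueError("sigma multiplier must be > 0")
    s = summary_stats(dist)
    return s.mean + n * s.sd


def poisson_threshold(dist: IntensityDistribution, alpha: float) -> int:
    """Poisson decision threshold, the comparison criterion used by
    single-particle calculators: the smallest integer L such that
    P(X > L) <= alpha for X ~ Poisson(mean of the distribution)."""
    _check_unsigned(dist)
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must be in (0, 1]")
    mu = summary_stats(dist).mean
    # smallest L with cdf(L) >= 1 - alpha; scipy's ppf of 0 is -1, clamp.
    level = stats.poisson.ppf(1.0 - alpha, mu)
    return int(max(level, 0))


def count_above(dist: IntensityDistribution, threshold: float) -> float:
    """Total frequency strictly above an intensity threshold."""
    if dist.signed:
        raise ValueError("operation requires an unsigned distribution")
    return float(sum(f for i, f in dist.frequencies.items() if i > threshold))
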