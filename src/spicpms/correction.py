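"""Histogram-subtraction background correction for monomodal SP-ICP-MS data.

When the particle signal distribution is inseparable from the dissolved-
element background distribution, fixed n-sigma thresholds either leave
false-positive background signals in the particle set or cut genuine
low-intensity particle signals.  This module removes the background by
working on the frequency-intensity histograms of a sample trace and a
matched blank acquired under identical conditions:

1. subtract the blank histogram from the sample histogram bin by bin;
2. the summed magnitude of the negative bins counts the particle events
   N_NP (windows that an NP pulse displaced out of the background shape);
3. N_bgd = N - N_NP background windows remain in the sample;
4. rescale the blank histogram by N_bgd / N so it represents only the
   background windows actually present in the sample;
5. subtract the rescaled blank from the sample histogram; the transition
   from negative to positive frequencies marks the background/particle
   boundary, and the modal background intensity is netted out of every
   particle pulse.

Frequencies stay fractional throughout steps 4-5; rounding happens only
when per-particle net intensities are emitted, because premature rounding
breaks the sum identity of step 4.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, TypeVar

import numpy as np

from .distributions import IntensityDistribution, modal_intensity

log = logging.getLogger(__name__)

_MODE_GAP_WARN = 2  # counts; diagnostic gap between I_mode and I_t


@dataclass
class CorrectionResult:
    """Outputs of one correction run on a sample/blank histogram pair."""

    n_total: float
    n_particles: float
    n_background: float
    transition_intensity: int
    modal_background: int
    corrected_distribution: IntensityDistribution  # signed, sample - bgd_corr
    net_intensities: np.ndarray  # one net count value (>= 1) per particle
    diagnostics: dict = field(default_factory=dict)


def _require_compatible(
    sample: IntensityDistribution, bgd: IntensityDistribution
) -> None:
    if sample.signed or bgd.signed:
        raise ValueError("both distributions must be unsigned")
    if sample.n != bgd.n:
        raise ValueError(
            f"window totals differ (sample N={sample.n}, background N={bgd.n}); "
            "acquire sample and blank over the same number of dwell windows"
        )
    if sample.dwell_time != bgd.dwell_time:
        raise ValueError(
            f"dwell times differ ({sample.dwell_time} vs {bgd.dwell_time} ms)"
        )


def subtract_distributions(
    sample: IntensityDistribution, bgd: IntensityDistribution
) -> IntensityDistribution:
    """Per-intensity difference sample - background over the union of
    intensity keys.  Requires equal window totals and dwell times; the
    result is signed and sums to zero."""
    _require_compatible(sample, bgd)
    keys = set(sample.frequencies) | set(bgd.frequencies)
    diff = {i: sample.freq(i) - bgd.freq(i) for i in keys}
    return IntensityDistribution(
        frequencies=diff, n=0.0, dwell_time=sample.dwell_time, signed=True
    )


def particle_count(diff: IntensityDistribution) -> float:
    """Number of particle events: the summed magnitude of the negative
    frequencies of an equal-N difference histogram (equal, by the zero-sum
    property, to the summed positive frequencies)."""
    if not diff.signed:
        raise ValueError("particle_count expects a signed difference histogram")
    return float(sum(-f for f in diff.frequencies.values() if f < 0))


def scale_background(
    bgd: IntensityDistribution, n_bgd: float, n_total: float
) -> IntensityDistribution:
    """Rescale a blank histogram to the N_bgd background windows actually
    present in the sample.  Frequencies are kept fractional; their sum is
    N_bgd to within 1e-9."""
    if bgd.signed:
        raise ValueError("scale_background expects an unsigned distribution")
    if not 0.0 <= n_bgd <= n_total:
        raise ValueError(f"n_bgd={n_bgd} outside [0, {n_total}]")
    factor = n_bgd / n_total
    scaled = {i: f * factor for i, f in bgd.frequencies.items()}
    return IntensityDistribution(
        frequencies=scaled, n=n_bgd, dwell_time=bgd.dwell_time
    )


def corrected_sample(
    sample: IntensityDistribution, bgd_corr: IntensityDistribution
) -> IntensityDistribution:
    """Per-intensity difference sample - rescaled background.  A small
    negative residual may remain where small-particle signals overlap the
    background; it is reported, not clipped, here."""
    if sample.signed:
        raise ValueError("sample distribution must be unsigned")
    keys = set(sample.frequencies) | set(bgd_corr.frequencies)
    diff = {i: sample.freq(i) - bgd_corr.freq(i) for i in keys}
    return IntensityDistribution(
        frequencies=diff, n=0.0, dwell_time=sample.dwell_time, signed=True
    )


def transition_intensity(diff_corr: IntensityDistribution) -> int:
    """The background/particle boundary: the largest intensity whose
    corrected frequency is negative (the last negative-to-positive
    crossing).  Returns -1 when no frequency is negative, i.e. everything
    above zero intensity is particle-dominated."""
    negatives = [i for i, f in diff_corr.frequencies.items() if f < 0]
    return max(negatives) if negatives else -1


def modal_background(bgd: IntensityDistribution) -> int:
    """The background intensity netted out of each pulse: the intensity at
    the maximum of the blank histogram (smallest such intensity on ties)."""
    return modal_intensity(bgd)


def run_correction(
    sample: IntensityDistribution, bgd: IntensityDistribution
) -> CorrectionResult:
    """Execute the full correction chain on a sample/blank histogram pair.

    Per-particle net intensities are emitted for every intensity strictly
    above the transition point, with multiplicity equal to the corrected
    frequency rounded to the nearest non-negative integer, and the modal
    background intensity subtracted.  Net values below 1 count are dropped
    (indistinguishable from background fluctuations).
    """
    _require_compatible(sample, bgd)
    diff = subtract_distributions(sample, bgd)
    n_np = particle_count(diff)
    n = sample.n
    n_bgd = n - n_np
    bgd_corr = scale_background(bgd, n_bgd, n)
    diff_corr = corrected_sample(sample, bgd_corr)
    i_t = transition_intensity(diff_corr)
    i_mode = modal_background(bgd)

    diagnostics: dict = {}
    residual_neg = sum(-f for f in diff_corr.frequencies.values() if f < 0)
    diagnostics["residual_negative_mass"] = residual_neg
    if abs(i_mode - i_t) > _MODE_GAP_WARN and i_t >= 0:
        msg = (
            f"modal background {i_mode} and transition intensity {i_t} "
            f"differ by more than {_MODE_GAP_WARN} counts"
        )
        diagnostics.setdefault("warnings", []).append(msg)
        log.warning(msg)

    nets: list[int] = []
    discarded = 0.0
    for i in sorted(sample.frequencies):
        if i <= i_t:
            continue
        multiplicity = int(round(max(diff_corr.freq(i), 0.0)))
        if multiplicity == 0:
            continue
        net = i - i_mode
        if net >= 1:
            nets.extend([net] * multiplicity)
        else:
            discarded += multiplicity
    diagnostics["net_below_one_count"] = discarded

    log.info(
        "correction: N=%s N_NP=%s N_bgd=%s I_t=%s I_mode=%s residual_neg=%.3f",
        n, n_np, n_bgd, i_t, i_mode, residual_neg,
    )
    return CorrectionResult(
        n_total=n,
        n_particles=n_np,
        n_background=n_bgd,
        transition_intensity=i_t,
        modal_background=i_mode,
        corrected_distribution=diff_corr,
        net_intensities=np.array(nets, dtype=np.int64),
        diagnostics=diagnostics,
    )


K = TypeVar("K", int, float)


def tail_filter(
    bins: Mapping[K, float], min_frequency: float = 10.0
) -> dict[K, float]:
    """Remove rare high-value bins from the tail of a distribution.

    Bins are dropped from the highest key inward while their frequency is
    below ``min_frequency``; the first bin meeting the minimum stops the
    scan, so interior low-frequency bins are never removed.
    """
    keys = sorted(bins)
    keep = len(keys)
    for k in reversed(keys):
        if bins[k] < min_frequency:
            keep -= 1
        else:
            break
    return {k: bins[k] for k in keys[:keep]}


def tail_filter_distribution(
    dist: IntensityDistribution, min_frequency: float = 10.0
) -> IntensityDistribution:
    """:func:`tail_filter` applied to an unsigned intensity distribution."""
    if dist.signed:
        raise ValueError("tail_filter expects an unsigned distribution")
    kept = tail_filter(dist.frequencies, min_frequency)
    return IntensityDistribution(
        frequencies=kept,
        n=float(sum(kept.values())),
        dwell_time=dist.dwell_time,
    )
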