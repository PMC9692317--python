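"""End-to-end orchestration: traces in, corrected size distribution out."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import trace_io
from .calibration import CalibrationModel, intensity_to_size, lod_size
from .correction import CorrectionResult, run_correction, tail_filter
from .distributions import build_distribution
from .trace_io import TimeTrace

log = logging.getLogger(__name__)


@dataclass
class SizeDistribution:
    """Particle diameters (nm, nearest-nm bins) with frequencies.

    ``max_position`` is the modal size bin (smallest on ties) and
    ``right_wing`` the largest size bin surviving the minimum-frequency
    tail filter; both are ``None`` for an empty distribution.
    """

    bins: dict[int, float]
    max_position: Optional[int]
    right_wing: Optional[int]
    n_particles: float
    lod_size: float
    dwell_time: float
    diagnostics: dict = field(default_factory=dict)


def _with_dwell(cal: CalibrationModel, dwell_time: float) -> CalibrationModel:
    return replace(cal, dwell_time=dwell_time)


def _count_histogram(intensities: np.ndarray) -> dict[int, float]:
    values, counts = np.unique(intensities, return_counts=True)
    return {int(v): float(c) for v, c in zip(values, counts)}


def _assemble(
    intensities: np.ndarray,
    cal: CalibrationModel,
    min_frequency: float,
) -> tuple[dict[int, float], Optional[int], Optional[int], float]:
    """Build nearest-nm bins, tail-filter them, and locate the distribution
    maximum on the native 1-count intensity grid of the surviving pulses.

    The rare-event filter operates on the size bins (where tail pulses
    accumulate), but the maximum is located on the intensity grid because
    nearest-nm bins merge an uneven number of integer count values once the
    per-count size step falls below 1 nm, which distorts bin frequencies.
    """
    counts_hist = _count_histogram(intensities)
    if not counts_hist:
        return {}, None, None, 0.0
    nm_of = {i: int(round(intensity_to_size(i, cal))) for i in counts_hist}
    bins: dict[int, float] = {}
    for i, f in counts_hist.items():
        bins[nm_of[i]] = bins.get(nm_of[i], 0.0) + f
    bins = tail_filter(bins, min_frequency)
    if not bins:
        return {}, None, None, 0.0
    kept = {i: f for i, f in counts_hist.items() if nm_of[i] in bins}
    best = max(kept.values())
    modal_count = min(i for i, f in kept.items() if f == best)
    mode = int(round(intensity_to_size(modal_count, cal)))
    return bins, mode, max(bins), float(sum(bins.values()))


def size_distribution(
    result: CorrectionResult,
    cal: CalibrationModel,
    min_frequency: float = 10.0,
) -> SizeDistribution:
    """Convert per-particle net intensities into a size distribution.

    Net intensities map through the calibration to equivalent spherical
    diameters; sizes below the 1-count detection limit are removed, the
    rare-event tail filter is applied, and the modal position and right
    wing are summarized.  Sizes are reported to the nearest nm without
    further binning (net intensities are integer counts, so sizes are
    naturally discrete).
    """
    cal.require_complete()
    lod = lod_size(cal)
    sizes = np.array(
        [intensity_to_size(i, cal) for i in result.net_intensities], dtype=float
    )
    below = sizes < lod
    if below.any():
        log.warning("%d particles below LOD_size %.1f nm removed", below.sum(), lod)
    kept = result.net_intensities[~below]
    bins, mode, wing, n_kept = _assemble(kept, cal, min_frequency)
    if not bins and result.net_intensities.size:
        log.warning("all particles removed by LOD floor or tail filter")
    return SizeDistribution(
        bins=bins,
        max_position=mode,
        right_wing=wing,
        n_particles=n_kept,
        lod_size=lod,
        dwell_time=cal.dwell_time,
        diagnostics={"n_below_lod": int(below.sum())},
    )


def uncorrected_size_distribution(
    result: CorrectionResult,
    cal: CalibrationModel,
    min_frequency: float = 10.0,
) -> SizeDistribution:
    """Size distribution of the same candidate pulses *without* netting out
    the modal background: gross window intensities mapped straight through
    the calibration.  This is the 'before correction' view in which the
    distribution maximum rides up with the dwell-scaled background."""
    cal.require_complete()
    gross = result.net_intensities + result.modal_background
    bins, mode, wing, n_kept = _assemble(gross, cal, min_frequency)
    return SizeDistribution(
        bins=bins,
        max_position=mode,
        right_wing=wing,
        n_particles=n_kept,
        lod_size=lod_size(cal),
        dwell_time=cal.dwell_time,
    )


def process_pair(
    sample: TimeTrace,
    blank: TimeTrace,
    cal: CalibrationModel,
    min_frequency: float = 10.0,
) -> tuple[CorrectionResult, SizeDistribution]:
    """Full pipeline on one matched sample/blank trace pair."""
    result = run_correction(build_distribution(sample), build_distribution(blank))
    sizes = size_distribution(result, _with_dwell(cal, sample.dwell_time), min_frequency)
    return result, sizes


def dwell_sweep_report(
    samples: Sequence[TimeTrace],
    blanks: Sequence[TimeTrace],
    cal: CalibrationModel,
    min_frequency: float = 10.0,
) -> pd.DataFrame:
    """Per-dwell-time summary: uncorrected and corrected distribution
    maxima, right wing and particle count — one row per dwell time."""
    blank_by_dwell = {b.dwell_time: b for b in blanks}
    rows = []
    for sample in samples:
        blank = blank_by_dwell.get(sample.dwell_time)
        if blank is None:
            raise ValueError(
                f"no blank matches sample dwell time {sample.dwell_time} ms"
            )
        result, sizes = process_pair(sample, blank, cal, min_frequency)
        uncorrected = uncorrected_size_distribution(
            result, _with_dwell(cal, sample.dwell_time), min_frequency
        )
        rows.append(
            {
                "dwell_time_ms": sample.dwell_time,
                "uncorrected_max_nm": uncorrected.max_position,
                "corrected_max_nm": sizes.max_position,
                "right_wing_nm": sizes.right_wing,
                "n_particles": result.n_particles,
            }
        )
    return pd.DataFrame(rows).sort_values("dwell_time_ms").reset_index(drop=True)


def report_header(result: CorrectionResult, sizes: SizeDistribution) -> dict:
    return {
        "N": result.n_total,
        "N_NP": result.n_particles,
        "N_bgd": result.n_background,
        "transition_intensity": result.transition_intensity,
        "modal_background": result.modal_background,
        "max_position_nm": sizes.max_position,
        "right_wing_nm": sizes.right_wing,
        "lod_size_nm": sizes.lod_size,
        "dwell_time_ms": sizes.dwell_time,
    }


def write_size_report(
    result: CorrectionResult,
    sizes: SizeDistribution,
    path: str | Path,
) -> Path:
    """Serialize a correction run and its size distribution as TSV."""
    return trace_io.write_report(report_header(result, sizes), sizes.bins, path)
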