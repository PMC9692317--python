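"""Reading and writing time-resolved SP-ICP-MS traces and reports.

A trace file is a single column of integer detector counts, one value per
dwell-time window, optionally preceded by ``#``-prefixed ``key: value``
header lines carrying the dwell time, m/z and label.  Vendor exports vary;
this is the simplest common denominator and is what the simulator writes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Optional

import numpy as np
import yaml

log = logging.getLogger(__name__)

_INT_TOL = 1e-9


@dataclass
class TimeTrace:
    """Sequence of per-window detector counts with acquisition metadata.

    Window ``k`` spans the half-open interval ``[k*dwell_time, (k+1)*dwell_time)``.
    Counts are absolute counts per window (not cps).
    """

    counts: np.ndarray
    dwell_time: float  # ms
    total_time: Optional[float] = None  # s
    mz: Optional[int] = None
    label: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.size < 1:
            raise ValueError("no windows: a trace needs at least one count value")
        if not np.issubdtype(self.counts.dtype, np.integer):
            rounded = np.rint(self.counts)
            if np.any(np.abs(self.counts - rounded) > _INT_TOL):
                raise ValueError("counts must be integers (within 1e-9)")
            self.counts = rounded.astype(np.int64)
        else:
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            raise ValueError("negative count in trace")
        if self.dwell_time <= 0:
            raise ValueError("dwell_time must be > 0")
        implied = self.n * self.dwell_time / 1000.0
        if self.total_time is None:
            self.total_time = implied
        elif abs(self.total_time - implied) > self.dwell_time / 1000.0:
            raise ValueError(
                f"total_time {self.total_time} s inconsistent with "
                f"{self.n} windows of {self.dwell_time} ms"
            )

    @property
    def n(self) -> int:
        """Total number of dwell-time windows N."""
        return int(self.counts.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TimeTrace):
            return NotImplemented
        return (
            np.array_equal(self.counts, other.counts)
            and self.dwell_time == other.dwell_time
            and self.mz == other.mz
            and self.label == other.label
        )


@dataclass
class RunConfig:
    """Flat run configuration for the pipeline and CLI."""

    dwell_time: float = 10.0  # ms
    min_tail_frequency: float = 10.0
    sigma_multiplier: float = 3.0
    seed: int = 0
    dilution_factor: float = 1.0
    paths: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.dwell_time <= 0:
            raise ValueError("dwell_time must be > 0")
        if self.min_tail_frequency < 0:
            raise ValueError("min_tail_frequency must be >= 0")


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    known = {k: v for k, v in data.items() if k in RunConfig.__dataclass_fields__}
    return RunConfig(**known)


def _parse_value(token: str, lineno: int) -> int:
    try:
        x = float(token)
    except ValueError as exc:
        raise ValueError(f"non-numeric record on line {lineno}: {token!r}") from exc
    r = round(x)
    if abs(x - r) > _INT_TOL:
        raise ValueError(f"non-integer count on line {lineno}: {token!r}")
    if r < 0:
        raise ValueError(f"negative count on line {lineno}: {token!r}")
    return int(r)


def read_trace(
    path: str | Path,
    dwell_time: Optional[float] = None,
    mz: Optional[int] = None,
) -> TimeTrace:
    """Read a single-column counts file into a :class:`TimeTrace`.

    ``#``-header metadata in the file is used unless overridden by the
    keyword arguments.  Non-integer values within 1e-9 of an integer are
    rounded; anything else is an error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"trace file not found: {path}")
    meta: dict[str, Any] = {}
    values: list[int] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if ":" in body:
                    key, _, val = body.partition(":")
                    meta[key.strip()] = val.strip()
                continue
            values.append(_parse_value(line, lineno))
    if not values:
        raise ValueError(f"no windows: {path} contains no count records")
    if dwell_time is None:
        dwell_time = float(meta.get("dwell_time", 0.0) or 0.0)
        if dwell_time <= 0:
            raise ValueError(f"dwell_time not given and absent from {path} header")
    if mz is None and "mz" in meta:
        mz = int(meta["mz"])
    label = meta.get("label", path.stem)
    total_time = float(meta["total_time"]) if "total_time" in meta else None
    return TimeTrace(
        counts=np.array(values, dtype=np.int64),
        dwell_time=float(dwell_time),
        total_time=total_time,
        mz=mz,
        label=label,
    )


def write_trace(trace: TimeTrace, path: str | Path) -> Path:
    """Write a trace in the single-column dialect read by :func:`read_trace`."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# dwell_time: {trace.dwell_time!r}\n")
        if trace.mz is not None:
            fh.write(f"# mz: {trace.mz}\n")
        if trace.label:
            fh.write(f"# label: {trace.label}\n")
        for c in trace.counts:
            fh.write(f"{int(c)}\n")
    return path


def counts_to_cps(counts: float, dwell_time: float) -> float:
    """Convert absolute counts in one window to counts per second."""
    if dwell_time <= 0:
        raise ValueError("dwell_time must be > 0")
    return counts / (dwell_time / 1000.0)


def cps_to_counts(cps: float, dwell_time: float) -> float:
    """Inverse of :func:`counts_to_cps`; exact roundtrip for rational inputs."""
    if dwell_time <= 0:
        raise ValueError("dwell_time must be > 0")
    return cps * (dwell_time / 1000.0)


def write_report(
    header: Mapping[str, Any],
    bins: Mapping[float, float],
    path: str | Path,
) -> Path:
    """Write a sizing report: ``#`` key-value header block plus one
    ``size_nm<TAB>frequency`` row per size bin.  Floats are written with
    ``repr`` so the file re-reads bit-exactly."""
    path = Path(path)
    if not bins:
        log.warning("writing report with empty size distribution: %s", path)
    with open(path, "w") as fh:
        for key, val in header.items():
            fh.write(f"# {key}\t{val!r}\n")
        fh.write("size_nm\tfrequency\n")
        for size in sorted(bins):
            fh.write(f"{size!r}\t{bins[size]!r}\n")
    return path


def _parse_header_value(val: str) -> Any:
    try:
        return int(val)
    except ValueError:
        pass
    try:
        return float(val)
    except ValueError:
        pass
    if val == "None":
        return None
    return val.strip("'\"")


def read_report(path: str | Path) -> tuple[dict[str, Any], dict[float, float]]:
    """Read a report written by :func:`write_report`."""
    header: dict[str, Any] = {}
    bins: dict[float, float] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line.lstrip("#").strip().partition("\t")
                header[key] = _parse_header_value(val)
                continue
            if line.startswith("size_nm"):
                continue
            size, _, freq = line.partition("\t")
            bins[float(size)] = float(freq)
    if not bins:
        warnings.warn(f"report {path} holds an empty size distribution")
    return header, bins
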