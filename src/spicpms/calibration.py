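"""Indirect size calibration for SP-ICP-MS without particle standards.

The chain: (i) the mass of a single spherical particle from its diameter
and bulk density; (ii) transport efficiency from a particle-number standard
(60 nm Ag) of known mass concentration; (iii) the detected analyte mass per
dwell window implied by a dissolved standard of concentration C,
m = eta_TE * V * t_dt * C; (iv) an origin-constrained straight line of
blank-subtracted intensity against that detected mass, whose slope is the
instrument sensitivity in counts per gram of Ti; (v) intensity -> particle
mass -> equivalent spherical diameter.

Ionization efficiency is taken as 100% and the transport efficiency of the
Ag standard and the analyte particles as identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np

from . import units

#: Bulk density of TiO2, g/cm^3.
TIO2_DENSITY = 4.23
#: Standard literature density of silver, g/cm^3 (for the 60 nm Ag standard).
AG_DENSITY = 10.49


@dataclass
class ParticleStandard:
    """A particle-number standard of known size and mass concentration."""

    diameter: float  # nm
    density: float  # g/cm^3
    mass_concentration: float  # ug/L of dispersion
    element: str = "Ag"

    def __post_init__(self) -> None:
        if self.diameter <= 0 or self.density <= 0:
            raise ValueError("diameter and density must be > 0")


@dataclass
class CalibrationModel:
    """Everything needed to turn a net pulse intensity into a diameter."""

    transport_efficiency: float  # dimensionless fraction
    flow_rate: float  # mL/min
    dwell_time: float  # ms
    sensitivity: float | None = None  # counts per gram of detected Ti
    molar_ratio: float = units.molar_ratio_tio2_ti()  # TiO2/Ti mass factor
    particle_density: float = TIO2_DENSITY  # g/cm^3

    def __post_init__(self) -> None:
        if not 0.0 < self.transport_efficiency <= 1.0:
            raise ValueError("transport_efficiency must be in (0, 1]")
        if self.flow_rate <= 0 or self.dwell_time <= 0:
            raise ValueError("flow_rate and dwell_time must be > 0")
        if self.sensitivity is not None and self.sensitivity <= 0:
            raise ValueError("sensitivity must be > 0")
        if self.molar_ratio < 1.0:
            raise ValueError("molar_ratio must be >= 1")

    @property
    def complete(self) -> bool:
        return self.sensitivity is not None

    def require_complete(self) -> None:
        if not self.complete:
            raise ValueError("incomplete calibration: sensitivity not fitted")

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            for key in (
                "transport_efficiency",
                "flow_rate",
                "dwell_time",
                "sensitivity",
                "molar_ratio",
                "particle_density",
            ):
                fh.write(f"{key}\t{getattr(self, key)!r}\n")
        return path

    @classmethod
    def load(cls, path: str | Path) -> "CalibrationModel":
        kwargs = {}
        with open(path) as fh:
            for line in fh:
                key, _, val = line.strip().partition("\t")
                kwargs[key] = None if val == "None" else float(val)
        return cls(**kwargs)


def particle_mass(diameter: float, density: float) -> float:
    """Mass (g) of a spherical particle: m = d^3 * pi * rho / 6."""
    if diameter < 0:
        raise ValueError("diameter must be >= 0")
    if density <= 0:
        raise ValueError("density must be > 0")
    d_cm = units.nm_to_cm(diameter)
    return d_cm**3 * math.pi * density / 6.0


def particle_size(mass: float, density: float) -> float:
    """Equivalent spherical diameter (nm): d = (6 m / (pi rho))^(1/3)."""
    if mass < 0:
        raise ValueError("mass must be >= 0")
    if density <= 0:
        raise ValueError("density must be > 0")
    d_cm = (6.0 * mass / (math.pi * density)) ** (1.0 / 3.0)
    return units.cm_to_nm(d_cm)


def transport_efficiency(
    n_detected: float,
    standard: ParticleStandard,
    flow_rate: float,
    acquisition_time: float,
) -> float:
    """Fraction of nebulized particles reaching the detector.

    The ratio of detected particle events to the number of standard
    particles introduced during the acquisition, the latter computed from
    the standard's mass concentration (ug/L), the sample flow rate
    (mL/min), the acquisition time (s) and the single-particle mass.
    """
    if n_detected <= 0 or flow_rate <= 0 or acquisition_time <= 0:
        raise ValueError("all inputs must be > 0")
    volume_l = units.ml_per_min_to_l_per_s(flow_rate) * acquisition_time
    introduced_mass = units.ug_per_l_to_g_per_l(standard.mass_concentration) * volume_l
    n_introduced = introduced_mass / particle_mass(standard.diameter, standard.density)
    if n_introduced <= 0:
        raise ValueError("zero particles introduced")
    return n_detected / n_introduced


def mass_per_window(concentration: float, cal: CalibrationModel) -> float:
    """Detected Ti mass (g) per dwell window for a dissolved standard of
    concentration ``concentration`` (ug/L): m = eta_TE * V * t_dt * C."""
    if concentration < 0:
        raise ValueError("concentration must be >= 0")
    flow_l_s = units.ml_per_min_to_l_per_s(cal.flow_rate)
    dwell_s = units.ms_to_s(cal.dwell_time)
    c_g_l = units.ug_per_l_to_g_per_l(concentration)
    return cal.transport_efficiency * flow_l_s * dwell_s * c_g_l


class SensitivityFit(NamedTuple):
    sensitivity: float  # counts per gram Ti
    stderr: float
    residuals: np.ndarray
    blank_intensity: float


def fit_sensitivity(
    points: Sequence[tuple[float, float]],
    cal: CalibrationModel,
) -> SensitivityFit:
    """Fit the transformed calibration line intensity = s * m through the
    origin, where m is the detected Ti mass per window implied by each
    standard concentration.

    ``points`` are (concentration ug/L, mean intensity counts).  If a blank
    (C = 0) point is present its intensity is subtracted from every point;
    otherwise the intensities are assumed already blank-corrected.
    """
    pts = [(float(c), float(i)) for c, i in points]
    if len(pts) < 2:
        raise ValueError("need at least 2 calibration points")
    blank = next((i for c, i in pts if c == 0.0), 0.0)
    nonblank = [(c, i - blank) for c, i in pts if c > 0.0]
    if not nonblank:
        raise ValueError("need at least one non-blank concentration")
    masses = np.array([mass_per_window(c, cal) for c, _ in nonblank])
    intens = np.array([i for _, i in nonblank])
    denom = float(np.dot(masses, masses))
    if denom == 0.0:
        raise ValueError("zero variance in detected mass")
    slope = float(np.dot(masses, intens) / denom)
    resid = intens - slope * masses
    dof = max(len(masses) - 1, 1)
    stderr = float(np.sqrt((resid @ resid) / dof / denom))
    if slope <= 0:
        raise ValueError("fitted sensitivity is not positive")
    return SensitivityFit(slope, stderr, resid, blank)


def intensity_to_size(net_intensity: float, cal: CalibrationModel) -> float:
    """Diameter (nm) of the particle whose whole-particle signal is
    ``net_intensity`` counts: counts -> Ti mass -> oxide mass -> sphere."""
    cal.require_complete()
    if net_intensity < 0:
        raise ValueError("net intensity must be >= 0")
    mass_ti = net_intensity / cal.sensitivity
    mass_np = mass_ti * cal.molar_ratio
    return particle_size(mass_np, cal.particle_density)


def lod_size(cal: CalibrationModel) -> float:
    """Size detection limit: the diameter whose whole-particle signal is a
    single count.  Depends only on the calibration, not on the background
    distribution."""
    return intensity_to_size(1.0, cal)


def sensitivity_for_lod(
    lod_nm: float,
    molar_ratio: float = units.molar_ratio_tio2_ti(),
    density: float = TIO2_DENSITY,
) -> float:
    """Sensitivity (counts/g Ti) of an instrument whose 1-count signal
    corresponds to a particle of diameter ``lod_nm``."""
    mass_ti = particle_mass(lod_nm, density) / molar_ratio
    return 1.0 / mass_ti


def default_calibration(dwell_time: float = 10.0) -> CalibrationModel:
    """A reference millisecond TiO2 setup: 5.7% transport efficiency,
    0.28 mL/min sample flow, sensitivity anchored at 1 count per 71 nm
    particle."""
    return CalibrationModel(
        transport_efficiency=0.057,
        flow_rate=0.28,
        dwell_time=dwell_time,
        sensitivity=sensitivity_for_lod(71.0),
    )
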