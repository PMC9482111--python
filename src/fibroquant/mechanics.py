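"""Intraocular-pressure mechanics of the ocular wall.

The eye globe is approximated as a pressurised thin-walled sphere, so the
circumferential (hoop) stress carried by the scleral wall follows the
Young-Laplace relation

    sigma = p * r / (2 * t)

with ``p`` the intraocular pressure (IOP), ``r`` the globe radius and ``t``
the wall (tunic) thickness.  Dividing the hoop stress by the tissue Young's
modulus gives the tensile strain experienced by resident fibroblasts; because
sclera strain-stiffens, a modulus *range* maps one IOP onto a strain *band*
(the stiff endpoint gives the lower strain, the compliant endpoint the upper).

All quantities are SI internally (Pa, m); conversion helpers handle the
clinical mmHg convention, and formatting helpers round to the significant
figures used in reporting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "MMHG_TO_PA",
    "OcularGeometry",
    "LoadingRegimen",
    "mmhg_to_pascal",
    "pascal_to_mmhg",
    "hoop_stress",
    "strain_band",
    "round_sig",
    "format_kpa",
    "format_percent",
    "strain_report",
]

#: Conversion factor from millimetres of mercury to pascal.
MMHG_TO_PA = 133.322


@dataclass(frozen=True)
class OcularGeometry:
    """Spherical-shell idealisation of the eye globe.

    Parameters
    ----------
    radius : float
        Globe radius in metres.
    wall_thickness : float
        Scleral wall thickness in metres.  Must be smaller than the radius
        for the thin-shell assumption to make sense.
    """

    radius: float
    wall_thickness: float

    def __post_init__(self) -> None:
        if not (self.radius > 0):
            raise ValueError(f"radius must be positive, got {self.radius}")
        if not (self.wall_thickness > 0):
            raise ValueError(
                f"wall_thickness must be positive, got {self.wall_thickness}"
            )
        if not (self.wall_thickness < self.radius):
            raise ValueError(
                "wall_thickness must be smaller than radius "
                f"({self.wall_thickness} >= {self.radius})"
            )


@dataclass(frozen=True)
class LoadingRegimen:
    """A cyclic tensile loading condition.

    Parameters
    ----------
    iop : float
        Intraocular pressure in pascal.
    modulus_low, modulus_high : float
        Endpoints of the tissue Young's-modulus range, in pascal.  The low
        (compliant) endpoint maps to the upper strain bound and vice versa.
    frequency : float
        Loading frequency in Hz.  Metadata only; no time-domain waveform is
        simulated.
    duration : float
        Loading duration in seconds.  Metadata only.
    """

    iop: float
    modulus_low: float
    modulus_high: float
    frequency: float = 1.0
    duration: float = 3600.0

    def __post_init__(self) -> None:
        if self.iop < 0:
            raise ValueError(f"iop must be non-negative, got {self.iop}")
        if not (0 < self.modulus_low <= self.modulus_high):
            raise ValueError(
                "moduli must satisfy 0 < modulus_low <= modulus_high, got "
                f"({self.modulus_low}, {self.modulus_high})"
            )
        if not (self.frequency > 0):
            raise ValueError(f"frequency must be positive, got {self.frequency}")


def mmhg_to_pascal(p_mmhg: float) -> float:
    """Convert a pressure from mmHg to pascal (factor 133.322 Pa/mmHg)."""
    if p_mmhg < 0:
        raise ValueError(f"pressure must be non-negative, got {p_mmhg} mmHg")
    return p_mmhg * MMHG_TO_PA


def pascal_to_mmhg(p_pa: float) -> float:
    """Convert a pressure from pascal to mmHg."""
    if p_pa < 0:
        raise ValueError(f"pressure must be non-negative, got {p_pa} Pa")
    return p_pa / MMHG_TO_PA


def hoop_stress(p: float, geom: OcularGeometry) -> float:
    """In-wall hoop stress of a pressurised thin sphere, sigma = p*r/(2t).

    Parameters
    ----------
    p : float
        Internal pressure (IOP) in pascal.
    geom : OcularGeometry
        Globe radius and wall thickness.

    Returns
    -------
    float
        Circumferential wall stress in pascal.
    """
    if p < 0:
        raise ValueError(f"pressure must be non-negative, got {p}")
    return p * geom.radius / (2.0 * geom.wall_thickness)


def strain_band(regimen: LoadingRegimen, geom: OcularGeometry) -> tuple[float, float]:
    """Tensile strain band implied by an IOP and a tissue modulus range.

    The hoop stress is divided by each modulus endpoint; the stiff endpoint
    yields the minimum strain and the compliant endpoint the maximum.

    Returns
    -------
    (strain_min, strain_max) : tuple of float
        Dimensionless strain fractions, ``strain_min <= strain_max``.
    """
    sigma = hoop_stress(regimen.iop, geom)
    strain_min = sigma / regimen.modulus_high
    strain_max = sigma / regimen.modulus_low
    return strain_min, strain_max


def round_sig(x: float, sig: int = 2) -> float:
    """Round ``x`` to ``sig`` significant figures (0 stays 0)."""
    if x == 0:
        return 0.0
    return round(x, sig - 1 - int(math.floor(math.log10(abs(x)))))


def format_kpa(p_pa: float, sig: int = 2) -> float:
    """Pressure in kPa rounded to ``sig`` significant figures, for reporting."""
    return round_sig(p_pa / 1000.0, sig)


def format_percent(fraction: float, sig: int = 2) -> float:
    """Dimensionless fraction as a percentage at ``sig`` significant figures."""
    return round_sig(fraction * 100.0, sig)


def strain_report(
    iop_mmhg: float,
    radius_m: float,
    thickness_m: float,
    modulus_low_pa: float,
    modulus_high_pa: float,
    sig: int = 2,
) -> dict:
    """One-call summary: IOP in mmHg -> stress and strain band.

    Returns a dict with the raw stress in Pa and the strain band both as
    fractions and as percentages rounded to ``sig`` significant figures.
    """
    geom = OcularGeometry(radius=radius_m, wall_thickness=thickness_m)
    regimen = LoadingRegimen(
        iop=mmhg_to_pascal(iop_mmhg),
        modulus_low=modulus_low_pa,
        modulus_high=modulus_high_pa,
    )
    smin, smax = strain_band(regimen, geom)
    return {
        "iop_mmhg": iop_mmhg,
        "iop_kpa": format_kpa(regimen.iop, sig),
        "stress_pa": hoop_stress(regimen.iop, geom),
        "strain_min": smin,
        "strain_max": smax,
        "strain_min_pct": format_percent(smin, sig),
        "strain_max_pct": format_percent(smax, sig),
    }
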