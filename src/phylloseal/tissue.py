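"""Tissue-level mechanics and environment utilities.

The elastic modulus of a turgid parenchymatous tissue rises linearly with
turgor: deformation of a pressurised thin-walled cell aggregate costs work
against the cell pressure (first term) and against stretching of the cell
walls (second term).  The relation implemented here,

    E_tissue = [3 P + 2 (t_cw / d_c) E_cw] / (1 - nu)

with turgor ``P``, cell diameter ``d_c``, wall thickness ``t_cw``, wall
elastic modulus ``E_cw`` and Poisson's ratio ``nu``, keeps that contractual
structure: it is affine-increasing in ``P`` and its geometry term scales
with the wall-thickness fraction times the wall modulus.  The two
dimensionless coefficients are calibrated so that, for measured
parenchyma/chlorenchyma parameters of succulent leaves (P = 0.042 MPa,
d_c = 77 um, t_cw = 0.42 um, nu = 0.28, E_cw = 5.00 MPa), the tissue
modulus is 0.25 MPa, and the full measured turgor range 0.03-0.09 MPa maps
onto the reported modulus range 0.20-0.43 MPa.

Also here: the conversion of a discrete net of peripheral vascular bundles
into a continuous ring of equivalent cross-sectional area, the correction
for preparation shrinkage of succulent tissues in thin sections, and the
conversion of relative air humidity to absolute water-vapour content.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "CellMechanics",
    "BundleRing",
    "HumidityState",
    "tissue_modulus",
    "ring_equivalent_thickness",
    "shrinkage_correct",
    "absolute_humidity",
    "saturation_vapour_density",
]

# Magnus saturation-vapour-pressure constants (Alduchov & Eskridge 1996,
# over liquid water): e_s(T) = A * exp(B*T / (T + C)), T in deg C, e_s in Pa.
MAGNUS_A_PA = 610.94
MAGNUS_B = 17.625
MAGNUS_C = 243.04

_R_GAS = 8.314462618  # J / (mol K)
_M_WATER = 0.018015  # kg / mol

# Dimensionless coefficients of the two-term tissue-modulus relation,
# calibrated against measured parenchyma/chlorenchyma data (module docstring).
TURGOR_COEFF = 3.0
WALL_COEFF = 2.0


@dataclass(frozen=True)
class CellMechanics:
    """Cell-scale parameters of the tissue-modulus relation.

    P : turgor pressure, MPa.
    d_c : cell diameter, um.
    t_cw : cell wall thickness, um.
    nu : Poisson's ratio of the tissue, dimensionless, in [0, 0.5).
    E_cw : elastic modulus of the cell wall, MPa.
    """

    P: float
    d_c: float
    t_cw: float
    nu: float
    E_cw: float

    def __post_init__(self):
        if not np.isfinite([self.P, self.d_c, self.t_cw, self.nu, self.E_cw]).all():
            raise ValueError("non-finite cell parameters")
        if self.P < 0:
            raise ValueError("turgor must be non-negative")
        if self.d_c <= 0:
            raise ValueError("cell diameter must be positive")
        if self.t_cw < 0 or self.E_cw < 0:
            raise ValueError("wall thickness and wall modulus must be non-negative")
        if not 0 <= self.nu < 0.5:
            raise ValueError("Poisson's ratio must lie in [0, 0.5)")


def tissue_modulus(cell: CellMechanics, decompose: bool = False):
    """Elastic modulus of parenchyma/chlorenchyma tissue, MPa.

    Returns the tissue modulus, or ``(E, turgor_term, wall_term)`` when
    ``decompose`` is true.  The first term is the turgor contribution, the
    second the contribution of cell/cell-wall geometry and wall stiffness.
    """
    turgor_term = TURGOR_COEFF * cell.P / (1.0 - cell.nu)
    wall_term = WALL_COEFF * (cell.t_cw / cell.d_c) * cell.E_cw / (1.0 - cell.nu)
    E = turgor_term + wall_term
    if decompose:
        return E, turgor_term, wall_term
    return E


@dataclass(frozen=True)
class BundleRing:
    """Peripheral vascular bundles at a common middle radius.

    bundle_areas : individual bundle cross-sectional areas, um^2.
    radius : middle radius of the net of bundles, um.
    """

    bundle_areas: np.ndarray
    radius: float

    def __post_init__(self):
        areas = np.asarray(self.bundle_areas, dtype=float)
        object.__setattr__(self, "bundle_areas", areas)
        if self.radius <= 0:
            raise ValueError("middle radius must be positive")
        if np.any(areas < 0):
            raise ValueError("bundle areas must be non-negative")


def ring_equivalent_thickness(ring: BundleRing) -> float:
    """Thickness of a continuous ring equivalent to the bundle net, um.

    The total bundle area is divided by the circumference ``2 pi r`` at the
    middle radius, i.e. the annulus with this thickness has the same total
    cross-sectional area as the discrete bundles.
    """
    if ring.bundle_areas.size == 0:
        warnings.warn("empty bundle list; ring-equivalent thickness is 0", stacklevel=2)
        return 0.0
    return float(np.sum(ring.bundle_areas)) / (2.0 * np.pi * ring.radius)


def shrinkage_correct(measured, shrink_fraction: float = 0.15):
    """Undo linear preparation shrinkage of succulent parenchymatous tissue.

    Thin-sectioning dehydrates succulent tissue, shrinking linear
    dimensions by ``shrink_fraction`` (default 15%); the in-vivo dimension
    is ``measured / (1 - shrink_fraction)``.  Apply to parenchymatous
    tissues only.
    """
    if not 0 <= shrink_fraction < 1:
        raise ValueError("shrink_fraction must lie in [0, 1)")
    measured = np.asarray(measured, dtype=float)
    out = measured / (1.0 - shrink_fraction)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class HumidityState:
    """Relative humidity plus either air temperature or saturation content.

    relative_humidity : fraction in [0, 1].
    temperature_c : air temperature, deg C (used with the Magnus formula).
    saturation_content : water-vapour density at saturation, g/m^3; if
        given it overrides the temperature route, which lets published
        saturation values be reproduced exactly.
    """

    relative_humidity: float
    temperature_c: float | None = None
    saturation_content: float | None = None

    def __post_init__(self):
        if not 0 <= self.relative_humidity <= 1:
            raise ValueError("relative humidity must lie in [0, 1]")
        if self.temperature_c is None and self.saturation_content is None:
            raise ValueError("provide temperature_c or saturation_content")
        if self.saturation_content is not None and self.saturation_content < 0:
            raise ValueError("saturation content must be non-negative")


def saturation_vapour_density(temperature_c: float) -> float:
    """Saturation water-vapour density at ``temperature_c``, g/m^3.

    Magnus approximation for the saturation pressure over liquid water,
    converted to density with the ideal-gas law.
    """
    e_s = MAGNUS_A_PA * np.exp(MAGNUS_B * temperature_c / (temperature_c + MAGNUS_C))
    t_kelvin = temperature_c + 273.15
    return float(e_s * _M_WATER / (_R_GAS * t_kelvin) * 1000.0)


def absolute_humidity(state: HumidityState) -> float:
    """Absolute water-vapour content of air, g/m^3.

    ``rh * saturation_content`` when a saturation content is supplied,
    otherwise ``rh`` times the Magnus/ideal-gas saturation density at the
    given temperature.
    """
    if state.saturation_content is not None:
        sat = state.saturation_content
    else:
        sat = saturation_vapour_density(state.temperature_c)
    return state.relative_humidity * sat
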