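"""Tensile biomechanics: geometry, stress, strain, stiffness, Poisson's ratio.

Whole succulent leaves are close to elliptical in cross-section, so each of
the five stations measured along the leaf contributes an area
``A = pi * a * b`` (half-width ``a``, half-height ``b``); the mean of the
five areas divides force to give engineering stress.  Strain is
displacement over original length.  The elastic modulus is the slope of the
initial linear part of the stress-strain curve, delimited here by a
deterministic window scan; Poisson's ratio is the transverse over axial
strain between the first and last image of that linear-elastic range.

Engineering (not true) stress and strain are used throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "LeafGeometry",
    "TensileRecord",
    "StressStrainCurve",
    "ElasticFit",
    "PoissonInput",
    "NoLinearRegionError",
    "cross_section_area",
    "rectangle_area",
    "mean_area",
    "stress_strain",
    "tensile_strength",
    "elastic_modulus",
    "poisson_ratio",
]

N_STATIONS = 5  # cross-sections measured along the leaf axis


class NoLinearRegionError(RuntimeError):
    """No initial window met the linearity threshold."""


def cross_section_area(a, b):
    """Elliptical cross-section area ``A = pi * a * b`` (half-axes)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.any(a <= 0) or np.any(b <= 0):
        raise ValueError("ellipse half-axes must be positive")
    out = np.pi * a * b
    return out if out.ndim else float(out)


def rectangle_area(width, height):
    """Rectangular cross-section, used for the epidermis strips."""
    if width <= 0 or height <= 0:
        raise ValueError("rectangle sides must be positive")
    return float(width * height)


@dataclass(frozen=True)
class LeafGeometry:
    """Five stations of ellipse half-axes ``(a, b)`` in metres."""

    stations: np.ndarray  # (5, 2)

    def __post_init__(self):
        st = np.asarray(self.stations, dtype=float)
        object.__setattr__(self, "stations", st)
        if st.shape != (N_STATIONS, 2):
            raise ValueError(f"expected {N_STATIONS} (a, b) stations, got {st.shape}")
        if np.any(st <= 0):
            raise ValueError("ellipse half-axes must be positive")

    @property
    def areas(self) -> np.ndarray:
        return cross_section_area(self.stations[:, 0], self.stations[:, 1])

    @property
    def mean_area(self) -> float:
        return float(np.mean(self.areas))


def mean_area(geometry: LeafGeometry) -> float:
    """Mean cross-sectional area over the five stations (m^2)."""
    return geometry.mean_area


@dataclass(frozen=True)
class TensileRecord:
    """Force-displacement record of one tensile test.

    times in s, force in N, displacement in m, original length ``L0`` in m.
    """

    times: np.ndarray
    force: np.ndarray
    displacement: np.ndarray
    L0: float
    label: str = ""

    def __post_init__(self):
        for name in ("times", "force", "displacement"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), float))
        n = self.times.size
        if self.force.shape != (n,) or self.displacement.shape != (n,):
            raise ValueError("time, force, displacement must have equal length")
        if n == 0:
            raise ValueError("empty tensile record")
        if self.L0 <= 0:
            raise ValueError("original length must be positive")
        if np.any(np.diff(self.displacement) < -1e-12 * max(1.0, self.displacement.max(initial=0.0))):
            raise ValueError("displacement must be non-decreasing")


@dataclass(frozen=True)
class StressStrainCurve:
    """Engineering stress (Pa) vs strain (dimensionless)."""

    strain: np.ndarray
    stress: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "strain", np.asarray(self.strain, float))
        object.__setattr__(self, "stress", np.asarray(self.stress, float))
        if self.strain.shape != self.stress.shape:
            raise ValueError("strain and stress must align")
        if np.any(self.strain < 0):
            raise ValueError("negative strain")


@dataclass(frozen=True)
class ElasticFit:
    """Initial-slope fit: modulus ``E`` (Pa), strain window, R^2."""

    E: float
    window: tuple[float, float]
    r2: float
    n_points: int

    def __post_init__(self):
        if self.E <= 0:
            raise ValueError("elastic modulus must be positive")
        if not self.window[0] < self.window[1]:
            raise ValueError("empty strain window")


@dataclass(frozen=True)
class PoissonInput:
    """Axial and transverse gauge lengths over the linear-elastic range (m)."""

    L0: float
    dL: float
    d0: float
    dd: float

    def __post_init__(self):
        if self.L0 <= 0 or self.d0 <= 0:
            raise ValueError("gauge lengths must be positive")


def stress_strain(record: TensileRecord, area: float) -> StressStrainCurve:
    """Pointwise engineering stress ``F/A`` and strain ``dL/L0``."""
    if area <= 0:
        raise ValueError("mean cross-sectional area must be positive")
    return StressStrainCurve(record.displacement / record.L0, record.force / area)


def tensile_strength(record: TensileRecord, area: float) -> float:
    """Maximum force per mean cross-sectional area (Pa).

    The maximum of the whole trace is used, so a force peak before a
    rupture drop is honoured.
    """
    if area <= 0:
        raise ValueError("mean cross-sectional area must be positive")
    return float(np.max(record.force)) / area


def elastic_modulus(
    curve: StressStrainCurve,
    r2_threshold: float = 0.999,
    min_points: int = 10,
) -> ElasticFit:
    """Slope of the initial linear (elastic) part of the stress-strain curve.

    The linear window is chosen deterministically: candidate windows all
    start at the low-strain end, and the longest window whose least-squares
    line achieves a coefficient of determination >= ``r2_threshold`` is
    selected.  For noisy data lower the threshold.
    """
    eps = curve.strain
    sig = curve.stress
    if eps.size < min_points:
        raise ValueError(
            f"need at least {min_points} points in the initial region, got {eps.size}"
        )
    best = None
    for j in range(min_points, eps.size + 1):
        x = eps[:j]
        y = sig[:j]
        slope, intercept = np.polyfit(x, y, 1)
        resid = y - (slope * x + intercept)
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
        if r2 >= r2_threshold:
            best = (slope, j, r2)
    if best is None:
        raise NoLinearRegionError(
            f"no initial window of >= {min_points} points reaches R^2 >= "
            f"{r2_threshold}; relax r2_threshold for noisy data"
        )
    slope, j, r2 = best
    if slope <= 0:
        raise NoLinearRegionError("initial slope is not positive")
    return ElasticFit(E=float(slope), window=(float(eps[0]), float(eps[j - 1])), r2=r2, n_points=j)


def poisson_ratio(inp: PoissonInput) -> float:
    """Poisson's ratio ``nu = (dd/d0) / (dL/L0)``.

    ``dd`` is the transverse contraction (positive when the sample thins)
    and ``dL`` the axial extension across the linear-elastic range.
    """
    if inp.dL <= 0:
        raise ValueError("axial extension dL must be positive for Poisson's ratio")
    return (inp.dd / inp.d0) / (inp.dL / inp.L0)
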