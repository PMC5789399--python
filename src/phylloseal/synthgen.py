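"""Synthetic experiments with known ground truth.

Three generators emulate the study designs that feed the analysis stages:

* :func:`simulate_tracks` — three-point leaf tracks for the wound-sealing
  kinematics.  The latent relative bending angle of subject ``s`` under
  condition ``c`` follows a saturating exponential,
  ``gamma_sc(t) = (gamma_inf_c + u_s) * (1 - exp(-t / tau_c))``, the
  simplest two-parameter law with the observed saturation toward a
  condition-dependent asymptote (negative for a water droplet on the
  wound).  The emitted coordinates realise that angle exactly: point 2
  sits at a fixed hinge, point 1 on a base ray whose orientation drifts
  smoothly (base motion), point 3 on a tip ray at ``delta_0 + gamma``
  relative to the base ray.  Optional i.i.d. Gaussian coordinate noise
  models tracking error.

* :func:`simulate_tensile` — a force-displacement record with elliptical
  leaf geometry: a linear-elastic segment of slope ``true_E``, a smooth
  concave yield that peaks exactly at ``true_strength``, a short rupture
  tail, and a transverse-contraction measurement pair consistent with
  ``true_poisson``.

* :func:`simulate_turgor` — cell-pressure-probe readings whose turgor
  trends linearly with measurement depth.

Everything is driven by ``numpy.random.default_rng`` seeded from the
spec, so identical inputs give identical outputs, bitwise for the text
exports.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .kinematics import TrackSeries
from .tensile import LeafGeometry, PoissonInput, TensileRecord

__all__ = [
    "Condition",
    "SealingScenario",
    "TensileSpec",
    "TurgorSpec",
    "TensileTruth",
    "default_scenario",
    "null_scenario",
    "latent_gamma",
    "simulate_tracks",
    "simulate_tensile",
    "simulate_turgor",
]


@dataclass(frozen=True)
class Condition:
    """One humidity condition of the sealing experiment.

    gamma_inf_deg : asymptotic relative bending angle, degrees (negative
        for the wound-opening droplet condition).
    tau_min : time constant of the saturating exponential, minutes.
    """

    label: str
    gamma_inf_deg: float
    tau_min: float

    def __post_init__(self):
        if not np.isfinite([self.gamma_inf_deg, self.tau_min]).all():
            raise ValueError("non-finite condition parameters")
        if self.tau_min <= 0:
            raise ValueError("time constant must be positive")


@dataclass(frozen=True)
class SealingScenario:
    """Design of a synthetic wound-sealing experiment."""

    conditions: tuple[Condition, ...]
    n_subjects: int = 17
    frame_interval_s: float = 30.0
    duration_min: float = 55.0
    evaluation_times_min: tuple[float, ...] = (1.0, 5.0, 10.0, 20.0, 40.0, 55.0)
    base_drift_amplitude_deg: float = 1.0
    coordinate_noise_sd: float = 0.05
    subject_sd_deg: float = 4.0
    delta0_deg: float = 3.0  # pre-injury actual bending angle
    base_arm: float = 8.0  # |p2 - p1|, mm
    tip_arm: float = 10.0  # |p2 - p3|, mm
    drift_period_min: float = 30.0
    seed: int = 0

    def __post_init__(self):
        if len(self.conditions) < 1:
            raise ValueError("need at least one condition")
        if self.n_subjects < 2:
            raise ValueError("need at least 2 subjects")
        if self.frame_interval_s <= 0 or self.duration_min <= 0:
            raise ValueError("frame interval and duration must be positive")
        ev = np.asarray(self.evaluation_times_min, dtype=float)
        if np.any(ev < 0) or np.any(ev > self.duration_min):
            raise ValueError("evaluation times must lie within [0, duration]")
        vals = [
            self.base_drift_amplitude_deg,
            self.coordinate_noise_sd,
            self.subject_sd_deg,
            self.delta0_deg,
        ]
        if not np.isfinite(vals).all():
            raise ValueError("non-finite scenario parameters")
        if self.coordinate_noise_sd < 0 or self.subject_sd_deg < 0:
            raise ValueError("noise magnitudes must be non-negative")

    @property
    def frame_times_s(self) -> np.ndarray:
        n = int(round(self.duration_min * 60.0 / self.frame_interval_s)) + 1
        return np.arange(n) * self.frame_interval_s


def default_scenario(seed: int = 0, **overrides) -> SealingScenario:
    """The four-condition design of the sealing study.

    24%, 49% and 100% relative air humidity plus a water droplet on the
    wound, 17 leaves, one frame per 30 s over 55 min.  Asymptotes fall
    with humidity and are negative for the droplet; the time constants
    are plausible shapes for drying-rate differences, not measured values.
    """
    scenario = SealingScenario(
        conditions=(
            Condition("rh24", 18.0, 8.0),
            Condition("rh49", 10.0, 12.0),
            Condition("rh100", 2.0, 20.0),
            Condition("droplet", -12.0, 6.0),
        ),
        seed=seed,
    )
    return replace(scenario, **overrides) if overrides else scenario


def null_scenario(seed: int = 0, **overrides) -> SealingScenario:
    """Design with no condition effect at all.

    All asymptotes are zero and the time constants identical, so the
    subject offset enters every condition identically and the condition
    effect of the downstream ANOVA holds exactly under the null.
    """
    scenario = SealingScenario(
        conditions=(
            Condition("rh24", 0.0, 10.0),
            Condition("rh49", 0.0, 10.0),
            Condition("rh100", 0.0, 10.0),
            Condition("droplet", 0.0, 10.0),
        ),
        seed=seed,
    )
    return replace(scenario, **overrides) if overrides else scenario


def latent_gamma(gamma_inf_deg, tau_min, t_min):
    """Noise-free relative bending angle of the latent sealing law."""
    t = np.asarray(t_min, dtype=float)
    return gamma_inf_deg * (1.0 - np.exp(-t / tau_min))


def simulate_tracks(scenario: SealingScenario, y_down: bool = False):
    """Generate one track per subject x condition plus the ground truth.

    Returns ``(tracks, truth)``: a list of :class:`TrackSeries` labelled
    ``s<subject>_<condition>`` and a long DataFrame with the latent
    (noise-free) ``gamma_deg`` per subject, condition and frame time.
    """
    rng = np.random.default_rng(scenario.seed)
    t_s = scenario.frame_times_s
    t_min = t_s / 60.0
    subject_offsets = rng.normal(0.0, scenario.subject_sd_deg, scenario.n_subjects)
    tracks = []
    truth_rows = []
    for s in range(scenario.n_subjects):
        drift_phase = rng.uniform(0.0, 2.0 * np.pi)
        for cond in scenario.conditions:
            gamma_inf = cond.gamma_inf_deg + subject_offsets[s]
            gamma = latent_gamma(gamma_inf, cond.tau_min, t_min)
            drift = scenario.base_drift_amplitude_deg * np.sin(
                2.0 * np.pi * t_min / scenario.drift_period_min + drift_phase
            )
            alpha = drift  # base-line angle wanders around horizontal
            beta = drift + scenario.delta0_deg + gamma
            # hinge at the origin; base ray points left, tip ray right
            p2 = np.zeros((t_s.size, 2))
            a_rad = np.radians(alpha + 180.0)
            b_rad = np.radians(beta)
            p1 = scenario.base_arm * np.stack([np.cos(a_rad), np.sin(a_rad)], axis=1)
            p3 = scenario.tip_arm * np.stack([np.cos(b_rad), np.sin(b_rad)], axis=1)
            pts = np.stack([p1, p2, p3], axis=1)
            if scenario.coordinate_noise_sd > 0:
                pts = pts + rng.normal(0.0, scenario.coordinate_noise_sd, pts.shape)
            if y_down:
                pts = pts.copy()
                pts[:, :, 1] = -pts[:, :, 1]
            label = f"s{s + 1:02d}_{cond.label}"
            tracks.append(
                TrackSeries(t_s, pts, units="mm", y_down=y_down, label=label)
            )
            truth_rows.append(
                pd.DataFrame(
                    {
                        "subject": f"s{s + 1:02d}",
                        "condition": cond.label,
                        "time_s": t_s,
                        "gamma_deg": gamma,
                        "gamma_inf_deg": gamma_inf,
                        "tau_min": cond.tau_min,
                    }
                )
            )
    truth = pd.concat(truth_rows, ignore_index=True)
    return tracks, truth


# --------------------------------------------------------------------------
# tensile


@dataclass(frozen=True)
class TensileSpec:
    """Ground truth and protocol of a synthetic tensile test."""

    true_E: float = 0.72e6  # Pa
    true_strength: float = 0.09e6  # Pa
    true_poisson: float = 0.28
    geometry: LeafGeometry = field(
        default_factory=lambda: LeafGeometry(
            np.array(
                [
                    [1.6e-3, 1.4e-3],
                    [1.7e-3, 1.5e-3],
                    [1.8e-3, 1.6e-3],
                    [1.7e-3, 1.5e-3],
                    [1.5e-3, 1.4e-3],
                ]
            )
        )
    )
    L0: float = 0.02  # m
    strain_rate: float = 0.002  # 1/s
    sampling_rate: float = 5.0  # Hz
    noise_sd_force: float = 0.0  # N
    yield_fraction: float = 0.7  # stress at the end of the linear segment
    yield_slope_fraction: float = 0.25  # tangent slope just past yield, as fraction of E
    rupture_drop: float = 0.35  # force fraction retained after rupture
    seed: int = 0

    def __post_init__(self):
        if min(self.true_E, self.true_strength, self.L0) <= 0:
            raise ValueError("modulus, strength and L0 must be positive")
        if not 0 <= self.true_poisson < 0.5:
            raise ValueError("Poisson's ratio must lie in [0, 0.5)")
        if self.strain_rate <= 0 or self.sampling_rate <= 0:
            raise ValueError("strain rate and sampling rate must be positive")
        if not 0 < self.yield_fraction < 1:
            raise ValueError("yield_fraction must lie in (0, 1)")
        if not 0 < self.yield_slope_fraction < 1:
            raise ValueError("yield_slope_fraction must lie in (0, 1)")
        if self.noise_sd_force < 0:
            raise ValueError("noise must be non-negative")


@dataclass(frozen=True)
class TensileTruth:
    """What the generator promised; used for recovery tests."""

    E: float
    strength: float
    poisson: float
    mean_area: float
    poisson_images: PoissonInput


def _stress_curve(spec: TensileSpec, strain: np.ndarray) -> np.ndarray:
    """Engineering stress law: linear, then a concave parabola to the peak.

    The tangent slope drops abruptly at the yield point (fibrous tissues
    yield sharply), then the parabola flattens to an apex exactly at the
    tensile strength.
    """
    e_y = spec.yield_fraction * spec.true_strength / spec.true_E
    s_y = spec.yield_fraction * spec.true_strength
    slope_y = spec.yield_slope_fraction * spec.true_E
    # parabola sigma_max - k (e_peak - e)^2 with slope slope_y at e_y
    e_peak = e_y + 2.0 * (spec.true_strength - s_y) / slope_y
    k = (spec.true_strength - s_y) / (e_peak - e_y) ** 2
    sigma = np.where(
        strain <= e_y,
        spec.true_E * strain,
        spec.true_strength - k * np.clip(e_peak - strain, 0.0, None) ** 2,
    )
    return sigma, e_y, e_peak


def simulate_tensile(spec: TensileSpec):
    """Synthesize one tensile test.

    Returns ``(record, geometry, truth)``.  Displacement grows at
    ``strain_rate * L0`` per second; force follows the stress law times
    the mean cross-sectional area, peaks exactly at
    ``true_strength * mean_area`` and then drops to the rupture tail.
    The transverse image pair shrinks according to ``true_poisson``.
    """
    rng = np.random.default_rng(spec.seed)
    area = spec.geometry.mean_area
    _, e_y, e_peak = _stress_curve(spec, np.array([0.0]))
    # sample up to the stress peak, then a short rupture tail
    t_peak = e_peak / spec.strain_rate
    n_main = int(np.floor(t_peak * spec.sampling_rate)) + 1
    t = np.arange(n_main) / spec.sampling_rate
    strain = spec.strain_rate * t
    sigma, e_y, e_peak = _stress_curve(spec, strain)
    # force the exact peak into the trace, then rupture
    t_tail = t[-1] + (np.arange(1, 4)) / spec.sampling_rate
    t = np.concatenate([t, [t_peak], t_tail])
    strain = np.concatenate([strain, [e_peak], spec.strain_rate * t_tail])
    sigma = np.concatenate(
        [
            sigma,
            [spec.true_strength],
            spec.rupture_drop * spec.true_strength * np.ones(3),
        ]
    )
    order = np.argsort(t, kind="stable")
    t, strain, sigma = t[order], strain[order], sigma[order]
    force = sigma * area
    if spec.noise_sd_force > 0:
        force = force + rng.normal(0.0, spec.noise_sd_force, force.size)
        force = np.clip(force, 0.0, None)
    record = TensileRecord(t, force, strain * spec.L0, spec.L0, label="synthetic")
    d0 = 2.0 * float(spec.geometry.stations[2, 0])
    dL = e_y * spec.L0
    dd = spec.true_poisson * e_y * d0
    truth = TensileTruth(
        E=spec.true_E,
        strength=spec.true_strength,
        poisson=spec.true_poisson,
        mean_area=area,
        poisson_images=PoissonInput(L0=spec.L0, dL=dL, d0=d0, dd=dd),
    )
    return record, spec.geometry, truth


# --------------------------------------------------------------------------
# turgor


@dataclass(frozen=True)
class TurgorSpec:
    """Design of a synthetic pressure-probe depth profile."""

    n_cells: int = 44
    depth_range_um: tuple[float, float] = (50.0, 600.0)
    turgor_mean: float = 0.042  # MPa
    turgor_sd: float = 0.0  # MPa
    depth_slope: float = 0.0  # MPa per um
    seed: int = 0

    def __post_init__(self):
        if self.n_cells < 3:
            raise ValueError("need at least 3 cells")
        if self.turgor_mean <= 0:
            raise ValueError("mean turgor must be positive")
        if self.turgor_sd < 0:
            raise ValueError("turgor sd must be non-negative")
        if not self.depth_range_um[0] < self.depth_range_um[1]:
            raise ValueError("empty depth range")


def simulate_turgor(spec: TurgorSpec) -> pd.DataFrame:
    """Turgor readings vs measurement depth, truncated at > 0 (MPa, um)."""
    rng = np.random.default_rng(spec.seed)
    depth = np.sort(rng.uniform(*spec.depth_range_um, spec.n_cells))
    turgor = spec.turgor_mean + spec.depth_slope * (depth - depth.mean())
    if spec.turgor_sd > 0:
        turgor = turgor + rng.normal(0.0, spec.turgor_sd, spec.n_cells)
    turgor = np.clip(turgor, 1e-6, None)
    return pd.DataFrame({"depth_um": depth, "turgor_MPa": turgor})
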