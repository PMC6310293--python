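"""Achilles tendon strain estimation from hindlimb kinematics.

A simplified planar (sagittal) model of the three triceps-surae musculo-tendon
units (lateral/medial gastrocnemius, soleus).  Each unit is a Hill-type muscle
segment in series with a passive tendon segment.  Musculo-tendon path length
is a calibrated polynomial in the sagittal joint angles (the gastrocnemii
cross the knee and ankle, the soleus only the ankle; none cross the hip).
Given prescribed joint-angle waveforms and an activation schedule, the series
force balance

    activation * fl(l_f / l_opt) * fv + fp(l_f / l_opt)  =  ft(eps_t)

is solved quasi-statically at every time sample for the tendon length, and
tendon strain is reported as (tendon length - tendon slack length) / tendon
slack length.  Healing-stage properties enter through two modifications: the
linear slope of the tendon force-strain curve is reduced 5x (healthy tendon
-> early callus), and unrepaired transection adds a 7 mm gap to the tendon
slack length, while suture repair restores a ~0 mm gap.

Cell-level strains are 0.28x the tissue-level tendon strain, reflecting
matrix shielding of the resident fibroblasts.

All lengths are millimetres, angles degrees (dorsiflexion and extension
positive), times seconds, strains dimensionless.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace

import numpy as np
import yaml
from scipy.optimize import brentq

__all__ = [
    "JointTrajectory",
    "ActivationSchedule",
    "TendonForceCurve",
    "MusculoTendonUnit",
    "StrainProfile",
    "CELL_STRAIN_FACTOR",
    "mt_length",
    "estimate_tendon_slack_length",
    "apply_transection_gap",
    "scale_callus_stiffness",
    "equilibrium_tendon_strain",
    "simulate_gait_strain",
    "simulate_immobilized_strain",
    "to_cell_strain",
    "load_default_units",
    "IMMOBILIZED_POSTURE",
]

#: Empirical tissue-to-cell strain transfer factor.
CELL_STRAIN_FACTOR = 0.28

#: Cast/Botox unloading posture: knee fixed at -50 deg flexion,
#: ankle at -30 deg plantar flexion, hip at neutral.
IMMOBILIZED_POSTURE = {"hip": 0.0, "knee": -50.0, "ankle": -30.0}

# Calibrated validity range of the fixture path polynomials (degrees).
ANGLE_LIMITS = {"hip": (-45.0, 45.0), "knee": (-75.0, 20.0), "ankle": (-45.0, 35.0)}


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass
class StrainProfile:
    """A (periodic) strain-vs-time trace at tendon or cell level."""

    times: np.ndarray            # seconds
    strain: np.ndarray           # dimensionless E11
    level: str = "tendon"        # 'tendon' or 'cell'
    period: float | None = 1.0   # gait cycle period, seconds

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.strain = np.asarray(self.strain, dtype=float)
        if self.times.shape != self.strain.shape:
            raise ValueError("times and strain must have the same shape")
        if self.level not in ("tendon", "cell"):
            raise ValueError("level must be 'tendon' or 'cell'")

    @property
    def mean(self) -> float:
        if self.times.size > 1:
            return float(np.trapezoid(self.strain, self.times)
                         / (self.times[-1] - self.times[0]))
        return float(self.strain[0])

    @property
    def min(self) -> float:
        return float(self.strain.min())

    @property
    def max(self) -> float:
        return float(self.strain.max())

    @property
    def amplitude(self) -> float:
        """Peak-to-trough strain, max - min."""
        return self.max - self.min


@dataclass
class JointTrajectory:
    """Sagittal joint angles over one gait cycle (degrees)."""

    times: np.ndarray
    hip_angle: np.ndarray
    knee_angle: np.ndarray
    ankle_angle: np.ndarray
    stance_fraction: float = 0.75

    def __post_init__(self) -> None:
        for name in ("times", "hip_angle", "knee_angle", "ankle_angle"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        n = self.times.size
        if any(getattr(self, a).size != n
               for a in ("hip_angle", "knee_angle", "ankle_angle")):
            raise ValueError("mismatched time grids between joint angle traces")
        if not (0.0 < self.stance_fraction < 1.0):
            raise ValueError("stance_fraction must lie in (0, 1)")
        if not np.all(np.isfinite(self.hip_angle)) \
                or not np.all(np.isfinite(self.knee_angle)) \
                or not np.all(np.isfinite(self.ankle_angle)):
            raise ValueError("joint angles must be finite")

    @property
    def period(self) -> float:
        return float(self.times[-1] - self.times[0])

    def angles_at(self, i: int) -> dict:
        return {"hip": float(self.hip_angle[i]),
                "knee": float(self.knee_angle[i]),
                "ankle": float(self.ankle_angle[i])}

    @classmethod
    def rat_gait(cls, n_samples: int = 201, period: float = 1.0,
                 stance_fraction: float = 0.75,
                 ankle_stance_rise: float = 22.0,
                 ankle_swing_dip: float = 3.000127,
                 knee_stance_rise: float = 8.0,
                 knee_swing_dip: float = 3.341080) -> "JointTrajectory":
        """Smooth parametric rat gait waveform.

        Stance (weight bearing, first 75% of the cycle) dorsiflexes the ankle
        under load; swing plantarflexes it while flexing the knee.  The
        waveform is periodic and continuous at the stance/swing boundary;
        the rise/dip amplitudes are fixture constants calibrated together
        with the path polynomials.
        """
        t = np.linspace(0.0, period, n_samples)
        phi = t / period
        hip = 10.0 * np.sin(2 * np.pi * phi)
        knee = np.where(
            phi < stance_fraction,
            -30.0 + knee_stance_rise * np.sin(np.pi * phi / stance_fraction),
            -30.0 - knee_swing_dip * np.sin(np.pi * (phi - stance_fraction)
                                            / (1.0 - stance_fraction)))
        ankle = np.where(
            phi < stance_fraction,
            -10.0 + ankle_stance_rise * np.sin(np.pi * phi / stance_fraction),
            -10.0 - ankle_swing_dip * np.sin(np.pi * (phi - stance_fraction)
                                             / (1.0 - stance_fraction)))
        return cls(t, hip, knee, ankle, stance_fraction)


@dataclass(frozen=True)
class ActivationSchedule:
    """Phase-dependent muscle activation: full activation during stance,
    minimal (0.05) during swing, with a short smoothing ramp at the
    boundaries to avoid discontinuity artifacts."""

    stance_activation: float = 1.0
    swing_activation: float = 0.05
    ramp_s: float = 0.010

    def __post_init__(self) -> None:
        if not (0.0 < self.swing_activation <= self.stance_activation <= 1.0):
            raise ValueError("require 0 < swing_activation <= stance_activation <= 1")

    def activation(self, t: float, period: float, stance_fraction: float) -> float:
        """Activation at time t within a cycle of the given period."""
        tc = t % period
        t_sw = stance_fraction * period  # stance->swing boundary
        hi, lo = self.stance_activation, self.swing_activation
        if t_sw <= tc < t_sw + self.ramp_s:
            return hi + (lo - hi) * (tc - t_sw) / self.ramp_s
        if tc >= period - self.ramp_s:  # swing->stance boundary at cycle wrap
            return lo + (hi - lo) * (tc - (period - self.ramp_s)) / self.ramp_s
        return hi if tc < t_sw else lo


@dataclass(frozen=True)
class TendonForceCurve:
    """Normalized tendon force-strain curve: quadratic toe region up to
    ``toe_strain`` followed by a linear region of slope ``linear_slope``
    (normalized force per unit strain).  Force is zero for a slack tendon."""

    linear_slope: float = 20.0
    toe_strain: float = 0.02
    callus_scale_factor: float = 5.0

    def __post_init__(self) -> None:
        if self.linear_slope <= 0:
            raise ValueError("linear_slope must be positive")
        if self.toe_strain < 0:
            raise ValueError("toe_strain must be non-negative")

    def force(self, strain: float) -> float:
        if strain <= 0.0:
            return 0.0
        k, et = self.linear_slope, self.toe_strain
        if et > 0 and strain < et:
            return k * strain * strain / (2.0 * et)
        return k * (strain - et / 2.0)


def scale_callus_stiffness(curve: TendonForceCurve,
                           factor: float | None = None) -> TendonForceCurve:
    """Soften a healthy tendon curve to early-callus properties.

    Divides the linear slope (and hence the force at every strain, the toe
    region scaling consistently) by ``factor`` (default: the curve's
    ``callus_scale_factor``, 5).  Mimics the drop from ~175 MPa healthy
    modulus to ~30-35 MPa initial callus.
    """
    if factor is None:
        factor = curve.callus_scale_factor
    if factor <= 0:
        raise ValueError("stiffness scale factor must be positive")
    if factor < 1:
        raise ValueError("stiffness scale factor must be >= 1")
    return replace(curve, linear_slope=curve.linear_slope / factor)


@dataclass
class MusculoTendonUnit:
    """One triceps-surae unit: Hill-type muscle in series with a passive tendon.

    ``mt_length_coefficients`` is the calibrated path polynomial
    L = const + c_hip*hip + c_knee*knee + c_ankle*ankle + c_ankle2*ankle^2
    (mm, degrees); it stands in for 3D musculoskeletal path geometry and is a
    fixture approximation, not anatomy.
    """

    name: str
    optimal_fiber_length: float          # mm
    tendon_slack_length: float           # mm
    max_isometric_force: float = 20.0    # N (cancels in normalized balance)
    mt_length_coefficients: dict = field(default_factory=dict)
    tendon_curve: TendonForceCurve = field(default_factory=TendonForceCurve)
    fl_width: float = 0.45               # active force-length bell width
    kpe: float = 4.0                     # passive fiber exponential shape
    e0: float = 0.6                      # passive fiber strain at max force

    def __post_init__(self) -> None:
        if self.tendon_slack_length <= 0:
            raise ValueError("tendon slack length must be positive")
        if self.optimal_fiber_length <= 0:
            raise ValueError("optimal fiber length must be positive")

    # -- normalized muscle curves -------------------------------------
    def active_fl(self, lnorm: float) -> float:
        if lnorm <= 0:
            return 0.0
        return float(np.exp(-(((lnorm - 1.0) / self.fl_width) ** 2)))

    def passive_fl(self, lnorm: float) -> float:
        if lnorm <= 1.0:
            return 0.0
        return float((np.exp(self.kpe * (lnorm - 1.0) / self.e0) - 1.0)
                     / (np.exp(self.kpe) - 1.0))

    def muscle_force(self, lnorm: float, activation: float) -> float:
        # quasi-static: force-velocity factor = 1
        return activation * self.active_fl(lnorm) + self.passive_fl(lnorm)

    def with_gap(self, gap_mm: float) -> "MusculoTendonUnit":
        """Return a copy whose slack length includes a transection gap."""
        return replace(self, tendon_slack_length=apply_transection_gap(
            self.tendon_slack_length, gap_mm))

    def with_callus(self, factor: float | None = None) -> "MusculoTendonUnit":
        return replace(self, tendon_curve=scale_callus_stiffness(
            self.tendon_curve, factor))


# --------------------------------------------------------------------------
# operations
# --------------------------------------------------------------------------

def mt_length(angles: dict, unit: MusculoTendonUnit) -> float:
    """Musculo-tendon path length (mm) at the given sagittal joint angles.

    Deterministic polynomial fixture; length increases with ankle
    dorsiflexion for all three units.  Angles outside the calibrated sweep
    raise a range error.
    """
    for joint, (lo, hi) in ANGLE_LIMITS.items():
        a = float(angles.get(joint, 0.0))
        if not (lo <= a <= hi):
            raise ValueError(
                f"{joint} angle {a:g} deg outside calibrated range [{lo}, {hi}]")
    c = unit.mt_length_coefficients
    hip = float(angles.get("hip", 0.0))
    knee = float(angles.get("knee", 0.0))
    ankle = float(angles.get("ankle", 0.0))
    length = (c.get("const", 0.0)
              + c.get("hip", 0.0) * hip
              + c.get("knee", 0.0) * knee
              + c.get("ankle", 0.0) * ankle
              + c.get("ankle2", 0.0) * ankle * ankle)
    if length <= 0:
        raise ValueError(f"non-physical path length {length:g} mm for {unit.name}")
    return float(length)


def apply_transection_gap(tsl: float, gap: float = 7.0) -> float:
    """Shift the tendon slack length by the transection gap (mm), exactly.

    gap = 7 mm models an unrepaired transection (stump retraction); gap = 0
    models suture repair (~0 mm gap).
    """
    if tsl <= 0:
        raise ValueError("tendon slack length must be positive")
    if gap < 0:
        raise ValueError("gap distance must be non-negative")
    return tsl + gap


def estimate_tendon_slack_length(unit: MusculoTendonUnit, sweep,
                                 tol: float = 1e-6, max_iter: int = 200) -> float:
    """Estimate tendon slack length from target normalized fiber lengths.

    ``sweep`` is a sequence of (joint-angle dict, target normalized fiber
    length) pairs spanning a physiologic range of postures.  The estimator
    minimizes, by Brent root-finding on the gradient, the least-squares
    residual between target fiber lengths and those implied by a candidate
    TSL (fiber length = path length - tendon slack length at the slack
    reference).  Converges to ``tol`` mm within ``max_iter`` iterations.
    """
    sweep = list(sweep)
    if len(sweep) < 2:
        raise ValueError("TSL estimation needs at least 2 distinct sweep postures")
    lengths = np.array([mt_length(angles, unit) for angles, _ in sweep])
    targets = np.array([float(lt) for _, lt in sweep])
    if np.any((targets <= 0) | (targets >= 2)):
        raise ValueError("target normalized fiber lengths must lie in (0, 2)")
    if np.ptp(lengths) == 0 and len(set(map(tuple, (tuple(sorted(a.items()))
                                                    for a, _ in sweep)))) == 1:
        raise ValueError("degenerate sweep: a single posture is underdetermined")

    lo_f = unit.optimal_fiber_length

    def grad(tsl: float) -> float:
        # d/dTSL of sum(((L - tsl)/lo_f - target)^2)
        resid = (lengths - tsl) / lo_f - targets
        return float(-2.0 * resid.sum() / lo_f)

    lo, hi = 1e-6, float(lengths.max())
    glo, ghi = grad(lo), grad(hi)
    if glo == 0.0:
        return lo
    if ghi == 0.0:
        return hi
    if glo * ghi > 0:
        raise RuntimeError(
            "TSL estimation failed to bracket a minimum; residuals at bounds: "
            f"{grad(lo):.3e}, {grad(hi):.3e}")
    tsl = brentq(grad, lo, hi, xtol=tol, maxiter=max_iter)
    resid = (lengths - tsl) / lo_f - targets
    rms = float(np.sqrt(np.mean(resid ** 2)))
    if not np.isfinite(tsl):
        raise RuntimeError(f"TSL estimation did not converge (rms residual {rms:.3e})")
    return float(tsl)


def equilibrium_tendon_strain(unit: MusculoTendonUnit, mt_len: float,
                              activation: float, resid_tol: float = 1e-8) -> float:
    """Quasi-static tendon strain from the series muscle-tendon force balance.

    Solves muscle force = tendon force for the tendon length by bracketed
    root-finding; returns (tendon length - TSL) / TSL.  A slack tendon
    (path length at or below the slack configuration, or zero muscle force)
    carries no force and returns strain 0.  Activation below 0.05 is
    rejected to avoid the numerical singularity of the muscle model near
    zero activation.
    """
    if mt_len <= 0:
        raise ValueError("musculo-tendon length must be positive")
    if not (0.05 - 1e-12 <= activation <= 1.0 + 1e-12):
        raise ValueError("activation must lie in [0.05, 1]")
    tsl = unit.tendon_slack_length

    if mt_len <= tsl:
        return 0.0

    def residual(lt: float) -> float:
        eps = (lt - tsl) / tsl
        lnorm = (mt_len - lt) / unit.optimal_fiber_length
        return unit.tendon_curve.force(eps) - unit.muscle_force(lnorm, activation)

    r0 = residual(tsl)
    if r0 >= 0.0:
        # muscle exerts no force at the slack configuration
        return 0.0
    hi = min(tsl * (1.0 + 1.0), mt_len)
    r_hi = residual(hi)
    n_expand = 0
    while r_hi <= 0.0:
        if hi >= mt_len - 1e-12 or n_expand > 20:
            raise RuntimeError(
                f"no force-balance root in bracket for {unit.name}: "
                f"residual({tsl:.4g})={r0:.3e}, residual({hi:.4g})={r_hi:.3e}")
        hi = min(hi * 1.3, mt_len)
        r_hi = residual(hi)
        n_expand += 1
    lt = brentq(residual, tsl, hi, xtol=1e-12 * tsl, rtol=8.9e-16)
    if abs(residual(lt)) > resid_tol:
        raise RuntimeError(
            f"force balance did not converge for {unit.name}: "
            f"residual {residual(lt):.3e} > {resid_tol:g}")
    return max((lt - tsl) / tsl, 0.0)


def simulate_gait_strain(trajectory: JointTrajectory,
                         schedule: ActivationSchedule,
                         units) -> StrainProfile:
    """Tendon-level strain profile over one gait cycle.

    Per-unit strain traces are computed sample by sample and averaged
    sample-wise across the three units into the reported profile.
    """
    units = list(units)
    if len(units) == 0:
        raise ValueError("at least one musculo-tendon unit required")
    n = trajectory.times.size
    period = trajectory.period
    traces = np.empty((len(units), n))
    for j, unit in enumerate(units):
        for i in range(n):
            a = schedule.activation(trajectory.times[i], period,
                                    trajectory.stance_fraction)
            length = mt_length(trajectory.angles_at(i), unit)
            traces[j, i] = equilibrium_tendon_strain(unit, length, a)
    avg = traces.mean(axis=0)
    return StrainProfile(trajectory.times.copy(), avg, level="tendon",
                         period=period)


def simulate_immobilized_strain(units, fixed_angles: dict | None = None,
                                activation: float = 0.05,
                                period: float = 1.0,
                                n_samples: int = 11) -> StrainProfile:
    """Constant strain profile for the immobilized (unloaded) condition.

    The knee is fixed at -50 deg flexion and the ankle at -30 deg plantar
    flexion with constant minimal activation 0.05 unless overridden.
    """
    if fixed_angles is None:
        fixed_angles = IMMOBILIZED_POSTURE
    units = list(units)
    strains = [equilibrium_tendon_strain(u, mt_length(fixed_angles, u), activation)
               for u in units]
    value = float(np.mean(strains))
    t = np.linspace(0.0, period, n_samples)
    return StrainProfile(t, np.full_like(t, value), level="tendon", period=period)


def to_cell_strain(profile: StrainProfile,
                   factor: float = CELL_STRAIN_FACTOR) -> StrainProfile:
    """Scale a tissue-level tendon strain profile to cell level (x0.28)."""
    if profile.level != "tendon":
        raise ValueError("profile is already at cell level")
    return StrainProfile(profile.times.copy(), profile.strain * factor,
                         level="cell", period=profile.period)


# --------------------------------------------------------------------------
# packaged fixture units
# --------------------------------------------------------------------------

def _load_config() -> dict:
    text = (importlib.resources.files("tendonheal") / "data"
            / "default_config.yaml").read_text()
    return yaml.safe_load(text)


def load_default_units(repaired: bool = True, healing: bool = True,
                       config: dict | None = None) -> list[MusculoTendonUnit]:
    """The three calibrated fixture units (LG, MG, soleus).

    ``healing=True`` applies the 5x callus stiffness reduction;
    ``repaired=False`` adds the 7 mm transection gap to each slack length.
    """
    cfg = (config or _load_config())["kinematics"]
    tc = cfg["tendon_curve"]
    curve = TendonForceCurve(linear_slope=tc["linear_slope"],
                             toe_strain=tc["toe_strain"],
                             callus_scale_factor=tc["callus_scale_factor"])
    fib = cfg["fiber"]
    units = []
    for name, u in cfg["units"].items():
        unit = MusculoTendonUnit(
            name=name,
            optimal_fiber_length=u["optimal_fiber_length"],
            tendon_slack_length=u["tendon_slack_length"],
            max_isometric_force=u.get("max_isometric_force", 20.0),
            mt_length_coefficients=dict(u["coefficients"]),
            tendon_curve=curve,
            fl_width=fib["fl_width"], kpe=fib["kpe"], e0=fib["e0"])
        if healing:
            unit = unit.with_callus()
        if not repaired:
            unit = unit.with_gap(cfg.get("gap_mm", 7.0))
        units.append(unit)
    return units
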