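"""Stress-fiber orientation dynamics under intermittent cyclic stretch.

The cell's stress-fiber (SF) population is represented as a probability
distribution over axial orientations theta in (-90, 90] degrees (36 bins of
5 degrees, measured from the loading axis x1).  Alignment is summarized by
the order parameter

    S = <cos 2 theta> = sum_i h(theta_i) cos(2 theta_i),

with S = 1 fully parallel to x1, S = -1 fully perpendicular and S = 0 random.

The kinetics are a phenomenological per-bin model with three ingredients:

* slow first-order assembly toward an anisotropic target distribution
  proportional to exp(b * cos 2 theta); the bias b saturates with the
  adapted static strain, so any sustained uniaxial constraint drives
  parallel alignment while a fully unloaded cell relaxes to isotropy;
* fast disassembly in bins whose axial strain rate is strongly negative
  (myosin force-velocity unloading during the shortening phase of each
  stretch cycle), gated by a smooth sigmoid on the negative rate; the
  disassembled mass returns to the cytosolic pool and redistributes, so
  total SF content is conserved;
* slow adaptation of the cell's reference strain toward the running mean
  strain (matrix/adhesion remodeling toward a mechanical equilibrium).

Disassembly is much faster than assembly (enforced rate ratio >= 10), which
is what makes short bouts of cyclic stretch drive alignment down quickly
while long rest periods are needed to recover.

During protocol simulation the disassembly gate is averaged over one strain
cycle (quadrature) and each on/off block is advanced by integrating the
resulting smooth ODE; `sf_step` exposes the explicit fixed-step update for
the instantaneous dynamics.  The model is deterministic; there is no RNG in
this module.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

__all__ = [
    "SFDistribution",
    "StretchProtocol",
    "SFKineticsParameters",
    "SFTimeCourse",
    "order_parameter",
    "sf_step",
    "simulate_protocol",
    "steady_state_alignment",
    "alignment_response_curve",
]

N_BINS_DEFAULT = 36


def _bin_centers(n_bins: int) -> np.ndarray:
    """Equally spaced centers over (-90, 90], including 0 and 90 deg."""
    width = 180.0 / n_bins
    return -90.0 + width * np.arange(1, n_bins + 1)


# --------------------------------------------------------------------------
# distribution container
# --------------------------------------------------------------------------

@dataclass
class SFDistribution:
    """Normalized stress-fiber orientation histogram.

    ``reference_strain`` carries the cell's adapted (remodeled) static
    strain state alongside the histogram.
    """

    bin_centers: np.ndarray
    probability: np.ndarray
    reference_strain: float = 0.0

    def __post_init__(self) -> None:
        self.bin_centers = np.asarray(self.bin_centers, dtype=float)
        self.probability = np.asarray(self.probability, dtype=float)
        if self.bin_centers.shape != self.probability.shape:
            raise ValueError("bin_centers and probability must match in shape")
        if np.any(self.probability < -1e-12):
            raise ValueError("probabilities must be non-negative")

    @classmethod
    def uniform(cls, n_bins: int = N_BINS_DEFAULT,
                reference_strain: float = 0.0) -> "SFDistribution":
        return cls(_bin_centers(n_bins), np.full(n_bins, 1.0 / n_bins),
                   reference_strain)

    @classmethod
    def delta(cls, angle_deg: float,
              n_bins: int = N_BINS_DEFAULT) -> "SFDistribution":
        """All mass in the bin containing ``angle_deg`` (wrapped to (-90, 90])."""
        centers = _bin_centers(n_bins)
        a = (angle_deg + 90.0) % 180.0 - 90.0
        if a == -90.0:
            a = 90.0
        idx = int(np.argmin(np.abs(centers - a)))
        h = np.zeros(n_bins)
        h[idx] = 1.0
        return cls(centers, h)

    @classmethod
    def biased(cls, kappa: float,
               n_bins: int = N_BINS_DEFAULT) -> "SFDistribution":
        """Axial von-Mises-type distribution, h ~ exp(kappa * cos 2 theta)."""
        centers = _bin_centers(n_bins)
        h = np.exp(kappa * np.cos(2 * np.radians(centers)))
        return cls(centers, h / h.sum())

    @classmethod
    def with_order_parameter(cls, s: float,
                             n_bins: int = N_BINS_DEFAULT) -> "SFDistribution":
        """Distribution whose discrete order parameter equals ``s`` exactly
        (to root-finding precision), via the axial von Mises family."""
        if not (-1.0 < s < 1.0):
            raise ValueError("target order parameter must lie in (-1, 1)")
        if s == 0.0:
            return cls.uniform(n_bins)
        sign = 1.0 if s > 0 else -1.0

        # S(kappa) for the discrete family is monotone in kappa
        def g(kappa: float) -> float:
            d = cls.biased(sign * kappa, n_bins)
            return sign * d.order_parameter - abs(s)

        kappa = brentq(g, 0.0, 60.0, xtol=1e-14)
        return cls.biased(sign * kappa, n_bins)

    @property
    def order_parameter(self) -> float:
        return order_parameter(self)

    @property
    def mean_angle(self) -> float:
        """Mean axial orientation in degrees (double-angle average)."""
        th = np.radians(self.bin_centers)
        c = float(np.sum(self.probability * np.cos(2 * th)))
        s = float(np.sum(self.probability * np.sin(2 * th)))
        return float(np.degrees(0.5 * np.arctan2(s, c)))

    def normalized(self) -> "SFDistribution":
        total = self.probability.sum()
        if total <= 0:
            raise ValueError("cannot normalize an empty distribution")
        return replace(self, probability=self.probability / total)


def order_parameter(distribution: SFDistribution) -> float:
    """Order parameter S = sum h(theta) cos(2 theta) of a normalized histogram."""
    h = distribution.probability
    if abs(h.sum() - 1.0) > 1e-6:
        raise ValueError(
            f"distribution is not normalized (sum = {h.sum():.8f})")
    return float(np.sum(h * np.cos(2 * np.radians(distribution.bin_centers))))


# --------------------------------------------------------------------------
# parameters and protocols
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SFKineticsParameters:
    """Rate constants of the stress-fiber kinetics (rates per hour,
    strain rates per second, strains dimensionless cell-level)."""

    assembly_rate: float = 0.35          # 1/h, slow assembly toward target
    disassembly_rate: float = 20.0       # 1/h, fast gated disassembly
    rate_threshold: float = 0.17         # 1/s, negative axial strain-rate gate
    rate_width: float = 0.02             # 1/s, gate smoothness
    adaptation_rate: float = 0.2         # 1/h, reference-strain adaptation
    target_kappa_max: float = 1.4        # target anisotropy saturation
    target_strain_scale: float = 0.0002  # strain scale of target saturation
    transverse_ratio: float = 0.0        # transverse contraction ratio
    n_bins: int = N_BINS_DEFAULT

    def __post_init__(self) -> None:
        if min(self.assembly_rate, self.disassembly_rate,
               self.rate_threshold, self.rate_width,
               self.adaptation_rate) <= 0:
            raise ValueError("all rates and thresholds must be positive")
        if self.disassembly_rate < 10.0 * self.assembly_rate:
            raise ValueError("disassembly must be at least 10x faster than assembly")

    # directional weighting of uniaxial strain(-rate): eps_theta = eps * c(theta)
    def axial_factor(self, centers_deg: np.ndarray) -> np.ndarray:
        th = np.radians(centers_deg)
        return np.cos(th) ** 2 - self.transverse_ratio * np.sin(th) ** 2

    def gate(self, axial_rate) -> np.ndarray:
        """Smooth sigmoid on strongly negative axial strain rate (1 when the
        rate is far below -rate_threshold, ~0 otherwise)."""
        x = (np.asarray(axial_rate, dtype=float) + self.rate_threshold) / self.rate_width
        return 1.0 / (1.0 + np.exp(np.clip(x, -500, 500)))

    def target_bias(self, eps_static: float) -> float:
        e = max(eps_static, 0.0)
        return self.target_kappa_max * (1.0 - np.exp(-e / self.target_strain_scale))

    def target(self, eps_static: float, centers_deg: np.ndarray) -> np.ndarray:
        b = self.target_bias(eps_static)
        h = np.exp(b * np.cos(2 * np.radians(centers_deg)))
        return h / h.sum()


@dataclass(frozen=True)
class StretchProtocol:
    """Intermittent uniaxial stretch protocol.

    On-blocks impose sinusoidal strain at ``frequency`` with peak-to-trough
    ``amplitude`` about ``mean_strain``; off-blocks hold the mean strain with
    no cycling (``hold_mean_during_rest=False`` drops to zero strain
    instead).  With ``include_sleep`` the on/off pattern fills ``wake_hours``
    and is followed by ``24 - wake_hours`` hours of rest, emulating the
    12 h / 12 h light-dark cycle.
    """

    frequency: float = 1.0         # Hz during on-blocks
    on_duration: float = 1.0       # h
    off_duration: float = 1.0      # h
    amplitude: float = 0.0         # peak-to-trough cell strain
    mean_strain: float | None = None   # defaults to amplitude / 2
    wake_hours: float = 12.0
    include_sleep: bool = False
    hold_mean_during_rest: bool = True

    def __post_init__(self) -> None:
        if self.on_duration <= 0:
            raise ValueError("on-block duration must be positive")
        if self.off_duration < 0:
            raise ValueError("off-block duration must be non-negative")
        if self.frequency <= 0:
            raise ValueError("stretch frequency must be positive")
        if self.amplitude < 0:
            raise ValueError("strain amplitude must be non-negative")

    @property
    def mean(self) -> float:
        return self.amplitude / 2.0 if self.mean_strain is None else self.mean_strain

    @property
    def average_frequency(self) -> float:
        """Time-averaged stretch frequency during waking activity."""
        return self.frequency * self.on_duration / (self.on_duration + self.off_duration)

    @classmethod
    def daily(cls, amplitude: float, mean_strain: float | None = None,
              frequency: float = 1.0) -> "StretchProtocol":
        """The default daily loading schedule: alternating 1 h at 1 Hz and
        1 h rest for 12 waking hours, then 12 h of sleep."""
        return cls(frequency=frequency, on_duration=1.0, off_duration=1.0,
                   amplitude=amplitude, mean_strain=mean_strain,
                   wake_hours=12.0, include_sleep=True)

    def blocks(self) -> list[tuple[float, bool]]:
        """One repetition as a list of (duration_h, cycling?) blocks."""
        out: list[tuple[float, bool]] = []
        if self.include_sleep:
            t = 0.0
            while t < self.wake_hours - 1e-9:
                on = min(self.on_duration, self.wake_hours - t)
                out.append((on, True))
                t += on
                if self.off_duration > 0 and t < self.wake_hours - 1e-9:
                    off = min(self.off_duration, self.wake_hours - t)
                    out.append((off, False))
                    t += off
            sleep = 24.0 - self.wake_hours
            if sleep > 0:
                out.append((sleep, False))
        else:
            out.append((self.on_duration, True))
            if self.off_duration > 0:
                out.append((self.off_duration, False))
        return out


@dataclass
class SFTimeCourse:
    """Time course of alignment produced by `simulate_protocol`."""

    times_h: np.ndarray
    order_parameters: np.ndarray
    final: SFDistribution
    converged: bool = False
    n_repetitions: int = 0

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        return self.times_h, self.order_parameters


# --------------------------------------------------------------------------
# dynamics
# --------------------------------------------------------------------------

def _rhs(h: np.ndarray, h_target: np.ndarray, dis: np.ndarray,
         params: SFKineticsParameters) -> np.ndarray:
    """Mass-conserving per-bin kinetics (rates in 1/h).

    Assembly toward the target distribution plus gated disassembly; the
    disassembled mass re-enters the assembling pool (proportional
    redistribution), so sum(h) is invariant.
    """
    ka = params.assembly_rate
    removal = dis * h
    return ka * (h_target - h) - removal + h * removal.sum()


def sf_step(state: SFDistribution, strain: float, strain_rate: float,
            dt: float, params: SFKineticsParameters | None = None) -> SFDistribution:
    """One explicit fixed-step update of the SF distribution.

    ``strain`` is the instantaneous axial cell strain, ``strain_rate`` its
    time derivative (1/s) and ``dt`` the step in seconds.  Raises if the
    step is so large that any bin would go negative.
    """
    if params is None:
        params = SFKineticsParameters(n_bins=state.bin_centers.size)
    if dt <= 0:
        raise ValueError("dt must be positive")
    h = state.probability
    if abs(h.sum() - 1.0) > 1e-6:
        raise ValueError("state distribution must be normalized")
    dt_h = dt / 3600.0
    centers = state.bin_centers
    c = params.axial_factor(centers)
    eps_ref = state.reference_strain
    eps_ref = eps_ref + dt_h * params.adaptation_rate * (strain - eps_ref)
    h_target = params.target(eps_ref, centers)
    dis = params.disassembly_rate * params.gate(strain_rate * c)
    h_new = h + dt_h * _rhs(h, h_target, dis, params)
    if np.any(h_new < 0):
        raise ValueError(
            f"step size dt={dt:g} s too large: a bin went negative "
            f"(min {h_new.min():.3e}); reduce dt")
    h_new = h_new / h_new.sum()
    return SFDistribution(centers, h_new, reference_strain=eps_ref)


def _cycle_averaged_disassembly(amplitude: float, frequency: float,
                                centers_deg: np.ndarray,
                                params: SFKineticsParameters,
                                n_quad: int = 256) -> np.ndarray:
    """Per-bin disassembly rate (1/h) averaged over one sinusoidal strain
    cycle: eps(t) = mean + (A/2) sin(2 pi f t)."""
    c = params.axial_factor(centers_deg)
    phases = 2 * np.pi * (np.arange(n_quad) + 0.5) / n_quad
    peak_rate = np.pi * frequency * amplitude  # max |d eps/dt|, 1/s
    rates = peak_rate * np.cos(phases)         # instantaneous d eps/dt
    g = params.gate(rates[:, None] * c[None, :]).mean(axis=0)
    return params.disassembly_rate * g


def _advance_block(h: np.ndarray, eps_ref: float, duration_h: float,
                   cycling: bool, protocol: StretchProtocol,
                   params: SFKineticsParameters,
                   record_times: np.ndarray | None = None):
    """Advance the distribution over one constant-condition block by
    integrating the cycle-averaged kinetics."""
    centers = _bin_centers(h.size)
    if cycling and protocol.amplitude > 0:
        dis = _cycle_averaged_disassembly(protocol.amplitude,
                                          protocol.frequency, centers, params)
        eps_env = protocol.mean
    else:
        dis = params.disassembly_rate * params.gate(0.0) * np.ones_like(h)
        eps_env = protocol.mean if protocol.hold_mean_during_rest else 0.0

    km = params.adaptation_rate

    def rhs(t, y):
        hh, er = y[:-1], y[-1]
        h_target = params.target(er, centers)
        dh = _rhs(hh, h_target, dis, params)
        return np.append(dh, km * (eps_env - er))

    y0 = np.append(h, eps_ref)
    t_eval = None
    if record_times is not None:
        t_eval = np.clip(record_times, 0.0, duration_h)
    sol = solve_ivp(rhs, (0.0, duration_h), y0, method="RK45",
                    rtol=1e-8, atol=1e-12, t_eval=t_eval)
    if not sol.success:
        raise RuntimeError(f"block integration failed: {sol.message}")
    y_end = sol.y[:, -1]
    h_end = np.clip(y_end[:-1], 0.0, None)
    h_end = h_end / h_end.sum()
    recorded = None
    if record_times is not None:
        recorded = sol.y[:-1, :].T  # (n_times, n_bins)
    return h_end, float(y_end[-1]), recorded


def simulate_protocol(protocol: StretchProtocol,
                      params: SFKineticsParameters | None = None,
                      initial: SFDistribution | None = None,
                      n_repetitions: int = 1,
                      samples_per_block: int = 0) -> SFTimeCourse:
    """Simulate ``n_repetitions`` of an intermittent stretch protocol.

    Alternates cycling on-blocks and rest off-blocks, recording the order
    parameter at every block boundary (plus ``samples_per_block`` interior
    samples per block if requested).  Deterministic.
    """
    if params is None:
        params = SFKineticsParameters()
    if initial is None:
        initial = SFDistribution.uniform(params.n_bins)
    if n_repetitions < 1:
        raise ValueError("n_repetitions must be >= 1")
    h = initial.probability.copy()
    eps_ref = initial.reference_strain
    centers = initial.bin_centers
    cos2 = np.cos(2 * np.radians(centers))

    times = [0.0]
    order = [float(np.sum(h * cos2))]
    t = 0.0
    for _ in range(n_repetitions):
        for duration, cycling in protocol.blocks():
            rec_t = None
            if samples_per_block > 0:
                rec_t = np.linspace(0.0, duration, samples_per_block + 1)[1:]
            h, eps_ref, rec = _advance_block(h, eps_ref, duration, cycling,
                                             protocol, params, rec_t)
            if rec is not None:
                for dt_i, row in zip(rec_t, rec):
                    times.append(t + dt_i)
                    hr = np.clip(row, 0, None)
                    order.append(float(np.sum(hr / hr.sum() * cos2)))
            t += duration
            if samples_per_block == 0:
                times.append(t)
                order.append(float(np.sum(h * cos2)))
    final = SFDistribution(centers, h, reference_strain=eps_ref)
    return SFTimeCourse(np.asarray(times), np.asarray(order), final,
                        n_repetitions=n_repetitions)


def steady_state_alignment(protocol: StretchProtocol,
                           params: SFKineticsParameters | None = None,
                           initial: SFDistribution | None = None,
                           tol: float = 0.01,
                           max_repetitions: int = 200) -> float:
    """Steady-state order parameter under a repeated stretch protocol.

    Repeats the protocol until the difference in alignment at the end of two
    consecutive repetitions is below ``tol`` (default 0.01), then returns the
    time-averaged order parameter over the last simulated repetition cycle.
    """
    if params is None:
        params = SFKineticsParameters()
    if initial is None:
        initial = SFDistribution.uniform(params.n_bins)
    state = initial
    prev_s = state.order_parameter
    history = [prev_s]
    for rep in range(1, max_repetitions + 1):
        course = simulate_protocol(protocol, params, state, n_repetitions=1)
        state = course.final
        s_end = state.order_parameter
        history.append(s_end)
        if abs(s_end - prev_s) < tol:
            # time-averaged S over one more (steady) repetition
            course = simulate_protocol(protocol, params, state,
                                       n_repetitions=1, samples_per_block=20)
            tt, ss = course.times_h, course.order_parameters
            return float(np.trapezoid(ss, tt) / (tt[-1] - tt[0]))
        prev_s = s_end
    raise RuntimeError(
        f"steady state not reached within {max_repetitions} repetitions; "
        f"last order parameters: {[f'{s:.4f}' for s in history[-5:]]}")


def alignment_response_curve(amplitudes, protocol_factory=None,
                             params: SFKineticsParameters | None = None
                             ) -> list[tuple[float, float]]:
    """Steady-state alignment versus cyclic strain amplitude.

    ``protocol_factory`` maps an amplitude to a `StretchProtocol`; by default
    the daily 1 h on / 1 h off schedule at 1 Hz.  Returns one
    (amplitude, steady-state S) pair per requested amplitude.
    """
    if protocol_factory is None:
        protocol_factory = StretchProtocol.daily
    out = []
    for a in amplitudes:
        if a < 0:
            raise ValueError("amplitudes must be non-negative")
        s = steady_state_alignment(protocol_factory(a), params)
        out.append((float(a), float(s)))
    return out
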