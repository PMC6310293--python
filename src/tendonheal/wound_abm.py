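"""Agent-based model of fibroblast-driven tendon scar formation.

A rectangular wound (transection gap) flanked along the tendon loading axis
by healthy tissue margins is discretized into 10 um square collagen patches;
each patch stores a collagen orientation histogram whose sum is the local
collagen area fraction.  Fibroblasts are point agents with a continuous 2D
position and an axial orientation.  Per time step each cell:

* is quiescent or activated according to the local chemokine concentration
  (high plateau inside the wound, exponential falloff into the margins);
* re-orients by integrating four cues - the condition's stretch-driven
  alignment cue (from the stress-fiber model), contact guidance from local
  collagen, the chemokine gradient, and persistence - as a weighted vector
  resultant in double-angle space plus bounded angular noise;
* migrates along its orientation axis (sign chosen toward the chemokine
  gradient) at a state-dependent speed, reflecting at domain boundaries;
* ticks mitosis/apoptosis timers; divides into a free neighboring spot
  (excluded volume: at most one cell per patch) or is removed;
* deposits collagen aligned with its own axis at the condition's synthesis
  rate, capped so patch density never exceeds 1.

Then all patches degrade collagen in proportion to local content
(first-order, 0.0025 per hour) and the (static) chemokine field advances.

All cell updates are synchronous and vectorized; the only order-sensitive
interaction (the per-patch deposition cap) is resolved by proportional
sharing.  Runs are bit-reproducible for a given seed.

Units: positions um, times hours, angles degrees in (-90, 90] measured from
the tendon loading axis (x), collagen in area-fraction units per patch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .stressfiber_alignment import SFDistribution, _bin_centers

__all__ = [
    "WoundGeometry", "AbmParameters", "ChemokineField", "CollagenPatch",
    "Fibroblast", "ScarMetrics", "WoundModel",
    "initialize_wound", "chemokine_gradient", "integrate_cues",
    "deposit_collagen", "degrade_collagen", "compute_scar_metrics",
]

N_BINS = 36


# --------------------------------------------------------------------------
# geometry, parameters, field
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class WoundGeometry:
    """Rectangular wound + healthy margins on a square patch grid.

    The tendon loading axis is x (theta = 0); the wound length spans it.
    """

    wound_length_mm: float = 7.0
    wound_width_mm: float = 1.0
    margin_mm: float = 0.5
    patch_um: float = 10.0

    def __post_init__(self) -> None:
        for name in ("wound_length_mm", "wound_width_mm", "margin_mm"):
            v = getattr(self, name) * 1000.0 / self.patch_um
            if abs(v - round(v)) > 1e-9:
                raise ValueError(
                    f"{name} must be an integral number of {self.patch_um} um patches")

    @property
    def nx(self) -> int:
        return round((self.wound_length_mm + 2 * self.margin_mm) * 1000.0
                     / self.patch_um)

    @property
    def ny(self) -> int:
        return round(self.wound_width_mm * 1000.0 / self.patch_um)

    @property
    def size_um(self) -> tuple[float, float]:
        return (self.nx * self.patch_um, self.ny * self.patch_um)

    @property
    def wound_x_um(self) -> tuple[float, float]:
        x0 = self.margin_mm * 1000.0
        return (x0, x0 + self.wound_length_mm * 1000.0)

    @property
    def patch_area_mm2(self) -> float:
        return (self.patch_um / 1000.0) ** 2


@dataclass(frozen=True)
class AbmParameters:
    """ABM rate and behavior parameters (times in hours, speeds um/h)."""

    cell_radius_um: float = 5.0
    cell_density_per_mm2: float = 500.0
    speed_quiescent: float = 1.0
    speed_activated: float = 50.0
    apoptosis_h: float = 240.0
    mitosis_quiescent_h: float = 12.0
    mitosis_activated_h: float = 240.0
    degradation_per_h: float = 0.0025
    chemokine_decay_um: float = 200.0
    activation_threshold: float = 0.5
    w_stretch: float = 1.0
    w_contact: float = 1.0
    w_chemokine: float = 1.0
    w_persistence: float = 0.5
    cue_concentration: float = 1.0      # von Mises kappa per unit cue resultant
    deposition_scale: float = 0.0002    # area fraction per collagen unit
    contact_saturation: float = 0.01    # density softening of contact cue
    margin_collagen_fraction: float = 0.5
    margin_order_parameter: float = 0.9
    wound_fraction_unrepaired: float = 0.001
    wound_fraction_repaired: float = 0.009
    wound_order_unrepaired: float = 0.0
    wound_order_repaired: float = 0.4

    @classmethod
    def from_config(cls, abm_cfg: dict) -> "AbmParameters":
        c = abm_cfg
        return cls(
            cell_radius_um=c["cell_radius_um"],
            cell_density_per_mm2=c["cell_density_per_mm2"],
            speed_quiescent=c["speed_um_per_h"]["quiescent"],
            speed_activated=c["speed_um_per_h"]["activated"],
            apoptosis_h=c["apoptosis_h"],
            mitosis_quiescent_h=c["mitosis_h"]["quiescent"],
            mitosis_activated_h=c["mitosis_h"]["activated"],
            degradation_per_h=c["degradation_per_h"],
            chemokine_decay_um=c["chemokine"]["decay_um"],
            activation_threshold=c["chemokine"]["activation_threshold"],
            w_stretch=c["cue_weights"]["stretch"],
            w_contact=c["cue_weights"]["contact"],
            w_chemokine=c["cue_weights"]["chemokine"],
            w_persistence=c["cue_weights"]["persistence"],
            cue_concentration=c["cue_concentration"],
            deposition_scale=c["deposition_scale"],
            margin_collagen_fraction=c["margin_collagen_fraction"],
            margin_order_parameter=c["margin_order_parameter"],
            wound_fraction_unrepaired=c["initial_wound"]["unrepaired"]["fraction"],
            wound_fraction_repaired=c["initial_wound"]["repaired"]["fraction"],
            wound_order_unrepaired=c["initial_wound"]["unrepaired"]["order_parameter"],
            wound_order_repaired=c["initial_wound"]["repaired"]["order_parameter"],
        )


@dataclass(frozen=True)
class ChemokineField:
    """Static chemokine profile: plateau 1 inside the wound, exponential
    falloff (length ``decay_um``) into the healthy margins."""

    wound_x0_um: float
    wound_x1_um: float
    decay_um: float
    domain_x_um: float
    domain_y_um: float

    def concentration(self, x):
        x = np.asarray(x, dtype=float)
        c = np.ones_like(x)
        left = x < self.wound_x0_um
        right = x > self.wound_x1_um
        c = np.where(left, np.exp(-(self.wound_x0_um - x) / self.decay_um), c)
        c = np.where(right, np.exp(-(x - self.wound_x1_um) / self.decay_um), c)
        return c

    def gradient_x(self, x):
        """d(concentration)/dx (per um); points toward the wound, zero inside."""
        x = np.asarray(x, dtype=float)
        g = np.zeros_like(x)
        left = x < self.wound_x0_um
        right = x > self.wound_x1_um
        g = np.where(left, np.exp(-(self.wound_x0_um - x) / self.decay_um)
                     / self.decay_um, g)
        g = np.where(right, -np.exp(-(x - self.wound_x1_um) / self.decay_um)
                     / self.decay_um, g)
        return g


def chemokine_gradient(field: ChemokineField, position) -> tuple[np.ndarray, float]:
    """Unit gradient direction and magnitude at a 2D position (um).

    Raises for positions outside the model domain.  Zero magnitude at the
    wound center (and everywhere inside the plateau) by symmetry.
    """
    x, y = float(position[0]), float(position[1])
    if not (0.0 <= x <= field.domain_x_um and 0.0 <= y <= field.domain_y_um):
        raise ValueError(f"position ({x:g}, {y:g}) um outside domain")
    gx = float(field.gradient_x(x))
    mag = abs(gx)
    if mag == 0.0:
        return np.array([0.0, 0.0]), 0.0
    return np.array([math.copysign(1.0, gx), 0.0]), mag


# --------------------------------------------------------------------------
# patch- and cell-level reference operations
# --------------------------------------------------------------------------

@dataclass
class CollagenPatch:
    """One 10 um collagen patch: an orientation histogram whose sum is the
    local collagen area fraction."""

    histogram: np.ndarray = field(
        default_factory=lambda: np.zeros(N_BINS))
    bin_centers: np.ndarray = field(
        default_factory=lambda: _bin_centers(N_BINS))

    @property
    def density(self) -> float:
        return float(self.histogram.sum())

    @property
    def mean_angle(self) -> float:
        th = np.radians(self.bin_centers)
        return float(np.degrees(0.5 * np.arctan2(
            np.sum(self.histogram * np.sin(2 * th)),
            np.sum(self.histogram * np.cos(2 * th)))))

    @property
    def local_order(self) -> float:
        """Order parameter of the patch histogram (0 for an empty patch)."""
        d = self.density
        if d <= 0:
            return 0.0
        h = self.histogram / d
        return float(np.sum(h * np.cos(2 * np.radians(self.bin_centers))))


@dataclass
class Fibroblast:
    """A single fibroblast agent (scalar reference implementation)."""

    position: np.ndarray
    orientation: float = 0.0        # degrees in (-90, 90]
    activated: bool = False
    age_h: float = 0.0
    mitosis_timer_h: float = 12.0
    apoptosis_timer_h: float = 240.0
    radius_um: float = 5.0


def _bin_of(angle_deg, n_bins: int = N_BINS):
    """Histogram bin index for an axial angle (centers -85..90, width 5)."""
    width = 180.0 / n_bins
    a = (np.asarray(angle_deg, dtype=float) + 90.0) % 180.0  # (0, 180]
    idx = np.floor((a + width / 2.0) / width).astype(int) - 1
    return np.mod(idx, n_bins)


def deposit_collagen(cell: Fibroblast, rate: float, dt: float,
                     patch: CollagenPatch,
                     scale: float = 0.001) -> CollagenPatch:
    """Deposit ``rate * dt * scale`` collagen aligned with the cell's axis.

    ``rate`` is the synthesis rate (arbitrary units per cell per hour) and
    ``scale`` converts it to patch area-fraction increments.  Density is
    capped at 1.
    """
    if rate < 0:
        raise ValueError("synthesis rate must be non-negative")
    amount = min(rate * dt * scale, max(0.0, 1.0 - patch.density))
    patch.histogram[_bin_of(cell.orientation, patch.histogram.size)] += amount
    return patch


def degrade_collagen(patch: CollagenPatch, dt: float,
                     rate_per_h: float = 0.0025) -> CollagenPatch:
    """First-order degradation: every bin decays by exp(-rate * dt)."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    patch.histogram *= math.exp(-rate_per_h * dt)
    return patch


def integrate_cues(stretch_cue: tuple[float, float] | None,
                   contact_cue: tuple[float, float] | None,
                   chemo_cue: tuple[float, float] | None,
                   persistence: float | None,
                   weights: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 0.5),
                   noise_deg: float = 0.0,
                   rng: np.random.Generator | None = None) -> float:
    """Integrate orientation cues into a single axial orientation (degrees).

    Each cue is a (direction_deg, strength) pair.  Stretch and contact cues
    are axial (theta and theta+180 equivalent); the chemokine cue is polar
    but folds onto the same axis in double-angle space.  The resultant of
    the weighted cue vectors in double-angle space sets the orientation; a
    vanishing resultant retains the persistence direction, and with no cues
    and no persistence a uniform random orientation is drawn from ``rng``.
    """
    if any(w < 0 for w in weights):
        raise ValueError("cue weights must be non-negative")
    z = 0.0 + 0.0j
    for (cue, w) in zip((stretch_cue, contact_cue, chemo_cue), weights[:3]):
        if cue is None:
            continue
        direction, strength = cue
        if strength < 0:
            raise ValueError("cue strength must be non-negative")
        z += w * strength * np.exp(2j * math.radians(direction))
    if persistence is not None:
        z += weights[3] * np.exp(2j * math.radians(persistence))
    if abs(z) < 1e-12:
        if persistence is not None:
            angle = persistence
        elif rng is not None:
            angle = float(rng.uniform(-90.0, 90.0))
        else:
            raise ValueError("no cues, no persistence and no rng to fall back on")
    else:
        angle = math.degrees(0.5 * np.angle(z))
    if noise_deg > 0.0:
        if rng is None:
            raise ValueError("orientation noise requires an rng")
        angle += noise_deg * float(rng.standard_normal())
    return float((angle + 90.0) % 180.0 - 90.0)


# --------------------------------------------------------------------------
# metrics
# --------------------------------------------------------------------------

@dataclass
class ScarMetrics:
    """Wound-averaged scar structure at one reporting time."""

    time_days: float
    collagen_area_fraction: float
    mean_angle_deg: float
    order_parameter: float
    total_collagen: float        # arbitrary units (sum density x patch area)
    n_cells: int = 0
    degenerate: bool = False     # True when the wound holds no collagen


# --------------------------------------------------------------------------
# the model
# --------------------------------------------------------------------------

class WoundModel:
    """Vectorized agent-based model of scar formation in a tendon wound."""

    def __init__(self, geometry: WoundGeometry, condition: str = "unrepaired",
                 params: AbmParameters | None = None, seed: int = 0,
                 stretch_cue: tuple[float, float] = (0.0, 0.5),
                 synthesis_rate: float = 1.0):
        if condition not in ("repaired", "unrepaired"):
            raise ValueError("condition must be 'repaired' or 'unrepaired'")
        self.geometry = geometry
        self.condition = condition
        self.params = params or AbmParameters()
        self.rng = np.random.default_rng(seed)
        self.seed = seed
        #: (direction_deg, strength) alignment cue from the stress-fiber model
        self.stretch_cue = stretch_cue
        #: collagen synthesis rate (au per cell per hour) from the mean strain
        self.synthesis_rate = synthesis_rate
        self.time_h = 0.0
        self.bin_centers = _bin_centers(N_BINS)
        self._cos2 = np.cos(2 * np.radians(self.bin_centers))
        self._sin2 = np.sin(2 * np.radians(self.bin_centers))

        g = geometry
        self.chemokine = ChemokineField(
            wound_x0_um=g.wound_x_um[0], wound_x1_um=g.wound_x_um[1],
            decay_um=self.params.chemokine_decay_um,
            domain_x_um=g.size_um[0], domain_y_um=g.size_um[1])

        #: global degradation factor: true patch values = hist * _decay.
        #: Keeping first-order decay in one scalar makes degradation exact
        #: and avoids touching the whole grid every step.
        self._decay = 1.0
        self._init_collagen()
        self._init_cells()
        self._total = float(self.hist.sum())
        self.last_deposited = 0.0
        self.last_degraded = 0.0
        self.last_births = 0
        self.last_deaths = 0

    # -- initialization ------------------------------------------------
    def _init_collagen(self) -> None:
        g, p = self.geometry, self.params
        n_patches = g.nx * g.ny
        self.hist = np.zeros((n_patches, N_BINS))
        ix = np.arange(g.nx)
        wound_cols = ((ix * g.patch_um + g.patch_um / 2 >= g.wound_x_um[0])
                      & (ix * g.patch_um + g.patch_um / 2 <= g.wound_x_um[1]))
        self.wound_mask = np.repeat(wound_cols, g.ny)

        if self.condition == "repaired":
            frac, s = p.wound_fraction_repaired, p.wound_order_repaired
        else:
            frac, s = p.wound_fraction_unrepaired, p.wound_order_unrepaired
        wound_hist = self._histogram_with_order(s) * frac
        margin_hist = (self._histogram_with_order(p.margin_order_parameter)
                       * p.margin_collagen_fraction)
        self.hist[self.wound_mask] = wound_hist
        self.hist[~self.wound_mask] = margin_hist

    def _histogram_with_order(self, s: float) -> np.ndarray:
        if s == 0.0:
            return np.full(N_BINS, 1.0 / N_BINS)
        return SFDistribution.with_order_parameter(s, N_BINS).probability

    def _init_cells(self) -> None:
        """Fibroblasts seed the healthy margins; the wound is cell-free.

        Initial ages and division phases are randomized uniformly over
        their periods to avoid synchronized apoptosis/mitosis waves.
        """
        g, p = self.geometry, self.params
        margin_um = g.margin_mm * 1000.0
        area_mm2 = g.margin_mm * g.wound_width_mm
        n_side = int(round(p.cell_density_per_mm2 * area_mm2))
        xs, ys, sides = [], [], []
        for x_lo in (0.0, g.wound_x_um[1]):
            xs.append(self.rng.uniform(x_lo, x_lo + margin_um, n_side))
            ys.append(self.rng.uniform(0.0, g.size_um[1], n_side))
        self.pos = np.column_stack([np.concatenate(xs), np.concatenate(ys)])
        n = self.pos.shape[0]
        self.ori = np.asarray(
            (self.rng.normal(0.0, 10.0, n) + 90.0) % 180.0 - 90.0)
        self.age = self.rng.uniform(0.0, p.apoptosis_h, n)
        self.apop = p.apoptosis_h - self.age
        self.mito = self.rng.uniform(0.0, p.mitosis_quiescent_h, n)

    @property
    def n_cells(self) -> int:
        return self.pos.shape[0]

    # -- helpers -------------------------------------------------------
    def _patch_index(self, pos: np.ndarray) -> np.ndarray:
        g = self.geometry
        ix = np.clip((pos[:, 0] / g.patch_um).astype(int), 0, g.nx - 1)
        iy = np.clip((pos[:, 1] / g.patch_um).astype(int), 0, g.ny - 1)
        return ix * g.ny + iy

    def total_collagen(self) -> float:
        """Grid-wide collagen (area-fraction mass, au)."""
        return float(self.hist.sum() * self._decay)

    # -- one time step -------------------------------------------------
    def step(self, dt: float = 0.5) -> None:
        """Advance the model by ``dt`` hours (dt <= 1 h for stability)."""
        if dt > 1.0:
            raise ValueError("ABM step dt must not exceed 1 hour")
        if dt <= 0:
            raise ValueError("dt must be positive")
        p = self.params
        n = self.n_cells
        births = deaths = 0
        deposited = 0.0

        if n > 0:
            conc = self.chemokine.concentration(self.pos[:, 0])
            activated = conc > p.activation_threshold
            gx = self.chemokine.gradient_x(self.pos[:, 0])

            # --- orientation: weighted cue resultant in double-angle space;
            # the new axial angle is drawn from a von Mises distribution whose
            # concentration scales with the resultant magnitude, so cells with
            # weak or conflicting cues disperse while strongly cued cells align
            pidx = self._patch_index(self.pos)
            rows = self.hist[pidx] * self._decay          # (n, bins), true units
            dens = rows.sum(axis=1)
            rx = rows @ self._cos2
            ry = rows @ self._sin2
            contact_mag = np.hypot(rx, ry) / (dens + p.contact_saturation)
            contact_dir2 = np.arctan2(ry, rx)             # double angle, rad

            sdir, sstr = self.stretch_cue
            z = (p.w_stretch * sstr * np.exp(2j * math.radians(sdir))
                 * np.ones(n, dtype=complex))
            z += p.w_contact * contact_mag * np.exp(1j * contact_dir2)
            chem_mag = np.abs(gx) * p.chemokine_decay_um  # normalized to <= 1
            # polar chemokine direction (+-x) folds to the 0-degree axis
            z += p.w_chemokine * chem_mag
            z += p.w_persistence * np.exp(2j * np.radians(self.ori))
            kappa = p.cue_concentration * np.abs(z)
            draw2 = self.rng.vonmises(np.angle(z), kappa)
            self.ori = np.degrees(0.5 * draw2)

            # --- migration along the orientation axis, toward the wound
            speed = np.where(activated, p.speed_activated, p.speed_quiescent)
            th = np.radians(self.ori)
            ux, uy = np.cos(th), np.sin(th)
            sign = np.sign(ux * gx)
            rand_sign = self.rng.integers(0, 2, n) * 2 - 1
            sign = np.where(sign == 0, rand_sign, sign)
            self.pos[:, 0] += speed * dt * sign * ux
            self.pos[:, 1] += speed * dt * sign * uy
            self._reflect()
            pidx = self._patch_index(self.pos)

            # --- timers, apoptosis, mitosis
            self.age += dt
            self.apop -= dt
            self.mito -= dt
            alive = self.apop > 0.0
            deaths = int(n - alive.sum())

            occupancy = np.bincount(pidx, minlength=self.hist.shape[0])
            ready = (self.mito <= 0.0) & alive
            if np.any(ready):
                idx = np.flatnonzero(ready)
                ang = self.rng.uniform(0.0, 2 * np.pi, idx.size)
                offs = (2 * p.cell_radius_um
                        * np.column_stack([np.cos(ang), np.sin(ang)]))
                cand = self.pos[idx] + offs
                cand[:, 0] = np.clip(cand[:, 0], 0.0, self.geometry.size_um[0])
                cand[:, 1] = np.clip(cand[:, 1], 0.0, self.geometry.size_um[1])
                cand_pidx = self._patch_index(cand)
                free = occupancy[cand_pidx] < 1
                idx_div = idx[free]
                births = idx_div.size
                # blocked cells retry after a short delay
                self.mito[idx[~free]] = 1.0
                reset = np.where(activated, p.mitosis_activated_h,
                                 p.mitosis_quiescent_h)
                self.mito[idx_div] = reset[idx_div]
                if births:
                    d_pos = cand[free]
                    d_ori = self.ori[idx_div]
                    d_act = activated[idx_div]
                    d_mito = np.where(d_act, p.mitosis_activated_h,
                                      p.mitosis_quiescent_h)
                    self.pos = np.vstack([self.pos[alive], d_pos])
                    self.ori = np.concatenate([self.ori[alive], d_ori])
                    self.age = np.concatenate([self.age[alive],
                                               np.zeros(births)])
                    self.apop = np.concatenate([self.apop[alive],
                                                np.full(births, p.apoptosis_h)])
                    keep_mito = self.mito[alive]
                    self.mito = np.concatenate([keep_mito, d_mito])
                    # recompute survivor-dependent arrays for deposition
                    pidx = self._patch_index(self.pos)
                else:
                    self._compact(alive)
                    pidx = self._patch_index(self.pos)
            else:
                self._compact(alive)
                pidx = self._patch_index(self.pos)

            # --- aligned collagen deposition (proportional cap sharing)
            if self.n_cells > 0 and self.synthesis_rate > 0:
                req = self.synthesis_rate * dt * p.deposition_scale
                upidx, inv = np.unique(pidx, return_inverse=True)
                dens_u = self.hist[upidx].sum(axis=1) * self._decay
                req_u = np.bincount(inv).astype(float) * req
                allowed_u = np.clip(1.0 - dens_u, 0.0, None)
                factor_u = np.where(req_u > allowed_u,
                                    allowed_u / np.where(req_u > 0, req_u, 1.0),
                                    1.0)
                amounts = req * factor_u[inv]
                bins = _bin_of(self.ori, N_BINS)
                np.add.at(self.hist, (pidx, bins), amounts / self._decay)
                deposited = float(amounts.sum())

        # --- proportional degradation (exact first-order decay, applied
        # through the global scalar factor)
        decay_step = math.exp(-p.degradation_per_h * dt)
        self._total += deposited
        degraded = self._total * (1.0 - decay_step)
        self._total *= decay_step
        self._decay *= decay_step

        # (static chemokine field: nothing to advance)
        self.time_h += dt
        self.last_deposited = deposited
        self.last_degraded = degraded
        self.last_births = births
        self.last_deaths = deaths

    def _compact(self, alive: np.ndarray) -> None:
        self.pos = self.pos[alive]
        self.ori = self.ori[alive]
        self.age = self.age[alive]
        self.apop = self.apop[alive]
        self.mito = self.mito[alive]

    def _reflect(self) -> None:
        lx, ly = self.geometry.size_um
        for j, lim in ((0, lx), (1, ly)):
            c = self.pos[:, j]
            c = np.abs(c)
            over = c > lim
            c[over] = 2 * lim - c[over]
            self.pos[:, j] = np.clip(c, 0.0, lim)

    # -- reporting -----------------------------------------------------
    def metrics(self) -> ScarMetrics:
        return compute_scar_metrics(self)

    def run(self, days: float, dt: float = 0.5,
            record_every_h: float = 24.0) -> list[ScarMetrics]:
        """Run for ``days`` simulated days, recording wound metrics."""
        out = [self.metrics()]
        n_steps = int(round(days * 24.0 / dt))
        record_every = max(int(round(record_every_h / dt)), 1)
        for k in range(1, n_steps + 1):
            self.step(dt)
            if k % record_every == 0 or k == n_steps:
                out.append(self.metrics())
        return out


def initialize_wound(geometry: WoundGeometry, condition: str,
                     seed: int = 0, params: AbmParameters | None = None,
                     **kwargs) -> WoundModel:
    """Construct the initial model state for a repair condition."""
    return WoundModel(geometry, condition=condition, params=params,
                      seed=seed, **kwargs)


def compute_scar_metrics(model: WoundModel) -> ScarMetrics:
    """Wound-region average area fraction, mean angle and order parameter.

    The per-patch orientation histograms are summed over the wound region,
    normalized, and reduced with S = sum h cos(2 theta).  An empty wound
    (no collagen at all) reports S = 0 with the ``degenerate`` flag set.
    """
    wound = model.hist[model.wound_mask] * model._decay
    if wound.shape[0] == 0:
        raise ValueError("model has an empty wound region")
    total_hist = wound.sum(axis=0)
    dens = wound.sum(axis=1)
    area_fraction = float(dens.mean())
    total = float(dens.sum() * model.geometry.patch_area_mm2)
    mass = total_hist.sum()
    if mass <= 0:
        return ScarMetrics(model.time_h / 24.0, area_fraction, 0.0, 0.0,
                           total, model.n_cells, degenerate=True)
    h = total_hist / mass
    s = float(np.sum(h * model._cos2))
    mean_angle = float(np.degrees(0.5 * np.arctan2(
        np.sum(h * model._sin2), np.sum(h * model._cos2))))
    return ScarMetrics(model.time_h / 24.0, area_fraction, mean_angle, s,
                       total, model.n_cells, degenerate=False)
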