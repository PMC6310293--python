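# Methods

`tendonheal` simulates healing of a transected rat Achilles tendon across
three scales: joint-level kinematics set tendon strain, tendon strain sets
fibroblast alignment and collagen synthesis, and an agent-based model (ABM)
integrates those cell behaviors into scar structure over six weeks.  The
coupling is strictly one-way (strain -> cells -> scar); deposited collagen
does not feed back onto tissue strain.

## 1. Musculo-tendon strain stage

Each of the three triceps-surae units (lateral/medial gastrocnemius,
soleus) is a Hill-type muscle segment in series with a passive tendon
segment.  The musculo-tendon path length is a polynomial in the sagittal
joint angles,

    L(hip, knee, ankle) = c0 + c_h*hip + c_k*knee + c_a*ankle + q_a*ankle^2,

with dorsiflexion and extension positive (degrees, output in mm).  The
gastrocnemii carry small knee terms, the soleus none, and no unit crosses
the hip.  At every time sample the series force balance

    a * fl(l_f / l_opt) + fp(l_f / l_opt) = ft(eps_t)

is solved for the tendon length by bracketed root finding (Brent, residual
closed below 1e-8 in normalized force), treating the gait cycle (1 Hz) as
quasi-static.  `fl` is a Gaussian bell (width 0.45), `fp` an exponential
with shape `kpe` and reference strain `e0`, and `ft` a quadratic-toe +
linear curve.  Tendon strain is (tendon length - slack length) / slack
length; a slack tendon carries no force and reports strain 0.

Healing-stage properties: the linear tendon slope is divided by 5 (healthy
~175 MPa modulus to early-callus ~35 MPa equivalent), and unrepaired
transection adds a 7 mm gap to each tendon slack length, while suture
repair restores a ~0 mm gap.  Loading is a parametric gait waveform (stance
75% of the cycle at activation 1, swing 25% at activation 0.05 with a 10 ms
switching ramp); unloading fixes the knee at -50 deg flexion and the ankle
at -30 deg plantar flexion at constant activation 0.05.  Per-unit strain
traces are averaged sample-wise into the reported tendon strain, and cell
strain is 0.28x the tissue strain (matrix shielding).

**Fixture calibration.**  The path polynomials and curve constants are
calibrated fixtures, not anatomy: they were fitted once (least squares) so
that the four cell-strain operating points of the healing conditions -
static 0.002 (unrepaired-unloaded), 0.009-0.043 cyclic (unrepaired-loaded),
static 0.012 (repaired-unloaded), 0.011-0.075 cyclic (repaired-loaded) -
are reproduced within the fixture tolerance of +-15% (achieved: within
+-10%), together with the cycle means near 0.030 and 0.049.  The calibrated
solution has a definite mechanical structure: the soft callus makes the
swing-phase force balance activation-dominated, unrepaired fibers (shifted
~7 mm shorter by the gap) operate on the ascending limb of the force-length
bell, and repaired fibers operate at or just past the peak.  The descending
limb is what lets the repaired static strain (0.012) slightly exceed the
repaired gait minimum (0.011) while the unrepaired ordering is reversed —
in a purely monotone series model those two orderings are mutually
exclusive.  The repaired stance point engages the steeply rising passive
curve, keeping repaired strains above unrepaired strains at every sample
(checked as an invariant, also under +-20% moment-arm perturbations).  The
quadratic ankle term reconciles the swing/immobilized excursion with the
stance excursion; path length still increases with dorsiflexion everywhere
in the gait range.

The tendon-slack-length estimator inverts target normalized fiber lengths
over a posture sweep by least squares (Brent on the scalar slack length,
tolerance 1e-6 mm); it is exercised by parameter recovery on synthetic
units rather than on anatomy.

## 2. Stress-fiber alignment stage

Cell orientation is represented as a probability histogram over axial
angles theta in (-90, 90], 36 bins of 5 deg with centers at -85..90 so the
parallel (S=1) and perpendicular (S=-1) references are exact on the grid.
Alignment is summarized by the order parameter S = <cos 2 theta>.

The kinetics are phenomenological, with three ingredients chosen to
reproduce the qualitative behaviors of thermodynamic stress-fiber models:

1. slow first-order assembly (0.35 h^-1) toward a target distribution
   proportional to exp(b cos 2 theta); the bias b saturates with the
   adapted static strain over a 2e-4 strain scale up to kappa_max = 1.4,
   so any sustained uniaxial constraint aligns cells parallel (S ~ 0.55)
   while a fully unloaded cell relaxes to isotropy;
2. fast disassembly (20 h^-1, enforced >= 10x the assembly rate) gated by a
   smooth sigmoid on strongly negative axial strain rate (threshold
   0.17 s^-1, width 0.02 s^-1; axial rate = d eps/dt * cos^2 theta), the
   myosin force-velocity unloading effect.  Disassembled subunits return to
   the cytosolic pool and redistribute, conserving total fiber content;
3. slow adaptation (0.2 h^-1) of the cell's reference strain toward the
   running mean strain (matrix/adhesion remodeling).

The rate threshold sits between the peak strain rates of a 0.5 Hz cycle at
amplitude 0.08 (0.126 s^-1) and a 1 Hz cycle at the same amplitude
(0.251 s^-1); that single constant is what makes equal time-averaged
frequencies behave differently, and the slow/fast rate asymmetry is what
makes short cyclic bouts cost more alignment than equal rest recovers.
These five constants were calibrated once against the qualitative targets
(static alignment ~0.55; near-random alignment at the repaired-loaded
operating point; perpendicular steady states for intermittent 1 Hz
protocols at amplitudes 0.06-0.10 but parallel for continuous 0.5 Hz;
protocol-independence below amplitude 0.02) and live in the config.

Protocols alternate on-blocks (sinusoidal strain at the protocol frequency)
and off-blocks (mean strain held by default; a config flag drops rest to
zero strain instead).  The default daily schedule is 1 h on at 1 Hz / 1 h
off for 12 waking hours followed by 12 h of sleep.  During simulation the
disassembly gate is averaged over one strain cycle (256-point quadrature)
and each block is advanced by integrating the resulting smooth ODE
(RK45, rtol 1e-8); `sf_step` exposes the explicit fixed-step update of the
instantaneous dynamics, and a test verifies the two agree over whole
cycles.  Steady state repeats the protocol until the end-of-repetition
alignment changes by less than 0.01, then reports the time-averaged S over
one further repetition.  The module is fully deterministic.

## 3. Collagen synthesis stage

Mean cellular strain over one gait cycle (trapezoidal average; equal to the
static strain for unloaded conditions) maps to a synthesis rate through

    rate(eps_m) = 0.6 + 1.3 / (1 + exp(-150 (eps_m - 0.02))),

bounded in [0.6, 1.9] arbitrary collagen units per cell per hour.  Only
ratios and orderings are meaningful.  The default sigmoid argument is the
identity transform of mean strain, which yields a loaded/unloaded
(0.030 vs 0.002) ratio of 2.44, consistent with the ~2x difference the
response is meant to encode; `transform: half` is available in the config
and is not the default.

## 4. Agent-based scar formation

A rectangular wound (1 mm wide; 0.5 mm long repaired, 7 mm unrepaired,
along the loading axis) plus 0.5 mm healthy margins is gridded into 10 um
patches, each holding a collagen orientation histogram whose sum is the
local area fraction.  Initial matrix: area fraction 0.001 at order 0
(unrepaired provisional matrix) or 0.009 at order 0.4 (repaired);
margins at fraction 0.5, order 0.9 (both exact by construction, via the
axial von Mises family).  Fibroblasts (radius 5 um) seed the margins at
500 cells/mm^2; the wound starts cell-free.

Chemokine: a static analytic profile, plateau 1 inside the wound with
exponential falloff (200 um) into the margins; cells above 50% of the
plateau are activated (speed 50 um/h, division timer 240 h) and others
quiescent (1 um/h, 12 h) — division timers as printed in the source
parameter table, although the quiescent/activated values appear swapped
relative to common usage; the excluded-volume rule below keeps the
population bounded either way.  Apoptosis removes cells at age 240 h.
Initial ages and division phases are randomized uniformly to avoid
synchronized waves.

Each 0.5 h step, synchronously and vectorized over cells:

* **orientation** — the stretch cue (direction 0 deg if the stress-fiber S
  is positive, 90 deg if negative; strength |S|), local contact guidance
  (patch histogram resultant, softened by +0.01 density), the chemokine
  gradient (polar, folding onto the wound axis) and persistence combine as
  a weighted resultant in double-angle space (weights 1, 1, 1, 0.5).  The
  new angle is drawn from a von Mises distribution centered on the
  resultant with concentration kappa = 1.0 * |resultant|, so weakly or
  inconsistently cued cells disperse while strongly cued cells align.  The
  concentration constant was calibrated once so the four healing conditions
  separate in wound order parameter; at 3.0 the contact-guidance feedback
  saturates every condition near S ~ 0.9 and erases them.
* **migration** — along the orientation axis at the state's speed, sign
  chosen toward the chemokine gradient (random where it vanishes),
  reflecting at the domain boundary.
* **division/death** — expired apoptosis timers remove cells; expired
  division timers place a daughter one diameter away if its patch is free
  (at most one cell per 10 um patch), else retry after 1 h.
* **deposition** — each cell adds rate * dt * 2e-4 area fraction into its
  patch's bin at its own orientation; requests are shared proportionally
  where a patch would exceed density 1.  The 2e-4 au^-1 scale is an
  arbitrary-units calibration chosen so the fastest-growing condition stays
  clearly below saturation at 42 days.

Then all patches degrade at 0.0025 h^-1.  Degradation is applied through a
single global decay factor (patch values = stored values x factor), which
makes first-order decay exact to machine precision and avoids touching the
whole grid every step; per-step mass balance (deposited - degraded) is
tracked alongside and tested to 1e-9.

Scar metrics average over the wound region only: patch histograms are
summed and normalized, giving the area fraction, mean angle and order
parameter; an empty wound reports S = 0 with a degenerate flag.

## 5. Orchestration and problem sizes

A condition run chains: strain simulation -> steady-state alignment under
the daily schedule (static solution for unloaded conditions, which bypass
the duty cycle entirely) -> synthesis rate -> ABM.  The ABM consumes one
stretch cue and one synthesis rate per condition, constant over healing,
since the strain inputs are time-invariant per condition.  All randomness
flows from a single run seed through `numpy` SeedSequence substreams;
identical seeds give bit-identical runs.

The trend-reproduction harness and the acceptance property suite run all
four conditions for 42 days on a scaled 0.5 x 1 mm test wound with three
seeds; full-size wounds (7 x 1 mm unrepaired) run with the same code and
stay within a few minutes per condition on one CPU.  The scaled wound keeps
the full structure (margins, cell-free wound, both repair states' initial
matrices) and is the package's standard verification geometry.

## 6. What the synthetic conditions do and do not show

The generator-side choices (parametric gait waveform, fixture path
polynomials, analytic chemokine profile, uniform per-condition strain)
emulate the printed study conditions, not measured anatomy or imaging data.
Passing tests therefore demonstrate that the pipeline's mechanisms produce
the reported orderings — repaired-loaded wounds least aligned yet most
collagen-rich; loading raising collagen content under both repair states;
unrepaired alignment insensitive to loading — under the stated strain
operating points.  They do not validate the absolute strain magnitudes in a
real hindlimb, absolute collagen amounts (arbitrary units), spatial strain
heterogeneity within the wound, or mechanical feedback from the stiffening
scar, all of which are outside the model.

## 7. Numerical notes and limitations

* Force balance: lowest-strain root is taken (continuation from the slack
  state); the steep passive curve keeps the residual monotone at the
  operating points.  Activation below 0.05 is rejected (singularity guard).
* The stress-fiber ODE is linear per bin given the cycle-averaged gate; the
  renormalization term is the only nonlinearity.  Off-blocks use the same
  integrator with the gate at its resting value.
* Cue integration tie-break: a vanishing cue resultant retains the previous
  orientation; a cell with no cues and no history draws uniformly.
* The ABM updates synchronously; the only order-sensitive interaction (the
  per-patch deposition cap) is resolved by proportional sharing, which is
  order-free.  Population-level results at dt = 0.5 h were
  indistinguishable across seeds in the tested bands.
* Wound order parameters depend on the cue-concentration constant;
  condition *orderings* were robust across the tested range (0.8-1.5) but
  absolute S values shift with it, mirroring the arbitrary units of the
  collagen scale.
* Strain transients within a gait cycle (force-velocity, inertia) are
  neglected; the quasi-static solution slightly compresses the oscillation
  extremes, which the fixture calibration absorbs.
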