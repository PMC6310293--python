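# tendonheal

Multiscale simulation of healing in the transected rat Achilles tendon —
for tendon mechanobiologists and modelers who want to ask how repair
(suture vs. natural healing) and loading (cage activity vs. immobilization)
shape scar collagen content and alignment.

Rat studies of Achilles rupture disagree about whether loading helps or
hurts the healing tendon.  This package implements a three-stage model
whose premise is that the disagreement is mechanical: each surgical and
loading protocol produces a different cellular strain history, and a single
set of cellular response curves then explains the divergent tissue
outcomes.

1. **Musculo-tendon strain.**  A planar Hill-type model of the triceps
   surae (lateral/medial gastrocnemius, soleus; muscle in series with a
   passive tendon) driven by gait or immobilization kinematics.  Healing
   enters as a 5x softer tendon force–strain slope (callus) and, for
   unrepaired tendons, a 7 mm transection gap added to the tendon slack
   length.  Tendon strain is `(l_T - l_T,slack) / l_T,slack`, averaged over
   the three units; cellular strain is 0.28x tissue strain.
2. **Stress-fiber alignment.**  The cell's stress-fiber orientation
   distribution h(θ) evolves by slow assembly toward a strain-set target
   and fast disassembly in directions with strongly negative strain rate,
   under intermittent loading protocols (default: 1 h at 1 Hz / 1 h rest
   for 12 waking hours, then 12 h sleep).  Alignment is summarized by the
   order parameter S = ⟨cos 2θ⟩ (1 parallel to load, 0 random, −1
   perpendicular).
3. **Collagen synthesis and scar formation.**  Mean cellular strain ε_m
   sets the per-cell synthesis rate through a fitted sigmoid,
   `rate = 0.6 + 1.3 / (1 + exp(−150 (ε_m − 0.02)))`, and an agent-based
   model of fibroblasts on a 10 µm collagen patch grid (chemokine-driven
   migration into the cell-free wound, cue-integrated orientation, aligned
   deposition, proportional degradation) integrates both signals into
   wound-averaged collagen area fraction, mean angle and order parameter
   over 42 days.

The model's headline result is an apparent paradox: loaded, suture-repaired
tendons develop the **least aligned** scar of the four repair × loading
conditions despite accumulating the **most collagen** — large cyclic
strains randomize cells while large mean strains maximize synthesis.

## Worked example

```python
from tendonheal import protocols

cond = protocols.Condition.from_name("rep-loaded", duration_days=42)
res = protocols.run_condition(cond, seed=1, wound_length_mm=0.5)

print(f"cell strain   {res.cell_profile.min:.4f}..{res.cell_profile.max:.4f}"
      f"  mean {res.mean_strain:.4f}")
print(f"alignment S   {res.alignment:+.3f}")
print(f"synthesis     {res.synthesis_rate:.3f} au/cell/h")
m = res.final_metrics
print(f"day {m.time_days:.0f}: area fraction {m.collagen_area_fraction:.3f}, "
      f"wound S {m.order_parameter:.3f}, total collagen {m.total_collagen:.3f} au")
```

prints

```
cell strain   0.0111..0.0825  mean 0.0564
alignment S   +0.156
synthesis     1.894 au/cell/h
day 42: area fraction 0.878, wound S 0.247, total collagen 0.439 au
```

Read: the repaired-loaded tendon cycles between cell strains 0.011 and
0.083.  The large strain amplitude drives stress-fiber disassembly along
the load, leaving cells nearly random (S = 0.16, versus ≈ 0.55 for the
other three conditions), so the scar's collagen order parameter at day 42
(0.25) is the lowest of the four conditions.  The large *mean* strain
(0.056) puts synthesis near the top of the response curve (1.89 au/cell/h,
versus 0.68 for unrepaired-unloaded), so total collagen is the highest.
Collagen amounts are arbitrary units: only ratios and orderings between
conditions are meaningful.  (This example runs the scaled 0.5 × 1 mm test
wound; pass `wound_length_mm=None` for the full condition geometry.)

The same pipeline is scriptable from the shell:

```
tendonheal strain --condition rep-loaded --out strain.csv
tendonheal heal --condition rep-loaded --days 42 --seed 1 --out run/
tendonheal duty --out duty.csv
tendonheal reproduce --seeds 1,2,3 --wound-length-mm 0.5 --out report/
```

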