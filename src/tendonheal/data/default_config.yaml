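# Default configuration: calibrated fixture geometry, cell-model rate
# constants, synthesis-curve constants and agent-based-model parameters.
# Lengths mm (kinematics) / um (ABM), angles degrees, rates per hour unless
# suffixed otherwise.

kinematics:
  gap_mm: 7.0                  # unrepaired transection gap added to TSL
  cell_strain_factor: 0.28     # tissue -> cell strain transfer
  fiber:
    fl_width: 0.45             # active force-length bell width
    kpe: 7.707259              # passive fiber exponential shape
    e0: 1.063838               # passive fiber strain at max normalized force
  tendon_curve:
    linear_slope: 14.310791    # normalized force per strain, healthy tendon
    toe_strain: 0.05
    callus_scale_factor: 5.0   # healthy -> early callus stiffness reduction
  gait:
    stance_fraction: 0.75
    stance_activation: 1.0
    swing_activation: 0.05
  # Fixture path polynomials (approximations, not anatomy), calibrated so the
  # four printed cell-strain operating points are reproduced.
  units:
    lateral_gastrocnemius:
      optimal_fiber_length: 7.544418
      tendon_slack_length: 31.594906
      max_isometric_force: 20.0
      coefficients: {const: 45.907134, ankle: 0.104290, knee: 0.009584,
                     hip: 0.0, ankle2: -0.002813}
    medial_gastrocnemius:
      optimal_fiber_length: 7.544418
      tendon_slack_length: 31.594906
      max_isometric_force: 22.0
      coefficients: {const: 49.807860, ankle: 0.218750, knee: 0.009083,
                     hip: 0.0, ankle2: -0.002813}
    soleus:
      optimal_fiber_length: 7.544418
      tendon_slack_length: 31.594906
      max_isometric_force: 12.0
      coefficients: {const: 45.762213, ankle: 0.104447, knee: 0.0,
                     hip: 0.0, ankle2: -0.002813}

stressfiber:
  assembly_rate: 0.35          # 1/h
  disassembly_rate: 20.0       # 1/h
  rate_threshold: 0.17         # 1/s
  rate_width: 0.02             # 1/s
  adaptation_rate: 0.2         # 1/h
  target_kappa_max: 1.4
  target_strain_scale: 0.0002
  transverse_ratio: 0.0
  n_bins: 36
  hold_mean_during_rest: true

synthesis:
  amplitude: 1.3
  steepness: 150.0
  inflection: 0.02
  floor: 0.6
  transform: identity          # or 'half'

abm:
  patch_um: 10.0
  wound_width_mm: 1.0
  wound_length_mm: {repaired: 0.5, unrepaired: 7.0}
  margin_mm: 0.5
  margin_collagen_fraction: 0.5
  margin_order_parameter: 0.9
  initial_wound:
    unrepaired: {fraction: 0.001, order_parameter: 0.0}
    repaired: {fraction: 0.009, order_parameter: 0.4}
  cell_density_per_mm2: 500.0
  cell_radius_um: 5.0
  speed_um_per_h: {quiescent: 1.0, activated: 50.0}
  apoptosis_h: 240.0
  mitosis_h: {quiescent: 12.0, activated: 240.0}
  degradation_per_h: 0.0025
  chemokine: {decay_um: 200.0, activation_threshold: 0.5}
  cue_weights: {stretch: 1.0, contact: 1.0, chemokine: 1.0, persistence: 0.5}
  cue_concentration: 1.0       # von Mises kappa per unit cue resultant
  deposition_scale: 0.0002     # area fraction per arbitrary collagen unit
  dt_h: 0.5
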