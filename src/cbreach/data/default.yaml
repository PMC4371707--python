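# Default configuration: 4-DOF, 11-muscle arm with an equilibrium-point
# central controller and a cerebellar context-correction module.
#
# Units: meters, seconds, radians, newtons.  Coordinate frame: shoulder at
# the origin, +y anterior, +x lateral, +z up; the arm hangs along -z in the
# zero pose.  Muscle attachment points are expressed in the body frame of
# the segment they ride on ("world" = trunk, "upper" = humerus frame with
# origin at the shoulder, "fore" = forearm frame with origin at the elbow).

arm:
  l_arm: 0.3
  l_farm: 0.35
  m_arm: 2.1
  m_farm: 1.65
  r_arm: 0.04
  r_farm: 0.03
  muscles:
  - name: sh_flex
    origin: [0.0, 0.05, 0.0]
    insertion: [0.0, 0.03, -0.12]
    origin_frame: world
    insertion_frame: upper
    f_max: 520.0
    k_passive: 40.0
    damping: 5.0
  - name: sh_ext
    origin: [0.0, -0.05, 0.0]
    insertion: [0.0, -0.03, -0.12]
    origin_frame: world
    insertion_frame: upper
    f_max: 520.0
    k_passive: 40.0
    damping: 5.0
  - name: sh_abd
    origin: [0.05, 0.0, 0.02]
    insertion: [0.03, 0.0, -0.1]
    origin_frame: world
    insertion_frame: upper
    bending_line:
    - [0.045, -0.05, 0.035]
    - [0.045, 0.05, 0.035]
    bending_frame: world
    wrap_normal: [1.0, 0.0, 1.0]
    f_max: 520.0
    k_passive: 40.0
    damping: 5.0
  - name: sh_add
    origin: [-0.05, 0.0, -0.02]
    insertion: [-0.03, 0.0, -0.1]
    origin_frame: world
    insertion_frame: upper
    f_max: 520.0
    k_passive: 40.0
    damping: 5.0
  - name: sh_rot_int
    origin: [-0.06, 0.05, -0.03]
    insertion: [0.035, 0.015, -0.07]
    origin_frame: world
    insertion_frame: upper
    f_max: 195.0
    k_passive: 40.0
    damping: 5.0
  - name: sh_rot_ext
    origin: [-0.06, -0.05, -0.03]
    insertion: [0.035, -0.015, -0.07]
    origin_frame: world
    insertion_frame: upper
    f_max: 195.0
    k_passive: 40.0
    damping: 5.0
  - name: biceps
    origin: [0.05, 0.03, 0.01]
    insertion: [0.01, 0.03, -0.05]
    origin_frame: world
    insertion_frame: fore
    f_max: 455.0
    k_passive: 40.0
    damping: 5.0
  - name: triceps
    origin: [-0.05, -0.03, 0.0]
    insertion: [-0.01, -0.025, 0.02]
    origin_frame: world
    insertion_frame: fore
    bending_line:
    - [-0.04, -0.035, -0.29]
    - [0.04, -0.035, -0.29]
    bending_frame: upper
    wrap_normal: [0.0, -1.0, 0.0]
    f_max: 390.0
    k_passive: 40.0
    damping: 5.0
  - name: brachialis
    origin: [0.0, 0.02, -0.2]
    insertion: [-0.02, 0.02, -0.06]
    origin_frame: upper
    insertion_frame: fore
    f_max: 325.0
    k_passive: 40.0
    damping: 5.0
  - name: stab_al
    origin: [0.06, 0.03, 0.0]
    insertion: [0.0, 0.035, -0.14]
    origin_frame: world
    insertion_frame: upper
    f_max: 195.0
    k_passive: 40.0
    damping: 5.0
  - name: stab_pm
    origin: [-0.06, -0.03, 0.0]
    insertion: [0.0, -0.035, -0.14]
    origin_frame: world
    insertion_frame: upper
    f_max: 195.0
    k_passive: 40.0
    damping: 5.0
plant:
  fv_v0: 1.0          # m/s, asymptotic shortening speed of the Hill curve
  fv_shape: 0.3       # curvature of the force-velocity hyperbola
  fv_ecc_max: 1.5     # eccentric plateau
  gravity: false
  g: 9.81
  qd_bound: 20.0      # rad/s; exceeding this flags the reach as unstable
  settle_speed: 0.1   # m/s; hand faster than this in the last second = not settled

controller:
  g_l: 2.0
  g_v: 1.0
  tau_filter: 0.04    # s, first-order low-pass on the command
  k_integral: 0.05    # 1/s, small integral component
  relu_order: pre     # positive part applied before ("pre") or after the filter
  proprioceptive_delay: 0.025   # s
  visual_delay: 0.150           # s

olive:
  n3: 10              # cells oscillating at 3 Hz
  n7: 10              # cells oscillating at 7 Hz
  p: 0.1              # oscillation modulation depth in the spike probability
  refractory: 0.2     # s
  parse: product      # spike-probability formula variant
  error_scale: 100.0  # error enters the spike gates in these units (cm)

cerebellum:
  m_f: 64             # maximum number of stored error-prone areas
  fusion_threshold: 0.08
  fusion_midpoint: 0.5
  episode_max: 0.25   # s, spikes older than this without episode end are dropped
  history_horizon: 0.6
  include_error_in_distance: true
  context_scales:
    error: 10.0       # lengths (m)
    error_rate: 1.0
    quaternion: 1.0
    rates: 1.0
    angle: 1.0
    command: 5.0
  models:
    "1": {method: efference, gain: 1.0, gamma_k: -64.0}
    "2": {method: muscle, amplitude: 0.02, gamma_k: -96.0}
    "3": {method: muscle, amplitude: 0.08, gamma_k: -80.0, require_visual: true}
    "4": {method: muscle_product, gain: 3000.0, gamma_k: -96.0, window: 0.15, w_cap: 0.025}

sim:
  dt_control: 0.001
  dt_physics: 0.0005
  horizon: 4.0
  reaches: 8
  beta_init: 0.02     # small initial abduction keeps the ZXZ chart regular
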