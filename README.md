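# cbreach

Cerebellar context–correction learning on an equilibrium-point reaching arm.

`cbreach` simulates 3D reaching with a 4-degree-of-freedom arm (a 3-DOF
shoulder plus an elbow) actuated by 11 Hill-type composite muscles, driven
by an equilibrium-point (threshold-control) central controller, and
augmented by a cerebellar module that learns **anticipative corrections**:
whenever the hand–target error starts to *increase*, complex spikes from a
model inferior olive trigger the storage of the current sensorimotor
context together with a corrective muscle command; re-entering a stored
context later replays the correction before the error can grow again.

It is aimed at computational-neuroscience work on cerebellar motor
learning, threshold control and the motor-error problem: how a sensory
error (a distance in visual space) can be converted into corrections in
motor coordinates (muscle stimulations) without an inverse model.

## The model in brief

**Central controller.** A target position is converted by inverse
kinematics (intrinsic ZXZ shoulder Euler angles α, β, γ ≡ 0 and elbow
flexion δ) into equilibrium muscle lengths λ. Each muscle is driven by the
positive part of a velocity error in a serial cascade,

    e_l = g_l (l − λ),   e_v = g_v (v + e_l),   u = [e_v]+  (filtered, + small integral)

with g_l = 2, g_v = 1, a 25 ms proprioceptive delay on all muscle and joint
afferents and a 150 ms delay on the visual error.

**Inferior olive.** N₃ = N₇ = 10 cells with 3 Hz and 7 Hz subthreshold
oscillations; the probability that cell *i* emits a complex spike at time
*t* is

    P_i(t) = (p cos[ω_i (t − φ_i)] + 1) / ((1 + e^(5 − E)) (1 + e^(30 − 15 [E′]+)))

gated by the error magnitude E and the positive part of its derivative
(in centimeters), with a 200 ms per-cell refractory period.

**Microcomplex.** Each complex spike whose error-increase episode ends
within 250 ms stores an *error-prone area*: a 28-component context (error,
pose, rates, efferent commands, desired pose) sampled
τ_v − τ_p + (t − t_cs)/2 before the spike, and a correction vector.
Recall is a normalized radial-basis readout,
D(i) = ‖f(i) − v‖², D_N = (M_F/‖D‖) D, output = Σ w(i) e^(γ D_N(i)) with
γ < 0; nearby or overflowing entries fuse into midpoints.

Four model variants differ in the error signal and correction source:

| model | error signal      | correction                                    |
|-------|-------------------|-----------------------------------------------|
| 1     | visual (olive)    | average efferent commands during the episode  |
| 2     | per-muscle (l > λ, elongating) | slight contraction of that muscle |
| 3     | per-muscle + visual-error gate | slight contraction of that muscle |
| 4     | visual (olive)    | gain · [⟨l⟩ − λ]+ [l̇]+ per muscle            |

**Idealized point-mass model.** Separately, the hand is reduced to a point
mass under a central force toward the target; an idealized cerebellum
(speed threshold, distance threshold, gain) stores impulses integrated from
the central force during error-increase episodes and replays them on state
re-entry. Each replayed impulse drains the magnitude of the angular
momentum |L| until the motion terminates at the target or becomes circular.

## Worked example

Run the learning protocol (8 successive reaches to each of the 8 standard
targets) for model 1:

```python
import numpy as np
from cbreach import default_config, run_experiment

table = run_experiment("1", cfg=default_config(), seed=1)
print(np.round(table.normalized_mean, 3))
```

```
[1.    0.986 0.975 0.963 0.947 0.947 0.964 0.962]
```

The numbers are the integrated error (time integral of the hand–target
distance over the 4 s reach, in m·s), averaged over the 8 targets and
normalized by the first reach. The decay across successive reaches is the
cerebellar learning effect: by the eighth reach the average error is ~4%
below the naive first reach (improvement is concentrated in the targets
whose baseline overshoots — reaches that never produce an error increase
give the cerebellum nothing to correct). `table.errors` holds the full
8 × 8 target-by-reach matrix, and `table.per_reach_sem` the standard
errors (S.D./√8) used for learning-curve plots (`reach plot`).

The same protocol is available from the shell:

```bash
reach run --model 1 --reaches 8 --seed 1 --out results/
reach ideal --runs 5 --seed 3 --out ideal_events.csv   # point-mass model
reach plot results/experiment_model_1.json
```

## Configuration

Everything is driven by one YAML configuration (see
`src/cbreach/data/default.yaml` for the annotated default): arm geometry
and the 11-muscle layout with bending lines, Hill parameters, controller
gains and delays, olive population, per-model cerebellar settings, and
integration steps. `reach run --config my.yaml` merges overrides over the
defaults. Coordinates are meters in a right-handed frame with the shoulder
at the origin, +y anterior, +z up; the arm hangs along −z in the zero pose.
Target files are CSV in centimeters, as conventionally printed.
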