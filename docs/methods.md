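# Methods

This note documents the model equations, the numerical choices, the
default parameters and what they were calibrated against, and the known
limitations of the simulator. Units are meters, seconds, radians and
newtons throughout; the shoulder sits at the origin of a right-handed
frame with +y anterior and +z up, and the arm hangs along −z in the zero
pose.

## Kinematics

The arm is a two-segment chain: upper arm `l_arm = 0.30 m` and
forearm+hand `l_farm = 0.35 m` (masses 2.1 / 1.65 kg, solid-cylinder
inertias with radii 4 / 3 cm). The shoulder orientation is parameterized
by intrinsic Z-X-Z Euler angles (α, β, γ), i.e. `R = Rz(α) Rx(β) Rz(γ)`;
elbow flexion δ rotates the forearm about the +x axis of the upper-arm
frame, carrying the hand anteriorly.

Inverse kinematics fixes γ = 0 to make the target → pose map one-to-one:

    α = atan2(−x, y)
    β = acos(−z/d) − acos((d² + l_arm² − l_farm²) / (2 d l_arm))
    δ = π − acos((l_arm² + l_farm² − d²) / (2 l_arm l_farm)),   d = |target|

For anterior targets (y > 0) the α branch reduces to
`asin(−x/√(x²+y²))`; the atan2 form extends the same relation to the whole
workspace so that forward-of-inverse is exact everywhere except the −z
axis (x = y = 0), where α is undefined and set to 0. Targets outside the
annulus `|l_arm − l_farm| ≤ d ≤ l_arm + l_farm` raise a reachability
error.

### Muscle paths

Each of the 11 composite muscles runs from an origin to an insertion
point, each fixed in the body frame of a segment (trunk, humerus or
forearm). A muscle may carry a *bending line* — a finite segment standing
in for bone — plus a *wrap normal* pointing toward its allowed side. The
straight path is used unless it falls on the forbidden side of the
bending line (decided by the sign of the common-perpendicular offset
between the two lines against the wrap normal); a wrapping path is routed
through the point `v` of the bending segment minimizing
`|p₁−v| + |v−p₂|`, which has a closed form: in (arc-length, distance)
coordinates along the line the problem is the planar two-point reflection
problem, giving `s* = (s₁ r₂ + s₂ r₁)/(r₁ + r₂)` clamped to the segment.
The wrap-side rule is our own construction (a single segment in 3D cannot
"block" a path without an orientation); it is continuous in the pose
except at the wrap on/off transition, which is exactly where the
straight and wrapped lengths agree.

The default 11-muscle layout (four cardinal shoulder muscles, two
rotators, biceps-like and triceps-like biarticulars, a brachialis-like
mono-articular elbow flexor, and two oblique stabilizers; bending lines
over the shoulder for the abductor and behind the elbow for the triceps)
is geometric, not anatomical. Its attachment points were chosen so that
the 11 × 4 moment-arm matrix is full rank across the workspace and, in
particular, so that muscle lengths remain sensitive to the arm's internal
(swivel) degree of freedom near β ≈ 0 — without that, the
equilibrium-point controller converges to length equilibria whose hand
position is far from the target.

## Plant

Muscle tension is

    T = F_max · a · fv(v) + k_passive · [l − l_rest]+ + b · [v]+

with activation `da/dt = ([u]+ − a)/τ_a`, τ_a = 40 ms, and a Hill
force–velocity factor `fv(v) = (1 + v/v₀)/(1 − c·v/v₀)` clipped to
[0, 1.5] (v < 0 is shortening; v₀ = 1 m/s, curvature c = 0.3). The
passive spring (40 N/m) engages only beyond the zero-pose rest length and
a small passive damping term (5 N·s/m) resists lengthening only, keeping
tension nonnegative. Note the damping term acts on stretch: a term that
added tension during shortening would be anti-damping and would break the
monotone force–velocity property.

Joint torques follow from virtual work, `τ = −Jᵀ T`, with `J = ∂l/∂q`
evaluated by central differences of the batched muscle-length kernel
(h = 1e−6). Rigid-body dynamics use the generalized coordinates
q = (α, β, γ, δ): the mass matrix is assembled from body Jacobians of the
two cylinders, and Coriolis/centrifugal forces come from central
differences of the mass matrix in Christoffel form. Integration is
semi-implicit Euler at `dt_physics = 0.5 ms` with two substeps per 1 ms
control step; within one control step the mass matrix and its
configuration gradient are frozen (they vary on the movement time scale),
while the velocity-dependent forces are recomputed every substep.

**Chart regularization.** The Z-X-Z chart is singular at β = 0 — exactly
the rest pose — where the α−γ gauge direction carries neither inertia nor
muscle stiffness. A constant Tikhonov term of 1.3·10⁻³ kg·m² is added to
the mass-matrix diagonal: the order of the axial inertia of the upper arm
and negligible against the 0.1–0.3 kg·m² inertias of the load-bearing
directions. The constant is deliberately configuration-independent so the
regularized system remains conservative (a q-dependent term would need
its own gradient in the Coriolis force), and the energy audit includes
it. With passive-spring torques only, total energy drifts < 0.02% over
1 s at dt = 0.1 ms.

Gravity is off by default (a flag enables it); there is no joint
friction.

**Instability flag.** A reach is flagged unstable if any joint rate
exceeds `qd_bound = 20 rad/s` (divergence) or if the hand still moves
faster than `settle_speed = 0.1 m/s` at any point of the final second of
the 4 s horizon (sustained non-settling oscillation — the arm thrashing
around instead of holding the target). Under the default configuration
the no-cerebellum baseline settles 7 of the 8 standard targets below 20%
of the initial distance; target 1 sustains a limit-cycle oscillation
(late hand speed ≈ 0.2 m/s vs ≤ 0.05 elsewhere) and is flagged, the
qualitative analog of a delayed equilibrium-point loop destabilizing for
particular target positions.

## Central controller

Length and velocity errors are the serial cascade `e_l = g_l (l − λ)`,
`e_v = g_v (v + e_l)` with g_l = 2 and g_v = 1 in all simulations. The
muscle stimulation is the positive part of e_v, low-pass filtered
(first-order, τ_f = 40 ms), plus a small integral of the controller's own
clipped output (k_i = 0.05 s⁻¹) that prevents the arm from resting in
equilibria away from the target. The positive part is applied *before*
the filter by default (a config switch reverses the order). All muscle
and joint afferents pass through a 25 ms transport delay; the visual
error and its derivative through 150 ms. The delay line returns the
sample at `t − delay` independent of read/write rates, and the initial
value before that.

τ_f and k_i are not constrained by theory; together with the muscle
parameters (F_max per muscle 195–520 N, fv curvature, damping) they were
calibrated once against the qualitative baseline behavior the
architecture presumes: the hand approaches each target slowly (below 20%
of the initial distance within ~0.5–2.5 s), oscillates around it rather
than converging exactly, and at least one target destabilizes.

## Inferior olive

The visual pathway holds N₃ = 10 cells oscillating at 3 Hz and N₇ = 10 at
7 Hz, phases evenly spaced across each cycle. The per-step (1 ms) spike
probability of cell i is

    P_i(t) = (p cos[ω_i (t − φ_i)] + 1) / ((1 + e^(5 − E)) (1 + e^(30 − 15 [E′]+)))

clipped to [0, 1], with modulation depth p = 0.1. The printed gate
constants (5, 30, 15) are dimensionless; the error is fed to the gates in
centimeters so that the magnitude gate is half-open 5 cm from the target
and the derivative gate at 2 cm/s — scales that sit inside the operating
range of a ~0.5 m reach. The published typography of this expression is
ambiguous; we read the oscillation term as divided by both sigmoidal
gates (the alternative additive parse, available as a config switch,
makes the probability ≥ 1 − p everywhere, which cannot be meant).
Probabilities are Bernoulli per 1 ms evaluation step, and each cell obeys
a 200 ms refractory period. One seeded generator drives all draws; a draw
is consumed for every cell on every step regardless of refractory state,
so spike streams are reproducible bit-for-bit.

The proprioceptive pathway (models 2 and 3) is rule-based and consumes no
randomness: muscle i "spikes" when its (delayed) length exceeds its
target length, is increasing, and 200 ms have passed since its last
spike; model 3 additionally requires the visual error to be increasing.

## Cerebellar microcomplex

The context is a fixed-order 28-vector: visual error and derivative
(150 ms delayed), shoulder quaternion and rate, elbow angle and rate
(25 ms delayed), the 11 velocity-error commands, and the desired pose
(quaternion + angle). Before any distance computation, components are
scaled (lengths ×10, commands ×5, rates/quaternions/angles ×1) so no
single unit dominates the metric; a mask can exclude the error components
from recall distances (included by default).

A pending spike is resolved when the error derivative returns to ≤ 0: if
that happens within 250 ms of the spike, a feature entry is stored, else
the spike is discarded. The stored feature is the context
`τ_v − τ_p + (t − t_cs)/2` before the spike — compensating the visual
delay relative to the proprioceptive one plus half the episode tail. The
correction vector depends on the variant:

* **model 1** — gain × the time-average of the efferent commands over the
  episode, shifted back by τ_v − τ_p (the episode is detected on
  visually-delayed error; the commands were recorded under the shorter
  proprioceptive delay);
* **models 2/3** — amplitude on the spiking muscle only (for these
  pathways the per-muscle elongation episode, `l̇ ≤ 0`, ends the wait);
* **model 4** — gain · [⟨l⟩ − λ]+ · [⟨l̇⟩]+ per muscle, averaged over a
  150 ms window before the episode end with the same τ_v − τ_p shift,
  and saturated at `w_cap = 0.025` per muscle. The saturation is ours:
  the raw product spans orders of magnitude across targets, and motor
  commands saturate physiologically; without it single stored corrections
  can dwarf the central controller's own output.

Recall: `D(i) = ‖f(i) − v‖²` in scaled coordinates,
`D_N = (M_F/‖D‖) D`, output `Σ w(i) exp(γ_k D_N(i))` added to the muscle
input (clipped at 0 together with it). The printed kernel only decays for
γ < 0, so γ_k must be negative. A new entry closer than the fusion
threshold (0.08 in scaled units) to an existing one — or arriving when
the store holds M_F = 64 entries — replaces its nearest neighbour by the
midpoint of features and corrections. Fusion is the mechanism that keeps
complex-spike storms (many cells firing within one episode) from
accumulating clusters of near-duplicate entries whose recalls would sum
into a single oversized kick; the 0.08 threshold was chosen for exactly
that reason, and much smaller values reproduce the oversized-kick
pathology.

Per-model defaults: model 1 gain 1.0, γ_k = −64; model 2 amplitude 0.02,
γ_k = −96; model 3 amplitude 0.08, γ_k = −80; model 4 gain 3000,
γ_k = −96. Models 2 and 3 deliberately differ: the bare muscle-level
error signal is not a reliable proxy for the hand error (an antagonist
stretching during a perfectly good approach still satisfies "long and
elongating"), so model 2 only tolerates small, sharply-tuned corrections,
while model 3's visual-error gate suppresses the spurious stores and
supports the larger amplitude. The simulator reproduces this: model 2
with model 3's amplitude degrades performance markedly.

## Experiment protocol

An experiment is 8 successive 4 s reaches to each of the 8 standard
targets (shipped in `data/targets.csv`, centimeters). The arm is reset to
rest between reaches; the cerebellar store persists across the reaches to
one target — that persistence is the learning — and is cleared between
targets. Performance is the integrated error ∫‖hand − target‖ dt over the
4 s (trapezoid at the control rate); tables report per-reach means across
targets, normalized by the first reach, with standard errors S.D./√8.
Under the defaults the normalized reach-8 means are ≈ 0.93–0.96 (model 1,
seed-dependent through the olive draws), 0.957 (model 2, deterministic),
0.941 (model 3, deterministic) and ≈ 0.996 (model 4), all with negative
Spearman trends. Model 4's margin is structurally thin: its corrections
inherit the muscle-level inconsistency noted above at the storage stage
(it contracts whichever muscles were long and elongating, including
antagonists stretched by a correct approach), which cancels most of what
its anticipative replay gains. Improvements concentrate on targets whose
baseline overshoots: a reach whose error never increases gives this
architecture nothing to learn from, so targets with monotone slow
approaches keep flat learning curves.

## Idealized point-mass model

The hand is a unit point mass under a central force toward the origin
(default linear spring, `F = −k r`, whose orbits are origin-centered
ellipses; an inverse-square law is available). An event begins when the
radial speed dr/dt exceeds the speed threshold; it is *confirmed* once
the error exceeds the distance threshold (so corrections are never
created close to the target). While (1) the error keeps increasing faster
than the speed threshold, (2) the mass has rotated less than π/2 about
the origin since onset, and (3) the accumulated impulse could not reverse
the radial velocity at onset, the central force is integrated; the gain
times that integral is stored against the scaled (position, velocity)
state at onset. A stored impulse fires when the state re-enters a ball of
radius 0.15 around its feature (checked every 0.5 ms), having left it
since creation or the last firing; at application the radial component is
clipped so the radial velocity keeps its sign. Integration is velocity
Verlet at dt = 0.1 ms, which conserves the angular momentum of the
central-force motion to ~10⁻¹³ relative accuracy between impulses. A run
terminates when the error enters the distance threshold or when the
radial-speed amplitude stays below the speed threshold for half a second
(near-circular). As |L| is drained by successive impulses a spring-law
orbit flattens toward a line through the origin, so its perihelion
eventually enters the distance threshold; circular orbits produce no
events at all because their radial velocity is identically zero.

## What the synthetic conditions do and do not show

All experiments are self-generated: the "data" are the 8 printed targets
and the seeded dynamics of the simulator itself. The muscle layout is
geometric rather than anatomical, there is no muscle fatigue, no signal
noise, no trial-to-trial variability beyond the olive's stochasticity,
and the visual error is an exact Euclidean distance. Passing tests
therefore demonstrate the internal consistency of the architecture — that
increase-triggered storage plus context-triggered replay reduces reach
error under these dynamics — not that it would do so for a human arm.
Known limitations: the Euler-chart regularization slightly augments the
axial shoulder inertia; the baseline instability is a sustained limit
cycle rather than a numerical divergence; and the learning effect sizes
depend on how oscillatory the baseline is, which is itself a calibration
choice.
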