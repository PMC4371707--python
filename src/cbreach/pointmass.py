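"""Idealized central-force model of reaching with impulsive corrections.

The hand is reduced to a point mass attracted toward the target (the
origin) by a central force whose magnitude depends only on the distance
(default: a linear spring, which yields closed-form elliptical orbits
centered on the origin).  An idealized "cerebellum", characterized by a
speed threshold, a distance threshold and a gain, watches the error
``r = |position|``:

* a correction **event** begins when the error starts increasing faster
  than the speed threshold and the error exceeds the distance threshold;
* the stored **impulse** is the gain times the integral of the central
  force from the event onset up to a stop time — the last time at which
  (1) the error is still increasing faster than the speed threshold,
  (2) the mass has not rotated more than pi/2 around the origin since
  onset, and (3) the accumulated impulse is not strong enough to reverse
  the radial velocity;
* the impulse is associated with the (position, velocity) state at onset
  and applied whenever the trajectory re-enters a ball around that state,
  with its radial component clipped so the radial velocity never flips
  sign.

Between impulses the dynamics are integrated with velocity Verlet, which
conserves angular momentum of the central-force motion to high accuracy.
Because circular orbits have zero radial velocity they never trigger
events; eccentric orbits trigger corrections whose successive applications
shrink the magnitude of the angular momentum until the motion terminates
near the target or becomes (near-)circular.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PointMassState",
    "IdealCerebellumParams",
    "central_force",
    "detect_event",
    "corrective_impulse",
    "simulate_ideal",
    "IdealSimResult",
]


@dataclass
class PointMassState:
    """Point-mass state; angular momentum is recomputed from r x mv."""

    position: np.ndarray
    velocity: np.ndarray
    mass: float = 1.0

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float).copy()
        self.velocity = np.asarray(self.velocity, dtype=float).copy()
        if self.mass <= 0:
            raise ValueError("mass must be positive")

    @property
    def angular_momentum(self) -> np.ndarray:
        return self.mass * np.cross(self.position, self.velocity)


@dataclass
class IdealCerebellumParams:
    """Speed threshold (m/s), distance threshold (m) and gain."""

    speed_threshold: float = 0.05
    distance_threshold: float = 0.1
    gain: float = 0.5
    trigger_radius: float = 0.15   # state-space ball for re-entry triggering
    velocity_scale: float = 1.0    # velocity weight in the state metric

    def __post_init__(self) -> None:
        if min(self.speed_threshold, self.distance_threshold, self.gain) < 0:
            raise ValueError("thresholds and gain must be nonnegative")


def central_force(r: np.ndarray, k: float = 1.0, law: str = "linear") -> np.ndarray:
    """Force pointing at the origin with distance-dependent magnitude.

    ``linear``: |F| = k |r| (spring).  ``inverse_square``: |F| = k / |r|^2.
    At the origin the force is zero.
    """
    r = np.asarray(r, dtype=float)
    rn = np.linalg.norm(r)
    if rn == 0.0:
        return np.zeros_like(r)
    if law == "linear":
        return -k * r
    if law == "inverse_square":
        return -k * r / rn**3
    raise ValueError(f"unknown force law {law!r}")


def detect_event(
    t: np.ndarray, r: np.ndarray, params: IdealCerebellumParams
) -> float | None:
    """First correction-event onset in a sampled error trajectory.

    Returns the onset time: the first time the radial speed ``dr/dt``
    crosses above the speed threshold while (or before) the error exceeds
    the distance threshold; ``None`` if no event occurs.
    """
    t = np.asarray(t, dtype=float)
    r = np.asarray(r, dtype=float)
    rdot = np.gradient(r, t)
    fast = rdot > params.speed_threshold
    onset = None
    for i in range(len(t)):
        if fast[i] and onset is None:
            onset = i
        elif not fast[i]:
            onset = None
            continue
        if onset is not None and r[i] > params.distance_threshold:
            return float(t[onset])
    return None


def corrective_impulse(
    t: np.ndarray,
    forces: np.ndarray,
    positions: np.ndarray,
    velocities: np.ndarray,
    params: IdealCerebellumParams,
    mass: float = 1.0,
) -> np.ndarray:
    """Impulse for an event given sampled histories starting at the onset.

    Integrates the central-force history (trapezoid) while the three stop
    conditions hold and multiplies by the gain.  The returned impulse, when
    added to ``mass * velocity`` at onset, cannot reverse the radial
    velocity.
    """
    t = np.asarray(t, dtype=float)
    forces = np.atleast_2d(forces)
    positions = np.atleast_2d(positions)
    velocities = np.atleast_2d(velocities)
    if len(t) < 2:
        return np.zeros(positions.shape[1])
    rhat0 = positions[0] / np.linalg.norm(positions[0])
    vr0 = float(velocities[0] @ rhat0)
    acc = np.zeros(positions.shape[1])
    angle = 0.0
    for i in range(1, len(t)):
        p_prev, p = positions[i - 1], positions[i]
        rn_prev, rn = np.linalg.norm(p_prev), np.linalg.norm(p)
        rdot = (rn - rn_prev) / (t[i] - t[i - 1])
        if rdot <= params.speed_threshold:          # condition 1
            break
        cosang = np.clip(p_prev @ p / (rn_prev * rn), -1.0, 1.0)
        angle += np.arccos(cosang)
        if angle > 0.5 * np.pi:                     # condition 2
            break
        inc = 0.5 * (forces[i - 1] + forces[i]) * (t[i] - t[i - 1])
        trial = acc + inc
        if vr0 + params.gain * float(trial @ rhat0) / mass <= 0.0:  # condition 3
            break
        acc = trial
    return params.gain * acc


@dataclass
class IdealSimResult:
    t: np.ndarray
    positions: np.ndarray
    velocities: np.ndarray
    events: list            # (t_onset, t_stop, impulse)
    corrections: list       # (t_applied, |L| before, |L| after, impulse)
    terminated: str         # "target" | "circular" | "horizon"
    store: list             # stored (feature, impulse) pairs

    def angular_momentum_magnitude(self) -> np.ndarray:
        l = np.cross(self.positions, self.velocities)
        return np.linalg.norm(l, axis=1)


def simulate_ideal(
    init: PointMassState,
    params: IdealCerebellumParams,
    T: float = 20.0,
    dt: float = 1e-4,
    k: float = 1.0,
    law: str = "linear",
    store: list | None = None,
    sample_every: int = 10,
) -> IdealSimResult:
    """Run the idealized model with event detection and stored impulses.

    The store holds (state-space feature, impulse) pairs; an entry fires
    when the scaled (position, velocity) state re-enters its trigger ball,
    having left it since the entry was created or last fired.  The radial
    component of an applied impulse is clipped so the radial velocity keeps
    its sign.  Terminates early once the error stays inside the distance
    threshold or the radial speed amplitude drops below the speed
    threshold over a full revolution (near-circular).
    """
    if T <= 0:
        raise ValueError("T must be positive")
    m = init.mass
    px, py, pz = (float(x) for x in init.position)
    vx, vy, vz = (float(x) for x in init.velocity)
    store = [] if store is None else store
    armed = np.ones(len(store), dtype=bool)
    feat_mat = np.stack([s[0] for s in store]) if store else np.empty((0, 6))
    n = int(round(T / dt))
    sv = params.velocity_scale
    trig2 = params.trigger_radius ** 2
    trigger_stride = 5  # state moves ~v*dt per step; checking every 0.5 ms loses nothing

    def force(x, y, z):
        if law == "linear":
            return -k * x, -k * y, -k * z
        rn = np.sqrt(x * x + y * y + z * z)
        if rn == 0.0:
            return 0.0, 0.0, 0.0
        c = -k / rn**3
        return c * x, c * y, c * z

    in_episode = False
    ep_live = False
    ep_confirmed = False
    ep_accx = ep_accy = ep_accz = 0.0
    ep_angle = 0.0
    ep_onset_state = None
    ep_vr0 = 0.0
    ep_rhx = ep_rhy = ep_rhz = 0.0
    ep_px = ep_py = ep_pz = 0.0
    ep_onset_t = 0.0

    events = []
    corrections = []
    ts, ps, vs = [], [], []
    fx, fy, fz = force(px, py, pz)
    rn_prev = np.sqrt(px * px + py * py + pz * pz)
    window = max(int(0.5 / dt), 1000)  # radial-speed amplitude lookback
    rdot_hist_max = 0.0
    rdot_hist_n = 0
    terminated = "horizon"
    t = 0.0
    for i in range(n):
        # re-entry triggering of stored impulses (vectorized, every few steps)
        if len(store) and i % trigger_stride == 0:
            state6 = np.array([px, py, pz, vx * sv, vy * sv, vz * sv])
            diff = feat_mat - state6
            inside = np.einsum("ij,ij->i", diff, diff) < trig2
            fired = False
            for j in np.nonzero(inside)[0]:
                if not armed[j]:
                    continue
                imp = store[j][1]
                rn = np.sqrt(px * px + py * py + pz * pz)
                if rn > 0:
                    rhx, rhy, rhz = px / rn, py / rn, pz / rn
                else:
                    rhx = rhy = rhz = 0.0
                vr = vx * rhx + vy * rhy + vz * rhz
                dvr = (imp[0] * rhx + imp[1] * rhy + imp[2] * rhz) / m
                imp_eff = imp.copy()
                if vr != 0.0 and vr * (vr + dvr) < 0.0:
                    # clip the radial part: keep 1% of the radial velocity
                    scale_r = (dvr + 0.99 * vr) * m
                    imp_eff = imp - scale_r * np.array([rhx, rhy, rhz])
                pos = np.array([px, py, pz])
                vel = np.array([vx, vy, vz])
                l_before = np.linalg.norm(np.cross(pos, m * vel))
                vel = vel + imp_eff / m
                vx, vy, vz = (float(x) for x in vel)
                l_after = np.linalg.norm(np.cross(pos, m * vel))
                corrections.append((t, l_before, l_after, imp_eff))
                armed[j] = False
                fired = True
            armed[~inside] = True
            if fired:
                fx, fy, fz = force(px, py, pz)

        # velocity Verlet step
        hx = vx + 0.5 * dt * fx / m
        hy = vy + 0.5 * dt * fy / m
        hz = vz + 0.5 * dt * fz / m
        px += dt * hx
        py += dt * hy
        pz += dt * hz
        fx, fy, fz = force(px, py, pz)
        vx = hx + 0.5 * dt * fx / m
        vy = hy + 0.5 * dt * fy / m
        vz = hz + 0.5 * dt * fz / m
        t += dt

        rn = np.sqrt(px * px + py * py + pz * pz)
        rdot = (rn - rn_prev) / dt
        rn_prev = rn

        # event detection / episode integration
        if not in_episode:
            if rdot > params.speed_threshold:
                in_episode = True
                ep_live = True
                ep_accx = ep_accy = ep_accz = 0.0
                ep_angle = 0.0
                ep_onset_state = np.array([px, py, pz, vx * sv, vy * sv, vz * sv])
                ep_onset_t = t
                ep_rhx, ep_rhy, ep_rhz = px / rn, py / rn, pz / rn
                ep_vr0 = vx * ep_rhx + vy * ep_rhy + vz * ep_rhz
                ep_px, ep_py, ep_pz = px, py, pz
                ep_confirmed = rn > params.distance_threshold
        else:
            if ep_live:
                dot = ep_px * px + ep_py * py + ep_pz * pz
                nrm = np.sqrt(ep_px**2 + ep_py**2 + ep_pz**2) * rn
                cosang = min(max(dot / nrm, -1.0), 1.0) if nrm > 0 else 1.0
                ep_angle += np.arccos(cosang)
                ep_px, ep_py, ep_pz = px, py, pz
                cond1 = rdot > params.speed_threshold
                cond2 = ep_angle <= 0.5 * np.pi
                tax = ep_accx + fx * dt
                tay = ep_accy + fy * dt
                taz = ep_accz + fz * dt
                cond3 = (
                    ep_vr0
                    + params.gain
                    * (tax * ep_rhx + tay * ep_rhy + taz * ep_rhz)
                    / m
                    > 0.0
                )
                if cond1 and cond2 and cond3:
                    ep_accx, ep_accy, ep_accz = tax, tay, taz
                else:
                    ep_live = False
                if rn > params.distance_threshold:
                    ep_confirmed = True
            if rdot <= params.speed_threshold:
                # episode over: store if it was confirmed
                acc = np.array([ep_accx, ep_accy, ep_accz])
                if ep_confirmed and float(acc @ acc) > 0:
                    impulse = params.gain * acc
                    events.append((ep_onset_t, t, impulse))
                    store.append((ep_onset_state, impulse))
                    feat_mat = np.vstack([feat_mat, ep_onset_state])
                    armed = np.append(armed, False)  # leave the ball first
                in_episode = False

        if i % sample_every == 0:
            ts.append(t)
            ps.append((px, py, pz))
            vs.append((vx, vy, vz))

        # termination checks
        ard = abs(rdot)
        if ard > rdot_hist_max:
            rdot_hist_max = ard
        rdot_hist_n += 1
        if rn < params.distance_threshold:
            terminated = "target"
            break
        if rdot_hist_n >= window:
            if rdot_hist_max < params.speed_threshold:
                terminated = "circular"
                break
            rdot_hist_max = 0.0
            rdot_hist_n = 0

    return IdealSimResult(
        t=np.asarray(ts),
        positions=np.asarray(ps),
        velocities=np.asarray(vs),
        events=events,
        corrections=corrections,
        terminated=terminated,
        store=store,
    )
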