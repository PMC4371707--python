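"""Hill-type muscle forces and 4-DOF rigid-body dynamics of the arm.

Muscle model
------------
Each composite muscle produces tension

    T = F_max * a * fv(v) + k_passive * [l - l_rest]+ + damping * [v]+

where ``a`` is a first-order activation state driven by the stimulation
(``da/dt = ([u]+ - a) / tau_act``), ``fv`` is a Hill force-velocity curve
(1 at isometric, 0 at the asymptotic shortening speed, clipped at an
eccentric plateau), the passive spring engages only beyond rest length, and
a small passive damping term resists lengthening.  Tension is never
negative and is monotone nondecreasing in the stimulation.

Dynamics
--------
The arm is two rigid cylinders in the generalized coordinates
``q = (alpha, beta, gamma, delta)`` (shoulder ZXZ Euler angles + elbow
flexion).  The mass matrix is assembled from body Jacobians; Coriolis and
centrifugal terms come from finite differences of the mass matrix
(Christoffel form).  Integration is semi-implicit Euler.  There is no joint
friction; gravity is optional and off by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _fast
from .kinematics import ArmGeometry, muscle_jacobian, muscle_lengths

__all__ = [
    "ArmState",
    "MuscleCommand",
    "muscle_force",
    "activation_step",
    "joint_torques",
    "mass_matrix",
    "step_dynamics",
    "total_energy",
]

# ZXZ chart regularization: the shoulder Euler angles are singular at
# beta = 0 (alpha and gamma rotations coincide), where the gauge direction
# alpha - gamma carries no inertia and no muscle stiffness.  A constant
# Tikhonov term on the order of the axial inertia of the upper arm
# (~2e-3 kg m^2) keeps accelerations along that direction physical; it is
# negligible against the 0.1-0.3 kg m^2 inertias of the load-bearing
# joints.  It is a constant so the regularized system stays conservative
# (a configuration-dependent term would need its own gradient in the
# Coriolis force), and the energy audit accounts for it.
_MASS_REG = 1.3e-3


@dataclass
class MuscleCommand:
    """Nonnegative stimulation vector for the 11 muscles."""

    u: np.ndarray

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=float)
        if np.any(self.u < 0):
            raise ValueError("muscle stimulations must be nonnegative")


@dataclass
class ArmState:
    """Joint coordinates, rates and muscle activation states."""

    q: np.ndarray                      # (4,) alpha, beta, gamma, delta
    qd: np.ndarray                     # (4,) rad/s
    activation: np.ndarray = None      # (11,) dimensionless
    unstable: bool = False

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float).copy()
        self.qd = np.asarray(self.qd, dtype=float).copy()
        if self.activation is None:
            self.activation = np.zeros(11)
        else:
            self.activation = np.asarray(self.activation, dtype=float).copy()

    def muscle_kinematics(self, geometry: ArmGeometry):
        """Muscle lengths, contraction velocities and the length Jacobian.

        ``v = J qd`` (chain rule), negative while a muscle shortens.
        """
        l, jac = muscle_jacobian(self.q, geometry)
        return l, jac @ self.qd, jac


def _fv(v: np.ndarray, v0: float, shape: float, ecc_max: float) -> np.ndarray:
    """Hill force-velocity factor; v < 0 is shortening."""
    v = np.asarray(v, dtype=float)
    out = (1.0 + v / v0) / (1.0 - shape * v / v0)
    return np.clip(out, 0.0, ecc_max)


def muscle_force(
    u,
    l,
    v,
    f_max=300.0,
    l_rest=0.3,
    k_passive=150.0,
    damping=30.0,
    activation=None,
    v0: float = 1.0,
    fv_shape: float = 4.0,
    fv_ecc_max: float = 1.5,
):
    """Instantaneous muscle tension (N).

    When ``activation`` is None the activation state is taken as the clipped
    stimulation itself (steady-state of the activation filter).
    """
    u = np.maximum(np.asarray(u, dtype=float), 0.0)
    if not np.all(np.isfinite(u)) or not np.all(np.isfinite(np.asarray(l))):
        raise FloatingPointError("non-finite muscle input")
    a = u if activation is None else np.asarray(activation, dtype=float)
    active = f_max * a * _fv(v, v0, fv_shape, fv_ecc_max)
    passive = k_passive * np.maximum(np.asarray(l) - l_rest, 0.0)
    visc = damping * np.maximum(np.asarray(v), 0.0)
    return np.maximum(active + passive + visc, 0.0)


def activation_step(activation, u, dt, tau_act=0.040):
    """Advance the first-order activation state by one step (exact update)."""
    decay = 1.0 - np.exp(-dt / tau_act)
    return activation + decay * (np.maximum(u, 0.0) - activation)


def muscle_tensions(
    state: ArmState, u: np.ndarray, l: np.ndarray, v: np.ndarray,
    geometry: ArmGeometry, plant_cfg: dict | None = None,
) -> np.ndarray:
    """Tensions for all muscles from current activations and kinematics."""
    cfg = plant_cfg or {}
    v0 = cfg.get("fv_v0", 1.0)
    shape = cfg.get("fv_shape", 4.0)
    ecc = cfg.get("fv_ecc_max", 1.5)
    g = geometry
    active = g._f_max * state.activation * _fv(v, v0, shape, ecc)
    passive = g._k_passive * np.maximum(l - g._l_rest, 0.0) + g._damping * np.maximum(
        v, 0.0
    )
    return np.maximum(active + passive, 0.0)


def joint_torques(
    tensions: np.ndarray, jac: np.ndarray
) -> np.ndarray:
    """Generalized torques from muscle tensions: ``tau = -J^T F``.

    ``jac`` is the muscle length Jacobian d l / d q; the sign convention is
    that positive tension acts to shorten the muscle (virtual work
    ``-F dl``).
    """
    return -np.asarray(jac).T @ np.asarray(tensions)


# ---------------------------------------------------------------------------
# Rigid-body dynamics
# ---------------------------------------------------------------------------


def _cylinder_inertia(m: float, r: float, length: float) -> np.ndarray:
    """Body-frame inertia of a solid cylinder with its axis along z."""
    i_perp = m * (3.0 * r * r + length * length) / 12.0
    i_ax = 0.5 * m * r * r
    return np.diag([i_perp, i_perp, i_ax])


def _mass_matrix_batch(q: np.ndarray, geometry: ArmGeometry) -> np.ndarray:
    """Mass matrices (B,4,4) for a batch of joint coordinates (B,4)."""
    q = np.atleast_2d(q)
    if _fast.HAVE_NUMBA:
        g = geometry
        return _fast.mass_kernel(
            np.ascontiguousarray(q), g.l_arm, g.l_farm, g.m_arm, g.m_farm,
            g.r_arm, g.r_farm,
        )
    b = q.shape[0]
    al, be, ga, de = q[:, 0], q[:, 1], q[:, 2], q[:, 3]
    ca, sa = np.cos(al), np.sin(al)
    cb, sb = np.cos(be), np.sin(be)
    cg, sg = np.cos(ga), np.sin(ga)
    # shoulder rotation
    rs = np.empty((b, 3, 3))
    rs[:, 0, 0] = ca * cg - sa * cb * sg
    rs[:, 0, 1] = -ca * sg - sa * cb * cg
    rs[:, 0, 2] = sa * sb
    rs[:, 1, 0] = sa * cg + ca * cb * sg
    rs[:, 1, 1] = -sa * sg + ca * cb * cg
    rs[:, 1, 2] = -ca * sb
    rs[:, 2, 0] = sb * sg
    rs[:, 2, 1] = sb * cg
    rs[:, 2, 2] = cb
    # angular velocity map for intrinsic ZXZ: w = ez*ad + Rz ex*bd + RzRx ez*gd
    a1 = np.zeros((b, 3))
    a1[:, 2] = 1.0
    a2 = np.stack([ca, sa, np.zeros(b)], axis=1)
    a3 = np.stack([sa * sb, -ca * sb, cb], axis=1)
    w1 = np.zeros((b, 3, 4))
    w1[:, :, 0] = a1
    w1[:, :, 1] = a2
    w1[:, :, 2] = a3
    # elbow axis: +x of the upper-arm frame
    ex_u = rs[:, :, 0]
    w2 = w1.copy()
    w2[:, :, 3] = ex_u
    g = geometry
    zhat = np.array([0.0, 0.0, 1.0])
    c1 = rs @ (-0.5 * g.l_arm * zhat)         # upper-arm COM
    e = rs @ (-g.l_arm * zhat)                # elbow
    cd, sd = np.cos(de), np.sin(de)
    # forearm COM offset from elbow, in world frame
    local = np.stack(
        [np.zeros(b), 0.5 * g.l_farm * sd, -0.5 * g.l_farm * cd], axis=1
    )
    r2 = np.einsum("bij,bj->bi", rs, local)

    def skew(v):
        s = np.zeros((v.shape[0], 3, 3))
        s[:, 0, 1] = -v[:, 2]
        s[:, 0, 2] = v[:, 1]
        s[:, 1, 0] = v[:, 2]
        s[:, 1, 2] = -v[:, 0]
        s[:, 2, 0] = -v[:, 1]
        s[:, 2, 1] = v[:, 0]
        return s

    v1 = -skew(c1) @ w1
    v2 = -skew(e) @ w1 - skew(r2) @ w2
    i1b = _cylinder_inertia(g.m_arm, g.r_arm, g.l_arm)
    i2b = _cylinder_inertia(g.m_farm, g.r_farm, g.l_farm)
    # forearm body frame = shoulder rotation composed with elbow rotation
    rx = np.zeros((b, 3, 3))
    rx[:, 0, 0] = 1.0
    rx[:, 1, 1] = cd
    rx[:, 1, 2] = -sd
    rx[:, 2, 1] = sd
    rx[:, 2, 2] = cd
    r2w = rs @ rx
    i1 = rs @ i1b @ rs.transpose(0, 2, 1)
    i2 = r2w @ i2b @ r2w.transpose(0, 2, 1)
    m = (
        g.m_arm * np.einsum("bki,bkj->bij", v1, v1)
        + np.einsum("bki,bkl,blj->bij", w1, i1, w1)
        + g.m_farm * np.einsum("bki,bkj->bij", v2, v2)
        + np.einsum("bki,bkl,blj->bij", w2, i2, w2)
    )
    return m


def mass_matrix(q: np.ndarray, geometry: ArmGeometry) -> np.ndarray:
    """4x4 configuration-dependent mass matrix of the arm."""
    return _mass_matrix_batch(np.asarray(q, dtype=float)[None, :], geometry)[0]


def _coriolis(q, qd, geometry, h=1e-6):
    """Coriolis/centrifugal generalized force c(q, qd) via dM/dq.

    c_k = qd^T dM/dq . qd terms in Christoffel form:
    c = (sum_i dM/dq_i qd_i) qd - 1/2 * d(qd^T M qd)/dq.
    """
    batch = np.tile(q, (8, 1))
    for k in range(4):
        batch[2 * k, k] += h
        batch[2 * k + 1, k] -= h
    ms = _mass_matrix_batch(batch, geometry)
    dm = (ms[0::2] - ms[1::2]) / (2.0 * h)  # (4,4,4): dM/dq_k
    mdot = np.einsum("kij,k->ij", dm, qd)
    quad = 0.5 * np.einsum("i,kij,j->k", qd, dm, qd)
    return mdot @ qd - quad


def gravity_torque(q, geometry, g=9.81, h=1e-6):
    """Generalized gravity force -dV/dq via finite differences of the COMs."""
    def pot(qq):
        al, be, ga, de = qq
        from .kinematics import shoulder_rotation_matrix, _elbow_rotation

        rs = shoulder_rotation_matrix(al, be, ga)
        c1 = rs @ np.array([0.0, 0.0, -0.5 * geometry.l_arm])
        e = rs @ np.array([0.0, 0.0, -geometry.l_arm])
        c2 = e + rs @ _elbow_rotation(de) @ np.array([0.0, 0.0, -0.5 * geometry.l_farm])
        return g * (geometry.m_arm * c1[2] + geometry.m_farm * c2[2])

    out = np.zeros(4)
    for k in range(4):
        qp, qm = q.copy(), q.copy()
        qp[k] += h
        qm[k] -= h
        out[k] = -(pot(qp) - pot(qm)) / (2.0 * h)
    return out


def step_dynamics(
    state: ArmState,
    torques: np.ndarray,
    dt: float,
    geometry: ArmGeometry,
    gravity: bool = False,
    g: float = 9.81,
    qd_bound: float = 20.0,
) -> ArmState:
    """Advance the joint state by one semi-implicit Euler step.

    Solves ``M(q) qdd + c(q, qd) = tau (+ gravity)`` and updates velocities
    before positions.  Exceeding ``qd_bound`` (rad/s) sets the instability
    flag on the returned state; the step itself never raises on divergence
    unless the state stops being finite.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    q, qd = state.q, state.qd
    tau = np.asarray(torques, dtype=float).copy()
    if gravity:
        tau = tau + gravity_torque(q, geometry, g=g)
    # one batched evaluation: base mass matrix + central differences dM/dq
    h = 1e-6
    batch = np.tile(q, (9, 1))
    for k in range(4):
        batch[1 + 2 * k, k] += h
        batch[2 + 2 * k, k] -= h
    ms = _mass_matrix_batch(batch, geometry)
    m = ms[0]
    m[np.diag_indices(4)] += _MASS_REG
    dm = (ms[1::2] - ms[2::2]) / (2.0 * h)  # (4,4,4): dM/dq_k
    mdot = np.einsum("kij,k->ij", dm, qd)
    c = mdot @ qd - 0.5 * np.einsum("i,kij,j->k", qd, dm, qd)
    qdd = np.linalg.solve(m, tau - c)
    qd_new = qd + dt * qdd
    q_new = q + dt * qd_new
    if not np.all(np.isfinite(q_new)) or not np.all(np.isfinite(qd_new)):
        raise FloatingPointError("dynamics diverged to non-finite state")
    new = ArmState(q_new, qd_new, state.activation)
    new.unstable = state.unstable or bool(np.max(np.abs(qd_new)) > qd_bound)
    return new


def advance_control_step(
    state: ArmState,
    torques: np.ndarray,
    dt: float,
    n_sub: int,
    geometry: ArmGeometry,
    gravity: bool = False,
    g: float = 9.81,
    qd_bound: float = 20.0,
) -> ArmState:
    """Advance through ``n_sub`` semi-implicit substeps of one control step.

    The mass matrix and its configuration gradient are evaluated once at the
    start of the control step and held over the substeps (they vary on the
    time scale of the movement, not of the integrator); velocity-dependent
    Coriolis forces are still recomputed each substep.
    """
    q, qd = state.q.copy(), state.qd.copy()
    tau = np.asarray(torques, dtype=float)
    if gravity:
        tau = tau + gravity_torque(q, geometry, g=g)
    h = 1e-6
    batch = np.tile(q, (9, 1))
    for k in range(4):
        batch[1 + 2 * k, k] += h
        batch[2 + 2 * k, k] -= h
    ms = _mass_matrix_batch(batch, geometry)
    m = ms[0]
    m[np.diag_indices(4)] += _MASS_REG
    dm = (ms[1::2] - ms[2::2]) / (2.0 * h)
    m_inv = np.linalg.inv(m)
    for _ in range(n_sub):
        dm_qd = dm @ qd            # (4,4): dM/dq_k qd
        c = qd @ dm_qd - 0.5 * (dm_qd @ qd)
        qd = qd + dt * (m_inv @ (tau - c))
        q = q + dt * qd
    if not (np.all(np.isfinite(q)) and np.all(np.isfinite(qd))):
        raise FloatingPointError("dynamics diverged to non-finite state")
    new = ArmState(q, qd, state.activation)
    new.unstable = state.unstable or bool(np.max(np.abs(qd)) > qd_bound)
    return new


def total_energy(state: ArmState, geometry: ArmGeometry, gravity: bool = False,
                 g: float = 9.81) -> float:
    """Kinetic plus passive-elastic (and optional gravitational) energy."""
    m = mass_matrix(state.q, geometry)
    m[np.diag_indices(4)] += _MASS_REG  # the chart-regularization inertia
    ke = 0.5 * state.qd @ m @ state.qd
    l = muscle_lengths(state.q, geometry)
    stretch = np.maximum(l - geometry.rest_lengths(), 0.0)
    k_p = np.array([mm.k_passive for mm in geometry.muscles])
    pe = 0.5 * np.sum(k_p * stretch**2)
    if gravity:
        from .kinematics import shoulder_rotation_matrix, _elbow_rotation

        rs = shoulder_rotation_matrix(*state.q[:3])
        c1 = rs @ np.array([0.0, 0.0, -0.5 * geometry.l_arm])
        c2 = rs @ (
            np.array([0.0, 0.0, -geometry.l_arm])
            + _elbow_rotation(state.q[3]) @ np.array([0.0, 0.0, -0.5 * geometry.l_farm])
        )
        pe += g * (geometry.m_arm * c1[2] + geometry.m_farm * c2[2])
    return float(ke + pe)
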