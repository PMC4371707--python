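"""Arm geometry, inverse/forward kinematics and muscle path lengths.

The arm is a two-segment chain: an upper arm of length ``l_arm`` attached to
the shoulder (at the origin) and a forearm+hand segment of length ``l_farm``
attached at the elbow.  The shoulder has three rotational degrees of freedom
parameterized by intrinsic Z-X-Z Euler angles (alpha, beta, gamma); the elbow
has a single flexion angle delta.  In the zero pose the arm hangs along -z,
with +y anterior and +x lateral; elbow flexion is a rotation about the +x
axis of the upper-arm body frame, so flexion carries the hand anteriorly.

Muscles are straight-line actuators between an origin and an insertion point,
each expressed in the body frame of the segment it attaches to (``world`` for
the trunk, ``upper``, or ``fore``).  A muscle may wrap around a "bending
line", a finite segment standing in for bone: when the straight path passes
on the forbidden side of that line the muscle is routed through the point of
the bending line that minimizes total path length.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _fast

__all__ = [
    "ReachabilityError",
    "MuscleGeometry",
    "ArmGeometry",
    "ArmPose",
    "shoulder_rotation_matrix",
    "shoulder_quaternion",
    "ik_angles",
    "forward_hand_position",
    "forward_elbow_position",
    "muscle_path_length",
    "muscle_lengths",
    "target_lengths",
]

N_MUSCLES = 11

_FRAMES = ("world", "upper", "fore")


class ReachabilityError(ValueError):
    """Raised when a target lies outside the reachable annulus of the arm."""


@dataclass
class MuscleGeometry:
    """Geometry and Hill parameters of one composite muscle.

    ``origin``/``insertion`` are 3-vectors in the body frame named by
    ``origin_frame``/``insertion_frame``.  ``bending_line`` is an optional
    pair of 3-vector endpoints (in ``bending_frame``); ``wrap_normal`` points
    toward the allowed side of the bending line: the muscle wraps whenever
    its straight path falls on the opposite side.
    """

    name: str
    origin: np.ndarray
    insertion: np.ndarray
    origin_frame: str = "world"
    insertion_frame: str = "upper"
    bending_line: np.ndarray | None = None  # (2, 3) endpoints
    bending_frame: str = "world"
    wrap_normal: np.ndarray | None = None
    # Hill parameters
    f_max: float = 300.0          # N
    tau_act: float = 0.040        # s
    damping: float = 30.0         # N s/m, passive, lengthening only
    k_passive: float = 150.0      # N/m
    l_rest: float | None = None   # m; filled from the zero pose if None

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.insertion = np.asarray(self.insertion, dtype=float)
        if self.origin_frame not in _FRAMES or self.insertion_frame not in _FRAMES:
            raise ValueError(f"unknown frame for muscle {self.name!r}")
        if self.origin_frame == self.insertion_frame and np.allclose(
            self.origin, self.insertion
        ):
            raise ValueError(f"muscle {self.name!r}: origin equals insertion")
        if self.bending_line is not None:
            self.bending_line = np.asarray(self.bending_line, dtype=float).reshape(2, 3)
            if np.allclose(self.bending_line[0], self.bending_line[1]):
                raise ValueError(
                    f"muscle {self.name!r}: bending line endpoints coincide"
                )
            if self.wrap_normal is None:
                raise ValueError(
                    f"muscle {self.name!r}: bending line requires a wrap normal"
                )
            self.wrap_normal = np.asarray(self.wrap_normal, dtype=float)
            self.wrap_normal = self.wrap_normal / np.linalg.norm(self.wrap_normal)
        for par in ("f_max", "tau_act", "damping", "k_passive"):
            if getattr(self, par) <= 0:
                raise ValueError(f"muscle {self.name!r}: {par} must be positive")


@dataclass
class ArmGeometry:
    """Fixed physical description of the arm: segments, inertia and muscles."""

    l_arm: float = 0.30    # m, upper arm
    l_farm: float = 0.35   # m, forearm + hand
    m_arm: float = 2.1     # kg
    m_farm: float = 1.65   # kg
    r_arm: float = 0.04    # m, cylinder radius (inertia only)
    r_farm: float = 0.03   # m
    muscles: list[MuscleGeometry] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.l_arm <= 0 or self.l_farm <= 0:
            raise ValueError("segment lengths must be positive")
        if self.muscles and len(self.muscles) != N_MUSCLES:
            raise ValueError(f"expected {N_MUSCLES} muscles, got {len(self.muscles)}")
        self._pack()
        if self.muscles:
            # rest lengths default to the lengths in the zero pose
            l0 = muscle_lengths(np.zeros(4), self)
            for m, l in zip(self.muscles, l0):
                if m.l_rest is None:
                    m.l_rest = float(l)
            self._f_max = np.array([m.f_max for m in self.muscles])
            self._k_passive = np.array([m.k_passive for m in self.muscles])
            self._damping = np.array([m.damping for m in self.muscles])
            self._l_rest = np.array([m.l_rest for m in self.muscles])

    # -- packed arrays for vectorized length evaluation ------------------
    def _pack(self) -> None:
        n = len(self.muscles)
        self._orig = np.zeros((n, 3))
        self._ins = np.zeros((n, 3))
        self._orig_f = np.zeros(n, dtype=int)
        self._ins_f = np.zeros(n, dtype=int)
        self._has_bl = np.zeros(n, dtype=bool)
        self._bl_a = np.zeros((n, 3))
        self._bl_b = np.zeros((n, 3))
        self._bl_f = np.zeros(n, dtype=int)
        self._bl_n = np.zeros((n, 3))
        for i, m in enumerate(self.muscles):
            self._orig[i] = m.origin
            self._ins[i] = m.insertion
            self._orig_f[i] = _FRAMES.index(m.origin_frame)
            self._ins_f[i] = _FRAMES.index(m.insertion_frame)
            if m.bending_line is not None:
                self._has_bl[i] = True
                self._bl_a[i] = m.bending_line[0]
                self._bl_b[i] = m.bending_line[1]
                self._bl_f[i] = _FRAMES.index(m.bending_frame)
                self._bl_n[i] = m.wrap_normal
        # one flat point table so a batch evaluation needs two einsums:
        # rows = all origins, insertions, bending endpoints and wrap normals
        self._bl_idx = np.nonzero(self._has_bl)[0]
        nb = len(self._bl_idx)
        pts = np.vstack(
            [self._orig, self._ins, self._bl_a[self._bl_idx], self._bl_b[self._bl_idx]]
        )
        frames = np.concatenate(
            [self._orig_f, self._ins_f, self._bl_f[self._bl_idx], self._bl_f[self._bl_idx]]
        )
        self._pt_table = pts
        self._pt_frames = frames.astype(np.int64)
        self._pt_up = frames == 1
        self._pt_fo = frames == 2
        self._n_pts = pts.shape[0]
        self._sl_orig = slice(0, n)
        self._sl_ins = slice(n, 2 * n)
        self._sl_bla = slice(2 * n, 2 * n + nb)
        self._sl_blb = slice(2 * n + nb, 2 * n + 2 * nb)
        # wrap normals: rotation only (world normals stay fixed)
        self._n_table = self._bl_n[self._bl_idx]
        self._n_up = self._bl_f[self._bl_idx] == 1
        self._n_fo = self._bl_f[self._bl_idx] == 2

    @property
    def reach(self) -> float:
        return self.l_arm + self.l_farm

    def rest_lengths(self) -> np.ndarray:
        return np.array([m.l_rest for m in self.muscles])


@dataclass
class ArmPose:
    """Joint pose: shoulder Euler angles (intrinsic ZXZ) plus elbow flexion."""

    alpha: float
    beta: float
    gamma: float
    delta: float

    @property
    def theta_e(self) -> float:
        """Elbow flexion angle (alias of delta)."""
        return self.delta

    @property
    def q_s(self) -> np.ndarray:
        """Unit quaternion (w, x, y, z) equivalent of the shoulder rotation."""
        return shoulder_quaternion(self.alpha, self.beta, self.gamma)

    def as_array(self) -> np.ndarray:
        return np.array([self.alpha, self.beta, self.gamma, self.delta])


def shoulder_rotation_matrix(alpha: float, beta: float, gamma: float) -> np.ndarray:
    """Rotation matrix of the shoulder for intrinsic Z-X-Z Euler angles.

    Equals ``Rz(alpha) @ Rx(beta) @ Rz(gamma)``.
    """
    ca, sa = np.cos(alpha), np.sin(alpha)
    cb, sb = np.cos(beta), np.sin(beta)
    cg, sg = np.cos(gamma), np.sin(gamma)
    return np.array(
        [
            [ca * cg - sa * cb * sg, -ca * sg - sa * cb * cg, sa * sb],
            [sa * cg + ca * cb * sg, -sa * sg + ca * cb * cg, -ca * sb],
            [sb * sg, sb * cg, cb],
        ]
    )


def shoulder_quaternion(alpha: float, beta: float, gamma: float) -> np.ndarray:
    """Unit quaternion (w, x, y, z) for the intrinsic ZXZ rotation."""
    hp, hm, hb = 0.5 * (alpha + gamma), 0.5 * (alpha - gamma), 0.5 * beta
    return np.array(
        [
            np.cos(hb) * np.cos(hp),
            np.sin(hb) * np.cos(hm),
            np.sin(hb) * np.sin(hm),
            np.cos(hb) * np.sin(hp),
        ]
    )


def ik_angles(target: np.ndarray, geometry: ArmGeometry) -> ArmPose:
    """Inverse kinematics: joint angles placing the hand at ``target``.

    The map is made one-to-one by fixing gamma = 0 (no axial rotation of the
    upper arm).  For targets on the -z axis (x = y = 0) alpha is undefined
    and set to 0.  Raises :class:`ReachabilityError` outside the annulus
    ``|l_arm - l_farm| <= |target| <= l_arm + l_farm``.
    """
    x, y, z = np.asarray(target, dtype=float)
    la, lf = geometry.l_arm, geometry.l_farm
    d2 = x * x + y * y + z * z
    d = np.sqrt(d2)
    tol = 1e-9
    if d > la + lf + tol or d < abs(la - lf) - tol:
        raise ReachabilityError(
            f"target at distance {d:.4f} m outside reachable annulus "
            f"[{abs(la - lf):.4f}, {la + lf:.4f}] m"
        )
    rho = np.hypot(x, y)
    # alpha = asin(-x / rho) on the anterior half-space; atan2 extends the
    # same relation to y < 0 so the forward map still inverts it exactly.
    alpha = 0.0 if rho < 1e-12 else np.arctan2(-x, y)
    beta = np.arccos(np.clip(-z / d, -1.0, 1.0)) - np.arccos(
        np.clip((d2 + la * la - lf * lf) / (2.0 * d * la), -1.0, 1.0)
    )
    delta = np.pi - np.arccos(
        np.clip((la * la + lf * lf - d2) / (2.0 * la * lf), -1.0, 1.0)
    )
    return ArmPose(float(alpha), float(beta), 0.0, float(delta))


def _elbow_rotation(delta: float) -> np.ndarray:
    c, s = np.cos(delta), np.sin(delta)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def forward_elbow_position(pose: ArmPose, geometry: ArmGeometry) -> np.ndarray:
    rs = shoulder_rotation_matrix(pose.alpha, pose.beta, pose.gamma)
    return rs @ np.array([0.0, 0.0, -geometry.l_arm])


def forward_hand_position(pose: ArmPose, geometry: ArmGeometry) -> np.ndarray:
    """Hand position for a pose; exact inverse of :func:`ik_angles` at gamma=0.

    The forearm endpoint is rotated by the elbow first, then the whole chain
    by the shoulder rotation.
    """
    rs = shoulder_rotation_matrix(pose.alpha, pose.beta, pose.gamma)
    u = np.array([0.0, 0.0, -geometry.l_arm]) + _elbow_rotation(pose.delta) @ np.array(
        [0.0, 0.0, -geometry.l_farm]
    )
    return rs @ u


def muscle_path_length(
    p1: np.ndarray,
    p2: np.ndarray,
    bending_line: np.ndarray | None = None,
    wrap_normal: np.ndarray | None = None,
) -> tuple[float, np.ndarray | None]:
    """Length of the muscle path from ``p1`` to ``p2``, wrapping if needed.

    Without a bending line (or when the straight path stays on the allowed
    side given by ``wrap_normal``) the length is the Euclidean distance and
    no via point is returned.  Otherwise the path is routed through the
    point ``v`` of the bending segment minimizing ``|p1-v| + |v-p2|`` and
    that minimal length is returned together with ``v``.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    if np.allclose(p1, p2):
        raise ValueError("muscle endpoints coincide")
    straight = float(np.linalg.norm(p2 - p1))
    if bending_line is None:
        return straight, None
    bl = np.asarray(bending_line, dtype=float).reshape(2, 3)
    a, b = bl
    d = b - a
    dd = float(d @ d)
    if dd < 1e-16:
        raise ValueError("degenerate bending line")
    if wrap_normal is None:
        raise ValueError("bending line requires a wrap normal")
    if not _wraps(p1, p2, a, d, dd, np.asarray(wrap_normal, dtype=float)):
        return straight, None
    length, via = _via_point(p1, p2, a, d, dd)
    return float(length), via


def _wraps(p1, p2, a, d, dd, n) -> bool:
    """Does the straight segment p1-p2 pass on the forbidden side?

    Decided from the common perpendicular between the muscle line and the
    (infinite) bending line: the offset from the bending line to the muscle
    line is compared against the wrap normal.
    """
    u = p2 - p1
    w0 = p1 - a
    uu = u @ u
    ud = u @ d
    den = uu * dd - ud * ud
    if den < 1e-14 * uu * dd + 1e-30:  # near-parallel lines
        off = w0 - (w0 @ d) / dd * d
    else:
        s = (ud * (w0 @ d) - dd * (w0 @ u)) / den
        s = min(max(s, 0.0), 1.0)  # stay on the muscle segment
        pm = p1 + s * u
        t = ((pm - a) @ d) / dd
        off = pm - (a + t * d)
    return float(off @ n) < 0.0


def _via_point(p1, p2, a, d, dd):
    """Closed-form minimizer of |p1-v| + |v-p2| over v on segment a..a+d.

    Along the line, the problem reduces to the planar two-point reflection
    problem in (arc length, perpendicular distance) coordinates.
    """
    t1 = ((p1 - a) @ d) / dd
    t2 = ((p2 - a) @ d) / dd
    r1 = np.linalg.norm(p1 - (a + t1 * d))
    r2 = np.linalg.norm(p2 - (a + t2 * d))
    if r1 + r2 < 1e-15:
        t = 0.5 * (t1 + t2)
    else:
        t = (t1 * r2 + t2 * r1) / (r1 + r2)
    t = min(max(t, 0.0), 1.0)
    v = a + t * d
    return np.linalg.norm(p1 - v) + np.linalg.norm(v - p2), v


# ---------------------------------------------------------------------------
# Vectorized muscle-length evaluation (hot path: finite-difference Jacobians)
# ---------------------------------------------------------------------------


def _rot_batch(q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Shoulder rotation matrices (B,3,3) and elbow rotations (B,3,3)."""
    al, be, ga, de = q[:, 0], q[:, 1], q[:, 2], q[:, 3]
    ca, sa = np.cos(al), np.sin(al)
    cb, sb = np.cos(be), np.sin(be)
    cg, sg = np.cos(ga), np.sin(ga)
    rs = np.empty((q.shape[0], 3, 3))
    rs[:, 0, 0] = ca * cg - sa * cb * sg
    rs[:, 0, 1] = -ca * sg - sa * cb * cg
    rs[:, 0, 2] = sa * sb
    rs[:, 1, 0] = sa * cg + ca * cb * sg
    rs[:, 1, 1] = -sa * sg + ca * cb * cg
    rs[:, 1, 2] = -ca * sb
    rs[:, 2, 0] = sb * sg
    rs[:, 2, 1] = sb * cg
    rs[:, 2, 2] = cb
    cd, sd = np.cos(de), np.sin(de)
    re = np.zeros((q.shape[0], 3, 3))
    re[:, 0, 0] = 1.0
    re[:, 1, 1] = cd
    re[:, 1, 2] = -sd
    re[:, 2, 1] = sd
    re[:, 2, 2] = cd
    return rs, re


def muscle_lengths(q: np.ndarray, geometry: ArmGeometry) -> np.ndarray:
    """Muscle path lengths at joint coordinates ``q = (alpha,beta,gamma,delta)``.

    Accepts a single pose ``(4,)`` or a batch ``(B, 4)``; returns ``(11,)``
    or ``(B, 11)``.  Wrapping via points are resolved with the closed-form
    segment minimization used by :func:`muscle_path_length`.
    """
    q = np.asarray(q, dtype=float)
    single = q.ndim == 1
    qb = q[None, :] if single else q
    g = geometry
    if _fast.HAVE_NUMBA:
        out = _fast.lengths_kernel(
            np.ascontiguousarray(qb),
            g._pt_table,
            g._pt_frames,
            len(g.muscles),
            g._bl_idx.astype(np.int64),
            g._n_table,
            g._bl_f[g._bl_idx].astype(np.int64),
            g.l_arm,
        )
        return out[0] if single else out
    rs, re = _rot_batch(qb)
    b = qb.shape[0]
    # transform the whole point table at once
    world = np.broadcast_to(g._pt_table, (b, g._n_pts, 3)).copy()
    if g._pt_up.any():
        world[:, g._pt_up] = np.einsum("bij,nj->bni", rs, g._pt_table[g._pt_up])
    if g._pt_fo.any():
        local = np.einsum("bij,nj->bni", re, g._pt_table[g._pt_fo])
        local[..., 2] -= g.l_arm
        world[:, g._pt_fo] = np.einsum("bij,bnj->bni", rs, local)
    p1 = world[:, g._sl_orig]
    p2 = world[:, g._sl_ins]
    diff = p2 - p1
    lengths = np.sqrt(np.einsum("bni,bni->bn", diff, diff))
    if len(g._bl_idx):
        idx = g._bl_idx
        a = world[:, g._sl_bla]
        bb = world[:, g._sl_blb]
        nrm = np.broadcast_to(g._n_table, (b, len(idx), 3)).copy()
        if g._n_up.any():
            nrm[:, g._n_up] = np.einsum("bij,nj->bni", rs, g._n_table[g._n_up])
        if g._n_fo.any():
            loc = np.einsum("bij,nj->bni", re, g._n_table[g._n_fo])
            nrm[:, g._n_fo] = np.einsum("bij,bnj->bni", rs, loc)
        q1 = p1[:, idx]
        q2 = p2[:, idx]
        d = bb - a
        dd = np.sum(d * d, axis=-1)
        u = q2 - q1
        w0 = q1 - a
        uu = np.sum(u * u, axis=-1)
        ud = np.sum(u * d, axis=-1)
        w0d = np.sum(w0 * d, axis=-1)
        w0u = np.sum(w0 * u, axis=-1)
        den = uu * dd - ud * ud
        par = den < 1e-14 * uu * dd + 1e-30
        with np.errstate(divide="ignore", invalid="ignore"):
            s = np.where(par, 0.0, (ud * w0d - dd * w0u) / np.where(den == 0, 1, den))
        s = np.clip(s, 0.0, 1.0)
        pm = q1 + s[..., None] * u
        t_off = np.sum((pm - a) * d, axis=-1) / dd
        off = pm - (a + t_off[..., None] * d)
        off_par = w0 - (w0d / dd)[..., None] * d
        off = np.where(par[..., None], off_par, off)
        wraps = np.sum(off * nrm, axis=-1) < 0.0
        # closed-form via point
        t1 = np.sum((q1 - a) * d, axis=-1) / dd
        t2 = np.sum((q2 - a) * d, axis=-1) / dd
        r1 = np.linalg.norm(q1 - (a + t1[..., None] * d), axis=-1)
        r2 = np.linalg.norm(q2 - (a + t2[..., None] * d), axis=-1)
        rsum = r1 + r2
        t = np.where(rsum < 1e-15, 0.5 * (t1 + t2), (t1 * r2 + t2 * r1) / np.where(rsum == 0, 1, rsum))
        t = np.clip(t, 0.0, 1.0)
        v = a + t[..., None] * d
        lw = np.linalg.norm(q1 - v, axis=-1) + np.linalg.norm(v - q2, axis=-1)
        lengths[:, idx] = np.where(wraps, lw, lengths[:, idx])
    return lengths[0] if single else lengths


def muscle_jacobian(
    q: np.ndarray, geometry: ArmGeometry, h: float = 1e-6
) -> tuple[np.ndarray, np.ndarray]:
    """Lengths and central-difference Jacobian d l / d q.

    Returns ``(l, J)`` with ``l`` shape (11,) and ``J`` shape (11, 4).
    One batched evaluation covers the base pose and all 8 perturbations.
    """
    q = np.asarray(q, dtype=float)
    batch = np.tile(q, (9, 1))
    for k in range(4):
        batch[1 + 2 * k, k] += h
        batch[2 + 2 * k, k] -= h
    ls = muscle_lengths(batch, geometry)
    l0 = ls[0]
    jac = np.empty((ls.shape[1], 4))
    for k in range(4):
        jac[:, k] = (ls[1 + 2 * k] - ls[2 + 2 * k]) / (2.0 * h)
    return l0, jac


def target_lengths(target: np.ndarray, geometry: ArmGeometry) -> np.ndarray:
    """Equilibrium (threshold) muscle lengths for a Cartesian target.

    Maps the target through :func:`ik_angles` and evaluates all 11 muscle
    path lengths at the resulting pose.
    """
    pose = ik_angles(target, geometry)
    lam = muscle_lengths(pose.as_array(), geometry)
    if np.any(lam <= 0):
        raise ValueError("non-positive muscle length; check geometry")
    return lam
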