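"""Experiment orchestration: single reaches, 8x8 learning protocols, metrics.

A *reach* is a 4 s episode: the arm starts at rest hanging along -z, the
inverse kinematics converts the target into equilibrium muscle lengths, and
the central controller (plus, for model variants 1-4, the cerebellar
module) drives the muscles at a 1 ms control step with 0.5 ms physics
substeps.  An *experiment* runs 8 successive reaches to each of the 8
standard targets; the cerebellar store persists across reaches to the same
target, which is what produces learning, and is reset between targets.

Reach quality is the integrated error: the time integral of the hand-target
distance over the episode.  Experiment tables average it across targets per
reach index, normalize by the first reach, and attach standard errors
(S.D. / sqrt(n_targets)), mirroring the usual learning-curve summary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import config as _config
from .cerebellum import (
    CerebellarStore,
    Microcomplex,
    context_scale_vector,
    pack_context,
)
from .controller import ControllerState, DelayedSignal, controller_output, length_velocity_errors
from .kinematics import (
    ArmGeometry,
    forward_hand_position,
    ik_angles,
    muscle_jacobian,
    shoulder_quaternion,
    target_lengths,
)
from .olive import OlivePopulation, proprioceptive_spikes
from .plant import (
    ArmState,
    activation_step,
    advance_control_step,
    joint_torques,
    muscle_tensions,
)

__all__ = [
    "ReachResult",
    "ExperimentTable",
    "integrated_error",
    "run_reach",
    "run_experiment",
    "make_store",
    "write_trajectory_csv",
]

VARIANTS = ("none", "1", "2", "3", "4")


@dataclass
class ReachResult:
    """Outcome of a single reach."""

    target_id: int
    reach_index: int
    integrated_error: float        # m s
    final_distance: float          # m
    unstable: bool
    n_spikes: int
    n_stored: int
    trajectory: dict | None = None  # arrays: t, hand, q, l, u, distance


@dataclass
class ExperimentTable:
    """Integrated errors for a full targets x reaches protocol."""

    errors: np.ndarray             # (n_targets, n_reaches)
    target_ids: list
    unstable: np.ndarray           # bool (n_targets, n_reaches)
    variant: str
    seed: int

    @property
    def per_reach_mean(self) -> np.ndarray:
        return self.errors.mean(axis=0)

    @property
    def normalized_mean(self) -> np.ndarray:
        m = self.per_reach_mean
        return m / m[0]

    @property
    def per_reach_sem(self) -> np.ndarray:
        n = self.errors.shape[0]
        return self.errors.std(axis=0, ddof=1) / np.sqrt(n) / self.per_reach_mean[0]

    def to_json(self, path) -> None:
        payload = {
            "variant": self.variant,
            "seed": self.seed,
            "target_ids": list(self.target_ids),
            "errors": self.errors.tolist(),
            "unstable": self.unstable.astype(int).tolist(),
            "per_reach_mean": self.per_reach_mean.tolist(),
            "normalized_mean": self.normalized_mean.tolist(),
            "per_reach_sem": self.per_reach_sem.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def integrated_error(t: np.ndarray, distance: np.ndarray, horizon: float) -> float:
    """Trapezoidal time integral of the hand-target distance (m s)."""
    t = np.asarray(t, dtype=float)
    d = np.asarray(distance, dtype=float)
    if t[-1] < horizon - 1e-6:
        raise ValueError(
            f"trajectory covers only {t[-1]:.3f} s of the {horizon:.3f} s horizon"
        )
    sel = t <= horizon + 1e-9
    return float(np.trapezoid(d[sel], t[sel]))


def make_store(variant: str, cfg: dict) -> CerebellarStore | None:
    """Cerebellar store configured for a model variant (None for baseline)."""
    if variant == "none":
        return None
    cb = cfg["cerebellum"]
    model = cb["models"][str(variant)]
    scales = context_scale_vector(
        cb.get("context_scales"),
        mask_error=not cb.get("include_error_in_distance", True),
    )
    return CerebellarStore(
        m_f=cb["m_f"],
        gamma_k=model["gamma_k"],
        fusion_threshold=cb["fusion_threshold"],
        fusion_midpoint=cb.get("fusion_midpoint", 0.5),
        scales=scales,
    )


def _make_microcomplex(variant: str, store: CerebellarStore, cfg: dict,
                       record_only: bool = False) -> Microcomplex:
    cb = cfg["cerebellum"]
    model = cb["models"][str(variant)]
    method = {"1": "efference", "2": "muscle", "3": "muscle", "4": "muscle_product"}[
        str(variant)
    ]
    return Microcomplex(
        store=store,
        method=method,
        tau_v=cfg["controller"]["visual_delay"],
        tau_p=cfg["controller"]["proprioceptive_delay"],
        gain=model.get("gain", 1.0),
        amplitude=model.get("amplitude", 0.05),
        window=model.get("window", 0.05),
        w_cap=model.get("w_cap", float("inf")),
        episode_max=cb["episode_max"],
        history_horizon=cb["history_horizon"],
        record_only=record_only,
    )


def run_reach(
    variant: str,
    target: np.ndarray,
    seed_or_rng,
    cfg: dict | None = None,
    geometry: ArmGeometry | None = None,
    store: CerebellarStore | None = None,
    target_id: int = 0,
    reach_index: int = 0,
    keep_trajectory: bool = False,
    record_only: bool = False,
) -> ReachResult:
    """Simulate one reach; mutates ``store`` in place when learning is on.

    ``seed_or_rng`` may be an integer seed or an existing Generator (the
    experiment protocol shares one stream across reaches).
    """
    if str(variant) not in VARIANTS:
        raise ValueError(f"unknown model variant {variant!r}")
    variant = str(variant)
    cfg = cfg if cfg is not None else _config.default_config()
    geometry = geometry if geometry is not None else _config.build_geometry(cfg)
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    target = np.asarray(target, dtype=float)

    sim = cfg["sim"]
    ctl = cfg["controller"]
    dt_c = sim["dt_control"]
    dt_p = sim["dt_physics"]
    horizon = sim["horizon"]
    n_sub = max(int(round(dt_c / dt_p)), 1)
    n_steps = int(round(horizon / dt_c))

    lam = target_lengths(target, geometry)
    pose_des = ik_angles(target, geometry)
    q_des = pose_des.q_s
    th_des = pose_des.theta_e

    state = ArmState(
        q=np.array([0.0, sim.get("beta_init", 0.02), 0.0, 0.0]),
        qd=np.zeros(4),
    )
    cstate = ControllerState(
        lam=lam,
        g_l=ctl["g_l"],
        g_v=ctl["g_v"],
        tau_filter=ctl["tau_filter"],
        k_integral=ctl["k_integral"],
        relu_order=ctl.get("relu_order", "pre"),
    )

    tau_p_delay = ctl["proprioceptive_delay"]
    tau_v_delay = ctl["visual_delay"]

    l0, jac = muscle_jacobian(state.q, geometry)
    from .kinematics import ArmPose

    hand = forward_hand_position(ArmPose(*state.q), geometry)
    e0 = float(np.linalg.norm(hand - target))
    qs0 = shoulder_quaternion(*state.q[:3])

    prop_delay = DelayedSignal(
        tau_p_delay,
        np.concatenate([l0, np.zeros(11), qs0, np.zeros(4), [state.q[3], 0.0]]),
    )
    vis_delay = DelayedSignal(tau_v_delay, np.array([e0, 0.0]))

    # cerebellar machinery
    micro = None
    olive_pop = None
    prop_last_spike = np.full(11, -np.inf)
    if variant != "none":
        if store is None:
            store = make_store(variant, cfg)
        micro = _make_microcomplex(variant, store, cfg, record_only=record_only)
        if variant in ("1", "4"):
            ol = cfg["olive"]
            olive_pop = OlivePopulation(
                n3=ol["n3"], n7=ol["n7"], p=ol["p"],
                refractory=ol["refractory"], parse=ol["parse"],
            )
    err_scale = cfg["olive"]["error_scale"]
    require_visual = (
        cfg["cerebellum"]["models"].get(variant, {}).get("require_visual", False)
        if variant != "none"
        else False
    )

    plant_cfg = cfg["plant"]
    gravity = plant_cfg.get("gravity", False)
    qd_bound = plant_cfg.get("qd_bound", 20.0)
    tau_act = np.array([m.tau_act for m in geometry.muscles])

    e_prev = e0
    qs_prev = qs0
    n_spikes = 0
    ts = np.empty(n_steps + 1)
    dist = np.empty(n_steps + 1)
    ts[0] = 0.0
    dist[0] = e0
    traj = None
    if keep_trajectory:
        traj = {
            "t": [0.0],
            "hand": [hand.copy()],
            "q": [state.q.copy()],
            "l": [l0.copy()],
            "u": [np.zeros(11)],
        }
    unstable = False
    late_speed_max = 0.0  # hand speed during the final second: settling check
    settle_speed = plant_cfg.get("settle_speed", 0.1)

    for k in range(n_steps):
        t = k * dt_c
        l, jac = muscle_jacobian(state.q, geometry)
        v = jac @ state.qd
        pose_arr = state.q
        hand = forward_hand_position(ArmPose(*pose_arr), geometry)
        e = float(np.linalg.norm(hand - target))
        edot = (e - e_prev) / dt_c
        e_prev = e
        qs = shoulder_quaternion(*pose_arr[:3])
        if qs @ qs_prev < 0:  # keep the quaternion on a continuous sheet
            qs = -qs
        qs_rate = (qs - qs_prev) / dt_c
        qs_prev = qs

        prop_delay.write(
            t, np.concatenate([l, v, qs, qs_rate, [pose_arr[3], state.qd[3]]])
        )
        vis_delay.write(t, np.array([e, edot]))

        prop = prop_delay.read(t)
        l_d, v_d = prop[0:11], prop[11:22]
        qs_d, qsd_d = prop[22:26], prop[26:30]
        th_d, thd_d = prop[30], prop[31]
        vis = vis_delay.read(t)
        e_d, ed_d = float(vis[0]), float(vis[1])

        e_l, e_v = length_velocity_errors(l_d, v_d, lam, cstate.g_l, cstate.g_v)
        u_central = controller_output(e_v, cstate, dt_c)

        c_cb = np.zeros(11)
        if micro is not None:
            efference = np.maximum(e_v, 0.0)
            context = pack_context(
                e_d, ed_d, qs_d, qsd_d, th_d, thd_d, efference, q_des, th_des
            )
            micro.observe(t, context, efference, l=l_d, v=v_d)
            if variant in ("1", "4"):
                spikes = olive_pop.step(e_d * err_scale, ed_d * err_scale, t, rng)
            else:
                spikes = proprioceptive_spikes(
                    l_d, v_d, lam, prop_last_spike, t,
                    require_visual=require_visual, edot=ed_d,
                    refractory=cfg["olive"]["refractory"],
                )
            n_spikes += len(spikes)
            micro.add_spikes(spikes)
            if micro.pending:
                micro.handle_pending(
                    t, ed_d, lam=lam, episode_over=(v_d <= 0.0)
                )
            c_cb = micro.output(context)

        u_total = np.maximum(u_central + c_cb, 0.0)
        state.activation = state.activation + (
            1.0 - np.exp(-dt_c / tau_act)
        ) * (u_total - state.activation)
        tensions = muscle_tensions(state, u_total, l, v, geometry, plant_cfg)
        torques = joint_torques(tensions, jac)
        state = advance_control_step(
            state, torques, dt_p, n_sub, geometry,
            gravity=gravity, g=plant_cfg.get("g", 9.81), qd_bound=qd_bound,
        )
        unstable = unstable or state.unstable

        hand_prev = hand
        hand = forward_hand_position(ArmPose(*state.q), geometry)
        d = float(np.linalg.norm(hand - target))
        ts[k + 1] = (k + 1) * dt_c
        dist[k + 1] = d
        if ts[k + 1] > horizon - 1.0:
            speed = float(np.linalg.norm(hand - hand_prev)) / dt_c
            late_speed_max = max(late_speed_max, speed)
        if keep_trajectory:
            traj["t"].append(ts[k + 1])
            traj["hand"].append(hand.copy())
            traj["q"].append(state.q.copy())
            traj["l"].append(l.copy())
            traj["u"].append(u_total.copy())

    # a reach is unstable if joint rates ever exceeded the divergence bound,
    # or if the hand was still moving fast during the final second
    # ("chaotic flailing" / sustained non-settling oscillation)
    unstable = unstable or (late_speed_max > settle_speed)
    ie = integrated_error(ts, dist, horizon)
    if keep_trajectory:
        traj = {k2: np.asarray(v2) for k2, v2 in traj.items()}
        traj["distance"] = dist
    return ReachResult(
        target_id=target_id,
        reach_index=reach_index,
        integrated_error=ie,
        final_distance=float(dist[-1]),
        unstable=unstable,
        n_spikes=n_spikes,
        n_stored=0 if micro is None else micro.n_stored,
        trajectory=traj,
    )


def run_experiment(
    variant: str,
    cfg: dict | None = None,
    seed: int = 0,
    targets: np.ndarray | None = None,
    n_reaches: int | None = None,
    geometry: ArmGeometry | None = None,
    progress=None,
) -> ExperimentTable:
    """The full learning protocol: successive reaches to each target.

    One seeded random stream is shared by all stochastic draws; the
    cerebellar store is carried across reaches to the same target and
    reset between targets.
    """
    cfg = cfg if cfg is not None else _config.default_config()
    geometry = geometry if geometry is not None else _config.build_geometry(cfg)
    targets = targets if targets is not None else _config.standard_targets()
    n_reaches = n_reaches if n_reaches is not None else cfg["sim"].get("reaches", 8)
    rng = np.random.default_rng(seed)
    errors = np.zeros((len(targets), n_reaches))
    unstable = np.zeros((len(targets), n_reaches), dtype=bool)
    for ti, target in enumerate(targets):
        store = make_store(str(variant), cfg)
        for ri in range(n_reaches):
            res = run_reach(
                variant, target, rng, cfg=cfg, geometry=geometry, store=store,
                target_id=ti + 1, reach_index=ri + 1,
            )
            errors[ti, ri] = res.integrated_error
            unstable[ti, ri] = res.unstable
            if progress is not None:
                progress(ti, ri, res)
    return ExperimentTable(
        errors=errors,
        target_ids=list(range(1, len(targets) + 1)),
        unstable=unstable,
        variant=str(variant),
        seed=seed,
    )


def write_trajectory_csv(result: ReachResult, path) -> None:
    """Per-reach trajectory file: t, hand xyz, joint angles, lengths, inputs."""
    traj = result.trajectory
    if traj is None:
        raise ValueError("reach was run without keep_trajectory=True")
    cols = (
        ["t", "hand_x", "hand_y", "hand_z", "alpha", "beta", "gamma", "delta"]
        + [f"l_{i}" for i in range(11)]
        + [f"u_{i}" for i in range(11)]
    )
    mat = np.column_stack([traj["t"], traj["hand"], traj["q"], traj["l"], traj["u"]])
    header = ",".join(cols)
    np.savetxt(path, mat, delimiter=",", header=header, comments="")
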