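"""Equilibrium-point central controller: error cascade, filtering, delays.

The controller receives (delayed) muscle lengths ``l`` and contraction
velocities ``v`` together with the target lengths ``lambda`` produced by the
inverse kinematics, and computes per-muscle errors

    e_l = g_l (l - lambda),      e_v = g_v (v + e_l).

The muscle stimulation is the positive part of the velocity error, passed
through a first-order low-pass filter, plus a small integral of the
controller's own output (which prevents the arm from resting in equilibria
away from the target).  All afferent signals reach the controller through a
proprioceptive delay line; visual error signals elsewhere in the
architecture use a longer visual delay.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ControllerState",
    "DelayedSignal",
    "length_velocity_errors",
    "controller_output",
]


def length_velocity_errors(l, v, lam, g_l: float = 2.0, g_v: float = 1.0):
    """Length and velocity errors of the serial cascade (stateless, exact)."""
    if g_l <= 0 or g_v <= 0:
        raise ValueError("gains must be positive")
    l = np.asarray(l, dtype=float)
    v = np.asarray(v, dtype=float)
    lam = np.asarray(lam, dtype=float)
    e_l = g_l * (l - lam)
    e_v = g_v * (v + e_l)
    return e_l, e_v


@dataclass
class ControllerState:
    """Mutable state of the central controller for one reach."""

    lam: np.ndarray                    # (11,) target lengths
    g_l: float = 2.0
    g_v: float = 1.0
    tau_filter: float = 0.05
    k_integral: float = 0.05
    relu_order: str = "pre"            # "pre": clip e_v before the filter
    filt: np.ndarray = None
    integ: np.ndarray = None
    last_u: np.ndarray = None

    def __post_init__(self) -> None:
        self.lam = np.asarray(self.lam, dtype=float)
        n = self.lam.shape[0]
        if self.filt is None:
            self.filt = np.zeros(n)
        if self.integ is None:
            self.integ = np.zeros(n)
        if self.last_u is None:
            self.last_u = np.zeros(n)


def controller_output(e_v: np.ndarray, state: ControllerState, dt: float) -> np.ndarray:
    """One control step: filter the clipped velocity error, add the integral.

    Returns the nonnegative stimulation vector and updates the filter and
    integral accumulators in ``state``.  The integral accumulates the
    controller's own (clipped) output.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    e_v = np.asarray(e_v, dtype=float)
    drive = np.maximum(e_v, 0.0) if state.relu_order == "pre" else e_v
    decay = 1.0 - np.exp(-dt / state.tau_filter)
    state.filt = state.filt + decay * (drive - state.filt)
    filtered = state.filt if state.relu_order == "pre" else np.maximum(state.filt, 0.0)
    state.integ = state.integ + state.last_u * dt
    u = np.maximum(filtered + state.k_integral * state.integ, 0.0)
    state.last_u = u
    return u


class DelayedSignal:
    """Pure transport delay on a sampled signal.

    ``write(t, x)`` records a sample; ``read(t)`` returns the latest sample
    recorded at or before ``t - delay``.  Before any sample is that old the
    initial sample is returned.  With zero delay the signal passes through.
    """

    def __init__(self, delay: float, initial, horizon_margin: float = 0.05):
        if delay < 0:
            raise ValueError("delay must be nonnegative")
        self.delay = float(delay)
        self._margin = horizon_margin
        x0 = np.array(initial, dtype=float) if np.ndim(initial) else float(initial)
        self._buf: deque = deque([(-np.inf, x0)])

    def write(self, t: float, value) -> None:
        x = np.array(value, dtype=float) if np.ndim(value) else float(value)
        self._buf.append((t, x))

    def read(self, t: float):
        """Sample at ``t - delay``; reads must be non-decreasing in ``t``.

        Samples older than the read point are discarded as they are passed,
        so writing faster than reading never loses the sample at
        ``t - delay`` and the result does not depend on call frequency.
        """
        target = t - self.delay + 1e-12
        buf = self._buf
        while len(buf) > 1 and buf[1][0] <= target:
            buf.popleft()
        return buf[0][1]
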