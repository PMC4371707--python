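"""Cerebellar microcomplex: context capture, correction storage and recall.

The microcomplex associates sensorimotor *contexts* in which an error
measure started to increase with corrective muscle commands that stopped
the increase.  A context is a 28-component vector: visual error and its
derivative (150 ms delayed), shoulder quaternion and its rate, elbow angle
and rate (25 ms delayed), the 11 efferent velocity-error commands, and the
desired pose (shoulder quaternion + elbow angle).

When a complex spike arrives, the spike is held until the error derivative
returns to zero or below.  If that happens within 250 ms, a new
"error-prone area" is stored: its feature vector is the context as it was

    tau_v - tau_p + (t - t_cs) / 2

before the spike (compensating the visual delay ``tau_v`` relative to the
proprioceptive delay ``tau_p`` plus half the episode), and its correction
vector comes from the active correction method (averaged efferent commands,
a single-muscle contraction, or the length-excess x elongation-rate
product).  Spikes whose episode exceeds 250 ms are discarded.

Recall is a normalized radial-basis readout: for stored features ``f(i)``
with corrections ``w(i)`` and current context ``v``,

    D(i)   = ||f(i) - v||^2        (component-scaled)
    D_N    = (M_F / ||D||) * D
    output = sum_i w(i) * exp(gamma * D_N(i)),   gamma < 0.

When the store is full, or a new feature lands too close to an existing
one, the new entry fuses with its nearest neighbour: both are replaced by a
child whose feature and correction are points on the segments joining the
parents'.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import json
import numpy as np

__all__ = [
    "CONTEXT_DIM",
    "ContextVector",
    "FeatureEntry",
    "HistoryBuffer",
    "CerebellarStore",
    "Microcomplex",
    "context_lookback_time",
    "correction_from_efference",
    "correction_from_muscle",
    "correction_model4",
]

CONTEXT_DIM = 28

# component layout of the context vector
_SLICES = {
    "error": slice(0, 1),
    "error_rate": slice(1, 2),
    "q_s": slice(2, 6),
    "q_s_rate": slice(6, 10),
    "theta_e": slice(10, 11),
    "theta_e_rate": slice(11, 12),
    "command": slice(12, 23),
    "q_des": slice(23, 27),
    "theta_des": slice(27, 28),
}


def pack_context(
    e: float,
    edot: float,
    q_s: np.ndarray,
    q_s_rate: np.ndarray,
    theta_e: float,
    theta_e_rate: float,
    command: np.ndarray,
    q_des: np.ndarray,
    theta_des: float,
) -> np.ndarray:
    """Assemble the 28-component context vector in its fixed order."""
    out = np.empty(CONTEXT_DIM)
    out[0] = e
    out[1] = edot
    out[2:6] = q_s
    out[6:10] = q_s_rate
    out[10] = theta_e
    out[11] = theta_e_rate
    out[12:23] = command
    out[23:27] = q_des
    out[27] = theta_des
    return out


def context_scale_vector(scales: dict | None = None, mask_error: bool = False) -> np.ndarray:
    """Per-component scaling applied before distance computation.

    ``scales`` maps component classes (error, error_rate, quaternion,
    rates, angle, command) to multipliers; heterogeneous units would
    otherwise dominate the context metric.  ``mask_error`` zeroes the
    error components so they do not participate in recall distances.
    """
    s = {
        "error": 10.0, "error_rate": 1.0, "quaternion": 1.0,
        "rates": 1.0, "angle": 1.0, "command": 5.0,
    }
    if scales:
        s.update(scales)
    out = np.empty(CONTEXT_DIM)
    out[_SLICES["error"]] = 0.0 if mask_error else s["error"]
    out[_SLICES["error_rate"]] = 0.0 if mask_error else s["error_rate"]
    out[_SLICES["q_s"]] = s["quaternion"]
    out[_SLICES["q_s_rate"]] = s["rates"]
    out[_SLICES["theta_e"]] = s["angle"]
    out[_SLICES["theta_e_rate"]] = s["rates"]
    out[_SLICES["command"]] = s["command"]
    out[_SLICES["q_des"]] = s["quaternion"]
    out[_SLICES["theta_des"]] = s["angle"]
    return out


ContextVector = np.ndarray  # a (28,) float array with the layout above


@dataclass
class FeatureEntry:
    """One stored error-prone area: feature vector, correction, metadata."""

    f: np.ndarray              # (28,) context at the compensated lookback time
    w: np.ndarray              # (11,) corrective muscle command
    t_cs: float = np.nan       # spike time (audit metadata)
    t_feature: float = np.nan  # time the stored context was sampled at

    def __post_init__(self) -> None:
        self.f = np.asarray(self.f, dtype=float)
        self.w = np.asarray(self.w, dtype=float)


def context_lookback_time(t_cs: float, t: float, tau_v: float, tau_p: float) -> float:
    """How long before the spike the stored context is sampled.

    Compensates the visual delay relative to the proprioceptive one, plus
    half the time from the spike to the end of the error-increase episode.
    """
    if t < t_cs:
        raise ValueError("episode end precedes the spike")
    return tau_v - tau_p + 0.5 * (t - t_cs)


class HistoryBuffer:
    """Rolling record of timestamped samples (contexts, efference, lengths).

    ``lookup(t)`` returns the recorded sample nearest to ``t``; ``window``
    returns all samples in a closed interval.  The horizon must cover the
    deepest lookback the learning rules use.
    """

    def __init__(self, horizon: float = 0.6):
        self.horizon = float(horizon)
        self._t: list[float] = []
        self._data: list[dict] = []

    def record(self, t: float, **signals) -> None:
        self._t.append(t)
        self._data.append(signals)
        cutoff = t - self.horizon
        while len(self._t) > 1 and self._t[0] < cutoff:
            self._t.pop(0)
            self._data.pop(0)

    def lookup(self, t: float) -> dict:
        if not self._t:
            raise RuntimeError("empty history buffer")
        if t < self._t[0] - 1e-9 and self._t[-1] - t > self.horizon:
            raise RuntimeError("history horizon exceeded")
        idx = int(np.argmin(np.abs(np.asarray(self._t) - t)))
        return self._data[idx]

    def window(self, t0: float, t1: float) -> list[dict]:
        """Samples with t0 <= t <= t1; falls back to the nearest sample."""
        ts = np.asarray(self._t)
        sel = np.nonzero((ts >= t0 - 1e-9) & (ts <= t1 + 1e-9))[0]
        if sel.size == 0:
            return [self.lookup(t0)]
        return [self._data[i] for i in sel]


def correction_from_efference(
    history: HistoryBuffer,
    t_cs: float,
    t: float,
    tau_v: float,
    tau_p: float,
    gain: float = 1.0,
) -> np.ndarray:
    """Model-1 correction: gain x time-average of the efferent commands.

    The window is the error-increase episode shifted back by the visual-
    proprioceptive delay difference: [t_cs - (tau_v - tau_p), t - (tau_v - tau_p)].
    """
    shift = tau_v - tau_p
    samples = history.window(t_cs - shift, t - shift)
    eff = np.stack([s["efference"] for s in samples])
    return gain * eff.mean(axis=0)


def correction_from_muscle(index: int, amplitude: float, n: int = 11) -> np.ndarray:
    """Model-2/3 correction: a slight contraction of the spiking muscle."""
    if not 0 <= index < n:
        raise ValueError("muscle index out of range")
    w = np.zeros(n)
    w[index] = amplitude
    return w


def correction_model4(
    l_avg: np.ndarray,
    lam: np.ndarray,
    ldot: np.ndarray,
    gain: float = 1.0,
    w_cap: float = np.inf,
) -> np.ndarray:
    """Model-4 correction: gain * [<l> - lambda]+ * [ldot]+ per muscle.

    ``w_cap`` saturates each component: the length-excess x elongation-rate
    product spans orders of magnitude across reaches, and motor commands
    saturate physiologically; the cap keeps single stored corrections from
    dwarfing the central controller's own output.
    """
    l_avg = np.asarray(l_avg, dtype=float)
    lam = np.asarray(lam, dtype=float)
    ldot = np.asarray(ldot, dtype=float)
    w = gain * np.maximum(l_avg - lam, 0.0) * np.maximum(ldot, 0.0)
    return np.minimum(w, w_cap)


class CerebellarStore:
    """Bounded store of error-prone areas with RBF recall and fusion."""

    def __init__(
        self,
        m_f: int = 32,
        gamma_k: float = -1.0,
        fusion_threshold: float = 0.5,
        fusion_midpoint: float = 0.5,
        scales: np.ndarray | None = None,
    ):
        if gamma_k >= 0:
            raise ValueError("gamma_k must be negative (decaying kernel)")
        if m_f < 1:
            raise ValueError("m_f must be at least 1")
        if not 0.0 <= fusion_midpoint <= 1.0:
            raise ValueError("fusion midpoint must lie in [0, 1]")
        self.m_f = int(m_f)
        self.gamma_k = float(gamma_k)
        self.fusion_threshold = float(fusion_threshold)
        self.fusion_midpoint = float(fusion_midpoint)
        self.scales = (
            np.ones(CONTEXT_DIM) if scales is None else np.asarray(scales, dtype=float)
        )
        self.entries: list[FeatureEntry] = []
        self._f_mat: np.ndarray | None = None  # cached scaled feature matrix
        self._w_mat: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.entries)

    def _refresh_cache(self) -> None:
        if self.entries:
            self._f_mat = np.stack([e.f for e in self.entries]) * self.scales
            self._w_mat = np.stack([e.w for e in self.entries])
        else:
            self._f_mat = self._w_mat = None

    def add(self, entry: FeatureEntry) -> None:
        """Insert an entry, fusing with the nearest neighbour when needed."""
        if self.entries:
            fs = self._f_mat
            d = np.linalg.norm(fs - entry.f * self.scales, axis=1)
            j = int(np.argmin(d))
            if d[j] < self.fusion_threshold or len(self.entries) >= self.m_f:
                a = self.fusion_midpoint
                parent = self.entries[j]
                child = FeatureEntry(
                    f=(1.0 - a) * parent.f + a * entry.f,
                    w=(1.0 - a) * parent.w + a * entry.w,
                    t_cs=entry.t_cs,
                    t_feature=entry.t_feature,
                )
                self.entries[j] = child
                self._refresh_cache()
                return
        self.entries.append(entry)
        self._refresh_cache()

    def recall(self, v: ContextVector) -> np.ndarray:
        """RBF readout of the stored corrections at context ``v``."""
        if not self.entries:
            return np.zeros(11)
        diff = self._f_mat - np.asarray(v, dtype=float) * self.scales
        d = np.einsum("ij,ij->i", diff, diff)  # squared scaled distances
        norm = np.linalg.norm(d)
        if norm == 0.0:
            d_n = np.zeros_like(d)
        else:
            d_n = (self.m_f / norm) * d
        weights = np.exp(self.gamma_k * d_n)
        return weights @ self._w_mat

    # -- serialization ----------------------------------------------------
    def to_json(self, path) -> None:
        payload = {
            "m_f": self.m_f,
            "gamma_k": self.gamma_k,
            "fusion_threshold": self.fusion_threshold,
            "fusion_midpoint": self.fusion_midpoint,
            "scales": self.scales.tolist(),
            "entries": [
                {
                    "f": e.f.tolist(),
                    "w": e.w.tolist(),
                    "t_cs": None if np.isnan(e.t_cs) else e.t_cs,
                    "t_feature": None if np.isnan(e.t_feature) else e.t_feature,
                }
                for e in self.entries
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "CerebellarStore":
        with open(path) as fh:
            payload = json.load(fh)
        store = cls(
            m_f=payload["m_f"],
            gamma_k=payload["gamma_k"],
            fusion_threshold=payload["fusion_threshold"],
            fusion_midpoint=payload["fusion_midpoint"],
            scales=np.array(payload["scales"]),
        )
        for e in payload["entries"]:
            store.add(
                FeatureEntry(
                    f=np.array(e["f"]),
                    w=np.array(e["w"]),
                    t_cs=np.nan if e["t_cs"] is None else e["t_cs"],
                    t_feature=np.nan if e["t_feature"] is None else e["t_feature"],
                )
            )
        return store


@dataclass
class _PendingSpike:
    t_cs: float
    source: int | str


class Microcomplex:
    """One cerebellar module: spike handling, storage and recall.

    ``method`` selects how corrections are generated: ``"efference"``
    (model 1), ``"muscle"`` (models 2/3) or ``"muscle_product"`` (model 4).
    ``record_only`` disconnects the output (recall returns zero) while
    leaving learning untouched, for causality audits.
    """

    def __init__(
        self,
        store: CerebellarStore,
        method: str = "efference",
        tau_v: float = 0.150,
        tau_p: float = 0.025,
        gain: float = 1.0,
        amplitude: float = 0.05,
        window: float = 0.05,
        w_cap: float = np.inf,
        episode_max: float = 0.25,
        history_horizon: float = 0.6,
        record_only: bool = False,
    ):
        if method not in ("efference", "muscle", "muscle_product"):
            raise ValueError(f"unknown correction method {method!r}")
        self.store = store
        self.method = method
        self.tau_v = tau_v
        self.tau_p = tau_p
        self.gain = gain
        self.amplitude = amplitude
        self.window = window
        self.w_cap = w_cap
        self.episode_max = episode_max
        self.history = HistoryBuffer(horizon=history_horizon)
        self.record_only = record_only
        self.pending: list[_PendingSpike] = []
        self.n_stored = 0
        self.n_discarded = 0

    def observe(self, t: float, context: ContextVector, efference: np.ndarray,
                l: np.ndarray | None = None, v: np.ndarray | None = None) -> None:
        """Record the current signals into the rolling history."""
        self.history.record(
            t, context=np.asarray(context, dtype=float).copy(),
            efference=np.asarray(efference, dtype=float).copy(),
            l=None if l is None else np.asarray(l, dtype=float).copy(),
            v=None if v is None else np.asarray(v, dtype=float).copy(),
        )

    def add_spikes(self, spikes) -> None:
        for s in spikes:
            self.pending.append(_PendingSpike(t_cs=s.time, source=s.source))

    def handle_pending(self, t: float, edot: float,
                       lam: np.ndarray | None = None,
                       episode_over: np.ndarray | None = None) -> int:
        """Store or discard pending spikes given the current error derivative.

        ``edot`` is the (delayed) visual error derivative for visual-pathway
        spikes.  For muscle-pathway spikes ``episode_over`` gives, per
        muscle, whether that muscle's elongation episode has ended
        (``ldot <= 0``); when omitted, ``edot`` is used for all spikes.
        Returns the number of entries stored.
        """
        stored = 0
        keep = []
        for sp in self.pending:
            age = t - sp.t_cs
            if isinstance(sp.source, int) and episode_over is not None:
                over = bool(episode_over[sp.source])
            else:
                over = edot <= 0.0
            if over and age <= self.episode_max:
                self._store(sp, t, lam)
                stored += 1
            elif age > self.episode_max:
                self.n_discarded += 1
            else:
                keep.append(sp)
        self.pending = keep
        self.n_stored += stored
        return stored

    def _store(self, sp: _PendingSpike, t: float, lam: np.ndarray | None) -> None:
        lookback = context_lookback_time(sp.t_cs, t, self.tau_v, self.tau_p)
        sample_t = sp.t_cs - lookback
        f = self.history.lookup(sample_t)["context"]
        if self.method == "efference":
            w = correction_from_efference(
                self.history, sp.t_cs, t, self.tau_v, self.tau_p, gain=self.gain
            )
        elif self.method == "muscle":
            w = correction_from_muscle(int(sp.source), self.amplitude)
        else:  # muscle_product
            if lam is None:
                raise ValueError("muscle_product correction requires target lengths")
            # same delay compensation as the efference average: the episode is
            # detected on visually-delayed error, the lengths arrive with the
            # (shorter) proprioceptive delay
            shift = self.tau_v - self.tau_p
            samples = self.history.window(t - shift - self.window, t - shift)
            l_avg = np.stack([s["l"] for s in samples]).mean(axis=0)
            ldot = np.stack([s["v"] for s in samples]).mean(axis=0)
            w = correction_model4(l_avg, lam, ldot, gain=self.gain, w_cap=self.w_cap)
        self.store.add(FeatureEntry(f=f.copy(), w=w, t_cs=sp.t_cs, t_feature=sample_t))

    def output(self, context: ContextVector) -> np.ndarray:
        if self.record_only:
            return np.zeros(11)
        return self.store.recall(context)
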