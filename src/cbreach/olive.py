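"""Inferior-olive module: complex-spike generation.

Two pathways produce "complex spikes" (signals that a correction should be
stored):

* the **visual** pathway, a population of olivary cells with subthreshold
  oscillations at 3 Hz and 7 Hz whose spike probability is gated by the
  magnitude of the visual error and by the positive part of its derivative;
* the **proprioceptive** pathway (muscle-level), which fires for a muscle
  that is longer than its target length and still elongating.

The visual spike probability for cell ``i`` at time ``t`` is

    P_i(t) = (p cos[w_i (t - phi_i)] + 1)
             / ((1 + exp(5 - E)) (1 + exp(30 - 15 [E']+)))

clipped to [0, 1].  The gating constants 5 and 30 are dimensionless as
printed; the error enters the gates scaled to centimeters so that the
magnitude gate opens a few centimeters from the target and the derivative
gate at a few cm/s (see the configuration key ``olive.error_scale``).
Probabilities are per evaluation step; the spike step is fixed at 1 ms.
Every pathway enforces a 200 ms per-cell (or per-muscle) refractory period.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "OlivaryCell",
    "SpikeEvent",
    "OlivePopulation",
    "visual_spike_probability",
    "generate_visual_spikes",
    "proprioceptive_spikes",
]


@dataclass
class OlivaryCell:
    """One olivary cell: oscillation frequency, phase and last spike time."""

    freq_hz: float
    phase: float              # s, temporal offset of the oscillation
    last_spike: float = -np.inf

    @property
    def omega(self) -> float:
        return 2.0 * np.pi * self.freq_hz


@dataclass
class SpikeEvent:
    """A complex spike: time and source (visual pathway or a muscle index)."""

    time: float
    source: int | str = "visual"   # "visual" or muscle index 0..10
    cell: int | None = None


def visual_spike_probability(
    e: float,
    edot_pos: float,
    cell: OlivaryCell,
    t: float,
    p: float = 0.1,
    parse: str = "product",
) -> float:
    """Probability of a complex spike for one cell at time ``t``.

    ``e`` and ``edot_pos`` are the visual error and the positive part of its
    derivative in gating units (centimeters / cm s^-1 under the default
    configuration).  ``parse`` selects how the oscillation term combines
    with the two sigmoidal gates: ``"product"`` (default) divides the whole
    oscillation term by both gates; ``"additive"`` adds the bare oscillation
    to the gated constant term.
    """
    if edot_pos < 0:
        raise ValueError("edot_pos must be the positive part of the derivative")
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    osc = p * np.cos(cell.omega * (t - cell.phase))
    gate = (1.0 + np.exp(5.0 - e)) * (1.0 + np.exp(30.0 - 15.0 * edot_pos))
    if parse == "product":
        prob = (osc + 1.0) / gate
    elif parse == "additive":
        prob = osc + 1.0 / gate
    else:
        raise ValueError(f"unknown parse variant {parse!r}")
    return float(np.clip(prob, 0.0, 1.0))


def generate_visual_spikes(
    e: float,
    edot: float,
    cells: list[OlivaryCell],
    t: float,
    rng: np.random.Generator,
    p: float = 0.1,
    refractory: float = 0.2,
    parse: str = "product",
) -> list[SpikeEvent]:
    """One Bernoulli draw per cell; spikes respect the refractory period.

    The refractory clock of each spiking cell is updated in place.  The
    random draw is made for every cell regardless of refractory state so
    that the stream consumption (and hence determinism for a fixed seed)
    does not depend on recent spike history.
    """
    edot_pos = max(edot, 0.0)
    draws = rng.random(len(cells))
    out = []
    for i, cell in enumerate(cells):
        prob = visual_spike_probability(e, edot_pos, cell, t, p=p, parse=parse)
        if draws[i] < prob and t - cell.last_spike >= refractory:
            cell.last_spike = t
            out.append(SpikeEvent(time=t, source="visual", cell=i))
    return out


def proprioceptive_spikes(
    l: np.ndarray,
    ldot: np.ndarray,
    lam: np.ndarray,
    last_spike_times: np.ndarray,
    t: float,
    require_visual: bool = False,
    edot: float = 0.0,
    refractory: float = 0.2,
) -> list[SpikeEvent]:
    """Muscle-level complex spikes.

    For muscle ``i`` a spike requires (1) the length is increasing,
    (2) the length exceeds its target value, (3) at least ``refractory``
    seconds since that muscle's previous spike, and, when
    ``require_visual`` is set, (4) the visual error is increasing
    (``edot > 0``).  ``last_spike_times`` is updated in place.
    """
    l = np.asarray(l, dtype=float)
    ldot = np.asarray(ldot, dtype=float)
    lam = np.asarray(lam, dtype=float)
    if require_visual and edot <= 0.0:
        return []
    ok = (ldot > 0.0) & (l > lam) & (t - last_spike_times >= refractory)
    out = []
    for i in np.nonzero(ok)[0]:
        last_spike_times[i] = t
        out.append(SpikeEvent(time=t, source=int(i), cell=None))
    return out


class OlivePopulation:
    """The visual-pathway olive: a fixed population of oscillating cells.

    Phases within each frequency subpopulation are evenly spaced so the
    oscillation phases cover the whole cycle, spreading complex spikes over
    an episode of error increase.
    """

    def __init__(
        self,
        n3: int = 10,
        n7: int = 10,
        p: float = 0.1,
        refractory: float = 0.2,
        parse: str = "product",
    ):
        self.p = p
        self.refractory = refractory
        self.parse = parse
        self.cells: list[OlivaryCell] = []
        for n, f in ((n3, 3.0), (n7, 7.0)):
            period = 1.0 / f
            for k in range(n):
                self.cells.append(OlivaryCell(freq_hz=f, phase=k * period / max(n, 1)))
        self._omega = np.array([c.omega for c in self.cells])
        self._phase = np.array([c.phase for c in self.cells])

    def step(self, e, edot, t, rng) -> list[SpikeEvent]:
        """Vectorized equivalent of :func:`generate_visual_spikes`."""
        edot_pos = max(edot, 0.0)
        draws = rng.random(len(self.cells))
        osc = self.p * np.cos(self._omega * (t - self._phase))
        gate = (1.0 + np.exp(5.0 - e)) * (1.0 + np.exp(min(30.0 - 15.0 * edot_pos, 500.0)))
        if self.parse == "product":
            probs = (osc + 1.0) / gate
        else:
            probs = osc + 1.0 / gate
        probs = np.clip(probs, 0.0, 1.0)
        last = np.array([c.last_spike for c in self.cells])
        fire = (draws < probs) & (t - last >= self.refractory)
        out = []
        for i in np.nonzero(fire)[0]:
            self.cells[i].last_spike = t
            out.append(SpikeEvent(time=t, source="visual", cell=int(i)))
        return out

    def reset_refractory(self) -> None:
        for c in self.cells:
            c.last_spike = -np.inf
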