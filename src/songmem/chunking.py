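"""Masking-field list chunking with adaptive-resonance learning.

List chunks are category cells that learn to recognize the activity
patterns a working memory stores.  The chunk network is multi-scale and
self-similar: a chunk's *scale* is the number of (token, rank) cells it
has learned connections to, larger chunks are both more excitable and
exert stronger recurrent inhibition, so a chunk coding a longer list
(MYSELF) masks the chunks of its sublists (MY, SELF, ELF) whenever its
full list is present -- while an input containing only the sublist still
selects the sublist's chunk.

Learning follows the competitive-learning / adaptive-resonance pattern:
bottom-up weights of the winning chunk track the normalized input pattern
(instar), top-down expectation weights track the same pattern (outstar),
and a vigilance test on the match between input and the winner's learned
pattern decides whether to resonate (refine the winner) or commit a fresh
chunk.  Because working-memory storage preserves activity ratios, the
patterns that trained a chunk keep matching it after longer lists are
learned: no catastrophic forgetting.  Top-down read-out obeys the
matching rule: without a volitional signal the expectation only primes
its working-memory cells subliminally.

Habituative transmitter gates on the bottom-up pathways deplete with use
and recover slowly, limiting perseveration of a winning chunk.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .shunting import ShuntingParams
from .working_memory import WMGradient

__all__ = [
    "HabituativeGate",
    "habituate_step",
    "AdaptiveFilter",
    "Expectation",
    "MaskingField",
    "ChunkNetwork",
    "ChunkCapacityError",
    "chunk_activation",
    "learn",
    "readout_expectation",
]


# ---------------------------------------------------------------------------
# habituative gates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HabituativeGate:
    """Transmitter level z in [0, 1] with recovery delta and depletion rho.

    dz/dt = delta * (1 - z) - rho * S * z, so the equilibrium under a
    sustained gating signal S is z* = delta / (delta + rho * S).
    """

    z: float = 1.0
    recovery: float = 0.1
    depletion: float = 1.0

    def equilibrium(self, S: float) -> float:
        return self.recovery / (self.recovery + self.depletion * S)


def habituate_step(gate: HabituativeGate, S: float, dt: float) -> HabituativeGate:
    """One explicit-Euler step of transmitter habituation; bounds preserved."""
    if S < 0:
        raise ValueError("gating signal must be >= 0")
    dz = gate.recovery * (1.0 - gate.z) - gate.depletion * S * gate.z
    z = min(max(gate.z + dt * dz, 0.0), 1.0)
    return HabituativeGate(z=z, recovery=gate.recovery, depletion=gate.depletion)


# ---------------------------------------------------------------------------
# chunk network
# ---------------------------------------------------------------------------

@dataclass
class AdaptiveFilter:
    """Bottom-up LTM traces: (token, rank) cell -> chunk, each in [0, 1]."""

    weights: dict = field(default_factory=dict)  # chunk id -> {cell: w}
    learning_rate: float = 1.0


@dataclass
class Expectation:
    """Top-down expectation weights: chunk -> (token, rank) cells."""

    weights: dict = field(default_factory=dict)  # chunk id -> {cell: w}
    matching_gain: float = 1.0


@dataclass
class MaskingField:
    """Chunk cells with self-similar scales and activities.

    scale[j] = number of item connections chunk j has learned; excitability
    and recurrent inhibition both grow with scale.
    """

    capacity: int = 64
    scales: dict = field(default_factory=dict)      # chunk id -> int
    activities: dict = field(default_factory=dict)  # chunk id -> float
    labels: dict = field(default_factory=dict)      # chunk id -> str | None
    shunting: ShuntingParams = field(default_factory=ShuntingParams)


class ChunkCapacityError(RuntimeError):
    """No uncommitted chunk remains and no committed chunk matches."""


@dataclass
class ChunkNetwork:
    """Bundle of masking field + adaptive filter + expectation + gates."""

    field_: MaskingField = None
    filter: AdaptiveFilter = None
    expectation: Expectation = None
    gates: dict = None                 # chunk id -> {cell: HabituativeGate}
    vigilance: float = 0.8
    coverage_threshold: float = 0.95   # fraction of a chunk's weight mass
    #                                    that must be active for eligibility
    firing_threshold: float = 0.05     # WM output threshold for priming
    scale_gain: float = 0.2            # self-similar excitability per item

    def __post_init__(self) -> None:
        if self.field_ is None:
            self.field_ = MaskingField()
        if self.filter is None:
            self.filter = AdaptiveFilter()
        if self.expectation is None:
            self.expectation = Expectation()
        if self.gates is None:
            self.gates = {}

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        def wmap(w):
            return [[list(k), v] for k, v in w.items()]

        return {
            "schema_version": 1,
            "capacity": self.field_.capacity,
            "vigilance": self.vigilance,
            "chunks": {
                str(cid): {
                    "scale": self.field_.scales[cid],
                    "label": self.field_.labels.get(cid),
                    "bottom_up": wmap(self.filter.weights[cid]),
                    "top_down": wmap(self.expectation.weights[cid]),
                }
                for cid in self.field_.scales
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ChunkNetwork":
        if d.get("schema_version") != 1:
            raise ValueError(f"unsupported model schema {d.get('schema_version')!r}")
        net = cls(vigilance=d["vigilance"])
        net.field_.capacity = d["capacity"]

        def unmap(items):
            return {(k[0], int(k[1])): float(v) for k, v in items}

        for cid_str, c in d["chunks"].items():
            cid = int(cid_str)
            net.filter.weights[cid] = unmap(c["bottom_up"])
            net.expectation.weights[cid] = unmap(c["top_down"])
            net.field_.scales[cid] = int(c["scale"])
            net.field_.labels[cid] = c.get("label")
        return net

    def save(self, path) -> None:
        """Write the trained network as a schema-versioned JSON model file."""
        import json
        from pathlib import Path

        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path) -> "ChunkNetwork":
        import json

        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def weights_to_frame(self):
        """Bottom-up weight matrix as a tidy DataFrame."""
        import pandas as pd

        rows = [
            {"chunk": cid, "label": self.field_.labels.get(cid),
             "token": cell[0], "rank": cell[1], "weight": w}
            for cid, W in self.filter.weights.items()
            for cell, w in W.items()
        ]
        return pd.DataFrame(rows)


def _pattern(g: WMGradient) -> dict:
    return {c: g.activities[c] for c in g.presentation_order}


def _norm(p: dict) -> float:
    return math.sqrt(sum(v * v for v in p.values()))


def _normalized(p: dict) -> dict:
    n = _norm(p)
    if n == 0:
        return dict(p)
    return {c: v / n for c, v in p.items()}


def chunk_activation(g: WMGradient, net: ChunkNetwork,
                     update_gates: bool = False, dt: float = 0.1) -> tuple[dict, object]:
    """Bottom-up activation of chunks by a WM gradient; returns (C, winner).

    Bottom-up input to chunk j is the gate-modulated filtered sum
    ``sum_i x_i W_ij z_ij``.  The recurrent competition is self-similar:
    a larger chunk is more excitable, but it can only win when its learned
    item set is (nearly) fully present, because an incompletely supported
    large chunk is quenched by the recurrent inhibition of the smaller
    chunks whose items *are* fully active.  The settled outcome is
    computed directly: chunks whose active coverage falls below the
    coverage threshold are quenched; among the rest the maximal
    scale-weighted gated input wins if it clears the vigilance-independent
    firing threshold.  Winner is None for an empty or unrecognized field.
    """
    x = _pattern(g)
    C: dict = {}
    winner = None
    best = 0.0
    for cid, W in net.filter.weights.items():
        gates = net.gates.get(cid, {})
        raw = 0.0
        wmass = 0.0
        active_mass = 0.0
        for cell, wv in W.items():
            wmass += wv
            zg = gates.get(cell, HabituativeGate()).z
            xv = x.get(cell, 0.0)
            raw += xv * wv * zg
            if xv > 0.0:
                active_mass += wv
        coverage = active_mass / wmass if wmass > 0 else 0.0
        gain = 1.0 + net.scale_gain * net.field_.scales.get(cid, 0)
        act = gain * raw if coverage >= net.coverage_threshold else 0.0
        C[cid] = act
        if act > best and act > 1e-12:
            best = act
            winner = cid
    net.field_.activities = C
    if update_gates and winner is not None:
        gd = net.gates.setdefault(winner, {})
        for cell in net.filter.weights[winner]:
            gd[cell] = habituate_step(gd.get(cell, HabituativeGate()),
                                      x.get(cell, 0.0), dt)
    return C, winner


def _match_fraction(x: dict, W: dict) -> float:
    """Fraction of input energy covered by the chunk's learned item set."""
    total = sum(v * v for v in x.values())
    if total == 0:
        return 0.0
    covered = sum(v * v for c, v in x.items() if W.get(c, 0.0) > 0.0)
    return covered / total


def learn(g: WMGradient, net: ChunkNetwork, steps: int = 1,
          label: str | None = None) -> object:
    """Learn the current WM pattern; returns the chunk id trained.

    The bottom-up winner is adopted if the input pattern matches its
    learned item set above vigilance (resonance); otherwise a fresh chunk
    is committed (capacity error when exhausted).  Learning is gated
    instar / outstar: only the winner's weights move, toward the
    L2-normalized WM pattern.
    """
    x = _pattern(g)
    if not x:
        raise ValueError("cannot learn from an empty working memory")
    _, winner = chunk_activation(g, net)
    if winner is not None:
        match = _match_fraction(x, net.filter.weights[winner])
        if match < net.vigilance:
            winner = None
    if winner is None:
        if len(net.field_.scales) >= net.field_.capacity:
            raise ChunkCapacityError(
                f"all {net.field_.capacity} chunks committed and none matches"
            )
        winner = len(net.field_.scales)
        net.filter.weights[winner] = {}
        net.expectation.weights[winner] = {}
        net.field_.scales[winner] = 0
        net.field_.labels[winner] = label
    xn = _normalized(x)
    lr = net.filter.learning_rate
    W = net.filter.weights[winner]
    V = net.expectation.weights[winner]
    for _ in range(max(steps, 1)):
        for cell in set(xn) | set(W):
            target = xn.get(cell, 0.0)
            W[cell] = W.get(cell, 0.0) + lr * (target - W.get(cell, 0.0))
            V[cell] = V.get(cell, 0.0) + lr * (target - V.get(cell, 0.0))
    # prune numerically-zero traces, then update the self-similar scale
    for cell in [c for c, v in W.items() if v <= 1e-12]:
        del W[cell]
        V.pop(cell, None)
    net.field_.scales[winner] = len(W)
    if label is not None:
        net.field_.labels[winner] = label
    return winner


def readout_expectation(chunk_id: object, net: ChunkNetwork,
                        volition: bool = True,
                        shunting: ShuntingParams | None = None) -> WMGradient:
    """Read a chunk's learned expectation back into working memory.

    With volition on, the stored pattern is scaled into suprathreshold WM
    activities whose ratios match the learned pattern (so rehearsal
    reproduces the trained order).  With volition off the expectation is
    modulatory only: the returned priming pattern sits strictly below the
    firing threshold.
    """
    if chunk_id not in net.expectation.weights or not net.expectation.weights[chunk_id]:
        raise KeyError(f"chunk {chunk_id!r} is not committed")
    if shunting is None:
        shunting = net.field_.shunting
    V = net.expectation.weights[chunk_id]
    cells = sorted(V, key=lambda c: -V[c])  # primacy order = learned ratios
    if volition:
        scale = net.expectation.matching_gain
    else:
        vmax = max(V.values())
        scale = 0.5 * net.firing_threshold / vmax if vmax > 0 else 0.0
    drives = {}
    acts = {}
    for c in cells:
        acts[c] = V[c] * scale
    # reconstruct drives consistent with the shunting shares so that
    # rehearsal renormalization behaves as for a presented sequence
    total = sum(acts.values())
    B, A = shunting.B, shunting.A
    if total < B:
        for c in cells:
            drives[c] = acts[c] * A / (B - total)
    else:  # pragma: no cover - matching_gain keeps totals below B
        for c in cells:
            drives[c] = acts[c]
    return WMGradient(activities=acts, presentation_order=cells,
                      capacity=B, drives=drives)
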