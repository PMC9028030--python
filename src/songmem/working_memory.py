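"""Item-Order-Rank working memory: sequence storage as activity gradients.

A sequence is stored as a *spatial pattern* of activities over
(token, rank) cells: each arriving token is routed, by the numerosity-map
rank signal, to the hypercolumn cell for its k-th occurrence, so repeated
items (ABAC, a twice-sung word) occupy distinct cells.  Relative activity
encodes temporal order: a *primacy* gradient (activities strictly
decreasing in presentation order) is recalled correctly by iterated
choice of the most active cell, each readout self-inhibiting its cell
(inhibition of return) while the shunting field renormalizes the
remainder.

Storage model
-------------
Each stored cell carries an underlying drive ``u_i``; observable
activities are the shunting-normalized shares

    x_i = B * u_i / (A + sum_k u_k)

(the feedforward off-surround equilibrium), which preserves ratios of
drives exactly (the substrate of stable chunk learning) and bounds total
activity by B (limited capacity).  A new item enters with drive equal to
the input intensity; every already-stored drive is multiplied by a common
consolidation factor

    rho = shrink * (1 + eta * (B - T)) * (1 + gain * lambda)

where T is the current total activity, ``shrink`` < 1 is the transient
inhibition exerted by the arriving item, ``eta`` the recurrent on-center
consolidation that favours earlier items while the field is far from its
capacity, and ``lambda`` the top-down expectation support (modulatory:
proportional to the stored pattern itself, hence ratio-preserving).
While rho > 1 stored items stay ahead of newcomers (primacy); as T
approaches B, rho falls below 1 and late items overtake (bowing).  The
frozen defaults place the primacy/bow crossover at list length 4 without
top-down support and at 7 with it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Hashable, Sequence

import numpy as np

from . import number_map
from .shunting import ShuntingParams, feedforward_equilibrium

__all__ = [
    "ItemSequence",
    "WMParams",
    "WMGradient",
    "RecallTrace",
    "VocabularyError",
    "present_sequence",
    "gradient_shape",
    "rehearse",
    "last_item_rebound",
    "transient_span",
    "immediate_span",
    "serial_position_curve",
    "gradient_to_frame",
]

Token = Hashable
Cell = tuple  # (token, rank)


class VocabularyError(ValueError):
    """Token outside the configured alphabet."""


@dataclass
class ItemSequence:
    """An ordered list of tokens (repeats allowed)."""

    tokens: Sequence[Token]
    presentation_interval: float = 0.5

    def __len__(self) -> int:
        return len(self.tokens)


@dataclass
class WMParams:
    """Working-memory parameters (defaults frozen by span calibration).

    input_intensity : drive of each arriving item
    shrink          : multiplicative transient inhibition of stored drives
                      per arrival, in (0, 1)
    consolidation   : recurrent on-center consolidation gain eta
    expectation_gain: pathway gain from the learned top-down expectation
    top_down_gain   : volitional top-down support lambda (0 = bottom-up only)
    noise_sigma     : Gaussian perturbation of activities per rehearsal cycle
    recall_threshold: minimum perturbed activity for an item to be emitted
    seed            : rng seed for noisy rehearsal
    """

    shunting: ShuntingParams = field(default_factory=ShuntingParams)
    input_intensity: float = 0.5
    shrink: float = 0.71
    consolidation: float = 1.2
    expectation_gain: float = 0.155
    top_down_gain: float = 0.0
    top_down_at_recall: bool = False
    noise_sigma: float = 0.0
    recall_threshold: float = 0.0
    rehearsal_fade: float = 1.0
    seed: int = 0
    alphabet: tuple | None = None
    max_rank: int = 16

    def __post_init__(self) -> None:
        if self.top_down_gain < 0 or self.noise_sigma < 0:
            raise ValueError("top_down_gain and noise_sigma must be >= 0")
        if not (0 < self.shrink < 1):
            raise ValueError("shrink must be in (0, 1)")

    def with_top_down(self, lam: float) -> "WMParams":
        return replace(self, top_down_gain=lam)


DEFAULT_TOP_DOWN = 1.0
"""Frozen top-down support level used for immediate-span storage."""


@dataclass
class WMGradient:
    """Stored order code: activities over (token, rank) cells."""

    activities: dict
    presentation_order: list
    capacity: float
    drives: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.presentation_order)

    @property
    def total_activity(self) -> float:
        return float(sum(self.activities.values()))

    def activity_vector(self) -> np.ndarray:
        return np.array([self.activities[c] for c in self.presentation_order])

    @classmethod
    def from_drives(cls, order: list, drives: dict, shunting: ShuntingParams) -> "WMGradient":
        u = np.array([drives[c] for c in order]) if order else np.array([])
        x = feedforward_equilibrium(u, shunting) if order else u
        return cls(
            activities={c: float(v) for c, v in zip(order, x)},
            presentation_order=list(order),
            capacity=shunting.B,
            drives=dict(drives),
        )


@dataclass
class RecallTrace:
    """Ordered readout events (token, rank, latency) and the emptied WM."""

    events: list
    final_wm: WMGradient


# ---------------------------------------------------------------------------
# storage
# ---------------------------------------------------------------------------

def present_sequence(seq: ItemSequence | Sequence[Token], params: WMParams,
                     map_config: "number_map.NumberMapConfig | None" = None) -> WMGradient:
    """Store a token sequence as an activity gradient over (token, rank) cells.

    The k-th occurrence of a token is routed to rank k via the numerosity
    map; each arrival consolidates or erodes previously stored drives by
    the common factor rho described in the module docstring (ratio
    preservation is exact by construction).
    """
    tokens = seq.tokens if isinstance(seq, ItemSequence) else list(seq)
    sp = params.shunting
    A, B = sp.A, sp.B
    support = params.expectation_gain * params.top_down_gain

    order: list = []
    drives: dict = {}
    counts: dict = {}
    for tok in tokens:
        if params.alphabet is not None and tok not in params.alphabet:
            raise VocabularyError(f"token {tok!r} not in configured alphabet")
        k = counts.get(tok, 0) + 1
        counts[tok] = k
        rank = number_map.rank_signal(k, map_config).rank
        cell = (tok, rank)
        if cell in drives:  # cannot happen: rank counts occurrences
            raise RuntimeError("duplicate (token, rank) cell")
        U = sum(drives.values())
        T = B * U / (A + U)
        rho = params.shrink * (1.0 + params.consolidation * (B - T)) * (1.0 + support)
        for c in drives:
            drives[c] *= rho
        drives[cell] = params.input_intensity
        order.append(cell)
    return WMGradient.from_drives(order, drives, sp)


def gradient_shape(g: WMGradient, tol: float = 1e-6) -> str:
    """Classify the stored gradient: primacy, bowed, recency or flat."""
    if len(g) < 1:
        raise ValueError("gradient must store at least one item")
    x = g.activity_vector()
    if x.size == 1:
        return "primacy"
    d = np.diff(x)
    if np.all(d < -tol):
        return "primacy"
    if np.all(d > tol):
        return "recency"
    sign = np.where(d > tol, 1, np.where(d < -tol, -1, 0))
    nz = sign[sign != 0]
    if (nz.size >= 2 and nz[0] == -1 and nz[-1] == 1
            and np.all(np.diff(nz) >= 0)):  # single down->up transition
        return "bowed"
    return "flat"


# ---------------------------------------------------------------------------
# rehearsal
# ---------------------------------------------------------------------------

_LATENCY_BASE = 0.05
_LATENCY_GAIN = 0.1


def _renormalized(drives: dict, order: list, sp: ShuntingParams) -> dict:
    cells = [c for c in order if c in drives]
    u = np.array([drives[c] for c in cells])
    if u.size == 0:
        return {}
    x = feedforward_equilibrium(u, sp)
    return dict(zip(cells, x))


def rehearse(g: WMGradient, params: WMParams,
             rng: np.random.Generator | None = None) -> RecallTrace:
    """Winner-take-all readout with inhibition of return.

    Each cycle the rehearsal wave enables readout of the currently most
    active cell (exact ties broken toward the lower presentation index);
    the winner self-inhibits, the remaining field renormalizes upward
    (released from the winner's off-surround), and the cycle repeats until
    working memory is empty.  With ``noise_sigma > 0``, activities are
    perturbed each cycle and items whose perturbed activity falls below
    ``recall_threshold`` on their winning cycle are dropped rather than
    emitted (seeded).
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    sp = params.shunting
    drives = dict(g.drives)
    order = list(g.presentation_order)
    index = {c: i for i, c in enumerate(order)}
    events = []
    t = 0.0
    fade = 1.0
    while drives:
        x = _renormalized(drives, order, sp)
        cells = list(x.keys())
        act = fade * np.array([x[c] for c in cells])
        if params.noise_sigma > 0:
            act = act + rng.normal(0.0, params.noise_sigma, act.size)
        best = max(range(len(cells)), key=lambda i: (act[i], -index[cells[i]]))
        winner = cells[best]
        t += _LATENCY_BASE + _LATENCY_GAIN / (1.0 + max(act[best], 0.0))
        if act[best] >= params.recall_threshold:
            events.append((winner[0], winner[1], t))
        del drives[winner]  # inhibition of return
        fade *= params.rehearsal_fade  # attentional fading over output time
    final = WMGradient.from_drives([], {}, sp)
    return RecallTrace(events=events, final_wm=final)


def last_item_rebound(g: WMGradient, params: WMParams) -> list[float]:
    """Activity of the final stored item across rehearsal cycles.

    Returns the last item's activity after each preceding readout; once the
    penultimate item self-inhibits, the last item is freed from its
    off-surround and rebounds above its initially stored value.
    """
    sp = params.shunting
    drives = dict(g.drives)
    order = list(g.presentation_order)
    if not order:
        return []
    last = order[-1]
    index = {c: i for i, c in enumerate(order)}
    trace = []
    while drives:
        x = _renormalized(drives, order, sp)
        trace.append(float(x.get(last, 0.0)))
        cells = list(x.keys())
        act = np.array([x[c] for c in cells])
        best = max(range(len(cells)), key=lambda i: (act[i], -index[cells[i]]))
        del drives[cells[best]]
    return trace


# ---------------------------------------------------------------------------
# spans
# ---------------------------------------------------------------------------

def _span(params: WMParams, max_len: int = 40) -> int:
    best = 0
    for L in range(1, max_len + 1):
        seq = ItemSequence(tokens=[f"t{i}" for i in range(L)])
        g = present_sequence(seq, params)
        if gradient_shape(g) == "primacy":
            best = L
        else:
            break
    return best


def transient_span(params: WMParams) -> int:
    """Longest strictly-primacy list under bottom-up storage alone."""
    if params.top_down_gain != 0:
        raise ValueError("transient span is defined for top_down_gain = 0")
    return _span(params)


def immediate_span(params: WMParams) -> int:
    """Longest strictly-primacy list with top-down expectation support."""
    if params.top_down_gain <= 0:
        raise ValueError("immediate span requires top_down_gain > 0")
    return _span(params)


# ---------------------------------------------------------------------------
# serial-position phenomena
# ---------------------------------------------------------------------------

def serial_position_curve(list_len: int, n_trials: int, params: WMParams,
                          seed: int | None = None) -> dict:
    """Monte-Carlo recall statistics over seeded noisy rehearsals.

    Returns per-presentation-position recall probability and mean output
    position, plus order-inversion (transposition) probability by
    *baseline* output distance: inversions are counted relative to the
    noise-free recall order of the same gradient, since that is the order
    the stored activity pattern dictates; items adjacent in that order have
    the most similar activities and so are transposed most often.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if seed is None:
        seed = params.seed
    seq = ItemSequence(tokens=[f"t{i}" for i in range(list_len)])
    g = present_sequence(seq, params)
    # noise-free baseline order (no omissions)
    quiet = replace(params, noise_sigma=0.0, recall_threshold=0.0)
    base_events = rehearse(g, quiet).events
    base_pos = {(tok, rank): k for k, (tok, rank, _) in enumerate(base_events)}
    rng = np.random.default_rng(seed)
    recalled = np.zeros(list_len)
    out_pos_sum = np.zeros(list_len)
    out_pos_n = np.zeros(list_len)
    inv_count: dict[int, int] = {}
    inv_total: dict[int, int] = {}
    for _ in range(n_trials):
        trace = rehearse(g, params, rng=rng)
        pos_of = {}
        for out_idx, (tok, rank, _lat) in enumerate(trace.events):
            i = g.presentation_order.index((tok, rank))
            pos_of[i] = out_idx
            recalled[i] += 1
            out_pos_sum[i] += out_idx
            out_pos_n[i] += 1
        bpos = {g.presentation_order.index(c): p for c, p in base_pos.items()}
        for i in range(list_len):
            for j in range(list_len):
                if i == j or i not in pos_of or j not in pos_of:
                    continue
                if bpos[i] < bpos[j]:
                    d = bpos[j] - bpos[i]
                    inv_total[d] = inv_total.get(d, 0) + 1
                    if pos_of[i] > pos_of[j]:
                        inv_count[d] = inv_count.get(d, 0) + 1
    swap_prob = {d: inv_count.get(d, 0) / inv_total[d] for d in inv_total}
    with np.errstate(invalid="ignore"):
        mean_out = np.where(out_pos_n > 0, out_pos_sum / np.maximum(out_pos_n, 1), np.nan)
    return {
        "recall_prob": recalled / n_trials,
        "mean_output_position": mean_out,
        "swap_prob": swap_prob,
    }


def gradient_to_frame(g: WMGradient):
    """Gradient as a tidy DataFrame (position, token, rank, activity)."""
    import pandas as pd

    rows = [
        {"position": i, "token": c[0], "rank": c[1], "activity": g.activities[c]}
        for i, c in enumerate(g.presentation_order)
    ]
    return pd.DataFrame(rows)
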