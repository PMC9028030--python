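"""VITE trajectory generation and the movement-completion detector.

A reach is generated by integrating a difference vector toward a target:

    dD/dt = alpha * (-D + T - P)        (difference vector)
    dP/dt = G * [D]+                    (present position; rectified)

where T is the target position, P the present position and G >= 0 the
volitional GO signal that scales movement speed without changing the
path.  Bidirectional movement uses antagonistic channel pairs: each
coordinate is driven by [D]+ - [-D]+, the agonist and antagonist
rectified difference signals.  For a step target the outflow speed
profile |dP/dt| is bell shaped.

Sequential performance needs a signal that the current movement is
almost complete so the next item can be rehearsed smoothly.  Two leaky
averagers track the outflow speed, one fast (rate a) and one slow
(rate b < a).  While speed is rising the fast average leads (B - A < 0,
rehearsal gated off); after the speed peak the fast average falls first
and (B - A) turns positive, triggering the next readout shortly before
the movement ends.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "VITEParams",
    "ViteTrajectory",
    "CompletionSignal",
    "vite_reach",
    "completion_signal",
]


@dataclass(frozen=True)
class VITEParams:
    """Frozen defaults: alpha=10/s; averager rates a=20/s, b=4/s.

    GO values up to alpha/4 keep the (D, P) system overdamped so the
    approach to target is monotone per component.
    """

    alpha: float = 10.0
    a_fast: float = 20.0
    b_slow: float = 4.0

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if not (self.a_fast > self.b_slow > 0):
            raise ValueError("need fast rate a > slow rate b > 0")


@dataclass
class ViteTrajectory:
    t: np.ndarray        # (n,)
    P: np.ndarray        # (n, dims)
    D: np.ndarray        # (n, dims)
    speed: np.ndarray    # (n,), |dP/dt|


def vite_reach(T, P0, G: float, params: VITEParams | None = None,
               dt: float = 0.001, t_end: float | None = None) -> ViteTrajectory:
    """Integrate one reach from P0 toward T under GO signal G.

    The default horizon scales inversely with G (the slow closed-loop pole
    is approximately -G for G << alpha), long enough for the residual
    distance to fall below 1e-4 of the initial distance.
    """
    if params is None:
        params = VITEParams()
    if G < 0:
        raise ValueError("GO signal must be >= 0")
    if t_end is None:
        t_end = 12.0 / G if G > 0 else 1.0
    T = np.atleast_1d(np.asarray(T, dtype=float))
    P = np.atleast_1d(np.asarray(P0, dtype=float)).copy()
    D = np.zeros_like(P)
    n = int(np.ceil(t_end / dt)) + 1
    ts = np.arange(n) * dt
    Ps = np.empty((n, P.size))
    Ds = np.empty((n, P.size))
    spd = np.empty(n)
    for k in range(n):
        Ps[k] = P
        Ds[k] = D
        # antagonistic rectified channels: agonist [D]+, antagonist [-D]+
        outflow = G * (np.maximum(D, 0.0) - np.maximum(-D, 0.0))
        spd[k] = float(np.linalg.norm(outflow))
        D = D + dt * params.alpha * (-D + T - P)
        P = P + dt * outflow
    return ViteTrajectory(t=ts, P=Ps, D=Ds, speed=spd)


@dataclass
class CompletionSignal:
    t: np.ndarray
    fast: np.ndarray
    slow: np.ndarray
    difference: np.ndarray   # slow - fast
    trigger_time: float | None


def completion_signal(speed: np.ndarray, dt: float,
                      a: float = 20.0, b: float = 4.0) -> CompletionSignal:
    """(B_slow - A_fast) trace and the rehearsal trigger time.

    The trigger is the first time after the speed peak at which the slow
    average exceeds the fast average; None when the speed trace is zero
    (no movement, nothing to complete).
    """
    if not a > b > 0:
        raise ValueError("need a > b > 0")
    speed = np.asarray(speed, dtype=float)
    n = speed.size
    t = np.arange(n) * dt
    fast = np.empty(n)
    slow = np.empty(n)
    xf = xs = 0.0
    for k in range(n):
        xf += dt * a * (speed[k] - xf)
        xs += dt * b * (speed[k] - xs)
        fast[k] = xf
        slow[k] = xs
    diff = slow - fast
    trigger = None
    if speed.max() > 0:
        kpk = int(np.argmax(speed))
        after = np.flatnonzero(diff[kpk + 1:] > 0)
        if after.size:
            trigger = float(t[kpk + 1 + after[0]])
    return CompletionSignal(t=t, fast=fast, slow=slow, difference=diff,
                            trigger_time=trigger)


def trajectory_to_frame(tr: ViteTrajectory):
    """Trajectory as a tidy DataFrame (t, component, P, D, speed)."""
    import pandas as pd

    rows = []
    for k in range(tr.t.size):
        for c in range(tr.P.shape[1]):
            rows.append({"t": tr.t[k], "component": c,
                         "P": tr.P[k, c], "D": tr.D[k, c],
                         "speed": tr.speed[k]})
    return pd.DataFrame(rows)
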