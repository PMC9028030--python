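"""Recurrent shunting on-center off-surround dynamics.

This module is the circuit substrate shared by every other part of the
package: cell activities obey membrane-equation ("shunting") dynamics in
which excitatory input drives activity toward a ceiling ``B`` and
inhibitory input drives it toward a floor ``-C``.  The canonical ODE is

    dx_i/dt = -A*x_i + (B - x_i) * [I_i + sum_k on_ik * f(x_k)]
                     - (x_i + C) * [J_i + sum_k off_ik * g(s_k)]

where ``s_k = x_k`` for the fast variant, or ``s_k = y_k`` with
``dy_k/dt = eps * (-y_k + x_k)`` for the slow-inhibition variant whose
sluggish off-surround turns the circuit into an oscillator when driven by
a sufficiently large arousal input.

The module also houses the travelling-wave ("G-wave") utility: two
sequentially flashed Gaussian receptive-field activations whose summed
activity peak sweeps continuously between the two positions when the
fields overlap, with a speed set by the inter-stimulus interval and the
separation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "SignalFunction",
    "save_params",
    "load_params",
    "ShuntingParams",
    "InputSchedule",
    "NetworkState",
    "IntegrationInstabilityError",
    "step_network",
    "simulate",
    "total_activity",
    "feedforward_equilibrium",
    "gwave_peak_path",
    "gwave_sweep_speed",
    "trajectory_to_frame",
]


class IntegrationInstabilityError(RuntimeError):
    """Raised when explicit integration produces non-finite activities."""


# ---------------------------------------------------------------------------
# signal functions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SignalFunction:
    """Nonnegative, nondecreasing feedback signal f(x).

    family:
        ``linear``             -> gain * [x - threshold]+
        ``faster_than_linear`` -> gain * ([x - threshold]+) ** power
        ``sigmoid``            -> gain * u**power / (K**power + u**power)
                                  with u = [x - threshold]+ and half-point K.
    """

    family: str = "sigmoid"
    threshold: float = 0.0
    gain: float = 1.0
    power: float = 2.0
    half_point: float = 0.5  # sigmoid half-saturation point K

    def __post_init__(self) -> None:
        if self.family not in ("linear", "faster_than_linear", "sigmoid"):
            raise ValueError(f"unknown signal family {self.family!r}")
        if self.threshold < 0:
            raise ValueError("threshold must be >= 0")
        if self.gain <= 0:
            raise ValueError("gain must be > 0")
        if self.power < 1:
            raise ValueError("power must be >= 1")

    def __call__(self, x: np.ndarray | float) -> np.ndarray | float:
        u = np.maximum(np.asarray(x, dtype=float) - self.threshold, 0.0)
        if self.family == "linear":
            out = self.gain * u
        elif self.family == "faster_than_linear":
            out = self.gain * u ** self.power
        else:
            up = u ** self.power
            out = self.gain * up / (self.half_point ** self.power + up)
        return out

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "threshold": self.threshold,
            "gain": self.gain,
            "power": self.power,
            "half_point": self.half_point,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SignalFunction":
        return cls(**d)


ZERO_SIGNAL = SignalFunction(family="linear", gain=1e-12)
"""Numerically-zero signal (gain must be positive; this is negligible)."""


# ---------------------------------------------------------------------------
# parameters / state
# ---------------------------------------------------------------------------

@dataclass
class ShuntingParams:
    """Parameters of one recurrent shunting network.

    A    : passive decay rate (1/time), > 0
    B    : excitatory saturation ceiling, > 0
    C    : inhibitory saturation floor (activities live in [-C, B]), >= 0
    on_center : (n, n) nonnegative on-center weight matrix, or None for
                identity (pure self-excitation)
    off_surround : (n, n) nonnegative off-surround weight matrix, or None
                for all-ones-off-diagonal; whether the diagonal (self-
                inhibition) is zero is a wiring choice exposed here
    f, g : on-center / off-surround feedback signal functions
    epsilon : slow-interneuron rate (1/time); only used by the
              slow-inhibition variant
    slow_inhibition : if True the off-surround reads the slow interneuron
              activities y rather than x directly
    dt   : default integration step (explicit Euler)
    """

    A: float = 1.0
    B: float = 1.0
    C: float = 0.0
    on_center: np.ndarray | None = None
    off_surround: np.ndarray | None = None
    f: SignalFunction = field(default_factory=lambda: SignalFunction("sigmoid"))
    g: SignalFunction = field(
        default_factory=lambda: SignalFunction("linear", threshold=0.0, gain=1.0)
    )
    epsilon: float = 0.1
    slow_inhibition: bool = False
    dt: float | None = None

    def __post_init__(self) -> None:
        if self.A <= 0 or self.B <= 0:
            raise ValueError("A and B must be > 0")
        if self.C < 0:
            raise ValueError("C must be >= 0")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")
        if self.dt is None:
            self.dt = 0.001 / self.A
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        for name in ("on_center", "off_surround"):
            m = getattr(self, name)
            if m is not None:
                m = np.asarray(m, dtype=float)
                if (m < 0).any():
                    raise ValueError(f"{name} weights must be nonnegative")
                setattr(self, name, m)

    def on_matrix(self, n: int) -> np.ndarray:
        if self.on_center is None:
            return np.eye(n)
        return self.on_center

    def off_matrix(self, n: int) -> np.ndarray:
        if self.off_surround is None:
            m = np.ones((n, n)) - np.eye(n)
            return m
        return self.off_surround

    def to_dict(self) -> dict:
        return {
            "A": self.A,
            "B": self.B,
            "C": self.C,
            "on_center": None if self.on_center is None else np.asarray(self.on_center).tolist(),
            "off_surround": None if self.off_surround is None else np.asarray(self.off_surround).tolist(),
            "f": self.f.to_dict(),
            "g": self.g.to_dict(),
            "epsilon": self.epsilon,
            "slow_inhibition": self.slow_inhibition,
            "dt": self.dt,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ShuntingParams":
        d = dict(d)
        if d.get("f") is not None:
            d["f"] = SignalFunction.from_dict(d["f"])
        if d.get("g") is not None:
            d["g"] = SignalFunction.from_dict(d["g"])
        for k in ("on_center", "off_surround"):
            if d.get(k) is not None:
                d[k] = np.asarray(d[k], dtype=float)
        return cls(**d)


@dataclass
class InputSchedule:
    """Time courses of external excitatory (I) and inhibitory (J) inputs.

    ``excitatory`` / ``inhibitory`` are callables t -> array of shape (n,),
    required to be nonnegative on the simulation horizon.  Use
    :meth:`constant` for tonic inputs.
    """

    excitatory: Callable[[float], np.ndarray]
    inhibitory: Callable[[float], np.ndarray]

    @classmethod
    def constant(cls, I: Sequence[float] | float, J: Sequence[float] | float = 0.0,
                 n: int | None = None) -> "InputSchedule":
        I_arr = np.atleast_1d(np.asarray(I, dtype=float))
        J_arr = np.atleast_1d(np.asarray(J, dtype=float))
        if n is not None:
            if I_arr.size == 1:
                I_arr = np.full(n, I_arr[0])
            if J_arr.size == 1:
                J_arr = np.full(n, J_arr[0])
        if J_arr.size == 1 and I_arr.size > 1:
            J_arr = np.full(I_arr.size, J_arr[0])
        if (I_arr < 0).any() or (J_arr < 0).any():
            raise ValueError("inputs must be nonnegative")
        return cls(excitatory=lambda t: I_arr, inhibitory=lambda t: J_arr)


@dataclass
class NetworkState:
    """Activities x (and slow interneurons y) at time t."""

    x: np.ndarray
    y: np.ndarray | None = None
    t: float = 0.0

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        if self.y is not None:
            self.y = np.asarray(self.y, dtype=float)

    @classmethod
    def zeros(cls, n: int, slow: bool = False) -> "NetworkState":
        return cls(x=np.zeros(n), y=np.zeros(n) if slow else None, t=0.0)


# ---------------------------------------------------------------------------
# integration
# ---------------------------------------------------------------------------

def step_network(state: NetworkState, I: np.ndarray, J: np.ndarray,
                 params: ShuntingParams, dt: float | None = None) -> NetworkState:
    """One explicit-Euler step of the shunting ODE.

    The update is clipped to the invariant range [-C, B]; an
    :class:`IntegrationInstabilityError` names the offending cell if the
    raw update is non-finite.
    """
    if dt is None:
        dt = params.dt
    x = state.x
    n = x.size
    I = np.asarray(I, dtype=float)
    J = np.asarray(J, dtype=float)
    on = params.on_matrix(n)
    off = params.off_matrix(n)

    if params.slow_inhibition:
        y = state.y if state.y is not None else np.zeros(n)
        s = y
    else:
        s = x

    exc = I + on @ np.atleast_1d(params.f(x))
    inh = J + off @ np.atleast_1d(params.g(s))
    dx = -params.A * x + (params.B - x) * exc - (x + params.C) * inh
    x_new = x + dt * dx
    if not np.isfinite(x_new).all():
        bad = int(np.flatnonzero(~np.isfinite(x_new))[0])
        raise IntegrationInstabilityError(
            f"non-finite activity at cell {bad} with dt={dt}; reduce dt"
        )
    x_new = np.clip(x_new, -params.C, params.B)

    y_new = None
    if params.slow_inhibition:
        y = state.y if state.y is not None else np.zeros(n)
        y_new = y + dt * params.epsilon * (-y + x)
        y_new = np.maximum(y_new, 0.0)
    return NetworkState(x=x_new, y=y_new, t=state.t + dt)


def simulate(state0: NetworkState, schedule: InputSchedule,
             params: ShuntingParams, t_end: float,
             dt: float | None = None,
             record_every: int = 1) -> list[NetworkState]:
    """Integrate from ``state0`` to ``t_end``; returns the trajectory.

    ``record_every`` thins the stored trajectory (the final state is always
    recorded); the returned list always starts with ``state0``.
    """
    if t_end < 0:
        raise ValueError("t_end must be >= 0")
    if dt is None:
        dt = params.dt
    n_steps = int(np.ceil(t_end / dt)) if t_end > 0 else 0
    traj = [state0]
    state = state0
    for k in range(n_steps):
        I = schedule.excitatory(state.t)
        J = schedule.inhibitory(state.t)
        state = step_network(state, I, J, params, dt)
        if (k + 1) % record_every == 0 or k == n_steps - 1:
            traj.append(state)
    return traj


def total_activity(state: NetworkState) -> float:
    """Total suprathreshold activity sum_i max(x_i, 0)."""
    return float(np.maximum(state.x, 0.0).sum())


def feedforward_equilibrium(I: Sequence[float], params: ShuntingParams) -> np.ndarray:
    """Steady state of the feedforward off-surround configuration.

    With no recurrent feedback and each cell inhibited by the off-surround
    of all other inputs, dx_i/dt = -A x_i + (B - x_i) I_i - x_i sum_{k!=i} I_k
    gives x_i* = B I_i / (A + sum_k I_k): activities are normalized shares of
    the input pattern (ratio preservation + limited capacity).
    """
    I = np.asarray(I, dtype=float)
    return params.B * I / (params.A + I.sum())


# ---------------------------------------------------------------------------
# G-wave apparent motion
# ---------------------------------------------------------------------------

def _envelopes(t: np.ndarray, onset: float, offset: float,
               rise: float, decay: float) -> np.ndarray:
    """First-order low-pass response to a unit pulse on [onset, offset)."""
    e = np.zeros_like(t)
    during = (t >= onset) & (t < offset)
    e[during] = 1.0 - np.exp(-rise * (t[during] - onset))
    after = t >= offset
    peak = 1.0 - np.exp(-rise * (offset - onset))
    e[after] = peak * np.exp(-decay * (t[after] - offset))
    return e


def gwave_peak_path(pos1: float, pos2: float, onset2_delay: float,
                    sigma: float, rise: float = 20.0, decay: float = 8.0,
                    dt: float = 0.001, stim_duration: float | None = None,
                    horizon: float | None = None,
                    n_grid: int = 801) -> list[tuple[float, float]]:
    """Peak-position trace of two sequentially flashed Gaussian activations.

    Activity(p, t) = e1(t) exp(-(p-pos1)^2/2s^2) + e2(t) exp(-(p-pos2)^2/2s^2)
    with e1 a low-pass on/off transient of the first flash (on at t=0, off
    at ``onset2_delay``) and e2 of the second flash (on at ``onset2_delay``).
    When the Gaussians overlap the argmax sweeps continuously from pos1 to
    pos2; with negligible overlap it jumps.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    if onset2_delay < 0:
        raise ValueError("onset2_delay must be >= 0")
    if stim_duration is None:
        stim_duration = max(onset2_delay, dt)
    if horizon is None:
        horizon = onset2_delay + max(6.0 / decay, 0.2)
    t = np.arange(0.0, horizon + dt, dt)
    e1 = _envelopes(t, 0.0, stim_duration, rise, decay)
    e2 = _envelopes(t, onset2_delay, horizon + dt, rise, decay)
    lo, hi = min(pos1, pos2), max(pos1, pos2)
    p = np.linspace(lo - 2 * sigma, hi + 2 * sigma, n_grid)
    g1 = np.exp(-((p - pos1) ** 2) / (2 * sigma ** 2))
    g2 = np.exp(-((p - pos2) ** 2) / (2 * sigma ** 2))
    act = np.outer(e1, g1) + np.outer(e2, g2)
    idx = np.argmax(act, axis=1)
    return [(float(ti), float(p[i])) for ti, i in zip(t, idx)]


def gwave_sweep_speed(path: list[tuple[float, float]], pos1: float,
                      pos2: float, margin: float = 0.05) -> float:
    """Mean sweep speed between leaving pos1 and reaching pos2.

    Measured between the first time the peak departs pos1 by more than
    ``margin`` of the separation and the first time it comes within
    ``margin`` of pos2.  Returns nan when no complete sweep occurred.
    """
    sep = abs(pos2 - pos1)
    if sep == 0:
        return 0.0
    ts = np.array([q[0] for q in path])
    ps = np.array([q[1] for q in path])
    frac = np.abs(ps - pos1) / sep
    started = np.flatnonzero(frac > margin)
    arrived = np.flatnonzero(np.abs(ps - pos2) / sep < margin)
    if started.size == 0 or arrived.size == 0:
        return float("nan")
    t0 = ts[started[0]]
    later = arrived[arrived >= started[0]]
    if later.size == 0:
        return float("nan")
    t1 = ts[later[0]]
    if t1 <= t0:
        return float("nan")
    return float(sep * (1 - 2 * margin) / (t1 - t0))


def trajectory_to_frame(traj: list[NetworkState]):
    """Trajectory as a tidy DataFrame (t, cell, x, y)."""
    import pandas as pd

    rows = []
    for st in traj:
        for i, xi in enumerate(st.x):
            rows.append({
                "t": st.t,
                "cell": i,
                "x": float(xi),
                "y": float(st.y[i]) if st.y is not None else np.nan,
            })
    return pd.DataFrame(rows)


def save_params(params: ShuntingParams, path) -> None:
    """Write parameters as JSON conforming to shunting_params.schema.json."""
    import json
    from pathlib import Path

    Path(path).write_text(json.dumps(params.to_dict(), indent=2))


def load_params(path) -> ShuntingParams:
    """Read parameters from a JSON config (validated on construction)."""
    import json

    with open(path) as fh:
        return ShuntingParams.from_dict(json.load(fh))
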