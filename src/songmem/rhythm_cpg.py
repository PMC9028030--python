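"""Beat generation and rhythmic pattern formation with shunting CPGs.

Each channel is a shunting cell with recurrent self-excitation and a
*slow* self-inhibitory interneuron: driven by a tonic arousal (GO)
signal above a finite threshold, the on-center rapidly amplifies the
cell's activity and the sluggish inhibition then shuts it down, yielding
a relaxation oscillation -- a beat -- whose period shortens as GO grows.
Below threshold the channel is phasically responsive and decays to rest.

Channels are coupled two ways, reflecting the two interneuron types of
the circuit: *fast* off-surround inhibition (mediated directly by the
partner's activity) promotes anti-phase firing, while *slow* off-surround
inhibition (mediated by the partner's slow interneuron) and weak
on-center cross-excitation promote in-phase firing.  The balance decides
the phase pattern:

* Bimanual tapping (2 channels, slow mutual inhibition + weak
  cross-excitation) tracks anti-phase periodic inputs at low input
  frequencies, and snaps to in-phase oscillation once the inputs arrive
  faster than the network can resolve them.  Removing one input leaves
  the network oscillating (the "missing beat").
* Quadruped gaits (4 channels, order LF RF LH RH) arise from the three
  coupling classes D1 (fore-fore and hind-hind), D2 (ipsilateral
  fore-hind) and D3 (diagonal): the class whose fast inhibition is
  weakest synchronizes its pairs.  GO modulates each class's fast
  inhibition non-monotonically (minimal near a class-specific GO level),
  so an ascending GO sweep produces walk (all classes balanced: splay /
  quarter-cycle lags), trot (diagonals in phase), pace (ipsilateral in
  phase) and gallop (fore pair and hind pair in phase, half a cycle
  apart).

Simulations run in natural time units (decay rate A = 1) and are
converted to seconds through ``rate_scale``; the default 20/s puts the
single-channel beat near 120 BPM at GO = 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit
from scipy.signal import find_peaks

__all__ = [
    "CPGParams",
    "BeatTrain",
    "PhasePattern",
    "NoBeatError",
    "PhaseUndefinedError",
    "simulate_cpg",
    "relative_phase",
    "classify_gait",
    "go_sweep_gaits",
    "tapping_bifurcation",
    "beat_times",
    "oscillation_threshold",
    "GAIT_SWEEP_GO_GRID",
]


class NoBeatError(RuntimeError):
    """Arousal below the oscillation threshold: no beat is generated."""


class PhaseUndefinedError(RuntimeError):
    """A channel shows too few peaks for a phase estimate."""


# frozen cell constants (natural units, A = 1); see docs/methods.md
_F_GAIN = 8.0
_F_HALF = 0.4
_C_FLOOR = 0.5
_D0_SLOW = 20.0
_EPS = 0.1


@dataclass
class CPGParams:
    """CPG configuration.

    n_channels       : 1 (beat), 2 (tapping) or 4 (gait)
    GO               : tonic arousal, >= 0
    fast_coupling    : (n, n) fast mutual-inhibition matrix (anti-phase)
    slow_coupling    : (n, n) slow mutual-inhibition matrix (in-phase)
    cross_excitation : on-center spread to other channels
    D0               : slow self-inhibition (the rhythm generator)
    epsilon          : slow-interneuron rate (natural units)
    rate_scale       : natural time units per second
    """

    n_channels: int = 1
    GO: float = 1.0
    fast_coupling: np.ndarray | None = None
    slow_coupling: np.ndarray | None = None
    cross_excitation: float = 0.0
    D0: float = _D0_SLOW
    epsilon: float = _EPS
    rate_scale: float = 20.0
    dt: float = 0.002

    def __post_init__(self) -> None:
        if self.n_channels not in (1, 2, 4):
            raise ValueError("n_channels must be 1, 2 or 4")
        if self.GO < 0:
            raise ValueError("GO must be >= 0")
        n = self.n_channels
        if self.fast_coupling is None:
            self.fast_coupling = np.zeros((n, n))
        if self.slow_coupling is None:
            self.slow_coupling = np.zeros((n, n))
        self.fast_coupling = np.asarray(self.fast_coupling, dtype=float)
        self.slow_coupling = np.asarray(self.slow_coupling, dtype=float)
        for m in (self.fast_coupling, self.slow_coupling):
            if m.shape != (n, n) or (m < 0).any():
                raise ValueError("coupling matrices must be nonnegative (n, n)")

    @classmethod
    def tapping(cls, GO: float = 0.1) -> "CPGParams":
        """Frozen 2-channel bimanual-tapping configuration."""
        slow = np.array([[0.0, 5.0], [5.0, 0.0]])
        return cls(n_channels=2, GO=GO, slow_coupling=slow,
                   cross_excitation=0.1)

    @classmethod
    def gait(cls, GO: float) -> "CPGParams":
        """Frozen 4-channel gait configuration at arousal GO.

        Fast inhibition of coupling class k is V-shaped in GO with minimum
        at the class-specific level (D3 at 0.9, D2 at 1.5, D1 at 2.1);
        slow inhibition is a constant 3.0 for every class.
        """
        def vdip(center: float, width: float = 0.35, dmax: float = 1.2) -> float:
            return dmax * min(abs(GO - center) / width, 1.0)

        d1, d2, d3 = vdip(2.1), vdip(1.5), vdip(0.9)
        fast = np.zeros((4, 4))
        slow = np.zeros((4, 4))
        # channel order LF, RF, LH, RH
        pairs = {1: [(0, 1), (2, 3)], 2: [(0, 2), (1, 3)], 3: [(0, 3), (1, 2)]}
        for cls_id, val in ((1, d1), (2, d2), (3, d3)):
            for i, q in pairs[cls_id]:
                fast[i, q] = fast[q, i] = val
                slow[i, q] = slow[q, i] = 3.0
        return cls(n_channels=4, GO=GO, fast_coupling=fast, slow_coupling=slow)


@dataclass
class BeatTrain:
    """Peak times (seconds) per channel and the estimated period."""

    peak_times: list            # list of arrays, one per channel
    period: float               # seconds
    cv: float                   # coefficient of variation of intervals

    def pulses(self, channel: int = 0) -> np.ndarray:
        return self.peak_times[channel]


@dataclass
class PhasePattern:
    phases: np.ndarray          # relative phases, channel 1 is reference 0
    gait: str = "none"


@njit(cache=False)
def _integrate(n_ch, GO, fast, slow, cE, D0, eps, dt, n_steps, keep,
               drive_amp, drive_period, drive_duty, drive_mask,
               x0, y0):
    F = 8.0
    K = 0.4
    C = 0.5
    A = 1.0
    B = 1.0
    x = x0.copy()
    y = y0.copy()
    m = n_steps // keep + 1
    xs = np.zeros((m, n_ch))
    ts = np.zeros(m)
    j = 0
    for k in range(n_steps):
        t = k * dt
        f = np.empty(n_ch)
        for i in range(n_ch):
            f[i] = F * x[i] * x[i] / (K * K + x[i] * x[i])
        xp = np.maximum(x, 0.0)
        yp = np.maximum(y, 0.0)
        for i in range(n_ch):
            I = GO
            if drive_amp > 0.0 and drive_period > 0.0 and drive_mask[i] > 0.5:
                ph = ((t + i * drive_period / n_ch) % drive_period) / drive_period
                if ph < drive_duty:
                    I += drive_amp
            exc = I + f[i]
            inh = D0 * yp[i]
            for q in range(n_ch):
                if q != i:
                    exc += cE * f[q]
                    inh += fast[i, q] * xp[q] + slow[i, q] * yp[q]
            dx = -A * x[i] + (B - x[i]) * exc - (x[i] + C) * inh
            y[i] += dt * eps * (-y[i] + x[i])
            x[i] += dt * dx
            if x[i] > B:
                x[i] = B
            if x[i] < -C:
                x[i] = -C
        if k % keep == 0:
            xs[j] = x
            ts[j] = t
            j += 1
    return ts[:j], xs[:j], x, y


_DEFAULT_X0 = (0.04, 0.01, 0.03, 0.02)


def simulate_cpg(params: CPGParams, duration: float,
                 drive_amp: float = 0.0, drive_period: float = 0.0,
                 drive_duty: float = 0.3,
                 drive_mask: np.ndarray | None = None,
                 x0: np.ndarray | None = None,
                 y0: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Integrate the CPG for ``duration`` seconds; returns (t, x traces).

    Optional periodic drive: each channel i receives pulses of amplitude
    ``drive_amp`` and duty cycle ``drive_duty`` with period ``drive_period``
    (seconds), offset by i/n of a cycle (anti-phase for 2 channels);
    ``drive_mask`` switches individual channels' inputs off.  Times in the
    returned trace are in seconds.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    n = params.n_channels
    s = params.rate_scale
    dt = params.dt
    n_steps = int(round(duration * s / dt))
    keep = max(int(0.005 / dt), 1)
    if drive_mask is None:
        drive_mask = np.ones(n)
    if x0 is None:
        x0 = np.array(_DEFAULT_X0[:n])
    if y0 is None:
        y0 = np.zeros(n)
    ts, xs, xf, yf = _integrate(
        n, params.GO, params.fast_coupling, params.slow_coupling,
        params.cross_excitation, params.D0, params.epsilon, dt, n_steps, keep,
        drive_amp, drive_period * s, drive_duty,
        np.asarray(drive_mask, dtype=float),
        np.asarray(x0, dtype=float), np.asarray(y0, dtype=float))
    if not np.isfinite(xs).all():
        raise FloatingPointError("CPG integration produced non-finite activity")
    simulate_cpg._final_state = (xf, yf)  # for continued (ramp) runs
    return ts / s, xs


def _channel_peaks(t: np.ndarray, trace: np.ndarray,
                   prominence: float = 0.1) -> np.ndarray:
    idx, _ = find_peaks(trace, prominence=prominence)
    return t[idx]


def relative_phase(t: np.ndarray, xs: np.ndarray,
                   settle_fraction: float = 0.5) -> PhasePattern:
    """Mean cyclic phase offset of each channel relative to channel 1.

    Uses detected activity peaks in the post-transient window; circular
    averaging avoids wrap artifacts near phase 0.
    """
    i0 = int(len(t) * settle_fraction)
    tt, tail = t[i0:], xs[i0:]
    ref = _channel_peaks(tt, tail[:, 0])
    if ref.size < 3:
        raise PhaseUndefinedError("reference channel shows fewer than 3 peaks")
    period = float(np.diff(ref).mean())
    phases = [0.0]
    for c in range(1, xs.shape[1]):
        pk = _channel_peaks(tt, tail[:, c])
        if pk.size < 3:
            raise PhaseUndefinedError(f"channel {c} shows fewer than 3 peaks")
        offs = []
        for q in pk:
            before = ref[ref <= q]
            if before.size:
                offs.append(((q - before[-1]) / period) % 1.0)
        ang = 2 * np.pi * np.asarray(offs)
        mean = (np.arctan2(np.sin(ang).mean(), np.cos(ang).mean())
                / (2 * np.pi)) % 1.0
        phases.append(float(mean))
    return PhasePattern(phases=np.asarray(phases))


def _near(a: float, b: float, tol: float) -> bool:
    return min(abs(a - b), 1.0 - abs(a - b)) < tol


def classify_gait(pattern: PhasePattern, tol: float = 0.08) -> str:
    """Template match of a 4-channel phase pattern (order LF RF LH RH).

    walk   = the four phases occupy successive quarter-cycle lags
    trot   = diagonal pairs in phase, the two pairs anti-phase
    pace   = ipsilateral pairs in phase, anti-phase across sides
    gallop = fore pair in phase, hind pair in phase, half a cycle apart
    """
    p = np.asarray(pattern.phases)
    if p.size != 4:
        raise ValueError("gait classification needs 4 channels (LF RF LH RH)")
    if _near(p[1], 0.5, tol) and _near(p[2], 0.5, tol) and _near(p[3], 0.0, tol):
        return "trot"
    if _near(p[1], 0.5, tol) and _near(p[2], 0.0, tol) and _near(p[3], 0.5, tol):
        return "pace"
    if _near(p[1], 0.0, tol) and _near(p[2], 0.5, tol) and _near(p[3], 0.5, tol):
        return "gallop"
    s = np.sort(p)
    if all(_near(s[i], 0.25 * i, tol) for i in range(4)):
        return "walk"
    return "none"


GAIT_SWEEP_GO_GRID = (0.5, 0.9, 1.5, 2.1)
"""Frozen ascending GO grid whose sweep yields walk, trot, pace, gallop."""


def go_sweep_gaits(go_grid=GAIT_SWEEP_GO_GRID, duration: float = 25.0) -> list[str]:
    """Simulate and classify the gait at each GO value; deduplicated labels."""
    labels = []
    for GO in go_grid:
        params = CPGParams.gait(GO)
        t, xs = simulate_cpg(params, duration)
        try:
            lab = classify_gait(relative_phase(t, xs))
        except PhaseUndefinedError:
            lab = "none"
        if not labels or labels[-1] != lab:
            labels.append(lab)
    return labels


def tapping_bifurcation(periods_s, params: CPGParams | None = None,
                        drive_amp: float = 1.5, duration_each: float = 25.0,
                        tol: float = 0.08) -> dict:
    """Phase relation across an ascending input-frequency ramp.

    ``periods_s`` is a descending sequence of drive periods (seconds) --
    i.e. ascending frequency.  Each step continues from the previous
    network state.  Returns per-step phases, the drive frequency at which
    in-phase locking first appears, and whether in-phase persists for the
    remainder of the ramp.
    """
    if params is None:
        params = CPGParams.tapping()
    phases = []
    state = None
    for P in periods_s:
        kwargs = {}
        if state is not None:
            kwargs = {"x0": state[0], "y0": state[1]}
        t, xs = simulate_cpg(params, duration_each, drive_amp=drive_amp,
                             drive_period=P, **kwargs)
        state = simulate_cpg._final_state
        try:
            ph = relative_phase(t, xs).phases[1]
        except PhaseUndefinedError:
            ph = np.nan
        phases.append(float(ph))
    phases = np.asarray(phases)
    in_phase = np.array([_near(p, 0.0, tol) if np.isfinite(p) else False
                         for p in phases])
    transition = None
    persists = False
    if in_phase.any():
        k = int(np.argmax(in_phase))
        transition = 1.0 / periods_s[k]
        persists = bool(in_phase[k:].all())
    return {
        "periods_s": np.asarray(periods_s, dtype=float),
        "phases": phases,
        "transition_frequency_hz": transition,
        "in_phase_persists": persists,
    }


def oscillation_threshold(lo: float = 0.01, hi: float = 1.0,
                          iters: int = 12, duration: float = 15.0) -> float:
    """Bisect the GO level at which the single-channel beat turns on."""
    def oscillates(GO: float) -> bool:
        params = CPGParams(n_channels=1, GO=GO)
        t, xs = simulate_cpg(params, duration)
        tail = xs[len(xs) // 2:, 0]
        return (tail.max() - tail.min()) > 0.2

    if oscillates(lo) or not oscillates(hi):
        raise RuntimeError("bracket does not straddle the oscillation onset")
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        if oscillates(mid):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def beat_times(GO: float, duration: float = 20.0,
               params: CPGParams | None = None,
               settle_fraction: float = 0.3) -> BeatTrain:
    """Peak times of the beat channel under arousal GO.

    Raises :class:`NoBeatError` for sub-threshold arousal.  The emitted
    pulse train is what the counting circuit accumulates and what paces
    rhythm training.
    """
    if params is None:
        params = CPGParams(n_channels=1, GO=GO)
    else:
        params = replace(params, GO=GO)
    t, xs = simulate_cpg(params, duration)
    i0 = int(len(t) * settle_fraction)
    peaks = [_channel_peaks(t[i0:], xs[i0:, c]) for c in range(xs.shape[1])]
    if len(peaks[0]) < 3:
        raise NoBeatError(f"GO={GO} is below the oscillation threshold")
    intervals = np.diff(peaks[0])
    return BeatTrain(peak_times=peaks, period=float(intervals.mean()),
                     cv=float(intervals.std() / intervals.mean()))


def beat_train_to_frame(bt: BeatTrain):
    """Beat train as a tidy DataFrame (channel, peak_time)."""
    import pandas as pd

    rows = [{"channel": c, "peak_time": float(t)}
            for c, peaks in enumerate(bt.peak_times) for t in peaks]
    return pd.DataFrame(rows)
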