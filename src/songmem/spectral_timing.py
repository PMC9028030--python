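"""Cerebellar spectral timing: learning delays with a rate spectrum.

A conditioned stimulus (CS) drives a population of cells that each react
at a different rate ``r_i``.  Cell activation follows

    dx_i/dt = r_i * (-x_i + (1 - x_i) * I_CS(t))

a sharp sigmoid readout f(x) = x^p / (beta^p + x^p) of each activation
is gated by a slowly habituating transmitter

    dy_i/dt = r_i^q * (delta0 * (1 - y_i) - rho0 * f(x_i) * y_i)

and the gated signal g_i(t) = f(x_i(t)) * y_i(t) is a unimodal pulse
whose peak time decreases with r_i.  A teaching (unconditioned-stimulus)
pulse delivered at the interstimulus interval (ISI) trains adaptive
weights z_i toward the US amplitude in proportion to how active each
gated signal is at that instant, so the learned population output
R(t) = sum_i g_i(t) * z_i peaks at the trained ISI.

The gate-rate exponent q is slightly below 1: gate kinetics almost, but
not exactly, track each cell's activation timescale.  The near-scaling
makes the width of R grow in proportion to the trained interval (Weber
law) and keeps the fraction-of-peak duration window a nearly constant
multiple of the ISI; the residual asymmetry, together with the finite
extent of the spectrum, makes the amplitude envelope across trainable
intervals an inverted U -- small near the fast edge where no cell has
risen by the teaching time, largest just above the fastest peak time,
then declining toward the slow edge.

The cerebellar circuit expresses the same signal through long-term
depression: tonically active Purkinje cells are depressed by R(t), which
*disinhibits* their target nuclear cells during the trained window.
Both conventions are exposed; they yield identical timed durations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SpectrumConfig",
    "TimingSpectrum",
    "ConditioningProtocol",
    "TimedOutput",
    "ISIRangeError",
    "NoDurationError",
    "spectral_response",
    "train",
    "population_output",
    "timed_duration",
]


class ISIRangeError(ValueError):
    """Trained interval outside the spectrum's representable range."""


class NoDurationError(RuntimeError):
    """Population output never reaches the duration threshold."""


@dataclass(frozen=True)
class SpectrumConfig:
    """Spectrum layout and frozen canonical-cell constants.

    n_cells cells with peak times geometrically spaced over
    [min_peak_time, max_peak_time] seconds.  The representable training
    range deliberately extends below the fastest peak time: intervals
    down there are learnable but weakly and with late-biased peaks, which
    is what produces the rising limb of the amplitude envelope.
    """

    n_cells: int = 40
    min_peak_time: float = 0.12
    max_peak_time: float = 6.0
    beta: float = 0.45
    power: float = 12.0
    delta0: float = 0.005
    rho0: float = 16.0
    rate_exponent: float = 0.85   # q: gate rates scale as r^q
    horizon: float = 8.0          # seconds covered by the cached basis
    sim_dt: float = 2e-4
    grid_dt: float = 5e-4         # stored basis resolution

    @property
    def representable_range(self) -> tuple[float, float]:
        return (0.05, 0.7 * self.max_peak_time)


def _simulate_cells(rates: np.ndarray, cfg: SpectrumConfig) -> tuple[np.ndarray, np.ndarray]:
    """Gated signals g_i(t) for all rates on the stored grid (vectorized)."""
    r = np.asarray(rates, dtype=float)
    dt = cfg.sim_dt
    n_steps = int(round(cfg.horizon / dt))
    keep = max(int(round(cfg.grid_dt / dt)), 1)
    gate_rate = r ** cfg.rate_exponent
    x = np.zeros_like(r)
    y = np.ones_like(r)
    t_out = []
    g_out = []
    p, beta = cfg.power, cfg.beta
    for k in range(n_steps + 1):
        f = x ** p / (beta ** p + x ** p)
        if k % keep == 0:
            t_out.append(k * dt)
            g_out.append(f * y)
        x = x + dt * r * (-x + (1.0 - x))
        y = y + dt * gate_rate * (cfg.delta0 * (1.0 - y) - cfg.rho0 * f * y)
    return np.asarray(t_out), np.asarray(g_out).T  # (n_cells, n_t)


_basis_cache: dict = {}


def _basis(cfg: SpectrumConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """(t_grid, G, rates, peak_times) for the configured spectrum, cached.

    Rates are chosen so measured peak times land on the configured
    geometric grid, via a probe sweep and log-log inversion of the
    rate -> peak-time map.
    """
    if cfg in _basis_cache:
        return _basis_cache[cfg]
    probe = np.geomspace(0.05, 40.0, 48)
    t, Gp = _simulate_cells(probe, cfg)
    peaks = t[np.argmax(Gp, axis=1)]
    want = np.geomspace(cfg.min_peak_time, cfg.max_peak_time, cfg.n_cells)
    # peak time is decreasing in rate; interpolate in descending-peak order
    rates = np.exp(np.interp(np.log(want)[::-1], np.log(peaks)[::-1],
                             np.log(probe)[::-1]))[::-1]
    t, G = _simulate_cells(rates, cfg)
    peak_times = t[np.argmax(G, axis=1)]
    out = (t, G, rates, peak_times)
    _basis_cache[cfg] = out
    return out


@dataclass
class TimingSpectrum:
    """Rate spectrum with adaptive weights z_i in [0, z_max]."""

    config: SpectrumConfig = field(default_factory=SpectrumConfig)
    weights: np.ndarray = None
    z_max: float = 1.0

    def __post_init__(self) -> None:
        if self.config.n_cells < 20:
            raise ValueError("spectrum needs at least 20 cells")
        self._t, self._G, self.rates, self.peak_times = _basis(self.config)
        if self.weights is None:
            self.weights = np.zeros(self.config.n_cells)
        else:
            self.weights = np.asarray(self.weights, dtype=float)

    def gated_signals(self, t: np.ndarray) -> np.ndarray:
        """g_i(t) for all cells; shape (n_cells, len(t))."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        out = np.empty((self.config.n_cells, t.size))
        for i in range(self.config.n_cells):
            out[i] = np.interp(t, self._t, self._G[i], right=0.0)
        return out

    def copy(self) -> "TimingSpectrum":
        return TimingSpectrum(config=self.config, weights=self.weights.copy(),
                              z_max=self.z_max)


def spectral_response(rate: float, t: np.ndarray | float,
                      config: SpectrumConfig | None = None) -> np.ndarray:
    """Gated signal g(t) of a single cell with the given reaction rate.

    Unimodal in t with peak time strictly decreasing in the rate.
    """
    if config is None:
        config = SpectrumConfig()
    tg, G = _simulate_cells(np.array([rate]), config)
    t = np.asarray(t, dtype=float)
    return np.interp(t, tg, G[0], right=0.0)


@dataclass
class ConditioningProtocol:
    """Paired CS-US training: US teaching pulse at the ISI after CS onset."""

    ISI: float
    n_trials: int = 5
    cs_duration: float | None = None   # None = sustained through the trial
    us_amplitude: float = 1.0
    learning_rate: float = 0.2

    def __post_init__(self) -> None:
        if self.ISI <= 0:
            raise ValueError("ISI must be > 0")
        if self.n_trials < 0:
            raise ValueError("n_trials must be >= 0")


def train(spectrum: TimingSpectrum, protocol: ConditioningProtocol) -> np.ndarray:
    """Update adaptive weights from paired CS-US trials; returns weights.

    Per trial, dz_i = lr * g_i(ISI) * (US - z_i): learning concentrates in
    the cells most active when the teaching signal arrives.
    """
    lo, hi = spectrum.config.representable_range
    if not (lo <= protocol.ISI <= hi):
        raise ISIRangeError(
            f"ISI {protocol.ISI} s outside representable range [{lo:.3g}, {hi:.3g}] s"
        )
    g_at_us = spectrum.gated_signals(protocol.ISI)[:, 0]
    z = spectrum.weights
    for _ in range(protocol.n_trials):
        z = z + protocol.learning_rate * g_at_us * (protocol.us_amplitude - z)
    z = np.clip(z, 0.0, spectrum.z_max)
    spectrum.weights = z
    return z


@dataclass
class TimedOutput:
    """Learned population output R(t) with the duration threshold."""

    t: np.ndarray
    R: np.ndarray
    threshold: float
    convention: str = "excitatory_R"   # or "inverted_LTD"
    purkinje_tonic: float | None = None

    @property
    def disinhibition(self) -> np.ndarray:
        """Nuclear disinhibition window under the LTD convention.

        Purkinje output is tonic P0 minus the learned signal; nuclear
        cells see max(P0 - purkinje, 0) = R, the same timed signal.
        """
        P0 = self.purkinje_tonic if self.purkinje_tonic is not None else float(self.R.max())
        purkinje = P0 - np.minimum(self.R, P0)
        return np.maximum(P0 - purkinje, 0.0)


DEFAULT_THRESHOLD_FRACTION = 0.3
"""Duration threshold as a fraction of the maximum of R (frozen)."""


def population_output(spectrum: TimingSpectrum, t: np.ndarray,
                      convention: str = "excitatory_R",
                      threshold: float | None = None) -> TimedOutput:
    """R(t) = sum_i g_i(t) * z_i on the given time grid."""
    if convention not in ("excitatory_R", "inverted_LTD"):
        raise ValueError(f"unknown convention {convention!r}")
    t = np.asarray(t, dtype=float)
    R = spectrum.weights @ spectrum.gated_signals(t)
    if threshold is None:
        threshold = DEFAULT_THRESHOLD_FRACTION * float(R.max()) if R.size else 0.0
    return TimedOutput(t=t, R=R, threshold=threshold, convention=convention,
                       purkinje_tonic=float(R.max()) if R.size else None)


def timed_duration(output: TimedOutput, threshold: float | None = None,
                   beat_period: float | None = None) -> dict:
    """Contiguous interval around the peak where R >= threshold.

    Returns {"start", "end", "duration"} in seconds, plus
    "duration_beats" (nearest half beat) when a beat period is given.
    Raises :class:`NoDurationError` when R never reaches the threshold.
    """
    theta = output.threshold if threshold is None else threshold
    signal = output.R if output.convention == "excitatory_R" else output.disinhibition
    if signal.size == 0 or signal.max() < theta or signal.max() <= 0:
        raise NoDurationError("population output never reaches the threshold")
    ipk = int(np.argmax(signal))
    above = signal >= theta
    i0 = ipk
    while i0 > 0 and above[i0 - 1]:
        i0 -= 1
    i1 = ipk
    while i1 < signal.size - 1 and above[i1 + 1]:
        i1 += 1
    t = output.t

    def cross(ia: int, ib: int) -> float:
        # linear interpolation of the theta crossing between grid points
        if ia < 0 or ib >= t.size or signal[ib] == signal[ia]:
            return float(t[max(ia, 0) if ia >= 0 else ib])
        w = (theta - signal[ia]) / (signal[ib] - signal[ia])
        return float(t[ia] + w * (t[ib] - t[ia]))

    start = cross(i0 - 1, i0) if i0 > 0 else float(t[0])
    end = cross(i1 + 1, i1) if i1 < t.size - 1 else float(t[-1])
    out = {"start": start, "end": end, "duration": end - start}
    if beat_period is not None:
        beats = round(2.0 * (end - start) / beat_period) / 2.0
        out["duration_beats"] = max(beats, 0.5)
    return out


def output_to_frame(output: TimedOutput):
    """Trace as a tidy DataFrame (t, R, disinhibition)."""
    import pandas as pd

    return pd.DataFrame({
        "t": output.t,
        "R": output.R,
        "disinhibition": output.disinhibition,
    })
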