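"""Analog numerosity map: counting by accumulation and spatial read-out.

Each event in a sequence fires a transient detector whose burst is added to
a perfect accumulator.  The accumulated total is broadcast uniformly across
a spatial map of cells whose activation thresholds increase from left to
right, so small counts activate leftward cells and large counts rightward
cells.  A single competitive sharpening pass turns the resulting activation
step into a unimodal bump whose peak position encodes the count and whose
width, measured in numerosity units, grows with the count (Weber-law
widening).  The decoded peak supplies the *rank* signal that routes
repeated items to distinct hypercolumn positions in working memory, and the
count signal that paces rhythm training.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TransientAccumulator",
    "NumberMapConfig",
    "NumberMapProfile",
    "RankSignal",
    "CapacityError",
    "accumulate",
    "map_profile",
    "rank_signal",
    "profile_width",
]


class CapacityError(ValueError):
    """Requested count/rank exceeds the calibrated map range."""


@dataclass
class TransientAccumulator:
    """Perfect integrator of transient event bursts (reset per sequence)."""

    burst_amplitude: float = 1.0
    value: float = 0.0
    reset_policy: str = "per_sequence"

    def add_events(self, n: int) -> "TransientAccumulator":
        if n < 0:
            raise ValueError("event count must be >= 0")
        return TransientAccumulator(self.burst_amplitude,
                                    self.value + self.burst_amplitude * n,
                                    self.reset_policy)

    def reset(self) -> "TransientAccumulator":
        return TransientAccumulator(self.burst_amplitude, 0.0, self.reset_policy)


def accumulate(event_count: int, h: float = 1.0) -> TransientAccumulator:
    """Accumulator holding y = h * event_count after ``event_count`` bursts."""
    if event_count < 0:
        raise ValueError("event count must be >= 0")
    if h <= 0:
        raise ValueError("burst amplitude must be > 0")
    return TransientAccumulator(burst_amplitude=h).add_events(event_count)


@dataclass
class NumberMapConfig:
    """Calibrated numerosity map.

    ``n_counts`` is the supported count range 1..N.  The map itself uses
    ``n_cells`` positions with geometrically spaced thresholds ``Gamma_j``
    spanning the count range; cell sensitivity (sigmoid slope) scales
    inversely with its threshold, so each cell's tuning width in numerosity
    units is proportional to its preferred numerosity.
    """

    n_counts: int = 16
    n_cells: int = 48
    h: float = 1.0                  # burst amplitude the map is calibrated for
    beta: float = 8.0               # dimensionless sharpness: slope_j = beta / Gamma_j
    margin: float = 0.25            # threshold range extends margin beyond 1..N
    thresholds: np.ndarray = field(init=False)
    slopes: np.ndarray = field(init=False)
    _peak_table: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        lo = self.h * (1.0 - self.margin)
        hi = self.h * self.n_counts * (1.0 + self.margin)
        self.thresholds = np.geomspace(lo, hi, self.n_cells)
        self.slopes = self.beta / self.thresholds
        # calibration table: peak position for each supported count
        peaks = []
        for k in range(1, self.n_counts + 1):
            prof = map_profile(self.h * k, self)
            peaks.append(prof.peak_position)
        self._peak_table = np.asarray(peaks)
        if not np.all(np.diff(self._peak_table) >= 1):
            raise ValueError(
                "map calibration failed: peak positions not strictly "
                "increasing over supported counts; increase n_cells or beta"
            )

    def decode(self, peak_position: int) -> int:
        """Count whose calibrated peak position is nearest ``peak_position``."""
        return int(np.argmin(np.abs(self._peak_table - peak_position))) + 1


@dataclass
class NumberMapProfile:
    """Unimodal activity bump across map positions for one accumulated total."""

    activities: np.ndarray
    thresholds: np.ndarray
    preferred_numerosity: np.ndarray  # thresholds / h: position axis in count units

    @property
    def peak_position(self) -> int:
        return int(np.argmax(self.activities))


@dataclass
class RankSignal:
    rank: int
    confidence: float


def map_profile(y: float, config: NumberMapConfig) -> NumberMapProfile:
    """Map activation profile for accumulated total ``y``.

    Raw activation of cell j is a sigmoid of the uniformly broadcast total,
    ``a_j = 1 / (1 + exp(-slope_j (y - Gamma_j)))``; since thresholds
    increase across the map this is a descending step in j.  One pass of
    on-center off-surround sharpening -- each cell inhibited by its
    higher-threshold neighbour, ``b_j = [a_j - a_{j+1}]+`` -- contrast-
    enhances the step edge into a unimodal bump centred where the total
    matches the local threshold.
    """
    if y < 0:
        raise ValueError("accumulated total must be >= 0")
    # extend by one virtual cell continuing the geometric threshold ladder,
    # so the rightmost real cell receives proper neighbour inhibition
    ratio = config.thresholds[-1] / config.thresholds[-2]
    thr = np.concatenate([config.thresholds, [config.thresholds[-1] * ratio]])
    slp = np.concatenate([config.slopes, [config.beta / thr[-1]]])
    a = 1.0 / (1.0 + np.exp(-slp * (y - thr)))
    b = np.maximum(a[:-1] - a[1:], 0.0)
    return NumberMapProfile(
        activities=b,
        thresholds=config.thresholds.copy(),
        preferred_numerosity=config.thresholds / config.h,
    )


def rank_signal(occurrence_index: int, config: NumberMapConfig | None = None) -> RankSignal:
    """Rank of the k-th occurrence of an item, decoded from the map peak.

    Runs the full transient-accumulator -> map -> competition -> decode
    chain; for the calibrated map this is the identity over 1..n_counts.
    """
    if config is None:
        config = _default_config()
    if occurrence_index < 1:
        raise ValueError("occurrence index must be >= 1")
    if occurrence_index > config.n_counts:
        raise CapacityError(
            f"occurrence index {occurrence_index} exceeds map capacity "
            f"{config.n_counts}"
        )
    acc = accumulate(occurrence_index, config.h)
    prof = map_profile(acc.value, config)
    rank = config.decode(prof.peak_position)
    conf = float(prof.activities[prof.peak_position])
    return RankSignal(rank=rank, confidence=conf)


def profile_width(profile: NumberMapProfile, level: float = 0.5) -> float:
    """Half-height width of the bump, in numerosity units.

    The position axis is graded by each cell's preferred numerosity
    (threshold / burst amplitude); width at ``level`` of the peak is
    measured on that axis by linear interpolation.
    """
    act = profile.activities
    peak = act.max()
    if peak <= 0:
        return 0.0
    thr = level * peak
    above = act >= thr
    idx = np.flatnonzero(above)
    i0, i1 = idx[0], idx[-1]
    num = profile.preferred_numerosity

    def edge(ia: int, ib: int) -> float:
        # linear interpolation of the crossing between cells ia (below) and ib
        if ia < 0 or ia >= act.size or act[ib] == act[ia]:
            return float(num[ib])
        w = (thr - act[ia]) / (act[ib] - act[ia])
        return float(num[ia] + w * (num[ib] - num[ia]))

    left = edge(i0 - 1, i0) if i0 > 0 else float(num[0])
    right = edge(i1 + 1, i1) if i1 < act.size - 1 else float(num[-1])
    return max(right - left, 0.0)


_DEFAULT: NumberMapConfig | None = None


def _default_config() -> NumberMapConfig:
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = NumberMapConfig()
    return _DEFAULT


def profile_to_frame(profile: NumberMapProfile):
    """Profile as a tidy DataFrame (position, threshold, activity)."""
    import pandas as pd

    return pd.DataFrame({
        "position": np.arange(1, profile.activities.size + 1),
        "threshold": profile.thresholds,
        "activity": profile.activities,
    })
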