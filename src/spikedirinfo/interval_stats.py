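"""ISI extraction, logarithmic binning, firing-pattern entropy, rates,
detection blanking and its ten-ninths correction, and unit inclusion.

Firing-pattern entropy H(y) = -sum_i p(y_i) log2 p(y_i) is computed over
inter-spike intervals histogrammed on log-spaced bins (default 5 bins per
decade over 1 ms - 10 s; a fine 25 bins/decade variant resolves stimulation
entrainment peaks). Units are bits/spike.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import xlogy

from .spike_io import SpikeTrain

#: spikes required for a unit to enter rate/entropy/information analyses
MIN_SPIKES_INCLUSION = 500

#: rate correction for 1 ms detection blanking per 10 ms stimulation cycle:
#: spikes are detectable for only 9 ms of every 10 ms, so measured rates
#: underestimate true rates by the factor 9/10.
BLANKING_RATE_FACTOR = 10.0 / 9.0


@dataclass(frozen=True)
class LogBinning:
    """Geometric bin edges with ``bins_per_decade`` bins per factor of ten.

    The span [t_min, t_max] must cover an integer number of decades so that
    every decade is partitioned identically. Consecutive edges have ratio
    ``10**(1/bins_per_decade)``.
    """

    bins_per_decade: int
    t_min: float
    t_max: float
    edges: np.ndarray = field(repr=False, default=None)

    def __post_init__(self):
        if not (0 < self.t_min < self.t_max):
            raise ValueError("need 0 < t_min < t_max")
        decades = np.log10(self.t_max / self.t_min)
        n_dec = round(decades)
        if abs(decades - n_dec) > 1e-9:
            raise ValueError(
                f"t_max/t_min = {self.t_max / self.t_min:g} is not an integer power of 10"
            )
        n_bins = int(self.bins_per_decade * n_dec)
        edges = self.t_min * 10.0 ** (np.arange(n_bins + 1) / self.bins_per_decade)
        edges[-1] = self.t_max  # exact upper edge despite float exponentiation
        object.__setattr__(self, "edges", edges)

    @property
    def n_bins(self) -> int:
        return self.edges.size - 1

    def centers(self) -> np.ndarray:
        """Geometric bin centers (midpoints on the log axis)."""
        return np.sqrt(self.edges[:-1] * self.edges[1:])

    def index(self, values: np.ndarray) -> np.ndarray:
        """Bin index for each value, clamping out-of-range values into the
        first/last bin so no probability mass (or sample count) is lost."""
        idx = np.searchsorted(self.edges, values, side="right") - 1
        return np.clip(idx, 0, self.n_bins - 1)


def make_log_binning(bins_per_decade: int = 5, t_min: float = 1e-3,
                     t_max: float = 10.0) -> LogBinning:
    """Standard analysis binning: 5 bins/decade (coarse) or 25 (fine) over
    1 ms - 10 s, i.e. 4 decades -> 20 or 100 bins."""
    return LogBinning(bins_per_decade=bins_per_decade, t_min=t_min, t_max=t_max)


@dataclass(frozen=True)
class IntervalDistribution:
    """Histogram of intervals on a :class:`LogBinning`, with probabilities."""

    binning: LogBinning
    counts: np.ndarray
    n: int

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=np.int64)
        object.__setattr__(self, "counts", counts)
        if counts.size != self.binning.n_bins:
            raise ValueError("counts length must equal number of bins")
        if counts.sum() != self.n:
            raise ValueError("counts must sum to n")

    @property
    def probabilities(self) -> np.ndarray:
        return self.counts / self.n

    def mode_interval(self) -> float:
        """Geometric center of the most occupied bin, seconds."""
        return float(self.binning.centers()[np.argmax(self.counts)])


def compute_isis(train: SpikeTrain) -> np.ndarray:
    """Inter-spike intervals (seconds); empty for trains with < 2 spikes."""
    if train.n_spikes < 2:
        return np.empty(0)
    return np.diff(train.times)


def interval_histogram(intervals: np.ndarray, binning: LogBinning) -> IntervalDistribution:
    """Histogram intervals on log bins; out-of-range values are clamped into
    the edge bins rather than dropped, preserving n for bias correction."""
    intervals = np.asarray(intervals, dtype=float)
    if intervals.size == 0:
        raise ValueError("cannot histogram an empty interval set")
    idx = binning.index(intervals)
    counts = np.bincount(idx, minlength=binning.n_bins)
    return IntervalDistribution(binning=binning, counts=counts, n=int(intervals.size))


def entropy_bits(p: np.ndarray) -> float:
    """Shannon entropy -sum p log2 p in bits, with 0 log 0 = 0."""
    p = np.asarray(p, dtype=float)
    return float(-xlogy(p, p).sum() / np.log(2.0))


def entropy(dist: IntervalDistribution) -> float:
    """Firing-pattern entropy of an interval distribution, bits/spike."""
    return entropy_bits(dist.probabilities)


def firing_rate(train: SpikeTrain, blanked: bool = False) -> float:
    """Mean firing rate (Hz); multiply by ten-ninths when the recording was
    subject to per-cycle detection blanking (1 ms lost per 10 ms)."""
    if train.duration <= 0:
        raise ValueError("zero-length observation window")
    rate = train.n_spikes / train.duration
    return rate * BLANKING_RATE_FACTOR if blanked else rate


def apply_blanking(train: SpikeTrain, blank_ms: float = 1.0,
                   period_ms: float = 10.0, phase_s: float = 0.0) -> SpikeTrain:
    """Remove spikes falling in a ``blank_ms`` window repeating every
    ``period_ms``, emulating stimulation-artifact detection loss.

    ``phase_s`` anchors the blanking cycle, typically the first stimulation
    pulse time; default anchors at t=0.
    """
    if not 0 <= blank_ms < period_ms:
        raise ValueError("need 0 <= blank_ms < period_ms")
    if blank_ms == 0:
        return train
    period, blank = period_ms * 1e-3, blank_ms * 1e-3
    phase = np.mod(train.times - phase_s, period)
    return train.with_times(train.times[phase >= blank])


def unit_passes_inclusion(train: SpikeTrain, min_spikes: int = MIN_SPIKES_INCLUSION) -> bool:
    """True iff the unit has at least ``min_spikes`` spike waveforms."""
    return train.n_spikes >= min_spikes
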