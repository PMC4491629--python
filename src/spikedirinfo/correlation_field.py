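"""Smoothed cross-correlation, LFP preprocessing, PSD, and unit-field cross
bicoherence.

Spike trains are converted to unit impulse series, optionally convolved with
a unit-area gaussian kernel (25 ms SD) and mean-subtracted before
correlation. LFPs are zero-phase lowpassed below 675 Hz. Cross bicoherence

    B(f1, f2) = |<L(f1) S(f2) L*(f1+f2)>|
                / sqrt(<|L(f1) S(f2)|^2> <|L(f1+f2)|^2>)

(averages over segments; L = LFP spectrum, S = spike spectrum) measures the
phase coupling between every LFP frequency f1 and every spike-train
frequency f2, and is bounded in [0, 1] by the Cauchy-Schwarz inequality.
The conjugate sum-frequency reference is taken from the LFP.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .spike_io import LFPSignal, SpikeTrain


@dataclass(frozen=True)
class Correlogram:
    lags: np.ndarray
    values: np.ndarray
    max_value: float
    lag_at_max: float
    dominant_period: float | None


@dataclass(frozen=True)
class BicoherenceMatrix:
    f1: np.ndarray
    f2: np.ndarray
    values: np.ndarray  # shape (len(f1), len(f2))
    n_segments: int

    def peak_in(self, f1_range, f2_range) -> float:
        """Maximum value in a rectangular frequency neighborhood."""
        m1 = (self.f1 >= f1_range[0]) & (self.f1 <= f1_range[1])
        m2 = (self.f2 >= f2_range[0]) & (self.f2 <= f2_range[1])
        return float(self.values[np.ix_(m1, m2)].max())


def impulse_train(train: SpikeTrain, fs: float) -> np.ndarray:
    """Unit impulse series: one impulse in the sample bin containing each
    spike (half-open bins; an edge spike falls in the later bin). Two spikes
    in one bin sum, with a warning."""
    if fs < 1000.0:
        raise ValueError("impulse conversion requires fs >= 1 kHz")
    n = int(np.ceil((train.t_stop - train.t_start) * fs))
    idx = np.floor((train.times - train.t_start) * fs).astype(int)
    idx = np.clip(idx, 0, n - 1)
    out = np.bincount(idx, minlength=n).astype(float)
    if np.any(out > 1):
        warnings.warn("multiple spikes collided in one sample bin; summed",
                      stacklevel=2)
    return out


def smoothed_signal(train: SpikeTrain, kernel_sd: float = 0.025,
                    dt: float = 0.001) -> np.ndarray:
    """Impulse train convolved with a unit-area gaussian (SD ``kernel_sd``),
    then mean-subtracted. A single spike peaks at ~1/(kernel_sd*sqrt(2*pi))."""
    if dt > kernel_sd / 5:
        raise ValueError("dt must be at most kernel_sd/5 to resolve the kernel")
    n = int(np.ceil((train.t_stop - train.t_start) / dt))
    idx = np.clip(np.floor((train.times - train.t_start) / dt).astype(int), 0, n - 1)
    imp = np.bincount(idx, minlength=n).astype(float)
    half = int(np.ceil(5 * kernel_sd / dt))
    tk = np.arange(-half, half + 1) * dt
    kernel = np.exp(-0.5 * (tk / kernel_sd) ** 2) / (kernel_sd * np.sqrt(2 * np.pi))
    out = np.convolve(imp, kernel, mode="same")
    return out - out.mean()


def cross_correlation(a: np.ndarray, b: np.ndarray, max_lag: float,
                      dt: float = 0.001,
                      period_prominence: float = 4.0) -> Correlogram:
    """Normalized (Pearson) cross-correlation of two series on a common grid,
    over lags in [-max_lag, +max_lag].

    ``dominant_period`` is reported when the correlogram's power spectrum has
    a peak at least ``period_prominence`` times its median level, else None.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size != b.size:
        raise ValueError("series must share a common sampling grid")
    n = a.size
    az = (a - a.mean())
    bz = (b - b.mean())
    denom = n * a.std() * b.std()
    if denom == 0:
        raise ValueError("constant input series")
    full = sps.correlate(az, bz, mode="full", method="fft") / denom
    lags = sps.correlation_lags(n, n) * dt
    keep = np.abs(lags) <= max_lag
    lags, values = lags[keep], full[keep]
    imax = int(np.argmax(values))
    spec = np.abs(np.fft.rfft(values - values.mean())) ** 2
    freqs = np.fft.rfftfreq(values.size, d=dt)
    dominant_period = None
    if spec.size > 2:
        body = spec[1:]
        med = np.median(body)
        k = int(np.argmax(body)) + 1
        if med > 0 and spec[k] >= period_prominence * med and freqs[k] > 0:
            dominant_period = float(1.0 / freqs[k])
    return Correlogram(lags=lags, values=values,
                       max_value=float(values[imax]),
                       lag_at_max=float(lags[imax]),
                       dominant_period=dominant_period)


def lowpass_lfp(lfp: LFPSignal, cutoff: float = 675.0) -> LFPSignal:
    """Zero-phase Butterworth lowpass below ``cutoff`` Hz (order 4, applied
    forward-backward: >= 48 dB one octave above cutoff)."""
    if lfp.fs <= 2 * cutoff:
        raise ValueError(f"fs={lfp.fs} Hz too low for a {cutoff} Hz lowpass")
    sos = sps.butter(4, cutoff, btype="low", fs=lfp.fs, output="sos")
    filtered = sps.sosfiltfilt(sos, lfp.samples)
    return LFPSignal(samples=filtered, fs=lfp.fs,
                     channel_id=lfp.channel_id, region=lfp.region)


def welch_psd(lfp: LFPSignal, segment_s: float = 1.0, overlap: float = 0.5):
    """Averaged-periodogram PSD; returns (freqs, psd) with 1/segment_s Hz
    resolution. Parseval-consistent (integrated PSD ~ variance)."""
    nper = int(round(segment_s * lfp.fs))
    if nper > lfp.samples.size:
        raise ValueError("segment longer than the record")
    if not 0 <= overlap < 1:
        raise ValueError("overlap must be in [0, 1)")
    return sps.welch(lfp.samples, fs=lfp.fs, nperseg=nper,
                     noverlap=int(nper * overlap), detrend="constant")


def _segment(x: np.ndarray, nper: int, step: int) -> np.ndarray:
    n_seg = 1 + (x.size - nper) // step
    idx = np.arange(nper)[None, :] + step * np.arange(n_seg)[:, None]
    return x[idx]


def cross_bicoherence(lfp: LFPSignal, impulse_series: np.ndarray,
                      segment_s: float = 1.0, overlap: float = 0.5,
                      f_max: float = 120.0) -> BicoherenceMatrix:
    """Unit-field cross bicoherence on a common time base.

    The LFP and the spike impulse series must be sampled at the same rate and
    length. Segments are Hann-windowed and mean-subtracted; at least 8
    segments are required for a stable estimate. ``f_max`` limits the
    reported frequency grid (the sum frequency f1+f2 must stay below
    Nyquist).
    """
    x = np.asarray(lfp.samples, float)
    s = np.asarray(impulse_series, float)
    if x.size != s.size:
        raise ValueError("LFP and impulse series must share a common time base")
    fs = lfp.fs
    nper = int(round(segment_s * fs))
    step = max(1, int(round(nper * (1 - overlap))))
    if x.size < nper:
        raise ValueError("record shorter than one segment")
    n_seg = 1 + (x.size - nper) // step
    if n_seg < 8:
        raise ValueError(f"only {n_seg} segments; need at least 8")
    if 2 * f_max >= fs / 2:
        raise ValueError("f_max too high: f1+f2 must stay below Nyquist")
    win = sps.windows.hann(nper)
    xs = _segment(x, nper, step)
    ss = _segment(s, nper, step)
    xs = (xs - xs.mean(axis=1, keepdims=True)) * win
    ss = (ss - ss.mean(axis=1, keepdims=True)) * win
    L = np.fft.rfft(xs, axis=1)
    S = np.fft.rfft(ss, axis=1)
    freqs = np.fft.rfftfreq(nper, d=1.0 / fs)
    k_max = int(np.searchsorted(freqs, f_max, side="right"))
    f = freqs[1:k_max]          # skip DC
    k = np.arange(1, k_max)
    ksum = k[:, None] + k[None, :]
    nf = k.size
    acc_num = np.zeros((nf, nf), dtype=complex)
    acc_cross2 = np.zeros((nf, nf))
    acc_sum2 = np.zeros((nf, nf))
    for seg in range(n_seg):  # accumulate per segment to bound memory
        cross = L[seg, k][:, None] * S[seg, k][None, :]   # L(f1) S(f2)
        Lsum = L[seg, ksum]                               # L(f1+f2)
        acc_num += cross * np.conj(Lsum)
        acc_cross2 += np.abs(cross) ** 2
        acc_sum2 += np.abs(Lsum) ** 2
    num = np.abs(acc_num / n_seg)
    den = np.sqrt((acc_cross2 / n_seg) * (acc_sum2 / n_seg))
    with np.errstate(invalid="ignore", divide="ignore"):
        b = np.where(den > 0, num / den, 0.0)
    return BicoherenceMatrix(f1=f, f2=f.copy(), values=b, n_segments=n_seg)
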