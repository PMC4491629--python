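"""Synthetic recordings with the statistical structure the analysis assumes.

Three condition archetypes are generated:

* ``control`` — mutually independent background units firing with
  Poisson-like statistics at a few to a few tens of Hz.
* ``hPD`` (hemiparkinsonian) — cross-region pairs coupled by rate switching
  (a source spike slows the target for a short window, reproducing the
  conditioned-ISI separation between a fast ~40 ms mode and a slow ~250 ms
  mode), plus a shared beta (~28 Hz) field that phase-modulates the units.
* ``DBS`` — units entrained to 100 Hz periodic stimulation (ISI peaks at
  10 ms and subharmonics), coupling removed, per-cycle detection blanking
  applied, stimulation pulse times recorded.

All spike generation carries a 1 ms absolute refractory floor, implemented
as a dead-time renewal process whose exponential part is rate-compensated so
the realized mean rate equals the nominal rate exactly.

Every generator is deterministic given (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .interval_stats import apply_blanking
from .spike_io import BehaviorTrack, LFPSignal, RecordingSession, SpikeTrain

REFRACTORY_S = 1e-3

#: default trial length, seconds (15-minute electrophysiology trials)
DEFAULT_DURATION_S = 900.0


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CoupledPairSpec:
    """Rate-switching coupling: after each source spike (plus ``delay``) the
    target fires at ``target_coupled_rate`` for ``effect_window`` seconds,
    otherwise at ``target_base_rate``.

    Defaults give a source at 1 Hz gating the target between a fast 25 Hz
    regime (ISI mode ~40 ms) and a slow 4 Hz regime (ISI mode ~250 ms)."""

    source_rate: float = 1.0
    target_base_rate: float = 25.0
    target_coupled_rate: float = 4.0
    effect_window: float = 1.0
    delay: float = 0.0
    duration: float = DEFAULT_DURATION_S
    seed: int = 0

    def __post_init__(self):
        if min(self.source_rate, self.target_base_rate, self.target_coupled_rate) < 0:
            raise ValueError("rates must be non-negative")
        if self.effect_window <= 0 or self.duration <= 0:
            raise ValueError("effect_window and duration must be positive")
        if self.delay < 0:
            raise ValueError("delay must be non-negative")


@dataclass(frozen=True)
class EntrainmentSpec:
    """Stimulation entrainment: each pulse of a ``stim_rate`` grid elicits a
    spike with probability ``p_spike_per_pulse`` at pulse time + ``latency_s``
    + gaussian jitter. ``latency_s`` models the post-pulse spike latency and
    keeps entrained spikes out of the 1 ms artifact-blanking window."""

    stim_rate: float = 100.0
    p_spike_per_pulse: float = 0.9
    jitter_sd: float = 0.3e-3
    duration: float = DEFAULT_DURATION_S
    seed: int = 0
    latency_s: float = 3e-3

    def __post_init__(self):
        if not 0 <= self.p_spike_per_pulse <= 1:
            raise ValueError("p_spike_per_pulse must be in [0, 1]")
        if self.stim_rate <= 0:
            raise ValueError("stim_rate must be positive")


@dataclass(frozen=True)
class BetaFieldSpec:
    """Common beta-band oscillation driving both an LFP and a phase-locked
    unit. The LFP carries a weak, phase-locked second harmonic (relative
    amplitude ``harmonic``) so the third-order bispectrum has nonzero ground
    truth; ``locking_strength`` is a von-Mises-style concentration of spike
    phase on the beta cycle."""

    f_beta: float = 28.0
    lfp_noise_sd: float = 0.5
    locking_strength: float = 2.0
    unit_rate: float = 20.0
    fs: float = 1000.0
    duration: float = 60.0
    seed: int = 0
    harmonic: float = 0.3

    def __post_init__(self):
        if self.f_beta >= self.fs / 2:
            raise ValueError("f_beta must be below Nyquist")
        if self.locking_strength < 0:
            raise ValueError("locking_strength must be non-negative")


# ---------------------------------------------------------------------------
# Point-process primitives
# ---------------------------------------------------------------------------

def _renewal_times(rate: float, duration: float, rng: np.random.Generator,
                   refractory: float = REFRACTORY_S) -> np.ndarray:
    """Dead-time renewal process: ISI = refractory + Exp(rate') with the
    exponential rate compensated so the mean ISI is exactly 1/rate."""
    if rate < 0:
        raise ValueError("rate must be non-negative")
    if rate == 0:
        return np.empty(0)
    if rate * refractory >= 1:
        raise ValueError(f"rate {rate} Hz incompatible with {refractory}s refractory floor")
    rate_c = rate / (1.0 - rate * refractory)
    n_guess = int(rate * duration + 6 * np.sqrt(rate * duration) + 16)
    times = []
    t = 0.0
    while t < duration:
        isis = refractory + rng.exponential(1.0 / rate_c, size=n_guess)
        block = t + np.cumsum(isis)
        times.append(block[block < duration])
        t = block[-1]
    return np.concatenate(times) if times else np.empty(0)


def _make_train(times: np.ndarray, unit_id: str, region: str,
                duration: float) -> SpikeTrain:
    return SpikeTrain(unit_id=unit_id, region=region, times=times,
                      t_start=0.0, t_stop=duration)


def gen_poisson_train(rate: float, duration: float, seed: int | None = 0,
                      unit_id: str = "unit", region: str = "other") -> SpikeTrain:
    """Homogeneous background train at ``rate`` Hz on [0, duration] with the
    package-wide 1 ms refractory floor; exact nominal mean rate."""
    rng = np.random.default_rng(seed)
    return _make_train(_renewal_times(rate, duration, rng), unit_id, region, duration)


def gen_coupled_pair(spec: CoupledPairSpec, source_id: str = "src",
                     target_id: str = "tgt", source_region: str = "SNr",
                     target_region: str = "VA"):
    """Generate a (source, target) pair with rate-switching coupling.

    The target is drawn by thinning a dead-time renewal process at the
    maximum of the two target rates: each candidate spike is kept with
    probability rate(t)/max_rate, where rate(t) is the coupled rate whenever
    a source spike occurred in the window [t - delay - effect_window,
    t - delay). With equal rates the construction reduces exactly to an
    independent background train.
    """
    rng = np.random.default_rng(spec.seed)
    src = _renewal_times(spec.source_rate, spec.duration, rng)
    r_max = max(spec.target_base_rate, spec.target_coupled_rate)
    cand = _renewal_times(r_max, spec.duration, rng)
    if cand.size and src.size:
        # source spike in (t - delay - window, t - delay] <=> coupled regime
        lo = np.searchsorted(src, cand - spec.delay - spec.effect_window, side="right")
        hi = np.searchsorted(src, cand - spec.delay, side="right")
        in_window = hi > lo
    else:
        in_window = np.zeros(cand.size, dtype=bool)
    p = np.where(in_window, spec.target_coupled_rate / r_max,
                 spec.target_base_rate / r_max)
    keep = rng.random(cand.size) < p
    source = _make_train(src, source_id, source_region, spec.duration)
    target = _make_train(cand[keep], target_id, target_region, spec.duration)
    return source, target


def gen_entrained_train(spec: EntrainmentSpec, unit_id: str = "unit",
                        region: str = "other") -> SpikeTrain:
    """Unit entrained to periodic stimulation: one spike per pulse with
    probability p, jittered; 1 ms refractory floor enforced by dropping the
    later of any conflicting pair."""
    rng = np.random.default_rng(spec.seed)
    pulses = np.arange(0.0, spec.duration, 1.0 / spec.stim_rate)
    fired = rng.random(pulses.size) < spec.p_spike_per_pulse
    t = pulses[fired] + spec.latency_s
    if spec.jitter_sd > 0:
        t = t + rng.normal(0.0, spec.jitter_sd, size=t.size)
    t = np.sort(t)
    t = t[(t >= 0) & (t < spec.duration)]
    t = _enforce_refractory(t)
    return _make_train(t, unit_id, region, spec.duration)


def _enforce_refractory(times: np.ndarray, refractory: float = REFRACTORY_S) -> np.ndarray:
    if times.size < 2:
        return times
    keep = np.ones(times.size, dtype=bool)
    last = times[0]
    for i in range(1, times.size):
        if times[i] - last < refractory:
            keep[i] = False
        else:
            last = times[i]
    return times[keep]


def _phase_modulated_train(rate: float, f: float, kappa: float, phase0: float,
                           duration: float, rng: np.random.Generator) -> np.ndarray:
    """Spike train whose intensity is modulated by the phase of a common
    oscillation, lambda(t) ∝ exp(kappa cos(2 pi f t + phase0)), normalized so
    the cycle-average rate equals ``rate``. Implemented by thinning."""
    from scipy.special import i0
    if kappa == 0:
        return _renewal_times(rate, duration, rng)
    peak = rate * np.exp(kappa) / i0(kappa)
    cand = _renewal_times(peak, duration, rng)
    p = np.exp(kappa * (np.cos(2 * np.pi * f * cand + phase0) - 1.0))
    return cand[rng.random(cand.size) < p]


def gen_beta_unit_lfp(spec: BetaFieldSpec, unit_id: str = "unit",
                      channel_id: str = "ch", region: str = "SNr"):
    """A beta-oscillation LFP and a unit phase-locked to it.

    LFP = sin(2 pi f t) + harmonic * sin(4 pi f t + pi/4) + white noise; the
    phase-locked harmonic endows the field with bispectral content so unit-
    field cross bicoherence has a designed (f_beta, f_beta) peak.
    """
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.fs * spec.duration))
    t = np.arange(n) / spec.fs
    w = 2 * np.pi * spec.f_beta
    samples = (np.sin(w * t)
               + spec.harmonic * np.sin(2 * w * t + np.pi / 4)
               + rng.normal(0.0, spec.lfp_noise_sd, size=n))
    lfp = LFPSignal(samples=samples, fs=spec.fs, channel_id=channel_id,
                    region=region)
    spikes = _phase_modulated_train(spec.unit_rate, spec.f_beta,
                                    spec.locking_strength, 0.0,
                                    spec.duration, rng)
    train = _make_train(spikes, unit_id, region, spec.duration)
    return train, lfp


# ---------------------------------------------------------------------------
# Behavior
# ---------------------------------------------------------------------------

def gen_behavior_track(rotation_bias: float = 0.0, duration: float = 3600.0,
                       fs: float = 8.0, seed: int | None = 0,
                       heading_noise: float = 20.0,
                       box_cm=(30.0, 45.0)) -> BehaviorTrack:
    """Random-walk locomotion in a 30x45 cm box with a net heading drift.

    ``rotation_bias`` is deg/s of net clockwise (rightward) turning;
    ``heading_noise`` is the diffusion scale in deg/sqrt(s). Position follows
    the heading with a small speed and reflects off the walls.
    """
    if not 5.0 <= fs <= 10.0:
        raise ValueError("behavior sampling rate must be within 5-10 Hz")
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    dt = 1.0 / fs
    dheading = rotation_bias * dt + heading_noise * np.sqrt(dt) * rng.standard_normal(n)
    heading = np.cumsum(dheading)
    speed = 5.0  # cm/s, typical slow exploration
    dx = speed * dt * np.cos(np.deg2rad(heading))
    dy = speed * dt * np.sin(np.deg2rad(heading))
    x = _reflect(np.cumsum(dx) + box_cm[0] / 2, box_cm[0])
    y = _reflect(np.cumsum(dy) + box_cm[1] / 2, box_cm[1])
    return BehaviorTrack(t=np.arange(n) * dt, x=x, y=y,
                         heading=np.mod(heading, 360.0))


def _reflect(pos: np.ndarray, width: float) -> np.ndarray:
    pos = np.mod(pos, 2 * width)
    return np.where(pos > width, 2 * width - pos, pos)


# ---------------------------------------------------------------------------
# Whole sessions
# ---------------------------------------------------------------------------

def _lognormal_rates(n: int, rng: np.random.Generator,
                     lo: float = 8.0, hi: float = 30.0) -> np.ndarray:
    """Unit background rates, log-uniform on [lo, hi] Hz (skewed-right, as
    observed rate distributions are)."""
    return np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))


def gen_session(condition: str, n_snr_units: int = 4, n_va_units: int = 5,
                seed: int | None = 0, duration: float = DEFAULT_DURATION_S,
                coupled_rate_ratio: float = 0.16,
                beta_locking: float = 0.8,
                include_lfp: bool = True) -> RecordingSession:
    """Generate a full synthetic 15-min-equivalent recording session.

    ``control``: independent units. ``hPD``: each VA unit rate-switched by
    one SNr unit (coupled rate = ``coupled_rate_ratio`` x base rate, 1 s
    effect window) and all units weakly phase-locked to a common 28 Hz beta
    field. ``DBS``: independent background plus 100 Hz-entrained spikes,
    stimulation pulse times recorded and per-cycle detection blanking
    applied.
    """
    if n_snr_units < 1 or n_va_units < 1:
        raise ValueError("need at least one unit per region")
    rng = np.random.default_rng(seed)
    meta = {"seed": -1 if seed is None else int(seed), "synthetic": True,
            "generator": "spikedirinfo.synthetic_data.gen_session"}
    trains: list[SpikeTrain] = []
    lfps: list[LFPSignal] = []
    stim = None

    labels = [("SNr", f"snr{i:02d}") for i in range(n_snr_units)] + \
             [("VA", f"va{i:02d}") for i in range(n_va_units)]

    if condition == "control":
        rates = _lognormal_rates(len(labels), rng)
        for (region, uid), r in zip(labels, rates):
            sub = np.random.default_rng(rng.integers(2 ** 31))
            trains.append(_make_train(_renewal_times(r, duration, sub),
                                      uid, region, duration))
        if include_lfp:
            lfps.append(LFPSignal(rng.normal(0, 0.5, int(1000 * duration)),
                                  fs=1000.0, channel_id="lfp_snr", region="SNr"))
    elif condition == "hPD":
        f_beta = 28.0
        src_rates = _lognormal_rates(n_snr_units, rng, lo=1.0, hi=3.0)
        snr_times = []
        for i in range(n_snr_units):
            sub = np.random.default_rng(rng.integers(2 ** 31))
            # SNr sources phase-locked to the common beta field
            snr_times.append(_phase_modulated_train(
                src_rates[i], f_beta, beta_locking, 0.0, duration, sub))
            trains.append(_make_train(snr_times[i], f"snr{i:02d}", "SNr", duration))
        va_rates = _lognormal_rates(n_va_units, rng, lo=15.0, hi=30.0)
        for j in range(n_va_units):
            src = snr_times[j % n_snr_units]
            base = va_rates[j]
            coupled = base * coupled_rate_ratio
            sub = np.random.default_rng(rng.integers(2 ** 31))
            cand = _renewal_times(base, duration, sub)
            lo_i = np.searchsorted(src, cand - 1.0, side="right")
            hi_i = np.searchsorted(src, cand, side="right")
            p = np.where(hi_i > lo_i, coupled / base, 1.0)
            kept = cand[sub.random(cand.size) < p]
            trains.append(_make_train(kept, f"va{j:02d}", "VA", duration))
        if include_lfp:
            n = int(1000 * duration)
            t = np.arange(n) / 1000.0
            w = 2 * np.pi * f_beta
            lfps.append(LFPSignal(
                np.sin(w * t) + 0.3 * np.sin(2 * w * t + np.pi / 4)
                + rng.normal(0, 0.5, n),
                fs=1000.0, channel_id="lfp_snr", region="SNr"))
    elif condition == "DBS":
        stim = np.arange(0.0, duration, 0.01)
        rates = _lognormal_rates(len(labels), rng, lo=3.0, hi=10.0)
        for (region, uid), r in zip(labels, rates):
            sub = np.random.default_rng(rng.integers(2 ** 31))
            bg = _renewal_times(r, duration, sub)
            ent = gen_entrained_train(
                EntrainmentSpec(p_spike_per_pulse=float(sub.uniform(0.15, 0.35)),
                                jitter_sd=0.5e-3, duration=duration,
                                seed=int(sub.integers(2 ** 31))),
            ).times
            merged = _enforce_refractory(np.sort(np.concatenate([bg, ent])))
            tr = _make_train(merged, uid, region, duration)
            trains.append(apply_blanking(tr, blank_ms=1.0, period_ms=10.0,
                                         phase_s=float(stim[0])))
        if include_lfp:
            n = int(1000 * duration)
            t = np.arange(n) / 1000.0
            lfps.append(LFPSignal(
                0.8 * np.sin(2 * np.pi * 100.0 * t) + rng.normal(0, 0.5, n),
                fs=1000.0, channel_id="lfp_snr", region="SNr"))
    else:
        raise ValueError(f"unknown condition {condition!r}")

    return RecordingSession(condition=condition, trains=trains, lfps=lfps,
                            stim_pulse_times=stim, meta=meta)
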