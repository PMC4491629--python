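"""Per-session analysis orchestration and cross-condition comparison.

``run_session_analysis`` assembles, for one recording session: per-unit
rates (ten-ninths corrected when the session was blanked) and firing-pattern
entropies; per-pair directed information in both anatomical directions; a
population null fit and significant-pair fractions; and optional spectral
products (PSDs, unit-field cross bicoherence, smoothed cross-correlations).
``compare_conditions`` summarizes several such reports with bootstrap means,
25-75% CIs, and pairwise p_bca values.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import correlation_field as cf
from .directed_info import (
    Z_THRESHOLD_DEFAULT,
    classify_informative,
    fit_null_sigma,
    pairwise_information_table,
)
from .interval_stats import (
    MIN_SPIKES_INCLUSION,
    compute_isis,
    entropy,
    firing_rate,
    interval_histogram,
    make_log_binning,
    unit_passes_inclusion,
)
from .spike_io import RecordingSession


@dataclass
class AnalysisConfig:
    """Every analysis default in one place (documented units).

    bins_per_decade: log-ISI resolution (5 coarse / 25 fine)
    t_min_s, t_max_s: ISI bin range, seconds (integer decades)
    n_shuffles: CSI permutations for the bias correction
    z_threshold: null SD multiples for pair significance (alpha = 0.05)
    min_spikes: unit inclusion threshold (spike waveforms)
    kernel_sd_s: gaussian smoothing SD for cross-correlation, seconds
    blank_ms, period_ms: detection-blanking geometry for DBS artifact
    n_boot: bootstrap resamples; ci_quantiles: reported CI span
    segment_s, overlap: spectral segmentation for PSD/bicoherence
    """

    bins_per_decade: int = 5
    t_min_s: float = 1e-3
    t_max_s: float = 10.0
    n_shuffles: int = 100
    z_threshold: float = Z_THRESHOLD_DEFAULT
    min_spikes: int = MIN_SPIKES_INCLUSION
    kernel_sd_s: float = 0.025
    blank_ms: float = 1.0
    period_ms: float = 10.0
    n_boot: int = 100_000
    ci_quantiles: tuple = (0.25, 0.75)
    segment_s: float = 1.0
    overlap: float = 0.5
    seed: int = 0
    compute_spectra: bool = False
    compute_correlograms: bool = False
    #: impose the DBS detection blanking on control/hPD trains before
    #: analysis (robustness check that the artifact gap does not drive
    #: information differences between conditions)
    impose_blanking: bool = False

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as f:
            raw = yaml.safe_load(f) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        unknown = set(raw) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "ci_quantiles" in known:
            known["ci_quantiles"] = tuple(known["ci_quantiles"])
        return cls(**known)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["ci_quantiles"] = list(d["ci_quantiles"])
        with open(path, "w") as f:
            yaml.safe_dump(d, f, sort_keys=False)


@dataclass
class SessionReport:
    """All per-session analysis products."""

    condition: str
    unit_table: pd.DataFrame
    pair_table: pd.DataFrame
    null_sigma: Optional[float]
    fraction_significant: dict
    psd: dict = field(default_factory=dict)           # channel -> (f, Pxx)
    bicoherence: dict = field(default_factory=dict)   # (channel, unit) -> BicoherenceMatrix
    correlograms: dict = field(default_factory=dict)  # (unit_a, unit_b) -> Correlogram

    def to_dir(self, path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        self.unit_table.to_csv(path / "units.csv", index=False)
        self.pair_table.to_csv(path / "pairs.csv", index=False)
        summary = {
            "condition": self.condition,
            "null_sigma": self.null_sigma,
            "fraction_significant": self.fraction_significant,
        }
        with open(path / "summary.json", "w") as f:
            json.dump(summary, f, indent=2)

    @classmethod
    def from_dir(cls, path) -> "SessionReport":
        path = Path(path)
        with open(path / "summary.json") as f:
            summary = json.load(f)
        return cls(
            condition=summary["condition"],
            unit_table=pd.read_csv(path / "units.csv"),
            pair_table=pd.read_csv(path / "pairs.csv"),
            null_sigma=summary["null_sigma"],
            fraction_significant=summary["fraction_significant"],
        )


def run_session_analysis(session: RecordingSession,
                         config: AnalysisConfig | None = None) -> SessionReport:
    """Run the full per-session analysis.

    Firing rates of blanked (DBS) sessions are ten-ninths corrected; the
    correction never touches entropies or information. The population null
    is fit on the pooled I_dir of the session when enough negative values
    exist, otherwise significance columns are NaN with a warning.
    """
    cfg = config or AnalysisConfig()
    binning = make_log_binning(cfg.bins_per_decade, cfg.t_min_s, cfg.t_max_s)
    blanked = session.condition == "DBS"
    if cfg.impose_blanking and not blanked:
        from .interval_stats import apply_blanking
        from .spike_io import RecordingSession as _RS
        session = _RS(
            condition=session.condition,
            trains=[apply_blanking(tr, cfg.blank_ms, cfg.period_ms)
                    for tr in session.trains],
            lfps=session.lfps, stim_pulse_times=session.stim_pulse_times,
            behavior=session.behavior, meta=session.meta)
        blanked = True

    unit_rows = []
    for tr in session.trains:
        included = unit_passes_inclusion(tr, cfg.min_spikes)
        rate = firing_rate(tr, blanked=blanked)
        ent = np.nan
        if included:
            isis = compute_isis(tr)
            if isis.size:
                ent = entropy(interval_histogram(isis, binning))
        unit_rows.append((tr.unit_id, tr.region, tr.n_spikes, rate, ent, included))
    unit_table = pd.DataFrame(unit_rows, columns=[
        "unit_id", "region", "n_spikes", "rate_hz", "entropy_bits", "included"])
    if not unit_table["included"].any():
        raise ValueError("no units pass the inclusion threshold")

    pair_table = pairwise_information_table(
        session, direction="both", binning=binning,
        n_shuffles=cfg.n_shuffles, seed=cfg.seed, min_spikes=cfg.min_spikes)

    null_sigma = None
    fraction_significant = {}
    i_dir = pair_table["I_dir"].to_numpy()
    try:
        null = fit_null_sigma(i_dir[~np.isnan(i_dir)],
                              z_threshold=cfg.z_threshold)
        null_sigma = null.sigma
        flags, _ = classify_informative(np.nan_to_num(i_dir, nan=-np.inf), null)
        pair_table["significant"] = flags
        for d, grp in pair_table.groupby("direction"):
            fraction_significant[d] = float(grp["significant"].mean())
    except ValueError as exc:
        warnings.warn(f"population null not fit for this session: {exc}",
                      stacklevel=2)
        pair_table["significant"] = np.nan

    psd, bicoh, correlograms = {}, {}, {}
    if cfg.compute_spectra:
        for lfp in session.lfps:
            filtered = cf.lowpass_lfp(lfp) if lfp.fs > 1350.0 else lfp
            psd[lfp.channel_id] = cf.welch_psd(filtered, cfg.segment_s, cfg.overlap)
            for tr in session.trains:
                if tr.region == lfp.region and unit_passes_inclusion(tr, cfg.min_spikes):
                    imp = cf.impulse_train(tr, filtered.fs)
                    n = min(imp.size, filtered.samples.size)
                    bicoh[(lfp.channel_id, tr.unit_id)] = cf.cross_bicoherence(
                        type(filtered)(filtered.samples[:n], filtered.fs,
                                       filtered.channel_id, filtered.region),
                        imp[:n], cfg.segment_s, cfg.overlap)
                    break  # one unit per channel keeps the default run light
    if cfg.compute_correlograms:
        included = [tr for tr in session.trains
                    if unit_passes_inclusion(tr, cfg.min_spikes)]
        dt = cfg.kernel_sd_s / 5
        smoothed = {tr.unit_id: cf.smoothed_signal(tr, cfg.kernel_sd_s, dt)
                    for tr in included}
        for i, a in enumerate(included):
            for b in included[i + 1:]:
                correlograms[(a.unit_id, b.unit_id)] = cf.cross_correlation(
                    smoothed[a.unit_id], smoothed[b.unit_id],
                    max_lag=0.5, dt=dt)

    return SessionReport(condition=session.condition, unit_table=unit_table,
                         pair_table=pair_table, null_sigma=null_sigma,
                         fraction_significant=fraction_significant,
                         psd=psd, bicoherence=bicoh, correlograms=correlograms)


def compare_conditions(reports: dict, config: AnalysisConfig | None = None):
    """Compare I_dir across conditions.

    ``reports`` maps condition name -> SessionReport or list of
    SessionReports (pooled). Returns (summary_df, pvals_df): bootstrap mean
    and CI of I_dir per condition/direction, and the pairwise p_bca matrix
    per direction.
    """
    from .stats_boot import bootstrap_compare, bootstrap_mean_ci

    cfg = config or AnalysisConfig()
    if len(reports) < 2:
        raise ValueError("need at least 2 conditions to compare")
    pooled = {}
    for cond, rep in reports.items():
        reps = rep if isinstance(rep, (list, tuple)) else [rep]
        table = pd.concat([r.pair_table for r in reps], ignore_index=True)
        for d, grp in table.groupby("direction"):
            v = grp["I_dir"].dropna().to_numpy()
            pooled[(cond, d)] = v

    directions = sorted({d for (_, d) in pooled})
    rows = []
    for (cond, d), v in sorted(pooled.items()):
        if v.size < 2:
            warnings.warn(f"{cond}/{d}: fewer than 2 pairs; degenerate CI",
                          stacklevel=2)
            rows.append((cond, d, float(v.mean()) if v.size else np.nan,
                         np.nan, np.nan, v.size))
            continue
        mean, lo, hi = bootstrap_mean_ci(v, cfg.n_boot, cfg.ci_quantiles,
                                         seed=cfg.seed)
        rows.append((cond, d, mean, lo, hi, v.size))
    summary = pd.DataFrame(rows, columns=[
        "condition", "direction", "mean_I_dir", "ci_low", "ci_high", "n_pairs"])

    prow = []
    conds = sorted({c for (c, _) in pooled})
    for d in directions:
        for i, a in enumerate(conds):
            for b in conds[i + 1:]:
                va, vb = pooled.get((a, d)), pooled.get((b, d))
                if va is None or vb is None:
                    raise ValueError(f"direction {d!r} missing for {a!r} or {b!r}")
                if va.size < 2 or vb.size < 2:
                    p = np.nan
                else:
                    p = bootstrap_compare(va, vb, cfg.n_boot, seed=cfg.seed)
                prow.append((d, a, b, p))
    pvals = pd.DataFrame(prow, columns=["direction", "condition_a",
                                        "condition_b", "p_bca"])
    return summary, pvals
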