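"""Directed information between simultaneously recorded spike-train pairs.

For a target unit y and source unit x, each target spike k (from the second
onward) contributes an index-aligned pair: its inter-spike interval isi_k and
its cross-spike interval csi_k, the time back to the most recent source spike
strictly before it. Both are histogrammed on identical log bins. From the
joint distribution p(y_i, x_j):

    H_naive = H(y)                     (ISI marginal entropy)
    H_cond  = H(y, x) - H(x)           (conditional entropy of ISI given CSI)
    I_cond  = H_naive - H_cond >= 0    (mutual information; positively biased
                                        at finite n even for independent cells)
    I_shuf  = H_naive - <H_shuf>       (same quantity after randomly permuting
                                        the CSI sequence, averaged over
                                        n_shuffles permutations: the bias an
                                        independent pair of these marginals
                                        would show)
    I_dir   = I_cond - I_shuf          (bias-corrected directed information,
                                        bits/spike; may be negative for
                                        independent pairs)

Across a population of truly independent pairs I_dir is approximately
gaussian with zero mean; the null standard deviation is fit as a half-normal
MLE on the negative side, and pairs at least ``z`` (default 1.645, the 95th
standard-normal percentile) standard deviations above zero are classified
significantly informative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .interval_stats import (
    LogBinning,
    MIN_SPIKES_INCLUSION,
    entropy_bits,
    make_log_binning,
    unit_passes_inclusion,
)
from .spike_io import RecordingSession, SpikeTrain

#: z threshold for one-sided significance at alpha = 0.05
Z_THRESHOLD_DEFAULT = 1.645

DEFAULT_N_SHUFFLES = 100


@dataclass(frozen=True)
class CsiPairedSeries:
    """Index-aligned (isi_k, csi_k) samples for one ordered pair of units."""

    isi: np.ndarray
    csi: np.ndarray
    target_id: str = ""
    source_id: str = ""

    def __post_init__(self):
        object.__setattr__(self, "isi", np.asarray(self.isi, dtype=float))
        object.__setattr__(self, "csi", np.asarray(self.csi, dtype=float))
        if self.isi.size != self.csi.size:
            raise ValueError("isi and csi must be index-aligned (equal length)")
        if self.isi.size and (np.any(self.isi <= 0) or np.any(self.csi <= 0)):
            raise ValueError("intervals must be strictly positive")

    @property
    def n_pairs(self) -> int:
        return int(self.isi.size)


@dataclass(frozen=True)
class JointDistribution:
    """2-D histogram p(y_i, x_j) of (ISI, CSI) pairs on shared log bins."""

    binning: LogBinning
    joint: np.ndarray        # (n_bins, n_bins) probabilities
    n: int

    @property
    def p_isi(self) -> np.ndarray:
        return self.joint.sum(axis=1)

    @property
    def p_csi(self) -> np.ndarray:
        return self.joint.sum(axis=0)


@dataclass(frozen=True)
class PairInformation:
    """Entropy and information summary for one ordered pair, bits/spike."""

    H_naive: float
    H_cond: float
    I_cond: float
    I_shuf: float
    I_dir: float
    n_pairs: int
    n_shuffles: int
    seed: int | None = None
    target_id: str = ""
    source_id: str = ""


@dataclass(frozen=True)
class PopulationNull:
    """Half-normal null fit to the negative side of a population of I_dir."""

    sigma: float
    n_negative: int
    z_threshold: float = Z_THRESHOLD_DEFAULT


def compute_csi_series(target: SpikeTrain, source: SpikeTrain) -> CsiPairedSeries:
    """Build the paired (ISI, CSI) series for information directed from
    ``source`` to ``target``.

    For each target spike from the second onward, csi is the interval back to
    the most recent source spike *strictly* before it; target spikes with no
    earlier source spike are dropped. The construction is directional:
    swapping the roles of the trains gives a different series in general.
    """
    tt, ts = target.times, source.times
    if tt.size < 2 or ts.size == 0:
        return CsiPairedSeries(np.empty(0), np.empty(0),
                               target.unit_id, source.unit_id)
    isi = np.diff(tt)
    spikes = tt[1:]
    prev = np.searchsorted(ts, spikes, side="left") - 1
    ok = prev >= 0
    csi = spikes[ok] - ts[prev[ok]]
    # a source spike exactly coincident with the target spike is "not strictly
    # earlier": step back one more source spike, dropping if none exists
    coincident = csi == 0
    if np.any(coincident):
        prev_ok = prev[ok]
        prev_ok[coincident] -= 1
        keep = prev_ok >= 0
        csi = spikes[ok][keep] - ts[prev_ok[keep]]
        return CsiPairedSeries(isi[ok][keep], csi, target.unit_id, source.unit_id)
    return CsiPairedSeries(isi[ok], csi, target.unit_id, source.unit_id)


def joint_distribution(series: CsiPairedSeries, binning: LogBinning) -> JointDistribution:
    """2-D histogram of the paired series, identical binning on both axes."""
    if series.n_pairs == 0:
        raise ValueError("empty paired series")
    iy = binning.index(series.isi)
    ix = binning.index(series.csi)
    nb = binning.n_bins
    counts = np.bincount(iy * nb + ix, minlength=nb * nb).reshape(nb, nb)
    return JointDistribution(binning=binning, joint=counts / series.n_pairs,
                             n=series.n_pairs)


def joint_entropy(joint: JointDistribution) -> float:
    """H(y,x) = -sum_ij p(y_i,x_j) log2 p(y_i,x_j), bits/spike."""
    return entropy_bits(joint.joint.ravel())


def _entropies_from_indices(iy: np.ndarray, ix: np.ndarray, nb: int):
    n = iy.size
    H_y = entropy_bits(np.bincount(iy, minlength=nb) / n)
    H_x = entropy_bits(np.bincount(ix, minlength=nb) / n)
    H_joint = entropy_bits(np.bincount(iy * nb + ix, minlength=nb * nb) / n)
    return H_y, H_x, H_joint


def conditional_information(series: CsiPairedSeries, binning: LogBinning,
                            chain_rule: str = "standard"):
    """Return (H_naive, H_cond, I_cond) in bits/spike.

    ``chain_rule="standard"`` uses H(y|x) = H(y,x) - H(x), which makes
    I_cond = H(y) - H(y|x) the (non-negative) mutual information.
    ``chain_rule="printed"`` subtracts the ISI marginal instead,
    H(y|x) := H(y,x) - H(y); the resulting I_cond = 2H(y) - H(y,x) is not an
    information measure and can be negative — provided only for comparison.
    """
    if series.n_pairs == 0:
        raise ValueError("empty paired series")
    iy = binning.index(series.isi)
    ix = binning.index(series.csi)
    H_y, H_x, H_joint = _entropies_from_indices(iy, ix, binning.n_bins)
    if chain_rule == "standard":
        H_cond = H_joint - H_x
    elif chain_rule == "printed":
        H_cond = H_joint - H_y
    else:
        raise ValueError(f"unknown chain_rule {chain_rule!r}")
    return H_y, H_cond, H_y - H_cond


def shuffled_information(series: CsiPairedSeries, binning: LogBinning,
                         n_shuffles: int = DEFAULT_N_SHUFFLES,
                         seed: int | None = 0,
                         chain_rule: str = "standard") -> float:
    """I_shuf = H_naive - <H_shuf> over ``n_shuffles`` random reorderings of
    the CSI sequence (ISI order kept); deterministic under ``seed`` via one
    child random stream per shuffle."""
    info = directed_information(series, binning, n_shuffles=n_shuffles,
                                seed=seed, chain_rule=chain_rule)
    return info.I_shuf


def directed_information(series: CsiPairedSeries, binning: LogBinning,
                         n_shuffles: int = DEFAULT_N_SHUFFLES,
                         seed: int | None = 0,
                         chain_rule: str = "standard") -> PairInformation:
    """Full bias-corrected information estimate for one ordered pair."""
    if series.n_pairs < 2:
        raise ValueError("need at least 2 (isi, csi) pairs")
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    nb = binning.n_bins
    iy = binning.index(series.isi)
    ix = binning.index(series.csi)
    n = iy.size
    H_y, H_x, H_joint = _entropies_from_indices(iy, ix, nb)
    marg = H_x if chain_rule == "standard" else H_y
    H_cond = H_joint - marg
    I_cond = H_y - H_cond

    code_base = iy * nb
    streams = np.random.SeedSequence(seed).spawn(n_shuffles)
    H_shuf = np.empty(n_shuffles)
    for s, ss in enumerate(streams):
        perm = np.random.default_rng(ss).permutation(n)
        Hj = entropy_bits(np.bincount(code_base + ix[perm], minlength=nb * nb) / n)
        H_shuf[s] = Hj - marg
    # averaging the per-shuffle excess (rather than <H_shuf> itself) keeps
    # I_dir exactly zero when every shuffle reproduces H_cond (constant CSI)
    I_dir = float(np.mean(H_shuf - H_cond))
    I_shuf = I_cond - I_dir
    return PairInformation(
        H_naive=H_y, H_cond=H_cond, I_cond=I_cond, I_shuf=I_shuf,
        I_dir=I_dir, n_pairs=n, n_shuffles=n_shuffles, seed=seed,
        target_id=series.target_id, source_id=series.source_id,
    )


def fit_null_sigma(i_dir_values, min_negative: int = 10,
                   z_threshold: float = Z_THRESHOLD_DEFAULT) -> PopulationNull:
    """Fit the independent-pair null SD from the negative side of a
    population of bias-corrected I_dir values.

    Under the null the population is zero-mean gaussian, so the negative side
    is a half-normal whose MLE is sigma = sqrt(mean(v^2) over v < 0). At
    least ``min_negative`` negative values are required for a usable fit.
    """
    v = np.asarray(i_dir_values, dtype=float)
    neg = v[v < 0]
    if neg.size < min_negative:
        raise ValueError(
            f"only {neg.size} negative I_dir values (< {min_negative}); "
            "a larger population is needed to fit the null"
        )
    sigma = float(np.sqrt(np.mean(neg ** 2)))
    return PopulationNull(sigma=sigma, n_negative=int(neg.size),
                          z_threshold=z_threshold)


def classify_informative(i_dir_values, null: PopulationNull):
    """Flag pairs with I_dir at least ``z_threshold * sigma`` above zero
    (inclusive); returns (flags, fraction_significant)."""
    if not null.sigma > 0:
        raise ValueError("null sigma must be positive")
    v = np.asarray(i_dir_values, dtype=float)
    flags = v >= null.z_threshold * null.sigma
    return flags, float(flags.mean()) if v.size else float("nan")


_DIRECTIONS = {
    "SNr->VA": ("SNr", "VA"),
    "VA->SNr": ("VA", "SNr"),
}


def pairwise_information_table(session: RecordingSession,
                               direction: str = "both",
                               binning: LogBinning | None = None,
                               n_shuffles: int = DEFAULT_N_SHUFFLES,
                               seed: int | None = 0,
                               min_spikes: int = MIN_SPIKES_INCLUSION,
                               min_pairs: int = 2) -> pd.DataFrame:
    """Bias-corrected information for every ordered cross-region pair.

    Both directions are computed from the same inclusion-filtered unit sets,
    so orthodromic (SNr->VA) and antidromic (VA->SNr) row counts are equal
    when ``direction="both"``. Pairs whose CSI series is shorter than
    ``min_pairs`` are reported with NaN information columns.
    """
    if direction == "both":
        directions = list(_DIRECTIONS)
    elif direction in _DIRECTIONS:
        directions = [direction]
    else:
        raise ValueError(f"direction must be 'both' or one of {list(_DIRECTIONS)}")
    if binning is None:
        binning = make_log_binning()
    units = {
        reg: [tr for tr in session.units(reg) if unit_passes_inclusion(tr, min_spikes)]
        for reg in ("SNr", "VA")
    }
    if not units["SNr"] or not units["VA"]:
        raise ValueError("no eligible cross-region pairs (inclusion filter)")
    ss = np.random.SeedSequence(seed)
    rows = []
    for d in directions:
        src_reg, tgt_reg = _DIRECTIONS[d]
        for src in units[src_reg]:
            for tgt in units[tgt_reg]:
                series = compute_csi_series(tgt, src)
                pair_seed = int(ss.spawn(1)[0].generate_state(1, np.uint32)[0])
                if series.n_pairs >= min_pairs:
                    info = directed_information(series, binning, n_shuffles,
                                                seed=pair_seed)
                    vals = (info.H_naive, info.H_cond, info.I_cond,
                            info.I_shuf, info.I_dir, info.n_pairs)
                else:
                    warnings.warn(
                        f"pair {src.unit_id}->{tgt.unit_id}: only "
                        f"{series.n_pairs} (isi, csi) pairs; reporting NaN",
                        stacklevel=2,
                    )
                    vals = (np.nan,) * 5 + (series.n_pairs,)
                rows.append((src.unit_id, tgt.unit_id, d) + vals)
    return pd.DataFrame(rows, columns=[
        "source", "target", "direction",
        "H_naive", "H_cond", "I_cond", "I_shuf", "I_dir", "n_pairs",
    ])
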