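# Methods

## Interval distributions and entropy

All interval statistics (ISIs and CSIs) are histogrammed on geometric bins
with `bins_per_decade` bins per factor of ten. The default range is
1 ms–10 s: the lower edge sits at the absolute refractory floor, the upper
edge comfortably exceeds the longest interval a unit passing the 500-spike
inclusion rule can produce in a 15-minute trial. The range must span an
integer number of decades so every decade is partitioned identically.
Out-of-range intervals are clamped into the first/last bin rather than
dropped; this preserves both probability mass and the sample count n that
the shuffle bias correction depends on. Entropy is the plug-in estimate
−Σ p log2 p (bits/spike) with 0·log 0 ≡ 0.

Coarse (5 bins/decade) resolution is the analysis default; fine
(25 bins/decade) resolution resolves stimulation-entrainment structure
(ISI peaks at the 10 ms stimulation period and its integer multiples) but
needs more data per unit.

A float-precision caveat: a perfectly periodic train whose period falls
exactly on a bin edge (10 ms is an edge of both default binnings) can have
its interval mass split across the two adjacent bins by 1-ulp rounding of
spike-time differences. Zero-entropy assertions should therefore use a
binning whose bins contain the period in their interior; real (jittered)
data are unaffected.

## CSI construction and directed information

For information directed from source x to target y, each target spike from
the second onward contributes the pair (isi_k, csi_k), where csi_k is the
interval back to the most recent source spike *strictly* before the target
spike; target spikes with no earlier source spike (and coincident-only
sources) are dropped. This matches the operational meaning of conditioning
on "the source has/has not spiked recently" and keeps all intervals
strictly positive for log binning. CSIs are uncapped; values beyond the
10 s bin edge are clamped.

The conditional entropy uses the standard chain rule H(y|x) = H(y,x) − H(x),
so I_cond = H(y) − H(y|x) is the mutual information of the binned pair and
is non-negative by construction. (An alternative variant subtracting the
ISI marginal is available behind `chain_rule="printed"` for comparison; it
is not an information measure and can be negative.)

I_cond is positively biased for finite n even when the trains are
independent. The correction subtracts the shuffled information: the CSI
sequence is permuted uniformly (ISI order kept, CSI multiset preserved —
hence H(y) and H(x) are invariant across shuffles), the conditional entropy
recomputed, and the average over `n_shuffles = 100` permutations taken.
Each shuffle draws from its own child stream of a single master seed
(numpy `SeedSequence.spawn`), making every estimate bit-reproducible.
I_dir is computed as the mean of the per-shuffle entropy excesses
⟨H_shuf − H_cond⟩, which is algebraically I_cond − I_shuf but exactly zero
(not merely ~1e-15) in the degenerate constant-CSI case.

The estimator uses only the most recent ISI and CSI (one-dimensional
distributions). Higher-order history adds a dimension per interval and
rapidly outruns the data available in a 15-minute trial.

Directionality: the estimate is asymmetric in value (swapping the roles of
the units changes the series), but it is a mutual-information-style
quantity, not a causal one. On rate-switching coupled pairs, the reverse
orientation typically carries comparable — often slightly larger —
information than the forward one, because the slowed target's ISIs encode
the coupling state. Consumers should treat orthodromic/antidromic labels as
orientations of the same dependence, not as evidence of causal direction.

## Population null and significance

Across many truly independent pairs, I_dir is approximately gaussian with
zero mean (the shuffle correction centers it). Informative pairs contaminate
only the positive tail, so the null scale is fit from the negative side:
sigma = sqrt(mean(v²) over v < 0), the closed-form half-normal MLE under a
zero-mean symmetric null. The closed form is preferred over an iterative
curve fit to histogram counts: it is deterministic, transparent, and
binning-free. At least 10 negative values are required; fewer indicates a
population too small (or too contaminated) to calibrate, and the fit
refuses rather than guessing. Pairs with I_dir ≥ 1.645 σ (the 95th
standard-normal percentile, inclusive) are flagged significant at α = 0.05.

The empirical false-positive rate of the full chain on independent
synthetic pairs is slightly above the nominal 5% (typically 5–7% at
n = 500 pairs): consecutive CSIs are serially correlated (when no source
spike intervenes, csi_{k+1} = csi_k + isi_{k+1}), and the permutation
destroys that correlation, so the shuffle bias estimate is computed under a
mildly idealized exchangeability assumption. This is a property of the
method itself, shared by any shuffle-corrected plug-in estimator applied to
serially dependent samples.

## Blanking and rate correction

Stimulation artifacts prevent spike detection for ~1 ms of every 10 ms
cycle. `apply_blanking` removes spikes whose phase within the cycle falls in
the blank window (anchored at the first stimulation pulse when pulse times
are available, else at the window start). Rates measured from blanked data
are multiplied by 10/9 — the reciprocal of the 9/10 detection duty cycle.
The correction applies to firing rates only, never to entropies or
information; those are analyzed with and without an *imposed* blanking on
unstimulated data (`AnalysisConfig.impose_blanking`) to verify that the
detection gap does not drive condition differences.

## Synthetic data

The generators produce the statistical structure each analysis stage
assumes, at the study's own scales (900 s trials, units at a few to a few
tens of Hz):

- **Background trains** are dead-time renewal processes: ISI = 1 ms +
  Exp(rate′), with rate′ = rate/(1 − rate·1 ms) so the realized mean rate
  equals the nominal rate exactly. The 1 ms floor keeps intervals off the
  lower bin edge; at ≤ 50 Hz the ISI law is indistinguishable in practice
  from a homogeneous Poisson process.
- **Coupled pairs** implement rate switching: after each source spike (plus
  a delay), the target's intensity switches from its base rate (default
  25 Hz, fast ~40 ms ISI mode) to a coupled rate (default 4 Hz, slow
  ~250 ms mode) for an effect window (default 1 s). Implementation is by
  thinning a max-rate background train, so equal base and coupled rates
  reduce *exactly* to an independent train. Coupling strength is a pure
  ground-truth dial for information: contrast up, I_dir up.
- **Entrained units** fire with probability p on each pulse of a 100 Hz
  grid, at a 3 ms post-pulse latency with gaussian jitter. The latency
  keeps evoked spikes out of the 1 ms artifact-blanking window, as a
  synaptically driven response would be; ISI statistics are unaffected by
  the constant offset.
- **Beta field + locked unit**: LFP = sin(2π·28t) + 0.3·sin(2π·56t + π/4)
  + white noise. The phase-locked second harmonic gives the field genuine
  bispectral content so unit–field cross bicoherence has a designed
  (28, 28) Hz peak; a unit with von-Mises-style phase concentration κ
  (normalized so the cycle-averaged rate is preserved) locks to it.
- **Sessions** assemble the archetypes: control = independent units;
  hPD = SNr sources beta-locked to a shared field, VA units rate-switched
  by them (coupled rate = 0.16 × base by default); DBS = background plus
  entrained spikes, pulse times recorded, per-cycle blanking applied, and
  no cross-region coupling. Effect sizes are not quantified by any in-vivo
  report; the defaults are chosen once to reproduce the qualitative
  condition ordering (hPD information above control, restored under DBS)
  with clear margins at 900 s.
- **Behavior** is a reflecting random walk in a 30 × 45 cm box at 5–10
  samples/s whose heading integrates a deterministic rotational bias
  (deg/s, clockwise-positive in overhead-image coordinates) plus diffusion
  noise (deg/√s).

What the generators do *not* emulate: refractory recovery functions,
bursting, non-stationary rates, spike-sorting contamination, volume
conduction, or 1/f LFP backgrounds. Passing tests therefore demonstrate
correctness of the estimators under the assumed statistical structure, not
robustness to every pathology of in-vivo recordings.

## Spectral analyses

LFPs are zero-phase lowpass filtered below 675 Hz (4th-order Butterworth,
forward-backward: ≥ 48 dB one octave above cutoff). PSDs use Welch
averaging with 1 s Hann segments at 50% overlap (1 Hz resolution, ~28
averages per 15-minute record). Spike trains become unit impulse series
(one impulse per spike in half-open sample bins).

Cross bicoherence between an LFP L and spike series S is

    B(f1, f2) = |⟨L(f1) S(f2) L*(f1+f2)⟩| /
                sqrt(⟨|L(f1) S(f2)|²⟩ ⟨|L(f1+f2)|²⟩)

averaged over mean-subtracted, Hann-windowed segments; Cauchy–Schwarz
bounds it in [0, 1], and the normalization cancels any LFP gain. The
conjugate sum-frequency term is taken from the LFP (the field acts as the
phase reference); the convention is configurable. At least 8 segments are
required; background medians settle below 0.1 around 64 segments for
independent signals.

Cross-correlograms are computed on gaussian-smoothed, mean-subtracted
impulse trains (default kernel SD 25 ms, unit area; sample step ≤ SD/5),
normalized to Pearson correlation. A dominant period is reported when the
correlogram's spectral peak is at least 4× its median spectral level. Note
the 25 ms default kernel attenuates beta-band (≈28 Hz) structure by ~e⁻¹⁰;
use a narrower kernel (e.g. 5 ms) when probing beta periodicity. The beta
band is reported as 20–35 Hz.

## Bootstrap statistics

Population summaries of non-gaussian quantities are the sample mean with
the 25th–75th percentile interval of 100,000 bootstrap resamples of the
mean. Two-group comparisons (p_bca) are the two-sided sign fraction of the
bootstrap mean-difference distribution, clipped to [1/n_boot, 1]. Group
random streams are assigned in a canonical data-derived order so the
p-value is exactly invariant under swapping the groups.

## Problem sizes and determinism

Default analyses run one ordered pair (≈18,000 intervals, 100 shuffles) in
~30 ms; population calibrations (hundreds of pairs at 900 s) complete in
tens of seconds on one CPU. All stochastic components — generators,
shuffles, bootstraps — are driven by explicit seeds through numpy
`SeedSequence`, and repeated calls with the same seed are bit-identical.
The test suite asserts the null calibration at 500 pairs, parameter
recovery over 3 coupling contrasts × 50 seeds, and the three-condition
comparison at 5 sessions × 20 pairs per condition.

## Known limitations

- The shuffle correction assumes exchangeable (serially independent) CSI
  samples; real CSI sequences are autocorrelated, leaving a small residual
  positive bias (see the null-calibration note above).
- The half-normal null fit assumes the independent-pair distribution is
  symmetric about zero; strong contamination of the negative side (e.g.
  inhibitory-coupling-induced negative skew) would inflate sigma.
- One-dimensional interval distributions cannot detect dependencies that
  only appear across multiple consecutive intervals.
- The amphetamine-rotation classifier implements fixed thresholds
  (≥ 10 net ipsilateral rotations/min → hPD; ≤ 6 → alleviated); values
  between are reported as indeterminate rather than forced into a class.
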