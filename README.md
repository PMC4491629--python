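# spikedirinfo

Directed-information analysis of simultaneously recorded spike trains, built
for studying how basal-ganglia output neurons (substantia nigra pars
reticulata, SNr) influence motor-thalamus neurons (ventral anterior nucleus,
VA) in healthy, hemiparkinsonian (hPD), and deep-brain-stimulation (DBS)
conditions. The package is aimed at systems-neuroscience users who have
per-unit spike times (plus optional LFPs, stimulation pulse times, and
overhead-camera behavior tracks) and want pair-level information estimates
with honest bias correction and significance calibration.

## The estimator

For a target unit with inter-spike intervals (ISIs) *y* and a source unit
providing cross-spike intervals (CSIs) *x* — the time from each target spike
back to the most recent earlier source spike — both interval types are
histogrammed on logarithmic bins (5 bins/decade over 1 ms–10 s; 25
bins/decade for fine structure). Firing-pattern entropy is

    H(y) = − Σ_i p(y_i) log2 p(y_i)        [bits/spike]

and with the joint distribution p(y_i, x_j):

    H(y,x)  = − Σ_ij p(y_i, x_j) log2 p(y_i, x_j)
    I_cond  = H(y) − [H(y,x) − H(x)]        (≥ 0, positively biased at finite n)
    I_shuf  = H(y) − ⟨H_shuf⟩               (same estimate after randomly
                                             permuting the CSI sequence,
                                             averaged over 100 shuffles)
    I_dir   = I_cond − I_shuf               (bias-corrected directed information)

Across truly independent pairs, I_dir is approximately gaussian around zero;
a half-normal fit to the negative side of the population yields the null
standard deviation σ, and pairs with I_dir ≥ 1.645 σ are classified
significantly informative (α = 0.05). Supporting analyses include smoothed
(25 ms gaussian kernel) cross-correlation, Welch power spectral densities,
unit–field cross bicoherence (normalized to [0, 1]), 10/9 firing-rate
correction for 1 ms-per-10 ms stimulation-artifact blanking, and rotational
behavior metrics (ipsilateral preference 100 % × θ_R/(θ_L+θ_R)).

Because no public recordings exist for this preparation, the
`synthetic_data` module is a first-class component: it generates sessions
with the statistical structure of each condition (independent background
units; rate-switching coupled pairs plus a shared 28 Hz beta field; 100 Hz
entrained units with detection blanking) so every stage of the pipeline is
testable end to end.

## Worked example

```python
import numpy as np
from spikedirinfo import (compute_csi_series, directed_information,
                          make_log_binning, fit_null_sigma, classify_informative)
from spikedirinfo.synthetic_data import CoupledPairSpec, gen_coupled_pair, gen_poisson_train

binning = make_log_binning()          # 5 bins/decade over 1 ms - 10 s

# a coupled pair: each SNr spike slows the VA unit from 25 Hz to 4 Hz for 1 s
src, tgt = gen_coupled_pair(CoupledPairSpec(seed=0))
series = compute_csi_series(tgt, src)
info = directed_information(series, binning, n_shuffles=100, seed=0)
print(f"H_naive = {info.H_naive:.3f} bits/spike")
print(f"I_cond  = {info.I_cond:.4f} bits/spike")
print(f"I_shuf  = {info.I_shuf:.4f} bits/spike")
print(f"I_dir   = {info.I_dir:.4f} bits/spike")

# a null population of independent 20 Hz pairs calibrates significance
null_vals = []
for i in range(100):
    a = gen_poisson_train(20.0, 900.0, seed=2 * i, unit_id="a")
    b = gen_poisson_train(20.0, 900.0, seed=2 * i + 1, unit_id="b")
    null_vals.append(directed_information(compute_csi_series(b, a),
                                          binning, 100, seed=i).I_dir)
null = fit_null_sigma(null_vals)
flags, _ = classify_informative([info.I_dir], null)
print(f"null sigma = {null.sigma:.2e} bits/spike; coupled pair significant: {bool(flags[0])}")
```

prints

```
H_naive = 3.578 bits/spike
I_cond  = 0.2589 bits/spike
I_shuf  = 0.0187 bits/spike
I_dir   = 0.2402 bits/spike
null sigma = 6.93e-04 bits/spike; coupled pair significant: True
```

The coupled pair's conditional information (0.26 bits/spike) is mostly real
structure: the shuffle correction removes only the small finite-sample bias
(0.019 bits/spike), leaving a directed information hundreds of null standard
deviations above zero, while independent pairs scatter within ~7×10⁻⁴
bits/spike of zero.

### Command line

```
spikedirinfo gen-session --condition hPD --seed 1 --out session.h5
spikedirinfo analyze --session session.h5 --out report/
spikedirinfo pairinfo --session session.h5 --direction both --out pairs.csv
spikedirinfo compare --report control ctrl_report/ --report hPD report/ --out cmp/
```

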