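import numpy as np
import pytest

from spikedirinfo import make_log_binning
from spikedirinfo.spike_io import SpikeTrain


@pytest.fixture(scope="session")
def coarse_binning():
    return make_log_binning(5, 1e-3, 10.0)


@pytest.fixture(scope="session")
def fine_binning():
    return make_log_binning(25, 1e-3, 10.0)


def make_train(times, unit_id="u", region="other", t_start=0.0, t_stop=None):
    times = np.asarray(times, dtype=float)
    if t_stop is None:
        t_stop = (times[-1] + 1.0) if times.size else 1.0
    return SpikeTrain(unit_id=unit_id, region=region, times=times,
                      t_start=t_start, t_stop=t_stop)


@pytest.fixture(scope="session")
def independent_pair_population():
    """I_dir over 200 independent 20 Hz, 900 s pairs (shared across tests
    that need a realistic null population)."""
    from spikedirinfo import compute_csi_series, directed_information
    from spikedirinfo.synthetic_data import gen_poisson_train

    binning = make_log_binning()
    vals = []
    for i in range(200):
        src = gen_poisson_train(20.0, 900.0, seed=50_000 + 2 * i, unit_id="s")
        tgt = gen_poisson_train(20.0, 900.0, seed=50_001 + 2 * i, unit_id="t")
        series = compute_csi_series(tgt, src)
        vals.append(directed_information(series, binning, n_shuffles=100,
                                         seed=i).I_dir)
    return np.asarray(vals)
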