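import numpy as np
import pytest
from scipy import stats

from spikedirinfo import (
    classify_informative,
    compute_csi_series,
    conditional_information,
    directed_information,
    fit_null_sigma,
    joint_distribution,
    joint_entropy,
    make_log_binning,
    pairwise_information_table,
    shuffled_information,
)
from spikedirinfo.directed_info import CsiPairedSeries, PopulationNull
from spikedirinfo.interval_stats import entropy_bits, interval_histogram
from spikedirinfo.spike_io import RecordingSession
from spikedirinfo.synthetic_data import CoupledPairSpec, gen_coupled_pair, gen_poisson_train

from conftest import make_train


def random_series(rng, n, lo=2e-3, hi=5.0):
    """Independent log-uniform ISI/CSI samples (arbitrary positive values)."""
    return CsiPairedSeries(
        isi=np.exp(rng.uniform(np.log(lo), np.log(hi), n)),
        csi=np.exp(rng.uniform(np.log(lo), np.log(hi), n)),
    )


class TestCsiSeries:
    def test_direct_construction(self):
        target = make_train([1.0, 2.0], t_stop=3.0)
        source = make_train([0.5, 1.5], unit_id="s", t_stop=3.0)
        series = compute_csi_series(target, source)
        np.testing.assert_allclose(series.isi, [1.0])
        np.testing.assert_allclose(series.csi, [0.5])

    def test_empty_source_empty_series(self):
        target = make_train([1.0, 2.0], t_stop=3.0)
        source = make_train([], unit_id="s", t_stop=3.0)
        assert compute_csi_series(target, source).n_pairs == 0

    def test_target_spikes_without_earlier_source_dropped(self):
        target = make_train([0.2, 0.4, 2.0], t_stop=3.0)
        source = make_train([1.0], unit_id="s", t_stop=3.0)
        series = compute_csi_series(target, source)
        np.testing.assert_allclose(series.isi, [1.6])
        np.testing.assert_allclose(series.csi, [1.0])

    def test_coincident_source_spike_is_not_strictly_earlier(self):
        target = make_train([1.0, 2.0], t_stop=3.0)
        source = make_train([0.5, 2.0], unit_id="s", t_stop=3.0)
        series = compute_csi_series(target, source)
        np.testing.assert_allclose(series.csi, [1.5])  # back to 0.5, not 2.0

    def test_csi_is_backward_recurrence_of_poisson_source(self):
        # at target spike times the time back to the last source spike of an
        # independent Poisson process is Exp(rate)
        src = gen_poisson_train(20.0, 300.0, seed=21, unit_id="s")
        tgt = gen_poisson_train(20.0, 300.0, seed=22, unit_id="t")
        series = compute_csi_series(tgt, src)
        p = stats.kstest(series.csi, "expon", args=(0, 1 / 20.0)).pvalue
        assert p > 0.01

    def test_directionality(self):
        a = gen_poisson_train(10.0, 100.0, seed=5, unit_id="a")
        b = gen_poisson_train(10.0, 100.0, seed=6, unit_id="b")
        fwd = compute_csi_series(a, b)
        rev = compute_csi_series(b, a)
        assert fwd.n_pairs != rev.n_pairs or not np.allclose(fwd.csi, rev.csi)


class TestJointDistribution:
    def test_single_pair_point_mass(self, coarse_binning):
        s = CsiPairedSeries(isi=[0.05], csi=[0.2])
        j = joint_distribution(s, coarse_binning)
        assert j.joint.max() == 1.0
        assert j.joint.sum() == pytest.approx(1.0)

    def test_isi_marginal_matches_1d_histogram(self, coarse_binning):
        rng = np.random.default_rng(7)
        s = random_series(rng, 500)
        j = joint_distribution(s, coarse_binning)
        d = interval_histogram(s.isi, coarse_binning)
        np.testing.assert_allclose(j.p_isi, d.probabilities, atol=1e-12)

    def test_independent_series_factorizes(self, coarse_binning):
        # chi-squared independence test not rejected in the median over seeds
        pvals = []
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            s = random_series(rng, 4000)
            j = joint_distribution(s, coarse_binning)
            counts = j.joint * j.n
            expected = np.outer(j.p_isi, j.p_csi) * j.n
            mask = expected > 1e-12
            chi2 = ((counts[mask] - expected[mask]) ** 2 / expected[mask]).sum()
            dof = (np.count_nonzero(j.p_isi > 0) - 1) * (np.count_nonzero(j.p_csi > 0) - 1)
            pvals.append(stats.chi2.sf(chi2, dof))
        assert np.median(pvals) > 0.01


class TestJointEntropy:
    def _series_for_grid(self, binning, pairs):
        centers = binning.centers()
        isi = np.array([centers[i] for i, _ in pairs])
        csi = np.array([centers[j] for _, j in pairs])
        return CsiPairedSeries(isi=isi, csi=csi)

    def test_product_of_uniform4_marginals(self, coarse_binning):
        pairs = [(i, j) for i in range(4, 8) for j in range(4, 8)]
        j = joint_distribution(self._series_for_grid(coarse_binning, pairs),
                               coarse_binning)
        assert joint_entropy(j) == pytest.approx(4.0)

    def test_diagonal_uniform4(self, coarse_binning):
        pairs = [(i, i) for i in range(4, 8)]
        j = joint_distribution(self._series_for_grid(coarse_binning, pairs),
                               coarse_binning)
        assert joint_entropy(j) == pytest.approx(2.0)

    def test_matches_brute_force_summation(self, coarse_binning):
        rng = np.random.default_rng(9)
        s = random_series(rng, 2000)
        j = joint_distribution(s, coarse_binning)
        brute = -sum(p * np.log2(p) for p in j.joint.ravel() if p > 0)
        assert joint_entropy(j) == pytest.approx(brute, abs=1e-9)

    def test_bounded_by_marginals(self, coarse_binning):
        rng = np.random.default_rng(10)
        s = random_series(rng, 1000)
        j = joint_distribution(s, coarse_binning)
        h_y = entropy_bits(j.p_isi)
        h_x = entropy_bits(j.p_csi)
        h = joint_entropy(j)
        assert max(h_y, h_x) - 1e-9 <= h <= h_y + h_x + 1e-9


class TestConditionalInformation:
    def test_perfect_dependence_gives_full_entropy(self, coarse_binning):
        centers = coarse_binning.centers()
        # ISI bin is a deterministic function of CSI bin
        isi = np.repeat(centers[[3, 8, 13]], 10)
        csi = np.repeat(centers[[5, 10, 15]], 10)
        s = CsiPairedSeries(isi=isi, csi=csi)
        H_naive, H_cond, I_cond = conditional_information(s, coarse_binning)
        assert H_cond == pytest.approx(0.0, abs=1e-12)
        assert I_cond == pytest.approx(H_naive)

    def test_constant_csi_gives_zero(self, coarse_binning):
        rng = np.random.default_rng(11)
        s = CsiPairedSeries(isi=rng.exponential(0.05, 200), csi=np.full(200, 0.1))
        _, _, I_cond = conditional_information(s, coarse_binning)
        assert I_cond == pytest.approx(0.0, abs=1e-12)

    def test_finite_sample_bias_shrinks_with_n(self, coarse_binning):
        small, large = [], []
        for seed in range(50):
            rng = np.random.default_rng(200 + seed)
            small.append(conditional_information(random_series(rng, 100),
                                                 coarse_binning)[2])
            large.append(conditional_information(random_series(rng, 10_000),
                                                 coarse_binning)[2])
        assert np.median(small) > np.median(large) > 0

    def test_non_negative_across_random_series(self, coarse_binning):
        rng = np.random.default_rng(12)
        for _ in range(500):
            s = random_series(rng, int(rng.integers(2, 200)))
            assert conditional_information(s, coarse_binning)[2] >= -1e-9

    def test_printed_chain_rule_variant(self, coarse_binning):
        rng = np.random.default_rng(13)
        s = random_series(rng, 500)
        j = joint_distribution(s, coarse_binning)
        H_y = entropy_bits(j.p_isi)
        H_joint = joint_entropy(j)
        _, _, I_printed = conditional_information(s, coarse_binning,
                                                  chain_rule="printed")
        assert I_printed == pytest.approx(2 * H_y - H_joint)


class TestShuffledInformation:
    def test_constant_csi_shuffle_is_identity(self, coarse_binning):
        rng = np.random.default_rng(14)
        s = CsiPairedSeries(isi=rng.exponential(0.05, 300), csi=np.full(300, 0.1))
        info = directed_information(s, coarse_binning, n_shuffles=10, seed=0)
        assert info.I_shuf == info.I_cond
        assert info.I_dir == 0.0  # exactly

    def test_deterministic_under_seed(self, coarse_binning):
        rng = np.random.default_rng(15)
        s = random_series(rng, 400)
        a = shuffled_information(s, coarse_binning, n_shuffles=20, seed=42)
        b = shuffled_information(s, coarse_binning, n_shuffles=20, seed=42)
        assert a == b
        c = shuffled_information(s, coarse_binning, n_shuffles=20, seed=43)
        assert a != c

    def test_independent_series_shuffle_matches_conditional(self, coarse_binning):
        # shuffling preserves independence structure, so I_shuf ~ I_cond
        diffs = []
        for seed in range(50):
            rng = np.random.default_rng(300 + seed)
            s = random_series(rng, 1000)
            info = directed_information(s, coarse_binning, n_shuffles=20, seed=seed)
            diffs.append(info.I_dir)
        se = np.std(diffs) / np.sqrt(len(diffs))
        assert abs(np.mean(diffs)) < 3 * se


class TestDirectedInformation:
    def test_independent_pairs_mean_near_zero(self, independent_pair_population):
        vals = independent_pair_population
        se = vals.std() / np.sqrt(vals.size)
        assert abs(vals.mean()) < 3 * se

    def test_identity_i_dir(self, coarse_binning):
        rng = np.random.default_rng(16)
        s = random_series(rng, 500)
        info = directed_information(s, coarse_binning, n_shuffles=10, seed=1)
        assert info.I_cond == pytest.approx(info.H_naive - info.H_cond)
        assert info.I_dir == pytest.approx(info.I_cond - info.I_shuf)

    def test_coupling_detected_in_both_directions(self, coarse_binning):
        # rate coupling is detected whichever unit is treated as target (the
        # one-interval estimator is asymmetric in value but, like the in-vivo
        # observations it models, reports information in both orientations)
        fwd, rev = [], []
        for seed in range(20):
            spec = CoupledPairSpec(source_rate=2.0, target_base_rate=25.0,
                                   target_coupled_rate=5.0, effect_window=0.3,
                                   delay=0.05, duration=300.0, seed=seed)
            src, tgt = gen_coupled_pair(spec)
            fwd.append(directed_information(compute_csi_series(tgt, src),
                                            coarse_binning, 20, seed=seed).I_dir)
            rev.append(directed_information(compute_csi_series(src, tgt),
                                            coarse_binning, 20, seed=seed).I_dir)
        assert np.median(fwd) > 0.05
        assert np.median(rev) > 0.05
        assert not np.allclose(fwd, rev)  # genuinely asymmetric estimates


class TestPopulationNull:
    def test_sigma_recovered_from_gaussian(self):
        rng = np.random.default_rng(17)
        null = fit_null_sigma(rng.normal(0.0, 1.0, 10_000))
        assert 0.97 <= null.sigma <= 1.03

    def test_all_non_negative_is_error(self):
        with pytest.raises(ValueError, match="negative"):
            fit_null_sigma(np.abs(np.random.default_rng(0).normal(size=100)))

    def test_scale_equivariance(self):
        rng = np.random.default_rng(18)
        v = rng.normal(0.0, 1.0, 5000)
        s1 = fit_null_sigma(v).sigma
        s2 = fit_null_sigma(2 * v).sigma
        assert s2 == pytest.approx(2 * s1)

    def test_threshold_inclusive(self):
        null = PopulationNull(sigma=0.01, n_negative=50)
        flags, frac = classify_informative([1.645 * 0.01, 0.0, 0.02], null)
        assert list(flags) == [True, False, True]
        assert frac == pytest.approx(2 / 3)


class TestPairwiseTable:
    def _session(self):
        trains = []
        rates = {"SNr": [25.0, 30.0], "VA": [20.0, 25.0, 30.0]}
        i = 0
        for region, rs in rates.items():
            for r in rs:
                trains.append(gen_poisson_train(r, 120.0, seed=400 + i,
                                                unit_id=f"{region.lower()}{i}",
                                                region=region))
                i += 1
        # a unit below the inclusion threshold (2 Hz x 120 s = ~240 spikes)
        trains.append(gen_poisson_train(2.0, 120.0, seed=499,
                                        unit_id="weak", region="SNr"))
        return RecordingSession("control", trains=trains)

    def test_pair_counting_and_direction_symmetry(self):
        table = pairwise_information_table(self._session(), n_shuffles=5, seed=0)
        ortho = table[table.direction == "SNr->VA"]
        anti = table[table.direction == "VA->SNr"]
        assert len(ortho) == len(anti) == 6  # 2 SNr x 3 VA

    def test_subthreshold_unit_excluded(self):
        table = pairwise_information_table(self._session(), n_shuffles=5, seed=0)
        assert "weak" not in set(table.source) | set(table.target)

    def test_no_eligible_pairs_is_error(self):
        sess = RecordingSession("control", trains=[
            gen_poisson_train(20.0, 120.0, seed=1, unit_id="a", region="SNr")])
        with pytest.raises(ValueError, match="eligible"):
            pairwise_information_table(sess, n_shuffles=5)
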