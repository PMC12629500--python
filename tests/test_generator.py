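"""Copula raster generation, jitter, and raster-to-event conversion."""

import numpy as np
import pytest
from scipy import stats

from aoncb import (
    CorrelationSpec,
    InputPool,
    SpikeRaster,
    beta_marginal_params,
    calibrate_copula_sigma,
    empirical_count_correlation,
    jitter_spikes,
    raster_to_events,
    sample_raster,
)
from aoncb.generator import (
    _pair_moment,
    counts_from_spike_times,
    spike_times_from_counts,
)


class TestBetaMarginals:
    def test_worked_parameters(self):
        a, b = beta_marginal_params(10.0, 0.5, 1e-4)
        assert a == pytest.approx(1e-3)
        assert b == pytest.approx(0.999)

    @pytest.mark.parametrize("rho", [0.01, 0.3, 0.9])
    def test_mean_is_rate_times_dt(self, rho):
        r, dt = 7.0, 1e-4
        a, b = beta_marginal_params(r, rho, dt)
        assert a / (a + b) == pytest.approx(r * dt, rel=1e-12)

    def test_bernoulli_mixing_limit(self):
        a1, b1 = beta_marginal_params(10.0, 0.999, 1e-4)
        assert a1 < 1e-5 and b1 < 1e-2

    def test_boundary_rhos_rejected(self):
        with pytest.raises(ValueError):
            beta_marginal_params(10.0, 0.0, 1e-4)
        with pytest.raises(ValueError):
            beta_marginal_params(10.0, 1.0, 1e-4)


class TestCopulaCalibration:
    def test_zero_target_gives_zero_sigma(self):
        corr = CorrelationSpec(block_rho=np.array([[0.1, 0.0], [0.0, 0.1]]))
        Sigma = calibrate_copula_sigma(corr, [10.0, 10.0], 1e-4)
        assert Sigma[0, 1] == 0.0

    def test_sigma_monotone_in_target_rho(self):
        sigmas = []
        for rho_c in (0.01, 0.03, 0.06, 0.09):
            corr = CorrelationSpec(
                block_rho=np.array([[0.1, rho_c], [rho_c, 0.1]])
            )
            sigmas.append(calibrate_copula_sigma(corr, [10.0, 10.0], 1e-4)[0, 1])
        assert all(np.diff(sigmas) > 0)

    def test_round_trip_moment_by_sampling(self):
        # sampling oracle: draw the calibrated copula and check the mixed
        # moment within 2 Monte Carlo standard errors
        dt, r = 1e-4, 10.0
        corr = CorrelationSpec(block_rho=np.array([[0.2, 0.05], [0.05, 0.2]]))
        Sigma = calibrate_copula_sigma(corr, [r, r], dt)
        rng = np.random.default_rng(5)
        n = 1_000_000
        z = rng.multivariate_normal([0, 0], Sigma, size=n)
        a, b = beta_marginal_params(r, 0.2, dt)
        th = stats.beta(a, b).ppf(stats.norm.cdf(z))
        prod = th[:, 0] * th[:, 1]
        target = (r * dt) ** 2 + 0.05 * r * dt
        se = prod.std(ddof=1) / np.sqrt(n)
        assert abs(prod.mean() - target) < 2 * se

    def test_infeasible_target_raises(self):
        # the Frechet cross-moment bound is not attainable for very
        # different marginals, so a cross rho at the admissibility boundary
        # sqrt(rho_i rho_j) exceeds the comonotone copula moment
        edge = float(np.sqrt(0.04 * 0.9)) - 1e-9
        corr = CorrelationSpec(block_rho=np.array([[0.04, edge], [edge, 0.9]]))
        with pytest.raises(ValueError, match="infeasible"):
            calibrate_copula_sigma(corr, [10.0, 10.0], 1e-4)


class TestSampleRaster:
    def test_mean_count_matches_rate(self):
        corr = CorrelationSpec(block_rho=np.array([[0.1]]))
        r = sample_raster(corr, [InputPool("e", 100, 0.001, 20.0)], 1e-4, 100.0, 7)
        n = r.counts[0]
        target = 100 * 20.0 * 1e-4
        se = n.std() / np.sqrt(n.size)
        assert abs(n.mean() - target) < 3 * se

    def test_within_block_pairwise_correlation(self):
        corr = CorrelationSpec(block_rho=np.array([[0.25]]))
        r = sample_raster(
            corr, [InputPool("e", 8, 0.001, 10.0)], 1e-4, 100.0, 11, per_input=True
        )
        X = r.per_input[0]
        cc = np.corrcoef(X)
        vals = cc[np.triu_indices(8, 1)]
        assert abs(vals.mean() - 0.25) < 0.02

    def test_full_synchrony_block_fires_together(self):
        corr = CorrelationSpec(block_rho=np.array([[1.0]]))
        r = sample_raster(corr, [InputPool("e", 30, 0.001, 10.0)], 1e-4, 20.0, 3)
        active = r.counts[0][r.counts[0] > 0]
        assert active.size > 0
        assert np.all(active == 30)

    def test_counts_never_exceed_pool_size(self):
        corr = CorrelationSpec(block_rho=np.array([[0.9]]))
        r = sample_raster(corr, [InputPool("e", 5, 0.001, 50.0)], 1e-4, 50.0, 1)
        assert r.counts.max() <= 5

    def test_reproducible_under_seed(self):
        corr = CorrelationSpec(block_rho=np.array([[0.2]]))
        pools = [InputPool("e", 10, 0.001, 10.0)]
        a = sample_raster(corr, pools, 1e-4, 5.0, 42)
        b = sample_raster(corr, pools, 1e-4, 5.0, 42)
        assert np.array_equal(a.counts, b.counts)

    def test_split_subpopulation_invariance(self):
        # one pool of 40 vs two identical pools of 20 with full cross
        # correlation structure: summary statistics of the summed drive agree
        dt, T, r, rho = 1e-4, 200.0, 10.0, 0.3
        one = sample_raster(
            CorrelationSpec(block_rho=np.array([[rho]])),
            [InputPool("e", 40, 0.001, r)], dt, T, 21,
        )
        two = sample_raster(
            CorrelationSpec(block_rho=np.array([[rho, rho], [rho, rho]])),
            [InputPool("e", 20, 0.001, r), InputPool("e", 20, 0.001, r)],
            dt, T, 22,
        )
        tot1 = one.counts[0]
        tot2 = two.counts.sum(axis=0)
        se = 3 * np.sqrt(tot1.var() / tot1.size + tot2.var() / tot2.size)
        assert abs(tot1.mean() - tot2.mean()) < se
        # second moment of the summed count (synchrony-sensitive)
        m2_1, m2_2 = (tot1**2).mean(), (tot2**2).mean()
        se2 = 3 * np.sqrt((tot1**2).var() / tot1.size + (tot2**2).var() / tot2.size)
        assert abs(m2_1 - m2_2) < se2


class TestJitter:
    def test_zero_sigma_is_identity(self):
        t = np.array([0.1, 0.5, 0.9])
        assert np.array_equal(jitter_spikes(t, 0.0, 1.0, seed=0), t)

    def test_spike_count_conserved(self):
        rng = np.random.default_rng(0)
        t = np.sort(rng.uniform(0, 10.0, 500))
        j = jitter_spikes(t, 0.05, 10.0, seed=1)
        assert j.size == t.size
        assert np.all((j >= 0) & (j < 10.0))

    def test_jitter_erases_fine_timescale_correlation(self):
        # perfectly synchronous pair, strong jitter: correlation at dt-scale
        # windows collapses while total counts stay equal
        rng = np.random.default_rng(2)
        T = 100.0
        t = np.sort(rng.uniform(0, T, 2000))
        j1 = jitter_spikes(t, 0.05, T, seed=3)
        j2 = jitter_spikes(t, 0.05, T, seed=4)
        fine = empirical_count_correlation(j1, j2, 1e-3, T)
        coarse = empirical_count_correlation(j1, j2, 0.2, T)
        assert fine < 0.1 < coarse


class TestEmpiricalCountCorrelation:
    def test_identical_trains(self):
        rng = np.random.default_rng(1)
        t = np.sort(rng.uniform(0, 50.0, 1000))
        assert empirical_count_correlation(t, t, 0.05, 50.0) == pytest.approx(1.0)

    def test_independent_poisson_trains(self):
        rng = np.random.default_rng(2)
        t1 = np.sort(rng.uniform(0, 200.0, 2000))
        t2 = np.sort(rng.uniform(0, 200.0, 2000))
        val = empirical_count_correlation(t1, t2, 0.025, 200.0)
        assert abs(val) < 3.0 / np.sqrt(200.0 / 0.025)

    def test_copula_raster_round_trip_at_dt(self):
        rho, r, dt, T = 0.2, 10.0, 1e-4, 200.0
        raster = sample_raster(
            CorrelationSpec(block_rho=np.array([[rho]])),
            [InputPool("e", 2, 0.001, r)], dt, T, 31, per_input=True,
        )
        X = raster.per_input[0]
        t1 = spike_times_from_counts(X[0].astype(int), dt)
        t2 = spike_times_from_counts(X[1].astype(int), dt)
        val = empirical_count_correlation(t1, t2, dt, T)
        # sparse-binary correlation: the effective sample size is the
        # expected number of coincidences, not the number of bins
        n_coinc = rho * r * dt * (T / dt)
        assert abs(val - rho) < 3.0 * rho / np.sqrt(n_coinc)

    def test_too_short_recording_rejected(self):
        with pytest.raises(ValueError):
            empirical_count_correlation(np.array([0.1]), np.array([0.2]), 1.0, 50.0)


class TestRasterToEvents:
    def _raster(self, counts, metas):
        return SpikeRaster(dt=1e-4, counts=np.asarray(counts), subpop_meta=metas)

    def test_all_zero_raster_gives_empty_train(self):
        r = self._raster([[0, 0, 0]], [{"K": 5, "r": 1.0, "weights": {0: 0.001}}])
        ev = raster_to_events(r)
        assert ev.n_events == 0

    def test_single_spike_single_event(self):
        r = self._raster([[0, 1, 0]], [{"K": 5, "r": 1.0, "weights": {0: 0.002}}])
        ev = raster_to_events(r)
        assert ev.n_events == 1
        assert ev.times[0] == pytest.approx(2e-4)
        assert ev.We[0, 0] == pytest.approx(0.002)

    def test_mixed_bin_hand_sum(self):
        # 2 excitatory spikes of w=0.001 and 1 inhibitory of w=0.004 in a bin
        r = self._raster(
            [[2], [1]],
            [{"K": 10, "r": 1.0, "weights": {0: 0.001}},
             {"K": 10, "r": 1.0, "weights": {0: -0.004}}],
        )
        ev = raster_to_events(r)
        assert ev.We[0, 0] == pytest.approx(0.002)
        assert ev.Wi[0, 0] == pytest.approx(0.004)

    def test_event_times_strictly_increase(self):
        rng = np.random.default_rng(3)
        counts = rng.poisson(0.3, (1, 2000))
        r = self._raster(counts, [{"K": 50, "r": 1.0, "weights": {0: 0.001}}])
        ev = raster_to_events(r)
        assert np.all(np.diff(ev.times) > 0)


class TestRasterIO:
    def test_csv_round_trip(self, tmp_path):
        corr = CorrelationSpec(block_rho=np.array([[0.3]]))
        r = sample_raster(corr, [InputPool("e", 10, 0.001, 20.0)], 1e-4, 2.0, 9)
        path = tmp_path / "raster.csv"
        r.to_csv(path)
        back = SpikeRaster.from_csv(path)
        assert np.array_equal(back.counts, r.counts)
        assert back.dt == r.dt


def test_pair_moment_quadrature_matches_sampling():
    # dense-sampling oracle for the bivariate copula moment
    a, b = beta_marginal_params(10.0, 0.2, 1e-4)
    d = stats.beta(a, b)
    sigma = 0.5
    quad = _pair_moment(sigma, d, d)
    rng = np.random.default_rng(8)
    z1 = rng.standard_normal(400_000)
    z2 = sigma * z1 + np.sqrt(1 - sigma**2) * rng.standard_normal(400_000)
    prod = d.ppf(stats.norm.cdf(z1)) * d.ppf(stats.norm.cdf(z2))
    se = prod.std(ddof=1) / np.sqrt(prod.size)
    assert abs(quad - prod.mean()) < 3 * se
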