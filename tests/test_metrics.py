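"""Per-neuron metrics: latencies, star voltage, pioneers, PSPs, spectra."""
import numpy as np
import pytest

import pioneernet as pn
from pioneernet.events import NetworkSpikeEvent
from pioneernet.metrics import (LatencyTable, latency_cv, mean_latency,
                                psp_peak_time)


def events_at(times):
    return [NetworkSpikeEvent(t, 50.0, t - 5, t + 5) for t in times]


class TestSortByRate:
    def test_matches_oracle_sort(self, make_result):
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 50, size=30)
        neurons = np.repeat(np.arange(30), counts)
        times = rng.uniform(0, 10_000, size=neurons.size)
        res = make_result(neurons, times, n_exc=30, duration=10_000.0)
        ro = pn.sort_by_rate(res)
        oracle = np.argsort(counts, kind="stable")
        assert np.array_equal(ro.order, oracle)
        assert np.array_equal(np.sort(ro.rank), np.arange(1, 31))

    def test_ties_broken_by_id(self, make_result):
        res = make_result([1, 0], [100.0, 200.0], n_exc=3, duration=1000.0)
        ro = pn.sort_by_rate(res)
        # neuron 2 silent -> rank 1; neurons 0 and 1 tie -> lower ID first
        assert ro.rank.tolist() == [2, 3, 1]


class TestFirstSpikeLatencies:
    def test_earliest_spike_in_window(self, make_result):
        res = make_result([0, 0], [980.0, 995.0], n_exc=2, duration=2000.0)
        table = pn.first_spike_latencies(res, events_at([1000.0]))
        assert table.latencies[0, 0] == -20.0
        assert np.isnan(table.latencies[1, 0])

    def test_spike_outside_t0_is_missing(self, make_result):
        res = make_result([0], [900.0], n_exc=1, duration=2000.0)
        table = pn.first_spike_latencies(res, events_at([1000.0]))
        assert np.isnan(table.latencies[0, 0])

    def test_constructed_table_matches_hand_computation(self, make_result):
        peaks = [1000.0, 2000.0]
        neurons = [0, 0, 1, 1, 2]
        times = [970.0, 1990.0, 1005.0, 2030.0, 2100.0]
        res = make_result(neurons, times, n_exc=3, duration=3000.0)
        table = pn.first_spike_latencies(res, events_at(peaks))
        expect = np.array([[-30.0, -10.0],
                           [5.0, 30.0],
                           [np.nan, np.nan]])  # +100 is outside both windows
        assert np.allclose(table.latencies, expect, equal_nan=True)

    def test_forced_spikes_excluded(self, make_result):
        res = make_result([0, 0], [980.0, 990.0], n_exc=1, duration=2000.0,
                          forced=[True, False])
        table = pn.first_spike_latencies(res, events_at([1000.0]))
        assert table.latencies[0, 0] == -10.0


class TestLatencyConsistency:
    def table(self, taus):
        lat = np.array([taus], dtype=float)
        return LatencyTable(lat, -80.0, 35.0)

    def test_zero_spread_is_infinite_consistency(self):
        assert pn.latency_consistency(self.table([-10, -10, -10]))[0] == np.inf

    def test_hand_arithmetic(self):
        out = pn.latency_consistency(self.table([-20, -10]))[0]
        assert out == pytest.approx(15.0 / np.sqrt(50.0), rel=1e-12)

    def test_post_ns_firing_gives_negative_consistency(self):
        assert pn.latency_consistency(self.table([5, 15]))[0] < 0

    def test_single_latency_undefined(self):
        assert np.isnan(pn.latency_consistency(self.table([-10, np.nan]))[0])


class TestStarStats:
    def make(self, values, times=None):
        values = np.asarray(values, dtype=np.float32)[:, None]
        res = pn.SimulationResult(
            n_exc=1, n_inh=0, dt=0.5, duration=values.shape[0] * 10.0,
            warmup=0.0, spike_neuron=np.empty(0, np.int32),
            spike_time=np.empty(0), spike_forced=np.empty(0, bool),
            vstar=values,
            vstar_times=np.arange(values.shape[0]) * 10.0)
        return res

    def test_constant_vstar_has_zero_cv(self):
        res = self.make(np.full(100, -60.0))
        stats = pn.star_voltage_stats(res, [])
        assert stats.cv[0] == pytest.approx(0.0)
        assert stats.mean[0] == pytest.approx(-60.0)

    def test_cv_formula(self):
        rng = np.random.default_rng(0)
        res = self.make(rng.normal(-51.0, 1.0, size=200_000))
        stats = pn.star_voltage_stats(res, [])
        assert stats.cv[0] == pytest.approx(1.0, abs=0.02)

    def test_ns_samples_excluded(self):
        v = np.full(200, -60.0)
        v[100:104] = 0.0  # a "network spike" at t = 1000-1030
        res = self.make(v)
        stats = pn.star_voltage_stats(res, events_at([1010.0]))
        assert stats.mean[0] == pytest.approx(-60.0)


class TestPioneerCriterion:
    def test_both_criteria_required(self):
        is_p, frac = pn.identify_pioneers(
            cv_tau=[0.5, 0.7, 0.5, np.nan],
            cv_vstar=[1.0, 1.0, 0.3, 1.0])
        assert is_p.tolist() == [True, False, False, False]
        assert frac == 0.25

    def test_negative_cv_vstar_counts_via_magnitude(self):
        is_p, _ = pn.identify_pioneers(cv_tau=[0.2], cv_vstar=[-2.0])
        assert is_p[0]


class TestSpikeTriggeredDeviation:
    def test_random_spikes_give_no_deviation(self, make_result):
        """Probe spikes placed independently of a stationary activity
        trace show no systematic deviation."""
        rng = np.random.default_rng(2)
        bg = np.sort(rng.uniform(0, 200_000.0, 2000))
        res_bg = make_result(np.zeros(bg.size, int), bg, n_exc=1,
                             duration=200_000.0)
        act = pn.population_activity(res_bg, stride=1.0, kernel_width=3.0)
        probe = np.sort(rng.uniform(200.0, 199_800.0, 500))
        res = make_result(np.zeros(probe.size, int), probe, n_exc=1,
                          duration=200_000.0)
        _, gamma = pn.spike_triggered_deviation(res, act, [], 0)
        se = act.values.std() / np.sqrt(probe.size)
        assert np.abs(np.nanmean(gamma)) < 3 * se

    def test_planted_bumps_recovered(self, make_result):
        """Spikes placed at the centers of synthetic activity bumps
        reproduce the bump shape at negative lags."""
        from pioneernet.dynamics import ActivityTrace

        t = np.arange(100_000)* 1.0
        centers = np.arange(5000.0, 95_000.0, 1000.0)
        v = np.zeros(t.size)
        for c in centers:
            v += 10.0 * np.exp(-(t - c) ** 2 / (2 * 15.0 ** 2))
        act = ActivityTrace(times=t, values=v, stride=1.0, kernel_width=3.0,
                            population="exc", rates=np.zeros(1))
        res = make_result(np.zeros(centers.size, int), centers, n_exc=1,
                          duration=100_000.0)
        lags = np.arange(-50.0, 51.0, 1.0)
        _, gamma = pn.spike_triggered_deviation(res, act, [], 0, lags=lags)
        expected = 10.0 * np.exp(-lags ** 2 / (2 * 15.0 ** 2)) - v.mean()
        assert np.allclose(gamma, expected, atol=0.05)


class TestResourceDensity:
    def test_silent_neuron_density_at_one(self):
        topo = pn.NetworkTopology(
            n_exc=2, n_inh=1,
            pre=np.array([0], np.int32), post=np.array([1], np.int32),
            weight=np.array([1.0]), U=np.array([0.3]),
            tau_rec=np.array([800.0]), tau_facil=np.array([0.0]))
        quiet = pn.NeuronParams(I_b=0.0)  # presynaptic neuron never fires
        from pioneernet.config import inh_params
        res = pn.simulate(topo, 6000.0, params=(quiet, inh_params()),
                          record_resources=True, resource_stride_ms=5.0,
                          seed=0)
        grid, dens, samples = pn.resource_density(res, [], 0)
        assert samples.min() > 0.999
        assert grid[np.argmax(dens)] == pytest.approx(1.0, abs=0.05)

    def test_steady_firing_depletes_resources(self):
        """A tonically firing neuron's efferent R concentrates near the
        depression steady state 1/(1 + U tau_rec nu)."""
        U, tau_rec = 0.3, 500.0
        topo = pn.NetworkTopology(
            n_exc=2, n_inh=1,
            pre=np.array([0], np.int32), post=np.array([1], np.int32),
            weight=np.array([1.0]), U=np.array([U]),
            tau_rec=np.array([tau_rec]), tau_facil=np.array([0.0]))
        res = pn.simulate(topo, 42_000.0, record_resources=True,
                          resource_stride_ms=5.0, seed=0)
        nu = res.per_neuron_rates()[0]
        expected = 1.0 / (1.0 + U * (tau_rec / 1000.0) * nu)
        grid, dens, samples = pn.resource_density(res, [], 0)
        mode = grid[np.argmax(dens)]
        assert abs(mode - expected) < 0.1


class TestPspEstimates:
    def test_peak_time_arithmetic(self):
        assert psp_peak_time(30.0, 3.0) == pytest.approx(
            (90.0 / 27.0) * np.log(10.0), rel=1e-12)

    def test_zero_rate_gives_zero_steady_state(self):
        topo = pn.NetworkTopology(
            n_exc=2, n_inh=1,
            pre=np.array([0], np.int32), post=np.array([1], np.int32),
            weight=np.array([1000.0]), U=np.array([0.3]),
            tau_rec=np.array([800.0]), tau_facil=np.array([0.0]))
        df = pn.psp_estimates(topo, rates_hz=np.zeros(2),
                              v_mean=np.full(3, -55.0))
        assert df.loc[0, "psp_ss_mV"] == 0.0
        assert df.loc[0, "psp_single_mV"] > 0.0

    def test_steady_state_approximation_small_rate(self):
        """<W>_ss ~= tau_m * nu * W(t_max) for small rates."""
        topo = pn.NetworkTopology(
            n_exc=2, n_inh=1,
            pre=np.array([0], np.int32), post=np.array([1], np.int32),
            weight=np.array([1000.0]), U=np.array([0.3]),
            tau_rec=np.array([800.0]), tau_facil=np.array([0.0]))
        nu = 0.05
        df = pn.psp_estimates(topo, rates_hz=np.array([nu, 0.0]),
                              v_mean=np.full(3, -55.0))
        # tau_m in s times nu in Hz times single-spike PSP; the stated
        # approximation carries a shape factor (tau_m - tau_I)/(tau_m *
        # [exp(-t_max/tau_m) - exp(-t_max/tau_I)]) ~= 1.29 at these
        # constants, so agreement is to ~30%
        approx = (30.0 / 1000.0) * nu * df.loc[0, "psp_single_mV"]
        ratio = df.loc[0, "psp_ss_mV"] / approx
        assert 0.7 < ratio < 1.4


class TestSpectraAndCorrelations:
    def test_poisson_spectrum_is_flat_at_rate(self, make_result):
        rng = np.random.default_rng(3)
        nu = 20.0
        times = np.sort(rng.uniform(0, 100_000.0, rng.poisson(nu * 100)))
        res = make_result(np.zeros(times.size, int), times, n_exc=1,
                          duration=100_000.0)
        f, S, _ = pn.power_spectrum(res, [], neurons=[0], bin_t_s=20.0)
        high = S[0, f > 500.0]
        nu_realized = times.size / 100.0
        # periodogram samples are correlated across nothing but noisy;
        # the flat level must match the realized rate within a few percent
        assert abs(high.mean() - nu_realized) < 0.05 * nu_realized
        assert abs(high.mean() - nu) < 0.1 * nu

    def test_periodic_train_line_spectrum(self, make_result):
        period = 50.0  # ms -> 20 Hz line
        times = np.arange(0.0, 20_000.0, period)
        res = make_result(np.zeros(times.size, int), times, n_exc=1,
                          duration=20_000.0)
        f, S, _ = pn.power_spectrum(res, [], neurons=[0], bin_t_s=20.0)
        peak_f = f[1:][np.argmax(S[0, 1:])]
        assert peak_f == pytest.approx(20.0, abs=0.1)

    def test_identical_trains_fully_correlated(self, make_result):
        rng = np.random.default_rng(4)
        t = np.sort(rng.uniform(0, 20_000.0, 400))
        res = make_result(np.r_[np.zeros(400, int), np.ones(400, int)],
                          np.r_[t, t], n_exc=2, duration=20_000.0)
        mean, sd, n, _ = pn.pairwise_correlation(res, [], bin_t_s=20.0)
        assert mean == pytest.approx(1.0)
        assert n == 1

    def test_independent_poisson_nearly_uncorrelated(self, make_result):
        rng = np.random.default_rng(5)
        neurons, times = [], []
        for nid in range(20):
            t = np.sort(rng.uniform(0, 100_000.0, 500))
            neurons.extend([nid] * t.size)
            times.extend(t)
        res = make_result(neurons, times, n_exc=20, duration=100_000.0)
        mean, sd, n, _ = pn.pairwise_correlation(res, [], bin_t_s=20.0)
        assert abs(mean) < 0.01
        assert n == 190


class TestFullNetworkProperties:
    def test_latency_decreases_through_pioneer_range(self, full_het_analysis):
        """Mean first-spike latency falls with activity rank across the
        upper-middle of the sorted population (Spearman rho < 0)."""
        from scipy.stats import spearmanr

        res, act, events = full_het_analysis
        ro = pn.sort_by_rate(res)
        table = pn.first_spike_latencies(res, events)
        ml = mean_latency(table)
        sel = (ro.rank >= 200) & (ro.rank <= 320) & np.isfinite(ml)
        rho = spearmanr(ro.rank[sel], ml[sel]).statistic
        assert rho < -0.5

    def test_gamma_unbiased_for_surrogate_spikes(self, full_het_analysis):
        """Uniformly redistributed between-NS spikes show no systematic
        activity deviation."""
        res, act, events = full_het_analysis
        rng = np.random.default_rng(0)
        from pioneernet.events import between_ns_mask
        n_sp = 400
        cand = rng.uniform(res.warmup, res.duration, size=5 * n_sp)
        cand = cand[between_ns_mask(cand, events)][:n_sp]
        sur = pn.SimulationResult(
            n_exc=1, n_inh=0, dt=res.dt, duration=res.duration,
            warmup=res.warmup, spike_neuron=np.zeros(cand.size, np.int32),
            spike_time=np.sort(cand),
            spike_forced=np.zeros(cand.size, bool))
        lags, gamma = pn.spike_triggered_deviation(sur, act, events, 0)
        between = act.values[between_ns_mask(act.times, events)]
        se = between.std() / np.sqrt(cand.size)
        assert abs(np.nanmean(gamma)) < 3 * se

    def test_pioneers_sit_just_below_threshold(self, full_het_analysis):
        """Identified pioneers have mean V* within about one standard
        deviation below firing threshold."""
        res, act, events = full_het_analysis
        df = pn.compute_neuron_metrics(res, act, events)
        pio = df[df.is_pioneer]
        assert len(pio) > 0
        dist = (-50.0 - pio.star_mean_mV) / pio.star_sd_mV
        assert np.median(dist) < 2.0

    def test_resource_retention_decreases_with_activity(
            self, full_het_run, full_het_analysis):
        """Between-NS synaptic resources fall monotonically with activity
        rank: quiet neurons stay recovered, pioneer-range neurons retain
        substantially more than the most active neurons."""
        topo, res = full_het_run
        _, act, events = full_het_analysis
        ro = pn.sort_by_rate(res)
        from pioneernet.events import between_ns_mask
        mask = between_ns_mask(res.resource_times, events)
        mean_r = res.resources[mask].mean(axis=0)
        quiet = np.median(mean_r[ro.band(100, 160)])
        pioneer = np.median(mean_r[ro.band(260, 320)])
        top = np.median(mean_r[ro.band(340, 400)])
        assert quiet > pioneer > top
        assert pioneer > 0.4
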