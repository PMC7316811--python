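"""Stochastic IHC signal chain: stimulus, MET gating, membrane, Ca2+
channels, release, refractoriness and correlation summaries."""

import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ihcsync.syncytium_sim import (
    CaChannelModel,
    METModel,
    ReleaseRules,
    SinusoidStimulus,
    SyncytiumConfig,
    UndefinedCorrelationError,
    ap_probability,
    ca_open_prob_trace,
    correlation_summary,
    integrate_membrane,
    junctional_currents,
    lagged_pearson,
    make_stimulus,
    met_open_prob,
    prune_refractory,
    release_events,
    release_intensity,
    simulate_ca_channel,
    simulate_conditions,
    simulate_met_gating,
    simulate_syncytium,
)


class TestStimulus:
    def test_zero_amplitude_is_constant_zero(self):
        _, x = make_stimulus(SinusoidStimulus(amplitude=0.0,
                                              duration_ms=20.0))
        np.testing.assert_array_equal(x, 0.0)

    def test_period_spans_expected_samples(self):
        s = SinusoidStimulus(frequency_hz=500.0, dt_us=10.0,
                             duration_ms=20.0)
        t, x = make_stimulus(s)
        period_samples = int(round(1e6 / 500.0 / 10.0))
        assert period_samples == 200
        np.testing.assert_allclose(x[:1800], x[200:2000], atol=1e-9)

    def test_zero_mean_over_whole_cycles(self):
        s = SinusoidStimulus(duration_ms=20.0, amplitude=1.0)
        _, x = make_stimulus(s)
        assert abs(x.mean()) < 1e-12

    def test_dt_invariant_enforced(self):
        with pytest.raises(ValueError):
            SinusoidStimulus(dt_us=50.0)


class TestMETGating:
    def test_open_prob_closed_forms(self):
        m = METModel()
        assert met_open_prob(m.x_half, m) == pytest.approx(0.5)
        assert met_open_prob(m.x_half + m.slope, m) == \
            pytest.approx(1 / (1 + math.exp(-1.0)), rel=1e-12)
        assert met_open_prob(50.0, m) == pytest.approx(1.0, abs=1e-8)

    def test_stationary_mean_and_variance_binomial(self):
        # constant stimulus with p_inf = 0.3: mean 24 of 80, var n p (1-p)
        m = METModel(n_channels=80, x_half=math.log(7 / 3))
        x = np.zeros(200_000)
        counts = simulate_met_gating(x, m, rng=1, dt_us=10.0)
        counts = counts[5000:]  # discard burn-in
        assert counts.mean() == pytest.approx(24.0, abs=0.5)
        assert counts.var() == pytest.approx(80 * 0.3 * 0.7, rel=0.10)

    def test_fast_channel_limit_tracks_p_inf(self):
        # tau -> small: occupancy follows p_inf(x(t)) instantaneously
        s = SinusoidStimulus(duration_ms=50.0, amplitude=1.0)
        _, x = make_stimulus(s)
        m = METModel(n_channels=400, tau_met_us=15.0)
        counts = simulate_met_gating(x, m, rng=2, dt_us=10.0)
        p_emp = counts[100:] / m.n_channels
        p_inf = np.asarray(met_open_prob(x[100:], m))
        assert np.corrcoef(p_emp, p_inf)[0, 1] > 0.9

    def test_same_seed_identical(self):
        _, x = make_stimulus(SinusoidStimulus(duration_ms=20.0))
        a = simulate_met_gating(x, METModel(), rng=7)
        b = simulate_met_gating(x, METModel(), rng=7)
        np.testing.assert_array_equal(a, b)


class TestMembrane:
    def test_zero_met_conductance_relaxes_to_leak_reversal(self, fast_cfg):
        n = fast_cfg.stimulus.n_samples
        met = np.zeros((3, n))
        v = integrate_membrane(met, fast_cfg)
        assert np.all(np.abs(v[:, -1] - fast_cfg.compartment.e_leak_mV)
                      < 1e-6)

    def test_identical_met_input_makes_coupling_invisible(self, fast_cfg):
        n = fast_cfg.stimulus.n_samples
        rng = np.random.default_rng(0)
        one = rng.integers(0, 80, n).astype(float)
        met = np.tile(one, (3, 1))
        v_coupled = integrate_membrane(met, fast_cfg)
        v_uncoupled = integrate_membrane(
            met, replace(fast_cfg, rj_mohm=math.inf))
        np.testing.assert_allclose(v_coupled, v_uncoupled, atol=1e-9)

    def test_coupling_shrinks_voltage_differences(self, fast_cfg):
        c, u = simulate_conditions(fast_cfg)
        var_c = np.var(c.voltage[0] - c.voltage[1])
        var_u = np.var(u.voltage[0] - u.voltage[1])
        assert var_c < var_u

    def test_uncoupled_chain_equals_independent_single_cells(self, fast_cfg):
        cfg = replace(fast_cfg, rj_mohm=math.inf)
        res = simulate_syncytium(cfg)
        for i in range(cfg.n_cells):
            solo = integrate_membrane(res.met_open[i][None, :],
                                      replace(cfg, n_cells=1))
            np.testing.assert_array_equal(res.voltage[i], solo[0])

    def test_junctional_charge_conservation(self, fast_cfg):
        res = simulate_syncytium(fast_cfg)
        ij = junctional_currents(res.voltage, fast_cfg.rj_mohm)
        # current from cell i into i+1 is minus the current from i+1 into i
        # by construction; check net charge between the two directions
        q_fwd = ij.sum(axis=1)
        q_bwd = (-ij).sum(axis=1)
        np.testing.assert_allclose(q_fwd, -q_bwd, rtol=1e-9)


class TestCaChannel:
    def test_constant_vh_gives_half_activation(self):
        ca = CaChannelModel()
        v = np.full(5000, ca.vh_mV)
        p = ca_open_prob_trace(v, ca)
        assert p[-1] == pytest.approx(0.5, abs=1e-9)

    def test_instantaneous_limit(self):
        ca = CaChannelModel(tau_act_us=1e-6)
        v = np.linspace(-80, 0, 1000)
        p = ca_open_prob_trace(v, ca)
        p_inf = 1 / (1 + np.exp(-(v - ca.vh_mV) / ca.k_mV))
        np.testing.assert_allclose(p[1:], p_inf[1:], atol=1e-6)

    def test_step_response_time_constant(self):
        ca = CaChannelModel(tau_act_us=500.0)
        v = np.concatenate([np.full(2000, -80.0), np.full(3000, ca.vh_mV)])
        p = ca_open_prob_trace(v, ca, dt_us=10.0)
        resp = p[2000:]
        p0, p_inf = resp[0], 0.5
        # fit tau from the log-linear decay of the residual
        resid = (p_inf - resp[:200]) / (p_inf - p0)
        t = np.arange(200) * 10.0
        tau_fit = -1.0 / np.polyfit(t, np.log(resid), 1)[0]
        assert tau_fit == pytest.approx(500.0, rel=0.01)

    def test_markov_equilibrium_occupancy(self):
        # constant V: empirical occupancy equals p_inf within 3 SE
        ca = CaChannelModel()
        v = np.full(5000, -30.0)
        p_inf = 1 / (1 + math.exp(-(-30.0 - ca.vh_mV) / ca.k_mV))
        states = simulate_ca_channel(v, ca, rng=3, n_realizations=400)
        occ = states[:, 1000:].mean()
        n_samples = states[:, 1000:].size
        # decorrelation time ~ tau_act => effective sample count
        n_eff = n_samples / (2 * ca.tau_act_us / 10.0)
        se = math.sqrt(p_inf * (1 - p_inf) / n_eff)
        assert abs(occ - p_inf) < 3 * se

    def test_zero_closing_rate_stays_open(self):
        ca = CaChannelModel(vh_mV=-200.0)  # p_inf ~ 1 => beta ~ 0
        v = np.full(2000, 0.0)
        s = simulate_ca_channel(v, ca, rng=4)
        first_open = np.argmax(s)
        assert s[first_open:].all()

    def test_open_dwell_times_exponential(self):
        # mean open dwell = 1 / beta = tau / (1 - p_inf)
        ca = CaChannelModel(tau_act_us=500.0)
        v_const = -25.0  # p_inf = 0.5
        v = np.full(400_000, v_const)
        s = simulate_ca_channel(v, ca, rng=5)
        d = np.diff(np.concatenate([[0], s.astype(np.int8), [0]]))
        starts, ends = np.flatnonzero(d == 1), np.flatnonzero(d == -1)
        dwells = (ends - starts) * 10.0  # us
        expected = 500.0 / 0.5
        assert dwells.mean() == pytest.approx(expected, rel=0.05)


class TestReleaseAndRefractoriness:
    RULES = ReleaseRules(min_open_ms=2.0, refractory_ms=1.0)

    def test_single_long_opening_timestamped_at_threshold(self):
        dt = 10.0
        state = np.zeros(1000, bool)
        state[100:400] = True  # 3 ms opening starting at 1 ms
        ev = release_events(state, self.RULES, dt)
        assert ev.size == 1
        assert ev[0] == pytest.approx(1.0 + 2.0 - dt / 1e3)

    def test_short_opening_ignored(self):
        state = np.zeros(1000, bool)
        state[100:200] = True  # 1 ms
        assert release_events(state, self.RULES).size == 0

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_event_count_matches_interval_scan_oracle(self, seed):
        rng = np.random.default_rng(seed)
        state = rng.random(3000) < 0.6
        ev = release_events(state, self.RULES, dt_us=100.0)
        # brute-force scan of maximal open runs
        count, run = 0, 0
        for s in state:
            run = run + 1 if s else 0
            if run == 20:  # 2 ms at 100 us steps
                count += 1
        assert ev.size == count

    def test_greedy_refractory_pass(self):
        aps = prune_refractory(np.array([0.0, 1.0, 3.0]),
                               ReleaseRules(refractory_ms=2.0))
        np.testing.assert_array_equal(aps, [0.0, 3.0])

    def test_empty_events(self):
        assert prune_refractory(np.array([]), self.RULES).size == 0

    def test_unsorted_events_rejected(self):
        with pytest.raises(ValueError):
            prune_refractory(np.array([3.0, 1.0]), self.RULES)

    def test_no_isi_below_refractory(self):
        rng = np.random.default_rng(11)
        events = np.sort(rng.uniform(0, 100, 2000))
        aps = prune_refractory(events, ReleaseRules(refractory_ms=1.5))
        assert np.diff(aps).min() >= 1.5

    def test_poisson_dead_time_rate_oracle(self):
        # accepted rate for Poisson input at rate lam with dead time d:
        # lam / (1 + lam d)
        lam, dead = 2.0, 1.0  # per ms, ms
        rng = np.random.default_rng(12)
        n = 100_000
        events = np.cumsum(rng.exponential(1 / lam, n))
        aps = prune_refractory(events, ReleaseRules(refractory_ms=dead))
        rate = aps.size / events[-1]
        assert rate == pytest.approx(lam / (1 + lam * dead), rel=0.02)


class TestReleaseIntensity:
    def test_matches_monte_carlo_at_constant_voltage(self):
        ca = CaChannelModel()
        rules = ReleaseRules()
        v = np.full(50_000, -22.0)
        lam = release_intensity(v, ca, rules)  # events per ms
        analytic_rate = lam[30_000:].mean()
        from ihcsync.syncytium_sim import _ca_release_events_vec
        evs = _ca_release_events_vec(v, ca, rules,
                                     np.random.default_rng(6), 400, 10.0)
        t_total = (50_000 * 10.0 / 1e3 - rules.min_open_ms) * 400
        mc_rate = sum(e.size for e in evs) / t_total
        assert mc_rate == pytest.approx(analytic_rate, rel=0.05)

    def test_zero_before_min_open_elapsed(self):
        v = np.full(1000, 0.0)
        lam = release_intensity(v, CaChannelModel(), ReleaseRules())
        assert np.all(lam[:200] == 0.0)
        assert lam[200:].min() > 0.0


class TestAPProbability:
    def test_probabilities_valid_and_windows_tile(self, fast_cfg):
        res = simulate_syncytium(fast_cfg)
        traces = ap_probability(res, n_realizations=150, window_us=200.0)
        for tr in traces:
            assert np.all((tr.p_ap >= 0) & (tr.p_ap <= 1))
            np.testing.assert_allclose(np.diff(tr.window_edges_ms), 0.2)
        assert traces[0].window_edges_ms[0] == \
            fast_cfg.stimulus.onset_discard_ms

    def test_flat_without_stimulus(self):
        cfg = SyncytiumConfig(
            n_cells=1, seed=3,
            stimulus=SinusoidStimulus(amplitude=0.0, duration_ms=40.0,
                                      onset_discard_ms=5.0))
        res = simulate_syncytium(cfg)
        tr = ap_probability(res, n_realizations=400, window_us=200.0)[0]
        p = tr.p_ap
        se = math.sqrt(p.mean() * (1 - p.mean()) / 400)
        # stationary: no window deviates grossly from the mean
        assert np.abs(p - p.mean()).max() < 5 * se + 1e-12


class TestCorrelations:
    def test_exact_shift_gives_unit_correlation(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=5000)
        k = 37
        y = np.concatenate([np.zeros(k), x])[: x.size]
        r = lagged_pearson(x[: x.size - k], y[: x.size - k], k * 0.01, 10.0)
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_sign_flip(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=2000)
        assert lagged_pearson(x, -x, 0.0, 10.0) == pytest.approx(-1.0)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_matches_covariance_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=(2, 500))
        r = lagged_pearson(x, y, 0.0, 10.0)
        oracle = (np.mean(x * y) - x.mean() * y.mean()) / (x.std() * y.std())
        assert r == pytest.approx(oracle, abs=1e-12)

    def test_zero_variance_raises(self):
        with pytest.raises(UndefinedCorrelationError):
            lagged_pearson(np.ones(500), np.arange(500.0), 0.0, 10.0)

    def test_identical_cells_fully_correlated(self, fast_cfg):
        n = fast_cfg.stimulus.n_samples
        rng = np.random.default_rng(0)
        met = np.tile(rng.integers(0, 80, n).astype(float), (3, 1))
        res = simulate_syncytium(fast_cfg, met_counts=met)
        summ = correlation_summary(res)
        assert summ.pairwise["voltage"] == pytest.approx(1.0, abs=1e-9)
        assert summ.pairwise["ca_open_prob"] == pytest.approx(1.0, abs=1e-9)

    def test_coupling_raises_pairwise_voltage_correlation(self, fast_cfg):
        c, u = simulate_conditions(fast_cfg)
        assert correlation_summary(c).pairwise["voltage"] > \
            correlation_summary(u).pairwise["voltage"]


class TestSynchronizationProperties:
    def test_monotone_synchronization_with_coupling_strength(self):
        rjs = [math.inf, 100.0, 50.0, 25.0, 10.0]
        means = []
        for rj in rjs:
            vals = []
            for seed in range(20):
                cfg = SyncytiumConfig(
                    seed=seed, rj_mohm=rj,
                    stimulus=SinusoidStimulus(duration_ms=30.0,
                                              onset_discard_ms=5.0))
                res = simulate_syncytium(cfg)
                vals.append(correlation_summary(res).pairwise["voltage"])
            means.append(np.mean(vals))
        assert all(b > a for a, b in zip(means, means[1:]))

    def test_stage_ordering_and_coupling_gap(self, fast_cfg):
        # uncoupled: correlation with the stimulus does not improve down
        # the chain voltage -> Ca gating; coupling narrows the gap at
        # every stage
        gaps = {}
        cs, us = [], []
        for seed in range(5):
            c, u = simulate_conditions(replace(fast_cfg, seed=seed))
            cs.append(correlation_summary(c).vs_stimulus)
            us.append(correlation_summary(u).vs_stimulus)
        for stage in ("voltage", "ca_open_prob"):
            rc = np.mean([s[stage] for s in cs])
            ru = np.mean([s[stage] for s in us])
            assert rc > ru
            gaps[stage] = rc - ru
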