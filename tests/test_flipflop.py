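import numpy as np
import pytest

import sleepswitch.flipflop as ff


class TestBuildNetwork:
    def test_deterministic_from_seed(self):
        a = ff.build_network(42)
        b = ff.build_network(42)
        assert np.array_equal(a.W, b.W)

    def test_within_pool_weights_are_zero(self):
        net = ff.build_network(1)
        p = net.params
        assert np.all(net.W[p.sl_r, p.sl_r] == 0)
        assert np.all(net.W[p.sl_n, p.sl_n] == 0)

    def test_cross_pool_weights_inhibitory_and_bounded(self):
        net = ff.build_network(2)
        p = net.params
        w_nr = net.W[p.sl_n, p.sl_r]
        w_rn = net.W[p.sl_r, p.sl_n]
        assert np.all(w_nr <= 0) and np.all(w_rn <= 0)
        assert np.abs(w_nr).max() <= 1.0 / p.d_n_to_r
        assert np.abs(w_rn).max() <= 1.0 / p.d_r_to_n

    def test_connection_count_matches_binomial_expectation(self):
        counts = [
            int((ff.build_network(s).W[ff.FlipFlopParams().sl_n,
                                       ff.FlipFlopParams().sl_r] != 0).sum())
            for s in range(200)
        ]
        expect = 25 * 25 * 0.5
        sd = np.sqrt(25 * 25 * 0.25)
        assert abs(np.mean(counts) - expect) < 3 * sd / np.sqrt(200)

    def test_input_connections_full_and_signed(self):
        p = ff.FlipFlopParams()
        net_r = ff.build_network(3, scenario="ramp_to_r")
        assert np.all(net_r.W[p.sl_input, p.sl_r] == abs(p.input_weight))
        net_n = ff.build_network(3, scenario="ramp_to_n")
        assert np.all(net_n.W[p.sl_input, p.sl_n] == -abs(p.input_weight))

    def test_invalid_pool_sizes_rejected(self):
        with pytest.raises(ValueError):
            ff.FlipFlopParams(n_r=0, n_n=0, n_input=0)
        with pytest.raises(ValueError):
            ff.FlipFlopParams(conn_p=1.5)


class TestSimulate:
    def test_epoch_count(self):
        net = ff.build_network(1)
        out = ff.simulate(net, 1)
        assert out.n_epochs == 400
        assert out.spikes.shape == (8000, 60)

    def test_bit_identical_for_fixed_seed(self):
        net = ff.build_network(5)
        a = ff.simulate(net, 9)
        b = ff.simulate(net, 9)
        assert np.array_equal(a.spikes, b.spikes)
        assert np.array_equal(a.rate_diff, b.rate_diff)

    def test_noise_free_no_ramp_stays_in_n_state(self):
        net = ff.build_network(11)
        out = ff.simulate(net, 5, ramp=False, noise_amp=0.0)
        assert out.rate_diff.max() < 0.0

    def test_noise_free_ramp_single_transition(self):
        net = ff.build_network(11)
        out = ff.simulate(net, 5, ramp=True, noise_amp=0.0)
        d = out.rate_diff
        # one sign change among clearly-resolved epochs, ending R-dominant
        strong = d[np.abs(d) > 0.1]
        crossings = int(np.sum(np.diff(np.sign(strong)) != 0))
        assert crossings == 1
        assert d[-1] > 0

    def test_single_lif_isi_matches_closed_form(self):
        p = ff.FlipFlopParams(n_input=0, n_r=1, n_n=0, bias_r=2.0,
                              noise_amp=0.0, dt=0.001, total_iterations=20000)
        net = ff.build_network(0, p, scenario="ramp_to_r")
        out = ff.simulate(net, 0, ramp=False)
        spike_times = np.where(out.spikes[:, 0])[0] * p.dt
        isi = np.diff(spike_times)
        theory = np.log(2.0)  # ln(I / (I - 1)) at I = 2
        assert abs(isi.mean() - theory) / theory < 0.02


class TestScoreSwitch:
    def test_constant_below_threshold_is_all_n(self):
        d = np.full(50, -1.0)
        assert (ff.score_switch(d, thr_n=0.0, thr_r=1.0) == "N").all()

    def test_single_epoch_spike_removed_by_persistence(self):
        d = np.full(20, -1.0)
        d[10] = 5.0
        scored = ff.score_switch(d, thr_n=0.0, thr_r=1.0)
        assert (scored == "N").all()

    def test_alternating_blocks_hand_enumerated(self):
        d = np.concatenate([
            np.full(3, -1.0), np.full(3, 0.5), np.full(3, 2.0), np.full(3, -1.0)
        ])
        scored = ff.score_switch(d, thr_n=0.0, thr_r=1.0)
        assert "".join(scored) == "NNNtttRRRNNN"

    def test_thresholds_must_be_ordered(self):
        with pytest.raises(ValueError):
            ff.score_switch(np.zeros(5), thr_n=1.0, thr_r=0.0)


class TestDeriveThresholds:
    def test_symmetric_mixture_midpoints(self, rng):
        d = np.concatenate([rng.normal(-5, 1, 4000), rng.normal(5, 1, 4000)])
        thr = ff.derive_thresholds(d)
        assert thr.thr_n == pytest.approx(-2.5, abs=0.4)
        assert thr.thr_r == pytest.approx(2.5, abs=0.4)

    def test_thresholds_are_fraction_between_trough_and_modes(self, rng):
        d = np.concatenate([rng.normal(-5, 2.0, 4000), rng.normal(5, 1.0, 2000)])
        thr = ff.derive_thresholds(d)
        assert thr.thr_n == pytest.approx((thr.trough + thr.mode_n) / 2)
        assert thr.thr_r == pytest.approx((thr.trough + thr.mode_r) / 2)
        assert thr.thr_n < thr.thr_r

    def test_unimodal_raises(self, rng):
        with pytest.raises(ff.BistabilityError):
            ff.derive_thresholds(rng.normal(0, 1, 5000))


class TestMetricsAndGrids:
    def test_run_metrics_hand_case(self):
        scored = np.array(list("NNNttRRRttRRNN"))
        m = ff.run_metrics(scored)
        assert m.latency_to_r == 5
        assert not m.latency_censored
        assert m.n_n_epochs == 5 and m.n_r_epochs == 5
        assert m.nrt_density_from_n == pytest.approx(1 / 5)
        assert m.nrt_density_from_r == pytest.approx(1 / 5)

    def test_latency_censored_without_r(self):
        m = ff.run_metrics(np.array(list("NNNNtt")))
        assert m.latency_censored and m.latency_to_r == 6

    def test_grid_enumeration(self):
        runs = ff.grid_runs(reps=25)
        assert len(runs) == 25 * 121
        assert len({(a, b) for a, b, _ in runs}) == 121

    def test_bias_grid_values(self):
        assert len(ff.BIAS_VALUES) == 11
        assert ff.BIAS_VALUES[0] == 1.5 and ff.BIAS_VALUES[-1] == 2.5
        assert len(ff.D_VALUES) == 11
        assert ff.D_VALUES[0] == 1.8 and ff.D_VALUES[-1] == 2.8
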