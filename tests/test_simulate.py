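"""Synthetic spike datasets: latent dynamics, Poisson spiking, VAR realizations."""

import numpy as np
import pytest

from spikegc import (
    build_dataset,
    default_config,
    simulate_latent_rates,
    simulate_spike_trains,
    simulate_var_series,
    write_dataset,
)


class TestLatentRates:
    def test_zero_coupling_zero_noise_constant_at_fixed_point(self):
        cfg = default_config(seed=0, component_coupling=np.zeros((8, 8)), noise_sd=0.0)
        z = simulate_latent_rates(cfg, "correct")
        assert np.allclose(z, cfg.latent_mean)

    def test_unit_gain_makes_correct_and_error_identical(self):
        cfg = default_config(seed=0, coupling_peak_gain=1.0)
        zc = simulate_latent_rates(cfg, "correct", trial_index=3)
        ze = simulate_latent_rates(cfg, "error", trial_index=3)
        assert np.array_equal(zc, ze)

    def test_chain_lag1_crosscorrelation_matches_scalar_recursion(self):
        # two-component chain 1->2 coefficient 0.6; high mean so rectification
        # never binds and the dynamics are exactly linear
        C = np.array([[0.0, 0.0], [0.6, 0.0]])
        cfg = default_config(
            seed=5, n_components=2, component_coupling=C, noise_sd=1.0,
            latent_mean=100.0, trial_duration=60.0, rt_time=30.0,
            coupling_peak_gain=1.0,
        )
        z = simulate_latent_rates(cfg, "baseline", trial_index=0)
        x, y = z[0] - 100.0, z[1] - 100.0
        got = np.corrcoef(y[1:], x[:-1])[0, 1]
        # independent brute-force scalar AR recursion with the same substream
        rng = cfg.rng(0, 0)
        eps = rng.standard_normal((2, z.shape[1]))
        xo = np.zeros(z.shape[1])
        yo = np.zeros(z.shape[1])
        for k in range(1, z.shape[1]):
            xo[k] = eps[0, k]
            yo[k] = 0.6 * xo[k - 1] + eps[1, k]
        want = np.corrcoef(yo[1:], xo[:-1])[0, 1]
        assert abs(got - want) < 0.05

    def test_unstable_gain_rejected_with_diagnostic(self):
        C = 0.9 * np.eye(3)
        C[0, 1] = C[1, 0] = 0.3  # feedback loop: gain raises spectral radius
        with pytest.raises(ValueError, match="coupling_peak_gain"):
            default_config(seed=0, n_components=3, component_coupling=C,
                           coupling_peak_gain=4.0)

    def test_higher_gain_does_not_reduce_peak_lagged_crosscorrelation(self):
        vals = []
        for gain in (1.0, 4.0):
            cfg = default_config(seed=9, coupling_peak_gain=gain)
            cc = []
            for t in range(10):
                z = simulate_latent_rates(cfg, "correct", trial_index=t)
                i0 = int((cfg.rt_time - 0.5) / cfg.sample_dt)
                i1 = int((cfg.rt_time - 0.0) / cfg.sample_dt)
                hub, tgt = z[0, i0:i1], z[1, i0:i1]
                cc.append(np.corrcoef(tgt[1:], hub[:-1])[0, 1])
            vals.append(np.mean(cc))
        assert vals[1] >= vals[0]


class TestSpikeTrains:
    def test_mean_count_matches_poisson_rate(self):
        # zero loadings is disallowed, so use negligible ones instead
        lam, duration, n_rep = 6.0, 2.0, 200
        cfg = default_config(seed=2, baseline_rate=lam,
                            loading_matrix=np.full((20, 8), 1e-9))
        counts = []
        for t in range(n_rep):
            z = simulate_latent_rates(cfg, "baseline", trial_index=t)
            trains = simulate_spike_trains(z, cfg, trial_index=t)
            counts.append(np.mean([tr.n_spikes for tr in trains]))
        expected = lam * duration
        se = np.sqrt(expected / (n_rep * cfg.n_neurons))
        assert abs(np.mean(counts) - expected) < 3 * se

    def test_doubled_intensity_doubles_counts(self):
        means = []
        for lam in (5.0, 10.0):
            cfg = default_config(seed=3, baseline_rate=lam,
                                loading_matrix=np.full((20, 8), 1e-9))
            counts = []
            for t in range(100):
                z = simulate_latent_rates(cfg, "baseline", trial_index=t)
                counts.append(np.mean([tr.n_spikes for tr in
                                       simulate_spike_trains(z, cfg, trial_index=t)]))
            means.append(np.mean(counts))
        assert abs(means[1] / means[0] - 2.0) < 0.1

    def test_zero_intensity_gives_empty_trains(self):
        cfg = default_config(seed=1, baseline_rate=0.0,
                            loading_matrix=np.full((20, 8), 1e-12))
        z = np.zeros((8, 201))
        trains = simulate_spike_trains(z, cfg)
        assert all(tr.n_spikes == 0 for tr in trains)

    def test_spike_times_sorted_within_bounds(self):
        cfg = default_config(seed=4)
        z = simulate_latent_rates(cfg, "correct")
        for tr in simulate_spike_trains(z, cfg, t_start=10.0):
            assert np.all(np.diff(tr.times) > 0)
            assert tr.times.size == 0 or (tr.times[0] >= 10.0 and tr.times[-1] <= 12.0)


class TestVARSeries:
    def test_zero_coefficients_give_white_noise(self):
        n = 20000
        x = simulate_var_series(np.zeros((1, 3, 3)), np.eye(3), n, seed=0)
        for i in range(3):
            r1 = np.corrcoef(x[i, 1:], x[i, :-1])[0, 1]
            assert abs(r1) < 3 / np.sqrt(n)

    def test_stationary_variance_matches_lyapunov_iteration(self):
        A = np.array([[0.0, 0.0], [0.5, 0.0]])
        x = simulate_var_series(A[None], np.eye(2), 20000, seed=1)
        # brute-force discrete Lyapunov: Sigma <- A Sigma A' + Q to convergence
        S = np.eye(2)
        for _ in range(500):
            S = A @ S @ A.T + np.eye(2)
        assert abs(np.var(x[1]) - S[1, 1]) / S[1, 1] < 0.05

    def test_identical_seed_identical_series(self):
        A = 0.5 * np.eye(2)
        a = simulate_var_series(A[None], np.eye(2), 500, seed=7)
        b = simulate_var_series(A[None], np.eye(2), 500, seed=7)
        assert np.array_equal(a, b)

    def test_unstable_coefficients_rejected(self):
        with pytest.raises(ValueError, match="spectral radius"):
            simulate_var_series(1.1 * np.eye(2)[None], np.eye(2), 100, seed=0)


class TestBuildDataset:
    def test_trial_bookkeeping(self):
        cfg = default_config(seed=0, n_correct=3, n_error=2, n_baseline=4)
        ds = build_dataset(cfg)
        assert len(ds.trials) == 9
        labels = [t.label for t in ds.trials]
        assert labels.count("correct") == 3
        assert labels.count("error") == 2
        assert labels.count("baseline") == 4

    def test_empty_dataset_is_valid(self):
        cfg = default_config(seed=0, n_correct=0, n_error=0, n_baseline=0)
        assert build_dataset(cfg).trials == []

    def test_rerun_is_byte_identical(self, tmp_path):
        cfg = default_config(seed=11, n_correct=2, n_error=1, n_baseline=1)
        p1 = write_dataset(build_dataset(cfg), tmp_path / "a")
        p2 = write_dataset(build_dataset(cfg), tmp_path / "b")
        for key in ("spikes", "events"):
            assert open(p1[key]).read() == open(p2[key]).read()


class TestSilencingOption:
    def test_off_by_default(self):
        cfg = default_config(seed=5, n_correct=2, n_error=0, n_baseline=0)
        assert cfg.silence_prob == 0.0
        ds = build_dataset(cfg)
        assert all(tr.n_spikes > 0 for t in ds.trials for tr in t.trains)

    def test_silences_roughly_the_requested_fraction(self):
        cfg = default_config(seed=5, silence_prob=0.5,
                            n_correct=10, n_error=0, n_baseline=0)
        ds = build_dataset(cfg)
        empty = np.mean([tr.n_spikes == 0 for t in ds.trials for tr in t.trains])
        assert 0.35 < empty < 0.65

    def test_deterministic_given_seed(self):
        cfg = default_config(seed=6, silence_prob=0.3,
                            n_correct=3, n_error=0, n_baseline=0)
        a = build_dataset(cfg)
        b = build_dataset(cfg)
        for ta, tb in zip(a.trials, b.trials):
            for xa, xb in zip(ta.trains, tb.trains):
                assert np.array_equal(xa.times, xb.times)

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError, match="silence_prob"):
            default_config(seed=0, silence_prob=1.5)
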