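"""VAR fitting, BIC order selection, conditional Granger causality, pruning."""

import numpy as np
import pytest

from spikegc import (
    conditional_gc,
    fit_var,
    select_order,
    significance_filter,
    simulate_var_series,
    window_networks,
)


class TestFitVar:
    def test_recovers_exact_var1_without_noise(self):
        A = np.array([[0.6, 0.2], [-0.3, 0.5]])
        rng = np.random.default_rng(0)
        x = np.zeros((2, 40))
        x[:, 0] = rng.uniform(1, 2, 2)
        for t in range(1, 40):
            x[:, t] = A @ x[:, t - 1]
        model = fit_var(x, 1, center=False)
        assert np.allclose(model.coeffs[0], A, atol=1e-6)

    def test_white_noise_coefficients_near_zero(self):
        T = 10000
        x = np.random.default_rng(1).standard_normal((3, T))
        model = fit_var(x, 1)
        off = model.coeffs[0][~np.eye(3, dtype=bool)]
        assert np.all(np.abs(off) < 3 / np.sqrt(T))

    def test_omit_shrinks_dimensions(self):
        x = np.random.default_rng(2).standard_normal((4, 200))
        model = fit_var(x, 2, omit=1)
        assert model.resid_cov.shape == (3, 3)
        assert model.coeffs.shape == (2, 3, 3)

    def test_matches_statsmodels_unrestricted_fit(self):
        from statsmodels.tsa.api import VAR as SMVAR

        A = np.array([[0.5, 0.1], [0.2, 0.4]])
        x = simulate_var_series(A[None], np.eye(2), 2000, seed=3)
        x = x - x.mean(axis=1, keepdims=True)
        ours = fit_var(x, 1, center=False)
        sm = SMVAR(x.T).fit(1, trend="n")
        assert np.allclose(ours.coeffs[0], sm.coefs[0], atol=1e-8)

    def test_insufficient_samples_rejected(self):
        x = np.random.default_rng(3).standard_normal((5, 8))
        with pytest.raises(ValueError, match="insufficient"):
            fit_var(x, 2)


class TestSelectOrder:
    def test_var1_data_selects_order_one(self):
        A = np.array([[0.5, 0.2, 0.0], [0.0, 0.4, 0.2], [0.1, 0.0, 0.5]])
        hits = 0
        for seed in range(20):
            x = simulate_var_series(A[None], np.eye(3), 5000, seed=seed)
            hits += select_order(x, p_max=4) == 1
        assert hits >= 18

    def test_white_noise_selects_minimum_order(self):
        hits = 0
        for seed in range(20):
            x = np.random.default_rng(seed).standard_normal((3, 2000))
            hits += select_order(x, p_max=4) == 1
        assert hits >= 18

    def test_pmax_one_always_one(self):
        x = np.random.default_rng(0).standard_normal((2, 100))
        assert select_order(x, p_max=1) == 1


class TestConditionalGC:
    def test_bivariate_closed_form(self):
        # y(t) = c x(t-1) + e: restricted variance 1+c^2, unrestricted 1,
        # so F_{x->y} = ln(1 + c^2) and F_{y->x} = 0
        c = 0.5
        A = np.array([[0.0, 0.0], [c, 0.0]])
        x = simulate_var_series(A[None], np.eye(2), 20000, seed=1)
        net = significance_filter(conditional_gc(x, p=1))
        target = np.log(1 + c * c)
        assert abs(net.F[1, 0] - target) / target < 0.10
        assert net.sig_mask[1, 0]
        assert not net.sig_mask[0, 1]

    def test_conditional_equals_pairwise_for_two_series(self):
        # independent oracle: pairwise GC from two hand-rolled OLS fits
        A = np.array([[0.4, 0.0], [0.3, 0.5]])
        x = simulate_var_series(A[None], np.eye(2), 5000, seed=2)
        x = x - x.mean(axis=1, keepdims=True)
        net = conditional_gc(x, p=1)

        def ols_resid_var(y, Z):
            b = np.linalg.lstsq(Z, y, rcond=None)[0]
            r = y - Z @ b
            return np.sum(r * r) / len(y)

        for i, j in ((0, 1), (1, 0)):
            full = ols_resid_var(x[i, 1:], x[:, :-1].T)
            restricted = ols_resid_var(x[i, 1:], x[i, :-1][:, None])
            want = max(np.log(restricted / full), 0.0)
            assert net.F[i, j] == pytest.approx(want, abs=1e-9)

    def test_chain_indirect_link_not_significant(self):
        A = np.zeros((3, 3))
        A[1, 0] = A[2, 1] = 0.5
        bad = 0
        for seed in range(30):
            x = simulate_var_series(A[None], np.eye(3), 2000, seed=seed)
            net = significance_filter(conditional_gc(x, p=1))
            bad += bool(net.sig_mask[2, 0])
        assert bad <= 3

    def test_independent_noise_mostly_unconnected(self):
        x = np.random.default_rng(4).standard_normal((4, 10000))
        net = significance_filter(conditional_gc(x, p=1))
        assert net.F[net.sig_mask].size <= 1
        assert np.all(net.F[~net.sig_mask] == 0)

    def test_flooring_keeps_f_nonnegative(self):
        x = np.random.default_rng(5).standard_normal((5, 60))
        net = conditional_gc(x, p=1)
        assert np.all(net.F >= 0)


class TestSignificanceFilter:
    def test_strong_edge_survives(self):
        A = np.zeros((4, 4))
        A[1, 0] = 0.9
        hits = 0
        for seed in range(20):
            x = simulate_var_series(A[None], np.eye(4), 5000, seed=seed)
            net = significance_filter(conditional_gc(x, p=1))
            hits += bool(net.sig_mask[1, 0])
        assert hits >= 19

    def test_pruned_entries_are_zeroed(self):
        x = np.random.default_rng(6).standard_normal((3, 500))
        net = significance_filter(conditional_gc(x, p=1))
        assert np.all(net.F[~net.sig_mask] == 0.0)

    def test_tiny_window_marked_unusable(self):
        # T=8, N=6, p=1: regression feasible but df2 = 7 - 6 - 1 = 0
        x = np.random.default_rng(7).standard_normal((6, 8))
        net = significance_filter(conditional_gc(x, p=1))
        assert not net.usable


class TestWindowNetworks:
    def test_networks_match_window_centers(self):
        rng = np.random.default_rng(8)
        windows = [(0.25 + 0.125 * k, rng.standard_normal((3, 50))) for k in range(13)]
        nets = window_networks(windows, space_tag="nmf", p=1)
        assert len(nets) <= 13
        assert [n.window_center for n in nets] == [c for c, _ in windows[:len(nets)]]
        assert all(n.space_tag == "nmf" for n in nets)

    def test_zero_variance_row_skipped_not_crashed(self):
        rng = np.random.default_rng(9)
        seg = rng.standard_normal((3, 50))
        seg[1] = 2.0
        nets = window_networks([(0.0, seg)], p=1)
        assert nets == []

    def test_deterministic(self):
        rng = np.random.default_rng(10)
        windows = [(0.1 * k, rng.standard_normal((3, 60))) for k in range(4)]
        a = window_networks(windows, p=1)
        b = window_networks(windows, p=1)
        for na, nb in zip(a, b):
            assert np.array_equal(na.F, nb.F)
            assert np.array_equal(na.sig_mask, nb.sig_mask)


def test_true_coupling_directions_score_higher_than_null():
    """Ground-truth recovery: on the synthetic assembly latents, F on the
    planted coupling directions stochastically dominates F on null directions
    (one-sided rank-sum) in the peak-coupling window of correct trials."""
    from scipy.stats import mannwhitneyu

    from spikegc import default_config, simulate_latent_rates

    cfg = default_config(seed=11, n_correct=12)
    off = cfg.component_coupling - np.diag(np.diag(cfg.component_coupling))
    true_mask = off != 0
    null_mask = (off == 0) & ~np.eye(cfg.n_components, dtype=bool)
    i0 = int((cfg.rt_time - 0.5) / cfg.sample_dt)
    true_f, null_f = [], []
    for t in range(12):
        z = simulate_latent_rates(cfg, "correct", trial_index=t)
        net = conditional_gc(z[:, i0:i0 + 50], p=1)
        true_f.extend(net.F[true_mask])
        null_f.extend(net.F[null_mask])
    stat, p = mannwhitneyu(true_f, null_f, alternative="greater")
    assert p < 0.01
    assert np.mean(true_f) > np.mean(null_f)
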