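import numpy as np
import pytest

from stpanel import (ImputeConfig, PanelDataset, RegionGraph,
                     AdaptiveImputer, anomaly_aware_attention, anomaly_gate,
                     anomaly_scores, apply_confidence, confidence_scores,
                     feature_regularization, impute_missing)
from stpanel.adjust import deviation_score, ema_dispersion, temporal_weights

from conftest import random_panel


def path_graph_r(n=3):
    """Path r0-r1-...-r(n-1), ids matching random_panel's regions."""
    A = np.zeros((n, n))
    for i in range(n - 1):
        A[i, i + 1] = A[i + 1, i] = 1.0
    return RegionGraph([f"r{i}" for i in range(n)], A)


class TestConfidence:
    def test_constant_series_gives_full_confidence(self):
        """sigma_t = 0 everywhere -> gamma = exp(0) = 1."""
        x = np.full((10, 2), 3.0)
        np.testing.assert_allclose(confidence_scores(x, W_sigma=4), 1.0)

    def test_sigma_equal_to_baseline_gives_inverse_e(self):
        """A series whose rolling std always equals its long-run mean std
        scores gamma = exp(-1)."""
        rng = np.random.default_rng(0)
        x = rng.normal(size=(200, 1))
        g = confidence_scores(x, W_sigma=200, epsilon=1e-12)
        # at t = 199 the window is the full series: sigma_t == full std;
        # sigma_bar averages rolling stds, so force the exact case:
        from stpanel.adjust import rolling_std
        sig = rolling_std(x, ~np.isnan(x), 200)
        gamma_manual = np.exp(-sig[-1, 0] / (np.nanmean(sig) + 1e-12))
        np.testing.assert_allclose(g[-1, 0], gamma_manual)

    def test_exact_inverse_e_when_dispersion_constant(self):
        # alternate +-1 with a 2-step window: every post-warm-up window
        # has std 1, so sigma_t = sigma_bar and gamma = 1/e exactly.
        x = np.tile([1.0, -1.0], 20)[:, None]
        g = confidence_scores(x, W_sigma=2, epsilon=1e-15)
        np.testing.assert_allclose(g[1:, 0], np.exp(-1.0), atol=1e-9)

    def test_ema_recursion_hand_values(self):
        d = ema_dispersion(np.array([2.0, 4.0]), alpha_ema=0.5)
        np.testing.assert_allclose(d, [1.0, 2.5])

    def test_gamma_monotone_in_sigma(self):
        """Holding sigma_bar fixed, larger dispersion never raises gamma."""
        sigma = np.linspace(0, 5, 50)
        gamma = np.exp(-sigma / (1.0 + 1e-8))
        assert np.all(np.diff(gamma) <= 0)

    def test_values_in_unit_interval(self):
        rng = np.random.default_rng(5)
        panel = random_panel(rng, T=40, V=2, M=3, missing=0.2)
        for mode in ("window", "ema"):
            g = confidence_scores(panel, mode=mode)
            assert g.shape == panel.shape
            assert np.all(g > 0) and np.all(g <= 1)

    def test_warmup_never_raises(self):
        g = confidence_scores(np.array([[1.0], [2.0]]), W_sigma=14)
        assert g.shape == (2, 1)
        assert g[0, 0] == 1.0  # single point: neutral confidence

    def test_apply_confidence_scaling(self):
        h = np.array([[2.0], [4.0]])  # two features, dim-1 embeddings
        np.testing.assert_allclose(
            apply_confidence(h, np.array([0.5, 0.5])), [[1.0], [2.0]])
        np.testing.assert_allclose(apply_confidence(h, np.ones(2)), h)
        np.testing.assert_allclose(apply_confidence(h, np.zeros(2)), 0.0)


class TestAnomalyScores:
    def test_zero_deviation_scores_zero(self):
        assert deviation_score([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_hand_mean_of_deviations(self):
        assert deviation_score([3.0, 1.0], [2.0, 4.0]) == 2.0

    def test_translation_invariance(self):
        x, mu = np.array([3.0, 1.0]), np.array([2.0, 4.0])
        assert deviation_score(x + 7, mu + 7) == deviation_score(x, mu)

    def test_panel_scores_flag_injected_spike(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 0.1, size=(30, 1, 2))
        x[20, 0, :] += 10.0
        d = anomaly_scores(x, W_mu=10)
        assert d.shape == (30, 1)
        assert d[20, 0] == d.max() and d[20, 0] > 5

    def test_constant_series_scores_zero(self):
        d = anomaly_scores(np.full((10, 3), 2.0), W_mu=5)
        np.testing.assert_allclose(d, 0.0)


class TestAnomalyGate:
    def test_zero_and_halving_points(self):
        assert anomaly_gate(0.0) == 0.0
        assert anomaly_gate(np.log(2), kappa=1.0) == pytest.approx(0.5)

    def test_monotone_in_kappa_and_delta(self):
        d = np.linspace(0.01, 5, 50)
        assert np.all(anomaly_gate(d, 2.0) > anomaly_gate(d, 1.0))
        assert np.all(np.diff(anomaly_gate(d, 1.0)) > 0)
        assert np.all(anomaly_gate(d) < 1.0)


class TestAnomalyAwareAttention:
    def test_zero_deltas_reduce_to_plain_softmax(self):
        e = np.array([0.3, -0.2, 1.0])
        expect = np.exp(e) / np.exp(e).sum()
        for variant in ("subtractive", "multiplicative"):
            w, _ = anomaly_aware_attention(e, np.zeros(3), variant)
            np.testing.assert_allclose(w, expect)

    def test_multiplicative_hand_example(self):
        """e = [1, 1], gate values [0, 1] -> exponents [1, 0]."""
        # f = 1 - exp(-k d): d = 0 gives f = 0; d -> inf gives f -> 1
        w, _ = anomaly_aware_attention(
            np.array([1.0, 1.0]), np.array([0.0, 1e9]), "multiplicative")
        e = np.e
        np.testing.assert_allclose(w, [e / (1 + e), 1 / (1 + e)], atol=1e-6)

    def test_context_is_convex_average(self):
        h = np.array([[2.0], [4.0]])
        w, c = anomaly_aware_attention(np.zeros(2), np.zeros(2),
                                       "subtractive", embeddings=h)
        np.testing.assert_allclose(w, [0.5, 0.5])
        np.testing.assert_allclose(c, [3.0])

    def test_subtractive_weight_strictly_decreasing_in_delta(self):
        e = np.array([0.5, 0.2, -0.1])
        deltas = np.linspace(0, 3, 20)
        w0 = [anomaly_aware_attention(e, np.array([d, 0, 0]),
                                      "subtractive")[0][0]
              for d in deltas]
        assert np.all(np.diff(w0) < 0)

    def test_weights_normalized(self):
        rng = np.random.default_rng(2)
        e, d = rng.normal(size=7), np.abs(rng.normal(size=7))
        for variant in ("subtractive", "multiplicative"):
            w, _ = anomaly_aware_attention(e, d, variant)
            assert np.all(w >= 0)
            assert w.sum() == pytest.approx(1.0, abs=1e-6)

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            anomaly_aware_attention(np.zeros(0), np.zeros(0))


class TestFeatureRegularization:
    def test_zero_gamma_zero_penalty(self):
        assert feature_regularization(np.zeros((5, 3)), 1.0) == 0.0

    def test_hand_arithmetic(self):
        gamma = np.column_stack([np.full(4, 0.5), np.full(4, 1.0)])
        assert feature_regularization(gamma, 1.0) == pytest.approx(1.25)

    def test_linear_in_coefficient(self):
        rng = np.random.default_rng(3)
        g = rng.random((6, 2))
        assert feature_regularization(g, 3.0) == pytest.approx(
            3 * feature_regularization(g, 1.0))


def impute_oracle(panel, graph, cfg, t, v, m):
    """Independent single-cell evaluation of the spatial/temporal blend.

    Brute-force re-derivation: normalized spatial weights from adjacency
    and degrees, exponential-decay lag weights, adaptive alpha from the
    neighbor/lag confidence sums.
    """
    A = graph.adjacency
    D = A.sum(axis=0)
    w = np.zeros(graph.n_regions)
    for u in range(graph.n_regions):
        if A[u, v] > 0:
            w[u] = A[u, v] / np.sqrt(D[v] * D[u])
    obs_nb = [u for u in range(graph.n_regions)
              if w[u] > 0 and panel.mask[t, u, m]]
    spatial = conf_s = None
    if obs_nb:
        wn = np.array([w[u] for u in obs_nb])
        wn = wn / wn.sum()
        spatial = sum(wi * panel.values[t, u, m] for wi, u in zip(wn, obs_nb))
        frac = []
        for u in obs_nb:
            lo = max(0, t - cfg.w_conf + 1)
            frac.append(panel.mask[lo:t + 1, u, :].mean())
        conf_s = float(np.sum(wn * np.array(frac)))
    lags = [tau for tau in range(1, cfg.L_imp + 1)
            if t - tau >= 0 and panel.mask[t - tau, v, m]]
    temporal = None
    if lags:
        beta = np.exp(-cfg.rho * np.array(lags, float))
        beta = beta / beta.sum()
        temporal = sum(b * panel.values[t - tau, v, m]
                       for b, tau in zip(beta, lags))
    if spatial is None and temporal is None:
        return float(panel.values[:, :, m][panel.mask[:, :, m]].mean())
    if spatial is None:
        return temporal
    if temporal is None:
        return spatial
    if cfg.alpha_mix == "adaptive":
        full = np.exp(-cfg.rho * np.arange(1, cfg.L_imp + 1)).sum()
        conf_h = np.exp(-cfg.rho * np.array(lags, float)).sum() / full
        alpha = conf_s / (conf_s + conf_h)
    else:
        alpha = float(cfg.alpha_mix)
    return alpha * spatial + (1 - alpha) * temporal


class TestImputation:
    def test_two_neighbor_average(self):
        """alpha = 1, equal weights on neighbors valued 2 and 4 -> 3."""
        A = np.array([[0, 0, 1], [0, 0, 1], [1, 1, 0.0]])
        graph = RegionGraph(["a", "b", "c"], A)
        values = np.array([[[2.0], [4.0], [np.nan]]])
        mask = np.array([[[True], [True], [False]]])
        panel = PanelDataset(values, mask, [0], ["a", "b", "c"], ["f"])
        filled, rep = impute_missing(panel, graph, ImputeConfig(alpha_mix=1.0))
        assert filled.values[0, 2, 0] == pytest.approx(3.0)
        assert rep.iloc[0]["n_spatial"] == 2

    def test_uniform_lag_weights_at_zero_decay(self):
        np.testing.assert_allclose(
            temporal_weights(np.array([1, 2, 3]), rho=0.0), np.ones(3) / 3)

    def test_no_neighbors_forces_temporal_fill(self):
        graph = RegionGraph(["a", "b"], np.array([[0, 1], [1, 0.0]]))
        values = np.full((4, 2, 1), 5.0)
        values[3, 0, 0] = np.nan
        values[3, 1, 0] = np.nan  # neighbor also missing at t=3
        mask = ~np.isnan(values)
        panel = PanelDataset(values, mask, range(4), ["a", "b"], ["f"])
        filled, rep = impute_missing(panel, graph)
        row = rep[(rep.region == "a")].iloc[0]
        assert row["alpha"] == 0.0 and row["n_spatial"] == 0
        assert filled.values[3, 0, 0] == pytest.approx(5.0)

    def test_identity_on_fully_observed(self, small_panel, line_graph):
        filled, rep = impute_missing(small_panel, line_graph)
        assert len(rep) == 0
        np.testing.assert_array_equal(filled.values, small_panel.values)

    def test_fills_stay_in_source_hull(self):
        rng = np.random.default_rng(6)
        panel = random_panel(rng, T=20, V=3, M=2, missing=0.3)
        filled, rep = impute_missing(panel, path_graph_r())
        assert filled.fully_observed()
        for m in range(2):
            obs = panel.values[:, :, m][panel.mask[:, :, m]]
            fills = filled.values[:, :, m][~panel.mask[:, :, m]]
            assert fills.min() >= obs.min() - 1e-12
            assert fills.max() <= obs.max() + 1e-12

    def test_matches_independent_oracle(self):
        rng = np.random.default_rng(7)
        cfg = ImputeConfig()
        graph = path_graph_r()
        for _ in range(20):
            panel = random_panel(rng, T=8, V=3, M=2, missing=0.35)
            filled, _ = impute_missing(panel, graph, cfg)
            for t, v, m in np.argwhere(~panel.mask):
                expect = impute_oracle(panel, graph, cfg, t, v, m)
                assert filled.values[t, v, m] == pytest.approx(
                    expect, abs=1e-10)

    def test_feature_observed_nowhere_raises(self):
        graph = RegionGraph(["a", "b"], np.array([[0, 1], [1, 0.0]]))
        values = np.full((3, 2, 1), np.nan)
        panel = PanelDataset(values, ~np.isnan(values), range(3),
                             ["a", "b"], ["f"])
        with pytest.raises(ValueError, match="no observed"):
            impute_missing(panel, graph)

    def test_transformer_interface(self):
        rng = np.random.default_rng(8)
        panel = random_panel(rng, T=15, V=3, M=2, missing=0.2)
        imp = AdaptiveImputer(graph=path_graph_r())
        out = imp.fit(panel).transform(panel)
        assert out.fully_observed()
        assert len(imp.report_) == (~panel.mask).sum()
        assert imp.get_params()["rho"] == 0.5
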