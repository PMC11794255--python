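"""Adaptive contextual adjustment: confidence weighting, anomaly-aware
attention, and spatio-temporal imputation of missing panel entries.

These are the pre-model robustness components: they operate on the raw
panel (not on learned parameters) and produce the quantities the
forecaster consumes — per-feature confidence scores gamma in (0, 1]
that scale embeddings, per-time anomaly scores delta >= 0 that attenuate
temporal attention, and a deterministic fill for every masked cell that
blends spatial neighbors with recent history.

Conventions
-----------
* Rolling statistics use trailing windows; before a full window has
  accumulated they use all available history, with a minimum of two
  observed points — below that the neutral values gamma = 1 and
  delta = 0 apply (warm-up rule, never an exception).
* The anomaly baseline mu_t is the mean of observations strictly before
  t, so a spike does not mask itself.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .panel import PanelDataset, RegionGraph

__all__ = [
    "ImputeConfig",
    "confidence_scores",
    "apply_confidence",
    "anomaly_scores",
    "anomaly_gate",
    "anomaly_aware_attention",
    "impute_missing",
    "feature_regularization",
    "AdaptiveImputer",
]


def _series_view(x) -> tuple[np.ndarray, np.ndarray, bool]:
    """Normalize input to (values (T, S), mask (T, S), was_panel_3d)."""
    if isinstance(x, PanelDataset):
        T, V, M = x.shape
        return x.values.reshape(T, V * M), x.mask.reshape(T, V * M), True
    arr = np.asarray(x, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    mask = ~np.isnan(arr)
    if arr.ndim == 3:
        T, V, M = arr.shape
        return arr.reshape(T, V * M), mask.reshape(T, V * M), True
    return arr, mask, False


def rolling_std(values, mask, window: int) -> np.ndarray:
    """Trailing per-series standard deviation over the last ``window`` steps.

    Population std over the observed entries of the trailing window
    (including t). NaN where fewer than two observed points exist yet.
    """
    T, S = values.shape
    out = np.full((T, S), np.nan)
    v = np.where(mask, values, 0.0)
    for t in range(T):
        lo = max(0, t - window + 1)
        m = mask[lo:t + 1]
        n = m.sum(axis=0)
        ok = n >= 2
        s = v[lo:t + 1].sum(axis=0)
        ss = (v[lo:t + 1] ** 2).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            var = ss / np.maximum(n, 1) - (s / np.maximum(n, 1)) ** 2
        out[t, ok] = np.sqrt(np.maximum(var[ok], 0.0))
    return out


def confidence_scores(panel, mode: str = "window", W_sigma: int = 14,
                      alpha_ema: float = 0.9, epsilon: float = 1e-8):
    """Per-(time, feature) reliability score gamma in (0, 1].

    gamma_t = exp(-sigma_t / (sigma_bar + eps)) where sigma_t is the
    trailing rolling std over ``W_sigma`` steps and sigma_bar its
    long-run mean over time. In "ema" mode sigma_t is replaced by its
    exponential moving average delta_t = alpha * delta_{t-1} +
    (1 - alpha) * sigma_t (initialized from delta_{-1} = 0), making the
    score respond to variance trends rather than single-window noise.

    Accepts a PanelDataset or an array (T,), (T, M) or (T, V, M);
    returns gamma with the same time-leading shape. Warm-up steps
    (fewer than two observed points) get gamma = 1.
    """
    if W_sigma < 2:
        raise ValueError("W_sigma must be >= 2")
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    if mode not in ("window", "ema"):
        raise ValueError(f"unknown mode {mode!r}")
    orig_shape = panel.shape if isinstance(panel, PanelDataset) \
        else np.asarray(panel, dtype=float).shape
    values, mask, _ = _series_view(panel)
    sigma = rolling_std(values, mask, W_sigma)
    warm = np.isnan(sigma)
    with np.errstate(invalid="ignore"):
        sigma_bar = np.nanmean(np.where(warm, np.nan, sigma), axis=0)
    sigma_bar = np.where(np.isnan(sigma_bar), 0.0, sigma_bar)

    disp = np.where(warm, 0.0, sigma)
    if mode == "ema":
        ema = np.zeros_like(disp)
        prev = np.zeros(disp.shape[1])
        for t in range(disp.shape[0]):
            prev = alpha_ema * prev + (1.0 - alpha_ema) * disp[t]
            ema[t] = prev
        disp = ema
    gamma = np.exp(-disp / (sigma_bar + epsilon))
    gamma[warm] = 1.0
    return gamma.reshape(orig_shape)


def ema_dispersion(sigma: np.ndarray, alpha_ema: float) -> np.ndarray:
    """EMA of a dispersion sequence: d_t = a d_{t-1} + (1-a) s_t, d_{-1}=0."""
    sigma = np.asarray(sigma, dtype=float)
    out = np.zeros_like(sigma)
    prev = np.zeros(sigma.shape[1:]) if sigma.ndim > 1 else 0.0
    for t in range(sigma.shape[0]):
        prev = alpha_ema * prev + (1.0 - alpha_ema) * sigma[t]
        out[t] = prev
    return out


def apply_confidence(features: np.ndarray, gamma: np.ndarray) -> np.ndarray:
    """Scale per-feature embeddings by their confidence: h~ = gamma * h.

    ``gamma`` broadcasts against all but the trailing embedding axis of
    ``features`` (shape (..., M, d) scaled by gamma (..., M)).
    """
    features = np.asarray(features, dtype=float)
    gamma = np.asarray(gamma, dtype=float)
    if gamma.ndim == features.ndim - 1:
        gamma = gamma[..., None]
    return gamma * features


def anomaly_scores(panel, W_mu: int = 14):
    """Mean absolute deviation from a trailing-mean baseline.

    delta_t = (1/M) sum_m |x_t^(m) - mu_t^(m)| with mu_t the mean of
    the (up to ``W_mu``) observed values strictly before t. Computed per
    region for a (T, V, M) panel — shape (T, V) — and per time for a
    (T, M) series — shape (T,). Steps with fewer than two prior
    observations (or nothing observed at t) score 0.
    """
    if isinstance(panel, PanelDataset):
        values, mask = panel.values, panel.mask
    else:
        values = np.asarray(panel, dtype=float)
        mask = ~np.isnan(values)
    squeeze = values.ndim == 2
    if squeeze:
        values, mask = values[:, None, :], mask[:, None, :]
    T, V, M = values.shape
    delta = np.zeros((T, V))
    v0 = np.where(mask, values, 0.0)
    for t in range(T):
        lo = max(0, t - W_mu)
        m_hist = mask[lo:t]
        n = m_hist.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            mu = np.where(n > 0, v0[lo:t].sum(axis=0) / np.maximum(n, 1), np.nan)
        usable = mask[t] & (n >= 2)
        dev = np.abs(values[t] - mu)
        cnt = usable.sum(axis=1)
        delta[t] = np.where(
            cnt > 0, np.where(usable, dev, 0.0).sum(axis=1) / np.maximum(cnt, 1), 0.0)
    return delta[:, 0] if squeeze else delta


def deviation_score(x: np.ndarray, mu: np.ndarray) -> float:
    """delta = mean_m |x^(m) - mu^(m)| for a single time slice."""
    return float(np.mean(np.abs(np.asarray(x, float) - np.asarray(mu, float))))


def anomaly_gate(delta, kappa: float = 1.0):
    """Saturating modulation f(delta) = 1 - exp(-kappa * delta) in [0, 1)."""
    if kappa <= 0:
        raise ValueError("kappa must be > 0")
    return 1.0 - np.exp(-kappa * np.asarray(delta, dtype=float))


def anomaly_aware_attention(raw_scores, deltas, variant: str = "multiplicative",
                            lambda_anom: float = 1.0, kappa: float = 1.0,
                            embeddings=None):
    """Softmax attention over window lags, attenuated at anomalous steps.

    The subtractive variant softmaxes ``e - lambda * delta``; the
    multiplicative variant softmaxes ``e * (1 - f(delta))`` with the
    saturating gate f. Both reduce to a plain softmax when all deltas
    are zero. The lag axis is the last axis of ``raw_scores``.

    Returns ``(weights, context)``; context (the weight-averaged
    embeddings over the lag axis, which is ``embeddings``' second-to-last
    axis) is None when no embeddings are given.
    """
    e = np.asarray(raw_scores, dtype=float)
    d = np.asarray(deltas, dtype=float)
    if e.shape[-1] == 0:
        raise ValueError("empty lag window")
    if variant == "subtractive":
        logits = e - lambda_anom * d
    elif variant == "multiplicative":
        logits = e * (1.0 - anomaly_gate(d, kappa))
    else:
        raise ValueError(f"unknown variant {variant!r}")
    logits = logits - logits.max(axis=-1, keepdims=True)
    w = np.exp(logits)
    w /= w.sum(axis=-1, keepdims=True)
    context = None
    if embeddings is not None:
        h = np.asarray(embeddings, dtype=float)
        context = (w[..., None] * h).sum(axis=-2)
    return w, context


def feature_regularization(gamma, lambda_reg: float = 1e-3) -> float:
    """Penalty lambda * sum_m (mean over time of gamma^(m))^2.

    Discourages persistently dominant features; gamma may be (T, M) or
    (T, V, M) (regions averaged with time).
    """
    g = np.asarray(gamma, dtype=float)
    if g.ndim == 3:
        g = g.reshape(g.shape[0] * g.shape[1], g.shape[2])
    return float(lambda_reg * np.sum(g.mean(axis=0) ** 2))


# ---------------------------------------------------------------------------
# Dynamic spatio-temporal imputation


@dataclass
class ImputeConfig:
    """Settings of the spatial/temporal imputation blend.

    alpha_mix : float in [0, 1] or "adaptive"
        Weight on the spatial side; "adaptive" derives it per cell from
        the relative confidence of the two sides.
    rho : float >= 0
        Temporal decay rate; lag weights beta_tau ~ exp(-rho * tau),
        renormalized over the observed lags (rho = 0 gives uniform).
    L_imp : int
        Maximum temporal lookback in steps.
    w_conf : int
        Window over which a neighbor's observed fraction (its spatial
        confidence factor) is measured.
    """

    alpha_mix: float | str = "adaptive"
    rho: float = 0.5
    L_imp: int = 8
    w_conf: int = 14

    def __post_init__(self):
        if isinstance(self.alpha_mix, str):
            if self.alpha_mix != "adaptive":
                raise ValueError("alpha_mix must be a float or 'adaptive'")
        elif not 0.0 <= float(self.alpha_mix) <= 1.0:
            raise ValueError("alpha_mix must lie in [0, 1]")
        if self.rho < 0:
            raise ValueError("rho must be >= 0")
        if self.L_imp < 1:
            raise ValueError("L_imp must be >= 1")


def temporal_weights(observed_lags: np.ndarray, rho: float) -> np.ndarray:
    """beta_tau proportional to exp(-rho * tau) over the given lags, summing to 1."""
    w = np.exp(-rho * np.asarray(observed_lags, dtype=float))
    return w / w.sum()


def impute_missing(panel: PanelDataset, graph: RegionGraph,
                   cfg: ImputeConfig | None = None):
    """Fill every masked cell from observed neighbors and recent history.

    Each fill is ``alpha * spatial + (1 - alpha) * temporal`` where the
    spatial part averages observed neighbor values under the symmetric
    degree-normalized weights (renormalized over the observed neighbors)
    and the temporal part averages the cell's own observed recent lags
    under exponentially decaying weights. With adaptive mixing, alpha =
    S / (S + H) where S sums neighbor confidences (normalized weight x
    observed fraction) and H sums lag confidences (beta_tau x observed).
    When one side has no sources the other takes over; when both are
    empty the global observed mean of the feature stands in. A cell with
    no source at all raises.

    Only originally observed values feed the fills, so the result does
    not depend on cell order. Returns ``(filled_panel, report)`` with a
    per-fill DataFrame (time, region, feature, value, alpha, n_spatial,
    n_temporal, fallback).
    """
    cfg = cfg or ImputeConfig()
    if set(graph.region_ids) != set(panel.region_ids):
        raise ValueError("graph does not cover the panel's regions")
    if graph.region_ids != panel.region_ids:
        graph = graph.reorder(panel.region_ids)

    T, V, M = panel.shape
    values, mask = panel.values, panel.mask
    W = graph.norm_weights  # no self-loops: neighbors only
    # per-(t, v): fraction of the trailing w_conf steps observed (any feature)
    obs_frac = np.zeros((T, V))
    cell_obs = mask.mean(axis=2)
    for t in range(T):
        lo = max(0, t - cfg.w_conf + 1)
        obs_frac[t] = cell_obs[lo:t + 1].mean(axis=0)
    with np.errstate(invalid="ignore"):
        global_mean = np.array([
            values[:, :, m][mask[:, :, m]].mean() if mask[:, :, m].any() else np.nan
            for m in range(M)])

    out = panel.copy()
    rows = []
    for t, v, m in np.argwhere(~mask):
        # spatial side
        nb = np.flatnonzero((W[:, v] > 0) & mask[t, :, m])
        spatial = alpha_s = None
        if nb.size:
            wn = W[nb, v] / W[nb, v].sum()
            spatial = float(wn @ values[t, nb, m])
            alpha_s = float(np.sum(wn * obs_frac[t, nb]))
        # temporal side
        lags = np.array([tau for tau in range(1, cfg.L_imp + 1)
                         if t - tau >= 0 and mask[t - tau, v, m]])
        temporal = alpha_h = None
        if lags.size:
            beta = temporal_weights(lags, cfg.rho)
            temporal = float(beta @ values[t - lags, v, m])
            # lag confidences keep the full-lookback normalization, so
            # missing history lowers the temporal side's credibility
            full = np.exp(-cfg.rho * np.arange(1, cfg.L_imp + 1)).sum()
            alpha_h = float(np.exp(-cfg.rho * lags).sum() / full)
        # blend
        fallback = ""
        if spatial is None and temporal is None:
            if np.isnan(global_mean[m]):
                raise ValueError(
                    f"cell (t={t}, region={panel.region_ids[v]}, "
                    f"feature={panel.feature_names[m]}) has no observed "
                    "neighbors, history, or feature values anywhere")
            filled, alpha = float(global_mean[m]), np.nan
            fallback = "global_mean"
        elif spatial is None:
            filled, alpha = temporal, 0.0
        elif temporal is None:
            filled, alpha = spatial, 1.0
        else:
            if cfg.alpha_mix == "adaptive":
                alpha = alpha_s / (alpha_s + alpha_h) if alpha_s + alpha_h > 0 else 0.5
            else:
                alpha = float(cfg.alpha_mix)
            filled = alpha * spatial + (1.0 - alpha) * temporal
        out.values[t, v, m] = filled
        out.mask[t, v, m] = True
        rows.append({
            "time": panel.timestamps[t], "region": panel.region_ids[v],
            "feature": panel.feature_names[m], "value": filled,
            "alpha": alpha, "n_spatial": int(nb.size),
            "n_temporal": int(lags.size), "fallback": fallback,
        })
    report = pd.DataFrame(
        rows, columns=["time", "region", "feature", "value", "alpha",
                       "n_spatial", "n_temporal", "fallback"])
    return out, report


class AdaptiveImputer(TransformerMixin, BaseEstimator):
    """sklearn-style transformer wrapping :func:`impute_missing`.

    Parameters mirror :class:`ImputeConfig`; the region graph is a
    structural parameter fixed at construction. ``transform`` accepts a
    :class:`PanelDataset` and returns the fully observed panel; the
    per-fill report of the last transform is stored in ``report_``.
    """

    def __init__(self, graph: RegionGraph | None = None,
                 alpha_mix="adaptive", rho: float = 0.5,
                 L_imp: int = 8, w_conf: int = 14):
        self.graph = graph
        self.alpha_mix = alpha_mix
        self.rho = rho
        self.L_imp = L_imp
        self.w_conf = w_conf

    def fit(self, X: PanelDataset, y=None):
        if self.graph is None:
            raise ValueError("AdaptiveImputer requires a region graph")
        self.n_features_in_ = X.shape[2]
        return self

    def transform(self, X: PanelDataset) -> PanelDataset:
        cfg = ImputeConfig(self.alpha_mix, self.rho, self.L_imp, self.w_conf)
        filled, report = impute_missing(X, self.graph, cfg)
        self.report_ = report
        return filled
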