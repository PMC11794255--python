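"""Synthetic regional surveillance panels with known ground truth.

The generator produces the statistical structure the forecaster is built
for — temporal autocorrelation, cross-feature dependence through shared
latent states, spatial diffusion over a region graph — plus controlled
missingness and anomalous events, while retaining every ground-truth
quantity (latent states, outcome weights, masked cells, event labels)
so recovery can be tested.

Generative model (linear-Gaussian by design, so a linearized forecaster
configuration can provably recover the outcome weights):

    s_{v,t} = a * s_{v,t-1} + c * sum_u w_uv s_{u,t-1} + eps_state
    x_{v,t} = Lambda s_{v,t} + eps_obs
    y_{v,t} = w_true . x_{v,t} + b_true + eps_outcome

with ``w_uv`` the symmetric degree-normalized graph weights. Stationarity
requires the spectral radius of ``a I + c W`` to be below 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .panel import PanelDataset, RegionGraph

__all__ = ["SimParams", "make_graph", "simulate_panel", "inject_missing",
           "inject_anomalies"]


@dataclass
class SimParams:
    """Parameters of the linear-Gaussian panel generator.

    Defaults describe a moderately autocorrelated (ar_coef 0.6), weakly
    diffusing (spatial_coef 0.2) panel with observation noise at about a
    quarter of the latent scale — the regime regional surveillance
    indicators (case rates and their covariates) typically occupy.
    """

    n_regions: int = 9
    n_features: int = 3
    T: int = 200
    ar_coef: float = 0.6
    spatial_coef: float = 0.2
    latent_dim: int = 1
    feature_loading: np.ndarray | None = None   # (n_features, latent_dim)
    outcome_weights: np.ndarray | None = None   # (n_features,)
    outcome_bias: float = 0.5
    noise_sd_state: float = 1.0
    noise_sd_obs: float = 0.25
    noise_sd_outcome: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if min(self.n_regions, self.n_features, self.T, self.latent_dim) < 1:
            raise ValueError("sizes must be positive")
        if not -1.0 < self.ar_coef < 1.0:
            raise ValueError("ar_coef must lie in (-1, 1)")
        if self.spatial_coef < 0:
            raise ValueError("spatial_coef must be >= 0")
        for sd in (self.noise_sd_state, self.noise_sd_obs, self.noise_sd_outcome):
            if sd < 0:
                raise ValueError("noise sds must be >= 0")
        rng = np.random.default_rng(self.seed)
        if self.feature_loading is None:
            self.feature_loading = rng.normal(
                1.0, 0.3, size=(self.n_features, self.latent_dim))
        else:
            self.feature_loading = np.atleast_2d(
                np.asarray(self.feature_loading, dtype=float))
        if self.feature_loading.shape != (self.n_features, self.latent_dim):
            raise ValueError("feature_loading must be (n_features, latent_dim)")
        if self.outcome_weights is None:
            self.outcome_weights = rng.normal(0.5, 0.5, size=self.n_features)
        else:
            self.outcome_weights = np.asarray(self.outcome_weights, dtype=float)
        if self.outcome_weights.shape != (self.n_features,):
            raise ValueError("outcome_weights must be length n_features")


def make_graph(kind: str, n: int, seed: int = 0, p: float = 0.4,
               max_retries: int = 50) -> RegionGraph:
    """Region graph of a given family with unit edge weights.

    kind : {"grid", "erdos", "complete"}
        "grid" is the near-square rook-adjacency lattice on n nodes;
        "erdos" is G(n, p) redrawn until connected (up to max_retries);
        "complete" joins every pair.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if kind == "grid":
        rows = int(np.floor(np.sqrt(n)))
        while n % rows:
            rows -= 1
        g = nx.grid_2d_graph(rows, n // rows)
        g = nx.convert_node_labels_to_integers(g, ordering="sorted")
    elif kind == "complete":
        g = nx.complete_graph(n)
    elif kind == "erdos":
        rng = np.random.default_rng(seed)
        for _ in range(max_retries):
            g = nx.erdos_renyi_graph(n, p, seed=int(rng.integers(2**31)))
            if n == 1 or nx.is_connected(g):
                break
        else:
            raise RuntimeError(f"no connected G({n},{p}) draw in {max_retries} tries")
    else:
        raise ValueError(f"unknown graph kind {kind!r}")
    ids = [f"r{i}" for i in range(n)]
    A = nx.to_numpy_array(g, nodelist=range(n))
    return RegionGraph(ids, A)


def _transition_matrix(graph: RegionGraph, params: SimParams) -> np.ndarray:
    return params.ar_coef * np.eye(graph.n_regions) \
        + params.spatial_coef * graph.norm_weights


def simulate_panel(graph: RegionGraph, params: SimParams,
                   init_state: np.ndarray | None = None):
    """Draw a panel with targets from the linear-Gaussian model.

    Returns ``(panel, latent)`` with ``latent`` the (T, V, latent_dim)
    ground-truth state trajectory. Raises if the state transition is
    non-stationary (spectral radius >= 1).
    """
    if graph.n_regions != params.n_regions:
        raise ValueError("graph size does not match params.n_regions")
    Phi = _transition_matrix(graph, params)
    radius = np.max(np.abs(np.linalg.eigvals(Phi)))
    if radius >= 1.0:
        raise ValueError(f"non-stationary transition (spectral radius {radius:.3f})")

    rng = np.random.default_rng(params.seed)
    T, V, M, D = params.T, params.n_regions, params.n_features, params.latent_dim
    latent = np.zeros((T, V, D))
    if init_state is not None:
        state = np.broadcast_to(np.asarray(init_state, dtype=float), (V, D)).copy()
    else:
        # start near the stationary scale so early samples are not atypical
        scale = params.noise_sd_state / max(np.sqrt(1.0 - radius**2), 1e-3)
        state = rng.normal(0.0, scale, size=(V, D))
    for t in range(T):
        if t > 0:
            state = Phi @ state + rng.normal(
                0.0, params.noise_sd_state, size=(V, D))
        latent[t] = state
    values = latent @ params.feature_loading.T \
        + rng.normal(0.0, params.noise_sd_obs, size=(T, V, M))
    targets = values @ params.outcome_weights + params.outcome_bias \
        + rng.normal(0.0, params.noise_sd_outcome, size=(T, V))
    panel = PanelDataset(values, np.ones((T, V, M), dtype=bool),
                         np.arange(T), graph.region_ids,
                         [f"f{m}" for m in range(M)], targets)
    return panel, latent


def inject_missing(panel: PanelDataset, rate: float, pattern: str = "mcar",
                   seed: int = 0, block_len: int = 5):
    """Mask a fraction of cells; returns ``(panel, masked_indices)``.

    "mcar" masks each cell independently with probability ``rate``;
    "block" masks contiguous temporal runs of ``block_len`` steps at
    random (region, feature) series until roughly ``rate`` of cells are
    hidden. Masked cells get the NaN sentinel.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    out = panel.copy()
    T, V, M = out.shape
    if pattern == "mcar":
        hide = rng.random((T, V, M)) < rate
    elif pattern == "block":
        hide = np.zeros((T, V, M), dtype=bool)
        target = rate * T * V * M
        while hide.sum() < target:
            v, m = rng.integers(V), rng.integers(M)
            t0 = rng.integers(max(T - block_len + 1, 1))
            hide[t0:t0 + block_len, v, m] = True
            if rate >= 1.0:
                hide[:] = True
    else:
        raise ValueError(f"unknown pattern {pattern!r}")
    hide &= out.mask  # only observed cells can be hidden
    out.mask[hide] = False
    out.values[hide] = np.nan
    return out, np.argwhere(hide)


def inject_anomalies(panel: PanelDataset, events):
    """Shift all features of each (time, region) event by its magnitude.

    ``events`` is a sequence of ``(t, v, magnitude)`` with ``v`` a region
    index or id. Returns ``(panel, labels)`` where labels is the list of
    (t_index, v_index, magnitude) actually applied.
    """
    out = panel.copy()
    labels = []
    for t, v, mag in events:
        vi = out.region_ids.index(v) if isinstance(v, str) else int(v)
        if not 0 <= t < out.n_times:
            raise ValueError(f"event time {t} outside panel")
        out.values[t, vi, :] += float(mag)
        labels.append((int(t), vi, float(mag)))
    return out, labels
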