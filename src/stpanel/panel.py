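"""Regional health-surveillance panel data: containers, I/O, splitting, windowing.

A panel is a time × region × feature array of surveillance indicators
(case counts, environmental covariates, ...) with a boolean observation
mask, plus an optional per-(time, region) outcome series to forecast.
Files travel as long-format CSV (one row per observed cell) and the
region adjacency graph as JSON or a TSV edge list.

Time indexing is 0-based. A history window of size ``L`` covers the
``L + 1`` slices ``x_{t-L} … x_t`` (both ends inclusive); with the
default ``horizon = 1`` the window ending at ``t`` predicts the outcome
``y_t`` aligned with its last slice.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PanelDataset",
    "RegionGraph",
    "ForecastTask",
    "read_panel",
    "write_panel",
    "read_graph",
    "write_graph",
    "chronological_split",
    "make_windows",
]

#: Sentinel stored at unobserved cells; never consumed by model arithmetic.
MISSING = np.nan


@dataclass
class PanelDataset:
    """Time × region × feature observations with an observation mask.

    Attributes
    ----------
    values : ndarray, shape (T, V, M)
        Observed values; unobserved cells hold NaN.
    mask : ndarray of bool, shape (T, V, M)
        True where the cell was observed.
    timestamps : ndarray, shape (T,)
        Strictly increasing time labels.
    region_ids : list of str
    feature_names : list of str
    targets : ndarray, shape (T, V), optional
        Outcome y_{t,v} to forecast.
    """

    values: np.ndarray
    mask: np.ndarray
    timestamps: np.ndarray
    region_ids: list[str]
    feature_names: list[str]
    targets: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.timestamps = np.asarray(self.timestamps)
        self.region_ids = [str(r) for r in self.region_ids]
        self.feature_names = [str(f) for f in self.feature_names]
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask shapes differ")
        T, V, M = self.values.shape
        if len(self.timestamps) != T:
            raise ValueError("timestamps length mismatch")
        if len(self.region_ids) != V or len(set(self.region_ids)) != V:
            raise ValueError("region ids missing or duplicated")
        if len(self.feature_names) != M or len(set(self.feature_names)) != M:
            raise ValueError("feature names missing or duplicated")
        ts = np.asarray(self.timestamps, dtype=float)
        if T > 1 and not np.all(np.diff(ts) > 0):
            raise ValueError("timestamps must be strictly increasing")
        if self.targets is not None:
            self.targets = np.asarray(self.targets, dtype=np.float64)
            if self.targets.shape != (T, V):
                raise ValueError("targets must have shape (T, V)")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def n_times(self) -> int:
        return self.values.shape[0]

    def copy(self) -> "PanelDataset":
        return PanelDataset(
            self.values.copy(), self.mask.copy(), self.timestamps.copy(),
            list(self.region_ids), list(self.feature_names),
            None if self.targets is None else self.targets.copy(),
        )

    def slice_time(self, start: int, stop: int) -> "PanelDataset":
        """Contiguous time slice ``[start, stop)`` as a new panel."""
        return PanelDataset(
            self.values[start:stop], self.mask[start:stop],
            self.timestamps[start:stop], list(self.region_ids),
            list(self.feature_names),
            None if self.targets is None else self.targets[start:stop],
        )

    def fully_observed(self) -> bool:
        return bool(self.mask.all())


@dataclass
class RegionGraph:
    """Undirected region adjacency with symmetric degree normalization.

    ``norm_weights[u, v] = A[u, v] / sqrt(D_uu * D_vv)`` where
    ``D_vv = sum_u A[u, v]`` — the weighting used both for spatial
    aggregation and for spatial imputation.
    """

    region_ids: list[str]
    adjacency: np.ndarray

    def __post_init__(self):
        self.region_ids = [str(r) for r in self.region_ids]
        A = np.asarray(self.adjacency, dtype=np.float64)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError("adjacency must be square")
        if A.shape[0] != len(self.region_ids):
            raise ValueError("adjacency size does not match region count")
        if np.any(A < 0):
            raise ValueError("negative adjacency weight")
        if not np.allclose(A, A.T):
            raise ValueError("adjacency must be symmetric")
        self.adjacency = A

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    @property
    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=0)

    @property
    def norm_weights(self) -> np.ndarray:
        """w_uv = A_uv / sqrt(D_uu D_vv); zero where a degree is zero."""
        d = self.degrees
        with np.errstate(divide="ignore", invalid="ignore"):
            inv = np.where(d > 0, 1.0 / np.sqrt(d), 0.0)
        return self.adjacency * np.outer(inv, inv)

    def reorder(self, region_ids: Sequence[str]) -> "RegionGraph":
        idx = [self.region_ids.index(str(r)) for r in region_ids]
        return RegionGraph(list(region_ids), self.adjacency[np.ix_(idx, idx)])


@dataclass
class ForecastTask:
    """Window size, forecast horizon and chronological split ratios."""

    window: int = 8
    horizon: int = 1
    split_ratios: tuple[float, float, float] = (0.8, 0.1, 0.1)

    def __post_init__(self):
        if self.window < 0:
            raise ValueError("window must be >= 0")
        if self.horizon < 1:
            raise ValueError("horizon must be >= 1")
        if len(self.split_ratios) != 3 or any(r < 0 for r in self.split_ratios):
            raise ValueError("split_ratios must be three nonnegative reals")
        if abs(sum(self.split_ratios) - 1.0) > 1e-9:
            raise ValueError("split_ratios must sum to 1")


# ---------------------------------------------------------------------------
# File I/O


def write_panel(panel: PanelDataset, path_values, path_targets=None) -> None:
    """Write a panel as long CSV (time, region, feature, value, observed).

    Unobserved cells are written with an empty value and observed=0, so a
    read round-trips the mask exactly.
    """
    T, V, M = panel.shape
    t_idx, v_idx, m_idx = np.meshgrid(
        np.arange(T), np.arange(V), np.arange(M), indexing="ij")
    df = pd.DataFrame({
        "time": np.asarray(panel.timestamps)[t_idx.ravel()],
        "region": np.asarray(panel.region_ids, dtype=object)[v_idx.ravel()],
        "feature": np.asarray(panel.feature_names, dtype=object)[m_idx.ravel()],
        "value": panel.values.ravel(),
        "observed": panel.mask.ravel().astype(int),
    })
    df.loc[df["observed"] == 0, "value"] = np.nan
    df.to_csv(path_values, index=False)
    if path_targets is not None and panel.targets is not None:
        tt, vv = np.meshgrid(np.arange(T), np.arange(V), indexing="ij")
        tdf = pd.DataFrame({
            "time": np.asarray(panel.timestamps)[tt.ravel()],
            "region": np.asarray(panel.region_ids, dtype=object)[vv.ravel()],
            "target": panel.targets.ravel(),
        })
        tdf.to_csv(path_targets, index=False)


def read_panel(path_values, path_graph=None, path_targets=None):
    """Read a long-CSV panel and (optionally) its region graph.

    Rows absent from the CSV, and rows with observed=0, become
    mask=False cells. Returns ``PanelDataset`` or
    ``(PanelDataset, RegionGraph)`` when ``path_graph`` is given.
    """
    df = pd.read_csv(path_values, float_precision="round_trip")
    required = {"time", "region", "feature", "value"}
    if not required.issubset(df.columns):
        raise ValueError(f"panel CSV must have columns {sorted(required)}")
    if "observed" not in df.columns:
        df["observed"] = 1
    timestamps = np.sort(df["time"].unique())
    regions = sorted(df["region"].astype(str).unique())
    features = sorted(df["feature"].astype(str).unique())
    t_pos = {t: i for i, t in enumerate(timestamps)}
    v_pos = {r: i for i, r in enumerate(regions)}
    m_pos = {f: i for i, f in enumerate(features)}

    T, V, M = len(timestamps), len(regions), len(features)
    values = np.full((T, V, M), MISSING)
    mask = np.zeros((T, V, M), dtype=bool)
    ti = df["time"].map(t_pos).to_numpy()
    vi = df["region"].astype(str).map(v_pos).to_numpy()
    mi = df["feature"].astype(str).map(m_pos).to_numpy()
    obs = (df["observed"].to_numpy().astype(int) == 1) & df["value"].notna().to_numpy()
    values[ti[obs], vi[obs], mi[obs]] = df["value"].to_numpy()[obs]
    mask[ti[obs], vi[obs], mi[obs]] = True

    targets = None
    if path_targets is not None:
        tdf = pd.read_csv(path_targets, float_precision="round_trip")
        targets = np.full((T, V), np.nan)
        tti = tdf["time"].map(t_pos).to_numpy()
        tvi = tdf["region"].astype(str).map(v_pos).to_numpy()
        targets[tti, tvi] = tdf["target"].to_numpy()

    panel = PanelDataset(values, mask, timestamps, regions, features, targets)
    if path_graph is None:
        return panel
    graph = read_graph(path_graph)
    unknown = set(graph.region_ids) ^ set(regions)
    if unknown:
        raise ValueError(f"graph and panel regions disagree: {sorted(unknown)}")
    return panel, graph.reorder(regions)


def write_graph(graph: RegionGraph, path) -> None:
    """Write a graph as JSON {"regions": [...], "edges": [[u, v, w], ...]}."""
    edges = []
    A = graph.adjacency
    for i in range(graph.n_regions):
        for j in range(i + 1, graph.n_regions):
            if A[i, j] != 0:
                edges.append([graph.region_ids[i], graph.region_ids[j], A[i, j]])
    Path(path).write_text(json.dumps(
        {"regions": graph.region_ids, "edges": edges}, indent=1))


def read_graph(path) -> RegionGraph:
    """Read a region graph from JSON or from a TSV edge list (u, v, weight)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        obj = json.loads(path.read_text())
        regions = [str(r) for r in obj["regions"]]
        edges = [(str(u), str(v), float(w)) for u, v, w in obj["edges"]]
    else:
        df = pd.read_csv(path, sep="\t", header=None,
                         names=["u", "v", "w"], dtype={"u": str, "v": str})
        if df["w"].isna().any():
            df["w"] = df["w"].fillna(1.0)
        edges = list(df.itertuples(index=False, name=None))
        regions = sorted({str(u) for u, _, _ in edges} | {str(v) for _, v, _ in edges})
    pos = {r: i for i, r in enumerate(regions)}
    A = np.zeros((len(regions), len(regions)))
    for u, v, w in edges:
        if w < 0:
            raise ValueError("negative adjacency weight")
        if u not in pos or v not in pos:
            raise ValueError(f"edge endpoint {u!r}/{v!r} not in region list")
        A[pos[u], pos[v]] = w
        A[pos[v], pos[u]] = w
    return RegionGraph(regions, A)


# ---------------------------------------------------------------------------
# Splitting and windowing


def chronological_split(panel: PanelDataset, task: ForecastTask):
    """Split into contiguous, time-ordered train/validation/test segments.

    Segment lengths are ``floor(r_i * T)`` with the flooring remainder
    assigned to the training segment.
    """
    T = panel.n_times
    if T < 3:
        raise ValueError("need at least 3 time steps to split")
    lengths = [int(np.floor(r * T)) for r in task.split_ratios]
    lengths[0] += T - sum(lengths)
    for r, n in zip(task.split_ratios, lengths):
        if r > 0 and n == 0:
            raise ValueError(f"split ratio {r} yields an empty segment at T={T}")
    b1, b2 = lengths[0], lengths[0] + lengths[1]
    return panel.slice_time(0, b1), panel.slice_time(b1, b2), panel.slice_time(b2, T)


def make_windows(panel: PanelDataset, task: ForecastTask):
    """Supervised (history, target) pairs from a panel with targets.

    The history block for pair ``j`` is ``values[j : j+L+1]`` (oldest
    first); its target is ``targets[j + L + horizon - 1]``. The number of
    pairs is ``T - L - horizon + 1``.

    Returns
    -------
    histories : ndarray, shape (n, L+1, V, M)
    targets : ndarray, shape (n, V)
    target_times : ndarray of int, shape (n,)
        Time indices of the targets within the panel.
    """
    if panel.targets is None:
        raise ValueError("panel has no targets to window")
    L, h, T = task.window, task.horizon, panel.n_times
    if L + h > T:
        raise ValueError(f"insufficient history: window {L} + horizon {h} > T={T}")
    n = T - L - h + 1
    histories = np.stack([panel.values[j:j + L + 1] for j in range(n)])
    t_idx = np.arange(n) + L + h - 1
    return histories, panel.targets[t_idx], t_idx
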