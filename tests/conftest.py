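import numpy as np
import pytest

from stpanel import (PanelDataset, RegionGraph, SimParams, make_graph,
                     simulate_panel)


@pytest.fixture
def line_graph():
    """Path A-B-C with unit edges."""
    A = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=float)
    return RegionGraph(["A", "B", "C"], A)


@pytest.fixture
def small_panel(line_graph):
    params = SimParams(n_regions=3, n_features=2, T=30, seed=7)
    panel, _ = simulate_panel(line_graph, params)
    return panel


@pytest.fixture
def tiny_panel():
    """2 regions x 2 features x 12 steps, fully observed, with targets."""
    graph = make_graph("complete", 2, seed=0)
    params = SimParams(n_regions=2, n_features=2, T=12, seed=3)
    panel, _ = simulate_panel(graph, params)
    return panel, graph


def random_panel(rng, T=10, V=3, M=2, missing=0.0, targets=True):
    values = rng.normal(size=(T, V, M))
    mask = rng.random((T, V, M)) >= missing
    values = np.where(mask, values, np.nan)
    y = rng.normal(size=(T, V)) if targets else None
    return PanelDataset(values, mask, np.arange(T),
                        [f"r{i}" for i in range(V)],
                        [f"f{j}" for j in range(M)], y)
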