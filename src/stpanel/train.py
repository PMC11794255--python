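"""Training protocol, evaluation metrics, and gradient verification.

The protocol follows the training regime the forecaster is specified
with: AdamW (decoupled weight decay) at a configurable learning rate
with an optional cosine schedule, dropout in the encoder, global
gradient-norm clipping at 1.0, chronological 80:10:10 splitting, early
stopping on validation loss, and repetition over three random seeds
with mean +/- sd reporting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import PanelForecaster
from .panel import ForecastTask, PanelDataset, RegionGraph, \
    chronological_split, make_windows

__all__ = ["TrainConfig", "train", "train_multi_seed", "evaluate",
           "forecast_metrics", "gradient_check"]


@dataclass
class TrainConfig:
    """Optimization settings, with the protocol defaults.

    ``precision`` selects the storage precision of the fitted
    parameters; all internal computation is double precision (which the
    gradient checks require).
    """

    learning_rate: float = 1e-5
    batch_size: int = 32
    max_epochs: int = 200
    cosine_schedule: bool = True
    clip_norm: float = 1.0
    dropout: float = 0.3
    patience: int = 20
    weight_decay: float = 0.0
    seeds: tuple = (0, 1, 2)
    precision: str = "double"

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.clip_norm <= 0:
            raise ValueError("clip_norm must be > 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.precision not in ("double", "single"):
            raise ValueError("precision must be 'double' or 'single'")


def _apply_config(est: PanelForecaster, cfg: TrainConfig,
                  seed: int) -> PanelForecaster:
    est = est.__class__(**est.get_params())
    est.set_params(learning_rate=cfg.learning_rate, batch_size=cfg.batch_size,
                   max_epochs=cfg.max_epochs,
                   cosine_schedule=cfg.cosine_schedule,
                   clip_norm=cfg.clip_norm, dropout=cfg.dropout,
                   patience=cfg.patience, weight_decay=cfg.weight_decay,
                   seed=seed)
    return est


def train(train_panel: PanelDataset, val_panel: PanelDataset | None,
          graph: RegionGraph | None, est: PanelForecaster | None = None,
          cfg: TrainConfig | None = None, seed: int | None = None):
    """Fit a forecaster on pre-split panels; returns ``(est, report)``."""
    est = est if est is not None else PanelForecaster()
    if cfg is not None:
        est = _apply_config(est, cfg, est.seed if seed is None else seed)
    elif seed is not None:
        est = est.__class__(**{**est.get_params(), "seed": seed})
    est.fit(train_panel, graph, validation=val_panel)
    if cfg is not None and cfg.precision == "single":
        for p in est.params_.values():
            p.data = p.data.astype(np.float32).astype(np.float64)
    return est, est.report_


def train_multi_seed(train_panel, val_panel, test_panel, graph,
                     est: PanelForecaster | None = None,
                     cfg: TrainConfig | None = None):
    """Repeat training over ``cfg.seeds``; returns per-seed estimators,
    per-seed test metrics, and their mean/sd summary."""
    cfg = cfg or TrainConfig()
    fits, metrics = [], []
    for s in cfg.seeds:
        fitted, _ = train(train_panel, val_panel, graph, est, cfg, seed=int(s))
        fits.append(fitted)
        metrics.append(evaluate(fitted, test_panel))
    summary = {
        k: {"mean": float(np.mean([m[k] for m in metrics])),
            "sd": float(np.std([m[k] for m in metrics]))}
        for k in metrics[0]
    }
    return fits, metrics, summary


def forecast_metrics(y_hat: np.ndarray, y: np.ndarray) -> dict[str, float]:
    """MSE and MAE of forecasts against outcomes."""
    y_hat, y = np.asarray(y_hat, float), np.asarray(y, float)
    err = y_hat - y
    return {"mse": float(np.mean(err ** 2)), "mae": float(np.mean(np.abs(err)))}


def evaluate(est: PanelForecaster, panel: PanelDataset,
             task: ForecastTask | None = None) -> dict[str, float]:
    """Windowed test metrics of a fitted forecaster on a panel."""
    task = task or ForecastTask(window=est.window, horizon=est.horizon)
    _, targets, _ = make_windows(panel, task)
    y_hat = est.predict(panel)
    return forecast_metrics(y_hat, targets)


def split_train(panel: PanelDataset, graph: RegionGraph | None = None,
                est: PanelForecaster | None = None,
                cfg: TrainConfig | None = None,
                ratios=(0.8, 0.1, 0.1)):
    """Chronological 80:10:10 split, fit on train with early stopping on
    validation, report test metrics. Returns (est, metrics, splits)."""
    task = ForecastTask(window=(est.window if est else 8),
                        split_ratios=tuple(ratios))
    tr, va, te = chronological_split(panel, task)
    fitted, _ = train(tr, va, graph, est, cfg)
    return fitted, evaluate(fitted, te), (tr, va, te)


def gradient_check(est: PanelForecaster, panel: PanelDataset,
                   graph: RegionGraph | None = None, step: float = 1e-6,
                   precision: str = "double") -> dict:
    """Central finite differences vs analytic gradients of the composite
    loss, for every parameter group.

    Returns per-group maximum relative error (absolute for gradients of
    magnitude below 1) and the overall maximum under "max_rel_err".
    Refuses to run in single precision, where the tolerance is
    unreachable. An unfitted estimator is checked at its initialization
    point; a model with no trainable parameters yields an empty report.
    """
    if precision != "double":
        raise ValueError("gradient_check requires double precision")
    if hasattr(est, "params_"):
        params = est.params_
        if graph is None:
            graph = getattr(est, "graph_", None)
    else:
        params = est.build_params(panel.shape[2],
                                  np.random.default_rng(est.seed))
    params = {k: p for k, p in params.items() if p.requires_grad}
    if not params:
        return {"max_rel_err": np.nan, "groups": {}}

    def loss_value():
        return est.loss_on(panel, graph, params)[0]

    base = loss_value()
    for p in params.values():
        p.grad = None
    base.backward()
    analytic = {k: np.array(p.grad if p.grad is not None
                            else np.zeros_like(p.data))
                for k, p in params.items()}

    report = {}
    overall = 0.0
    for k, p in params.items():
        flat = p.data.reshape(-1)
        worst = 0.0
        for i in range(flat.size):
            orig = flat[i]
            flat[i] = orig + step
            hi = float(loss_value().data)
            flat[i] = orig - step
            lo = float(loss_value().data)
            flat[i] = orig
            fd = (hi - lo) / (2 * step)
            an = float(analytic[k].reshape(-1)[i])
            rel = abs(an - fd) / max(abs(an), abs(fd), 1.0)
            worst = max(worst, rel)
        report[k] = worst
        overall = max(overall, worst)
    return {"max_rel_err": overall, "groups": report}
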