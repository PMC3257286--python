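"""Early-stopping surface over paired rate models, selection, validation.

Each (k_on model, k_off model) pair from the two forward-selection
series is converted into a binding-free-energy predictor through
ΔG = ln(10)·RT·(log10 k_off − log10 k_on) and evaluated on a selection
set of experimental affinities.  Laying the resulting errors out on the
(k_on size × k_off size) grid gives an early-stopping surface; its
stationary point — the global RMSE minimum or correlation maximum — picks
the pair, which is then scored once on a disjoint validation set.  This
is the regularisation step: training alone would keep growing both
models, while the surface turns back up where the pair starts to overfit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .feature_selection import ModelSeries
from .regression import LinearRateModel, rmse
from .screening import correlation_pvalue, pearson
from .tables_io import AffinityTable, TableIntegrityError
from .thermo import DEFAULT_CONTEXT, ThermoContext, dg_from_log_rates

logger = logging.getLogger(__name__)


@dataclass
class StoppingSurface:
    """Selection-set error grids over paired model sizes."""

    kon_sizes: list[int]
    koff_sizes: list[int]
    rmse_grid: np.ndarray  # kcal/mol
    corr_grid: np.ndarray

    def __post_init__(self) -> None:
        shape = (len(self.kon_sizes), len(self.koff_sizes))
        self.rmse_grid = np.asarray(self.rmse_grid, dtype=float)
        self.corr_grid = np.asarray(self.corr_grid, dtype=float)
        if self.rmse_grid.shape != shape or self.corr_grid.shape != shape:
            raise ValueError(f"grids must have shape {shape}")
        if not (np.all(np.isfinite(self.rmse_grid))
                and np.all(np.isfinite(self.corr_grid))):
            raise ValueError("non-finite surface entry")


@dataclass
class SelectedPair:
    """The model pair at the surface's stationary point."""

    kon_model: LinearRateModel
    koff_model: LinearRateModel
    criterion: str  # rmse | correlation
    selection_metrics: dict[str, float]
    validation_metrics: dict[str, float] = field(default_factory=dict)
    selection_ids: tuple[str, ...] = ()
    train_ids: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "criterion": self.criterion,
            "kon_model": self.kon_model.to_dict(),
            "koff_model": self.koff_model.to_dict(),
            "selection_metrics": dict(self.selection_metrics),
            "validation_metrics": dict(self.validation_metrics),
            "selection_ids": list(self.selection_ids),
            "train_ids": list(self.train_ids),
        }


def predict_dg(
    kon_model: LinearRateModel,
    koff_model: LinearRateModel,
    table: AffinityTable,
    ctx: ThermoContext = DEFAULT_CONTEXT,
) -> np.ndarray:
    """Per-complex ΔG (kcal/mol) from a pair of rate models."""
    log_kon = kon_model.predict_table(table.base)
    log_koff = koff_model.predict_table(table.base)
    return dg_from_log_rates(log_kon, log_koff, ctx)


def _pair_metrics(pred: np.ndarray, obs: np.ndarray) -> dict[str, float]:
    corr = pearson(pred, obs)
    return {
        "rmse": rmse(pred, obs),
        "corr": corr,
        "p": correlation_pvalue(corr, len(obs)),
    }


def build_surface(
    kon_series: ModelSeries,
    koff_series: ModelSeries,
    selection: AffinityTable,
    ctx: ThermoContext = DEFAULT_CONTEXT,
) -> StoppingSurface:
    """Evaluate every pair of series entries on the selection affinities."""
    if len(kon_series) == 0 or len(koff_series) == 0:
        raise ValueError("both model series must be non-empty")
    if selection.base.n == 0:
        raise ValueError("selection set is empty")
    obs = selection.dg
    kon_pred = np.stack([m.predict_table(selection.base)
                         for m in kon_series.models])
    koff_pred = np.stack([m.predict_table(selection.base)
                          for m in koff_series.models])
    nr, nc = len(kon_series), len(koff_series)
    rmse_grid = np.empty((nr, nc))
    corr_grid = np.empty((nr, nc))
    for i in range(nr):
        for j in range(nc):
            pred = dg_from_log_rates(kon_pred[i], koff_pred[j], ctx)
            rmse_grid[i, j] = rmse(pred, obs)
            corr_grid[i, j] = pearson(pred, obs)
    return StoppingSurface(
        kon_sizes=[m.n_features for m in kon_series.models],
        koff_sizes=[m.n_features for m in koff_series.models],
        rmse_grid=rmse_grid,
        corr_grid=corr_grid,
    )


def select_pair(surface: StoppingSurface, criterion: str = "rmse") -> tuple[int, int]:
    """Grid indices of the stationary point.

    Global minimum of the RMSE grid or maximum of the correlation grid;
    ties broken by smallest i+j (parsimony), then smallest i.
    """
    if criterion == "rmse":
        grid = surface.rmse_grid
    elif criterion == "correlation":
        grid = -surface.corr_grid
    else:
        raise ValueError(f"criterion must be 'rmse' or 'correlation', "
                         f"got {criterion!r}")
    best = grid.min()
    ties = np.argwhere(grid == best)
    order = sorted((int(i) + int(j), int(i), int(j)) for i, j in ties)
    _, i, j = order[0]
    if len(ties) > 1:
        logger.info("surface tie at %d cells; kept (%d, %d)", len(ties), i, j)
    return i, j


def select_from_series(
    kon_series: ModelSeries,
    koff_series: ModelSeries,
    selection: AffinityTable,
    criterion: str = "rmse",
    ctx: ThermoContext = DEFAULT_CONTEXT,
    train_ids: tuple[str, ...] = (),
) -> tuple[SelectedPair, StoppingSurface]:
    """Build the surface, pick the stationary pair, attach selection metrics."""
    surface = build_surface(kon_series, koff_series, selection, ctx)
    i, j = select_pair(surface, criterion)
    kon_model = kon_series.models[i]
    koff_model = koff_series.models[j]
    pred = predict_dg(kon_model, koff_model, selection, ctx)
    pair = SelectedPair(
        kon_model=kon_model,
        koff_model=koff_model,
        criterion=criterion,
        selection_metrics=_pair_metrics(pred, selection.dg),
        selection_ids=tuple(selection.base.ids),
        train_ids=tuple(train_ids),
    )
    return pair, surface


def validate_pair(
    pair: SelectedPair,
    validation: AffinityTable,
    ctx: ThermoContext = DEFAULT_CONTEXT,
) -> dict[str, float]:
    """Score the selected pair on held-out affinities.

    Hard error if any validation complex was seen during training or
    selection (leakage guard).
    """
    seen = set(pair.selection_ids) | set(pair.train_ids)
    overlap = seen & set(validation.base.ids)
    if overlap:
        raise TableIntegrityError(
            f"validation ids overlap training/selection: {sorted(overlap)[:5]}"
        )
    pred = predict_dg(pair.kon_model, pair.koff_model, validation, ctx)
    metrics = _pair_metrics(pred, validation.dg)
    pair.validation_metrics = metrics
    return metrics
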