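"""The full screen → select-features → select-models → validate pipeline.

`run_workflow` ties the stages together for one configuration (one
partition scheme, one surface criterion, one seed) and returns a
compact selection/validation summary row: feature counts and LOO
metrics of the chosen rate models, selection-set RMSE and correlation
of the combined ΔG predictor, and validation-set RMSE, correlation and
significance.  All artifacts carry the seed and a hash
of the configuration so runs are reproducible and auditable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import tables_io
from .feature_selection import ModelSeries, SelectionConfig, select_features
from .model_selection import (SelectedPair, StoppingSurface, select_from_series,
                              validate_pair)
from .screening import screen_descriptors
from .tables_io import (AffinityTable, PartitionScheme, RateTable,
                        TableIntegrityError, make_scheme)
from .thermo import ThermoContext

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """One pipeline run: inputs, partitioning, selection knobs, seed."""

    kon_path: str | None = None
    koff_path: str | None = None
    affinity_path: str | None = None
    output_dir: str | None = None
    scheme: int = 4
    explicit_ids: dict[str, list[str]] | None = None  # train/selection/validation
    exclude: tuple[str, ...] = ()
    criterion: str = "rmse"
    screen_alpha: float = 0.01
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    thermo: ThermoContext = field(default_factory=ThermoContext)

    def __post_init__(self) -> None:
        if self.criterion not in ("rmse", "correlation"):
            raise ValueError(f"criterion must be 'rmse' or 'correlation', "
                             f"got {self.criterion!r}")
        if self.explicit_ids is None and self.scheme not in (1, 2, 3, 4):
            raise ValueError("scheme must be 1..4 or explicit_ids given")

    @property
    def seed(self) -> int:
        return self.selection.seed

    def config_hash(self) -> str:
        doc = dataclasses.asdict(self)
        return hashlib.sha256(
            json.dumps(doc, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class RunReport:
    """Everything one run produced, plus the Tables-4/5-shaped row."""

    row: dict
    scheme: PartitionScheme
    screen: list
    kon_series: ModelSeries
    koff_series: ModelSeries
    surface: StoppingSurface
    pair: SelectedPair


def _resolve_scheme(cfg: RunConfig, all_ids, kinetics_ids, validated_ids):
    if cfg.explicit_ids is not None:
        drop = {str(i).casefold() for i in cfg.exclude}
        sets = {
            k: frozenset(str(i).casefold() for i in cfg.explicit_ids[k]) - drop
            for k in ("train", "selection", "validation")
        }
        return PartitionScheme(name="explicit",
                               train_ids=sets["train"],
                               selection_ids=sets["selection"],
                               validation_ids=sets["validation"])
    return make_scheme(all_ids, kinetics_ids, validated_ids, cfg.scheme,
                       exclude=cfg.exclude)


def run_workflow(
    config: RunConfig,
    kon_table: RateTable | None = None,
    koff_table: RateTable | None = None,
    affinity_table: AffinityTable | None = None,
) -> RunReport:
    """Execute the full pipeline for one configuration.

    Tables may be passed in memory (e.g. from `synthetic_data.generate`)
    or read from the configured CSV paths.
    """
    if kon_table is None:
        kon_table = tables_io.read_rate_table(config.kon_path, "log10_kon")
    if koff_table is None:
        koff_table = tables_io.read_rate_table(config.koff_path, "log10_koff")
    if affinity_table is None:
        affinity_table = tables_io.read_affinity_table(config.affinity_path)

    all_ids = affinity_table.base.ids
    kinetics_ids = [i for i, f in
                    zip(all_ids, affinity_table.flags["has_kinetics"]) if f]
    validated_ids = [i for i, f in
                     zip(all_ids, affinity_table.flags["validated"]) if f]
    scheme = _resolve_scheme(config, all_ids, kinetics_ids, validated_ids)

    # leakage guard before any fit: PartitionScheme asserts disjointness on
    # construction; also require training rows to exist in the rate tables
    kon_train = kon_table.subset(scheme.train_ids)
    koff_train = koff_table.subset(scheme.train_ids)
    for label, tab in (("kon", kon_train), ("koff", koff_train)):
        if tab.base.n == 0:
            raise TableIntegrityError(
                f"no {label} training rows for {scheme.name}"
            )
    selection_tab = affinity_table.subset(scheme.selection_ids)
    validation_tab = affinity_table.subset(scheme.validation_ids)
    if selection_tab.base.n == 0 or validation_tab.base.n == 0:
        raise TableIntegrityError(f"{scheme.name}: empty selection or "
                                  "validation affinity subset")

    screen = screen_descriptors(kon_train, alpha=config.screen_alpha)
    logger.info("screen: %d descriptors significant at alpha=%g",
                len(screen), config.screen_alpha)

    kon_series = select_features(kon_train, config.selection)
    koff_series = select_features(koff_train, config.selection)
    pair, surface = select_from_series(
        kon_series, koff_series, selection_tab,
        criterion=config.criterion, ctx=config.thermo,
        train_ids=tuple(kon_train.base.ids),
    )
    validation = validate_pair(pair, validation_tab, ctx=config.thermo)

    row = {
        "scheme": scheme.name,
        "criterion": config.criterion,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "kon_n_features": pair.kon_model.n_features,
        "kon_loo_corr": pair.kon_model.metrics["cv_corr"],
        "kon_loo_rmse": pair.kon_model.metrics["cv_rmse"],
        "koff_n_features": pair.koff_model.n_features,
        "koff_loo_corr": pair.koff_model.metrics["cv_corr"],
        "koff_loo_rmse": pair.koff_model.metrics["cv_rmse"],
        "selection_rmse": pair.selection_metrics["rmse"],
        "selection_corr": pair.selection_metrics["corr"],
        "validation_rmse": validation["rmse"],
        "validation_corr": validation["corr"],
        "validation_p": validation["p"],
    }
    report = RunReport(row=row, scheme=scheme, screen=screen,
                       kon_series=kon_series, koff_series=koff_series,
                       surface=surface, pair=pair)
    if config.output_dir is not None:
        _write_artifacts(config, report)
    return report


def _write_artifacts(config: RunConfig, report: RunReport) -> None:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {"seed": config.seed, "config_hash": config.config_hash()}

    Path(out / "report.json").write_text(json.dumps(report.row, indent=2))
    scheme_doc = {
        **meta,
        "name": report.scheme.name,
        "train_ids": sorted(report.scheme.train_ids),
        "selection_ids": sorted(report.scheme.selection_ids),
        "validation_ids": sorted(report.scheme.validation_ids),
    }
    (out / "scheme.json").write_text(json.dumps(scheme_doc, indent=2))
    (out / "pair.json").write_text(
        json.dumps({**report.pair.to_dict(), **meta}, indent=2))
    for label, series in (("kon", report.kon_series),
                          ("koff", report.koff_series)):
        doc = {
            **meta,
            "target": series.target,
            "best_index": series.best_index,
            "cv_history": list(series.cv_history),
            "models": [m.to_dict() for m in series.models],
        }
        (out / f"series_{label}.json").write_text(json.dumps(doc, indent=2))
    stamp = f"# seed={meta['seed']} config_hash={meta['config_hash']}\n"
    with open(out / "screen.csv", "w") as fh:
        fh.write(stamp)
        fh.write("descriptor,r,n,p\n")
        for rec in report.screen:
            fh.write(f"{rec.descriptor},{rec.r:.6f},{rec.n},{rec.p:.6g}\n")
    surf = report.surface
    with open(out / "surface.csv", "w") as fh:
        fh.write(stamp)
        fh.write("kon_size,koff_size,rmse,corr\n")
        for i, si in enumerate(surf.kon_sizes):
            for j, sj in enumerate(surf.koff_sizes):
                fh.write(f"{si},{sj},{surf.rmse_grid[i, j]:.6f},"
                         f"{surf.corr_grid[i, j]:.6f}\n")
    logger.info("artifacts written to %s", out)
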