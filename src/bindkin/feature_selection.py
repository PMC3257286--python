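"""Population-based greedy forward feature selection.

The search keeps a population of descriptor subsets (default 20) and
grows every member by one descriptor per iteration: iteration 1 scores
each descriptor alone; iteration t scores every S ∪ {d} for retained S
and d ∉ S, after collapsing duplicate subsets.  Candidates are ranked by
5-fold cross-validated RMSE under a single fold plan shared by the whole
run (paired comparisons), ties broken by the lexicographic feature-name
tuple so runs are deterministic.  The best subset of each size is stored
as that size's model.  A speculative-round counter increments whenever an
iteration's best RMSE fails to beat the global best and resets on any new
global best; the search stops after `speculative_rounds` consecutive
speculative iterations (default 10), when descriptors are exhausted, or
at `max_features`.

No per-size stopping decision is made here — the stored series, including
the speculative tail past the global best, is handed to the early-stopping
surface, which is where regularisation actually happens.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .regression import (FoldPlan, KFoldScorer, LinearRateModel, fit_with_cv,
                         make_fold_plan)
from .tables_io import RateTable

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SelectionConfig:
    population: int = 20
    folds: int = 5
    speculative_rounds: int = 10
    max_features: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population < 1:
            raise ValueError("population must be >= 1")
        if self.folds < 2:
            raise ValueError("need at least 2 folds")
        if self.speculative_rounds < 0:
            raise ValueError("speculative_rounds must be >= 0")
        if self.max_features is not None and self.max_features < 1:
            raise ValueError("max_features must be >= 1 when set")


@dataclass
class ModelSeries:
    """Best model per feature count from one forward-selection run.

    ``models[i]`` has i+1 features; ``cv_history[i]`` is its 5-fold CV
    RMSE; ``best_index`` marks the global CV minimum; entries after it
    are the speculative tail.  ``retained_history[i]`` lists the feature
    tuples kept in the population at size i+1 (for the forward-growth
    audit: every retained subset extends some subset retained earlier).
    """

    target: str
    models: list[LinearRateModel]
    cv_history: list[float]
    best_index: int
    seed: int
    fold_plan: FoldPlan | None = None
    retained_history: list[list[tuple[str, ...]]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.models) != len(self.cv_history):
            raise ValueError("models and cv_history length mismatch")
        for i, m in enumerate(self.models):
            if m.n_features != i + 1:
                raise ValueError(f"series entry {i} has {m.n_features} features")
        if not 0 <= self.best_index < len(self.models):
            raise ValueError("best_index out of range")

    def __len__(self) -> int:
        return len(self.models)

    @property
    def best_model(self) -> LinearRateModel:
        return self.models[self.best_index]


def _usable_columns(table: RateTable) -> list[str]:
    X = table.base.values
    constant = X.std(axis=0) == 0.0
    if constant.any():
        skipped = [d for d, c in zip(table.base.descriptor_names, constant) if c]
        logger.warning("ignoring %d constant descriptor columns: %s",
                       len(skipped), skipped)
    return [d for d, c in zip(table.base.descriptor_names, constant) if not c]


def evaluate_population(
    candidates: Sequence[Sequence[str]],
    table: RateTable,
    plan: FoldPlan,
) -> list[tuple[tuple[str, ...], float]]:
    """Score candidate feature subsets by shared-plan k-fold RMSE.

    Duplicate subsets collapse to one entry.  Subsets whose fit fails
    (singular folds) are excluded with a warning; an error is raised only
    if every candidate fails.  The result is sorted by (RMSE, sorted
    feature-name tuple), the retention order of the selector.
    """
    if len(candidates) == 0:
        raise ValueError("no candidate subsets to evaluate")
    names = table.base.descriptor_names
    col = {d: j for j, d in enumerate(names)}
    unique: dict[frozenset, tuple[str, ...]] = {}
    for cand in candidates:
        key = frozenset(cand)
        if not key:
            raise ValueError("empty candidate subset")
        unique.setdefault(key, tuple(sorted(cand)))

    scorer = KFoldScorer(table.base.values, table.response, plan)
    scored: list[tuple[tuple[str, ...], float]] = []
    failed: list[tuple[str, ...]] = []
    for subset in unique.values():
        try:
            score = scorer.score([col[f] for f in subset])
        except KeyError as exc:
            raise KeyError(f"candidate names a missing descriptor: {exc}") from exc
        except (np.linalg.LinAlgError, ValueError):
            failed.append(subset)
            continue
        scored.append((subset, score))
    if failed:
        logger.warning("excluded %d unfittable candidate subsets (e.g. %s)",
                       len(failed), failed[0])
    if not scored:
        raise ValueError("every candidate subset failed to fit")
    scored.sort(key=lambda item: (item[1], item[0]))
    return scored


def select_features(table: RateTable, cfg: SelectionConfig) -> ModelSeries:
    """Run the population-based greedy forward search on a rate table."""
    pool = _usable_columns(table)
    if not pool:
        raise ValueError("no usable (non-constant) descriptor columns")
    n = table.base.n
    if n < cfg.folds * 2:
        raise ValueError(f"{n} rows is too few for {cfg.folds}-fold CV")

    plan = make_fold_plan(n, cfg.folds, cfg.seed)
    max_size = len(pool) if cfg.max_features is None else min(
        cfg.max_features, len(pool))
    # each training fold must keep more rows than parameters
    min_train = n - int(np.ceil(n / cfg.folds))
    max_size = min(max_size, min_train - 2)
    if max_size < 1:
        raise ValueError("too few rows per training fold to fit any model")

    retained: list[tuple[str, ...]] = [()]
    models: list[LinearRateModel] = []
    cv_history: list[float] = []
    retained_history: list[list[tuple[str, ...]]] = []
    global_best = np.inf
    speculative = 0

    for size in range(1, max_size + 1):
        candidates = [
            (*subset, d)
            for subset in retained
            for d in pool
            if d not in subset
        ]
        scored = evaluate_population(candidates, table, plan)
        retained = [subset for subset, _ in scored[: cfg.population]]
        retained_history.append(list(retained))
        best_subset, best_rmse = scored[0]
        models.append(fit_with_cv(table, best_subset, cv_rmse_kfold=best_rmse))
        cv_history.append(best_rmse)
        logger.debug("size %d: best CV RMSE %.4f with %s",
                     size, best_rmse, best_subset)

        if best_rmse < global_best:
            global_best = best_rmse
            speculative = 0
        else:
            speculative += 1
            if speculative >= cfg.speculative_rounds:
                logger.info("terminating after %d speculative rounds at size %d",
                            speculative, size)
                break

    best_index = int(np.argmin(cv_history))
    return ModelSeries(
        target=table.response_name,
        models=models,
        cv_history=cv_history,
        best_index=best_index,
        seed=cfg.seed,
        fold_plan=plan,
        retained_history=retained_history,
    )
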