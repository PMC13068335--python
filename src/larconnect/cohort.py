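"""Multi-cohort evaluation harness for biomarker panels.

Enumerates a model grid (dataset x comparison x panel x sex stratum x
classifier), evaluates each cell by 20x5-fold stratified cross-validated
AUC with either a dense PLS-DA or a random-forest classifier, and
aggregates full-data-refit feature importances as percentage ranks across
well-performing models (mean AUC above a threshold).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .core_io import ExpressionMatrix
from .splsda import PanelSpec, fit_splsda, predict_scores, vip

logger = logging.getLogger(__name__)

CLASSIFIERS = ("plsda", "random_forest")
STRATA = ("combined", "male", "female")


@dataclass(frozen=True)
class ModelGridCell:
    dataset: str
    comparison: tuple  # (negative group, positive group)
    panel: str
    stratum: str = "combined"
    classifier: str = "plsda"

    def __post_init__(self) -> None:
        if self.stratum not in STRATA:
            raise ValueError(f"unknown stratum {self.stratum!r}")
        if self.classifier not in CLASSIFIERS:
            raise ValueError(f"unknown classifier {self.classifier!r}")


@dataclass
class EvalResult:
    cell: ModelGridCell
    mean_auc: float
    sd_auc: float
    importances: pd.Series
    n_samples: int
    n_genes: int


def enumerate_grid(axes: Mapping[str, Sequence]) -> list[dict]:
    """Full Cartesian product of the axes, in declared order, lexicographic
    within each axis's given ordering."""
    for name, values in axes.items():
        if len(values) == 0:
            raise ValueError(f"axis {name!r} is empty")
    names = list(axes)
    return [dict(zip(names, combo)) for combo in itertools.product(*axes.values())]


def _cv_auc(X: pd.DataFrame, y: np.ndarray, classifier: str, repeats: int, folds: int,
            seed: int, n_trees: int) -> tuple[float, float]:
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.metrics import roc_auc_score
    from sklearn.model_selection import StratifiedKFold

    pos = sorted(set(y))[1]
    y_bin = (y == pos).astype(int)
    aucs = []
    for r in range(repeats):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed + r)
        scores = np.empty(len(y))
        for train, test in skf.split(X, y):
            if classifier == "plsda":
                model = fit_splsda(X.iloc[train], y[train], ncomp=2, keepX=None,
                                   positive_class=pos)
                scores[test] = predict_scores(model, X.iloc[test])
            else:
                rf = RandomForestClassifier(
                    n_estimators=n_trees, max_features="sqrt", random_state=seed + r
                ).fit(X.iloc[train], y_bin[train])
                scores[test] = rf.predict_proba(X.iloc[test])[:, 1]
        aucs.append(roc_auc_score(y_bin, scores))
    aucs = np.asarray(aucs)
    return float(aucs.mean()), float(aucs.std(ddof=1))


def evaluate_cell(
    matrix: ExpressionMatrix,
    sample_table: pd.DataFrame,
    cell: ModelGridCell,
    panel: PanelSpec,
    repeats: int = 20,
    folds: int = 5,
    seed: int = 0,
    n_trees: int = 500,
) -> EvalResult | None:
    """Evaluate one grid cell; returns ``None`` (with a logged reason) when a
    class is too small to stratify.

    Samples are restricted to the cell's two comparison groups and sex
    stratum; panel genes missing from the dataset are dropped, erroring if
    fewer than half are present.  Importances come from a full-data refit
    (VIP for PLS-DA, impurity importance for the forest).
    """
    from sklearn.ensemble import RandomForestClassifier

    genes = [g for g in panel.genes if g in matrix.values.index]
    missing = [g for g in panel.genes if g not in matrix.values.index]
    if len(genes) < 0.5 * len(panel.genes):
        raise ValueError(
            f"{cell.dataset}: only {len(genes)}/{len(panel.genes)} panel genes present; "
            f"missing {missing[:10]}..."
        )
    if missing:
        logger.info("%s/%s: dropping %d missing panel genes", cell.dataset, panel.name, len(missing))

    keep = sample_table["group"].isin(cell.comparison)
    if cell.stratum != "combined":
        keep &= sample_table["sex"] == cell.stratum
    samples = sample_table.index[keep]
    y = sample_table.loc[samples, "group"].to_numpy()
    counts = pd.Series(y).value_counts()
    if len(counts) < 2 or counts.min() < folds:
        logger.warning("skipping %s: class sizes %s too small for %d folds",
                       cell, counts.to_dict(), folds)
        return None

    X = matrix.values.loc[genes, samples].T  # samples x genes
    X = X.loc[:, X.std(axis=0, ddof=1) > 0]
    mean_auc, sd_auc = _cv_auc(X, y, cell.classifier, repeats, folds, seed, n_trees)

    pos = sorted(set(y))[1]
    if cell.classifier == "plsda":
        model = fit_splsda(X, y, ncomp=2, keepX=None, positive_class=pos)
        importances = vip(model)
    else:
        rf = RandomForestClassifier(
            n_estimators=n_trees, max_features="sqrt", random_state=seed
        ).fit(X, (y == pos).astype(int))
        importances = pd.Series(rf.feature_importances_, index=X.columns, name="importance")
    return EvalResult(
        cell=cell,
        mean_auc=mean_auc,
        sd_auc=sd_auc,
        importances=importances,
        n_samples=len(y),
        n_genes=X.shape[1],
    )


def percentage_rank(importances: pd.Series) -> pd.Series:
    """Map importances to [0, 1]: highest -> 1, lowest -> 0, ties averaged."""
    vals = np.asarray(importances, dtype=float)
    if vals.size < 2:
        raise ValueError("need at least 2 features to rank")
    ranks = (rankdata(vals, method="average") - 1.0) / (vals.size - 1.0)
    return pd.Series(ranks, index=importances.index, name="pct_rank")


def aggregate_ranks(results: Sequence[EvalResult], auc_min: float = 0.70) -> pd.DataFrame:
    """Average each biomarker's percentage rank over models with mean AUC
    above ``auc_min``; a biomarker only enters the average of models whose
    panel contains it."""
    rows: dict = {}
    n_qual = 0
    for res in results:
        if res is None or not (res.mean_auc > auc_min):
            continue
        n_qual += 1
        ranks = percentage_rank(res.importances)
        for gene, r in ranks.items():
            rows.setdefault(gene, []).append(r)
    if n_qual == 0:
        return pd.DataFrame(columns=["mean_rank", "n_models"])
    table = pd.DataFrame(
        {
            "mean_rank": {g: float(np.mean(v)) for g, v in rows.items()},
            "n_models": {g: len(v) for g, v in rows.items()},
        }
    )
    return table.sort_values("mean_rank", ascending=False, kind="mergesort")


def evaluate_grid(
    datasets: Mapping[str, tuple[ExpressionMatrix, pd.DataFrame]],
    comparisons: Mapping[str, tuple],
    panels: Mapping[str, PanelSpec],
    strata: Sequence[str] = STRATA,
    classifiers: Sequence[str] = CLASSIFIERS,
    repeats: int = 20,
    folds: int = 5,
    seed: int = 0,
    n_trees: int = 500,
) -> list[EvalResult]:
    """Evaluate every grid cell whose dataset holds both comparison groups."""
    results = []
    for ds_name, (matrix, samples) in datasets.items():
        groups = set(samples["group"])
        for comp_name, pair in comparisons.items():
            if not set(pair) <= groups:
                continue
            for panel_name, panel in panels.items():
                for stratum in strata:
                    for clf in classifiers:
                        cell = ModelGridCell(ds_name, tuple(pair), panel_name, stratum, clf)
                        res = evaluate_cell(
                            matrix, samples, cell, panel,
                            repeats=repeats, folds=folds, seed=seed, n_trees=n_trees,
                        )
                        if res is not None:
                            results.append(res)
    return results


def results_table(results: Sequence[EvalResult]) -> pd.DataFrame:
    """Long-format results (one row per evaluated grid cell)."""
    return pd.DataFrame(
        [
            {
                "dataset": r.cell.dataset,
                "comparison": " vs ".join(map(str, r.cell.comparison)),
                "panel": r.cell.panel,
                "stratum": r.cell.stratum,
                "classifier": r.cell.classifier,
                "mean_auc": r.mean_auc,
                "sd_auc": r.sd_auc,
                "n_samples": r.n_samples,
                "n_genes": r.n_genes,
            }
            for r in results
        ]
    )
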