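"""Sparse PLS-DA: decomposition, cross-validated keepX tuning, panel rules.

The classifier is a two-class sparse partial least squares discriminant
analysis in the mixOmics construction: columns of X are centered and
unit-scaled, the class labels are dummy-coded (two centered, scaled
columns), and each component's X-weight vector is computed by NIPALS with
magnitude-ranked soft-thresholding so that exactly ``keepX`` entries stay
nonzero.  X is deflated by its own scores/loadings; Y is not deflated.
Tuning follows the study design: stratified 5-fold cross-validation
repeated 20 times over a keepX grid, retaining the smallest panel whose
mean AUC clears a threshold (0.70 by default).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

_NIPALS_TOL = 1e-9
_NIPALS_MAX_ITER = 500


@dataclass
class SPLSDAModel:
    """Fitted sparse PLS-DA model.

    ``weights`` (p x H) has exactly ``keepX[h]`` nonzero rows per column
    and unit norm per column; ``scores`` = deflated-X projections,
    ``y_loadings`` (H x 2) regresses the centered/scaled dummy Y on scores.
    """

    ncomp: int
    keepX: tuple[int, ...]
    genes: list
    classes: tuple
    weights: np.ndarray  # p x H
    x_loadings: np.ndarray  # p x H
    y_loadings: np.ndarray  # H x 2
    scores: np.ndarray  # n x H
    x_mean: np.ndarray
    x_sd: np.ndarray

    @property
    def selected_genes(self) -> list:
        """Genes with a nonzero weight in any component."""
        nz = np.any(self.weights != 0, axis=1)
        return [g for g, keep in zip(self.genes, nz) if keep]

    def selected_by_component(self) -> list[list]:
        return [
            [g for g, w in zip(self.genes, self.weights[:, h]) if w != 0]
            for h in range(self.ncomp)
        ]


def _as_xy(X, y):
    """Coerce X to (samples x genes ndarray, gene list) and y to labels."""
    if isinstance(X, pd.DataFrame):
        genes = list(X.columns)
        Xa = X.to_numpy(dtype=float)
    else:
        Xa = np.asarray(X, dtype=float)
        genes = list(range(Xa.shape[1]))
    ya = np.asarray(y)
    return Xa, genes, ya


def _dummy(y: np.ndarray, classes: tuple) -> np.ndarray:
    Y = np.zeros((len(y), 2))
    for k, c in enumerate(classes):
        Y[y == c, k] = 1.0
    Yc = Y - Y.mean(axis=0)
    sd = Yc.std(axis=0, ddof=1)
    return Yc / sd


def _soft_threshold_keep(a: np.ndarray, keep: int) -> np.ndarray:
    """Keep the ``keep`` largest-|a| entries, soft-thresholded by the largest
    excluded magnitude; zero the rest."""
    p = a.size
    if keep >= p:
        return a.copy()
    absa = np.abs(a)
    # threshold = largest excluded magnitude
    thr = np.partition(absa, p - keep - 1)[p - keep - 1]
    out = np.sign(a) * np.maximum(absa - thr, 0.0)
    return out


def fit_splsda(X, y, ncomp: int = 2, keepX=None, positive_class=None) -> SPLSDAModel:
    """Fit a two-class sparse PLS-DA model.

    Parameters
    ----------
    X
        samples x genes matrix (DataFrame or array).
    y
        two-class labels; ``positive_class`` defaults to the
        lexicographically larger label.
    keepX
        number of genes retained per component (int broadcasts across
        components; ``None`` means no sparsity).
    """
    Xa, genes, ya = _as_xy(X, y)
    n, p = Xa.shape
    labels = sorted(set(ya))
    if len(labels) != 2:
        raise ValueError(f"expected exactly 2 classes, got {labels}")
    if positive_class is None:
        positive_class = labels[1]
    classes = (next(c for c in labels if c != positive_class), positive_class)

    if keepX is None:
        keepX = (p,) * ncomp
    elif np.isscalar(keepX):
        keepX = (int(keepX),) * ncomp
    else:
        keepX = tuple(int(k) for k in keepX)
    if len(keepX) != ncomp:
        raise ValueError(f"keepX must have {ncomp} entries, got {len(keepX)}")
    if any(k < 1 or k > p for k in keepX):
        raise ValueError(f"keepX entries must lie in [1, {p}], got {keepX}")

    x_mean = Xa.mean(axis=0)
    x_sd = Xa.std(axis=0, ddof=1)
    const = x_sd == 0
    if const.any():
        bad = [genes[i] for i in np.flatnonzero(const)]
        raise ValueError(f"constant gene columns: {bad[:10]}")
    Xs = (Xa - x_mean) / x_sd
    Y = _dummy(ya, classes)

    W = np.zeros((p, ncomp))
    P = np.zeros((p, ncomp))
    Q = np.zeros((ncomp, 2))
    T = np.zeros((n, ncomp))
    Xh = Xs.copy()
    for h in range(ncomp):
        M = Xh.T @ Y  # p x 2
        # initialize v from the dominant right singular vector of M
        _, _, vt = np.linalg.svd(M, full_matrices=False)
        v = vt[0]
        w = np.zeros(p)
        for _ in range(_NIPALS_MAX_ITER):
            a = M @ v
            a = _soft_threshold_keep(a, keepX[h])
            norm = np.linalg.norm(a)
            if norm == 0:
                raise ValueError(f"component {h + 1}: all weights thresholded to zero")
            w_new = a / norm
            v_new = M.T @ w_new
            v_new /= np.linalg.norm(v_new)
            if np.linalg.norm(w_new - w) < _NIPALS_TOL:
                w = w_new
                break
            w, v = w_new, v_new
        t = Xh @ w
        tt = float(t @ t)
        ph = Xh.T @ t / tt
        qh = Y.T @ t / tt
        Xh = Xh - np.outer(t, ph)
        W[:, h], P[:, h], Q[h], T[:, h] = w, ph, qh, t

    return SPLSDAModel(
        ncomp=ncomp,
        keepX=keepX,
        genes=genes,
        classes=classes,
        weights=W,
        x_loadings=P,
        y_loadings=Q,
        scores=T,
        x_mean=x_mean,
        x_sd=x_sd,
    )


def predict_scores(model: SPLSDAModel, X_new) -> np.ndarray:
    """Continuous discriminant score for the positive class.

    Applies the stored centering/scaling, projects through the deflation
    sequence, and returns T_new @ q_pos (0 at the training mean; positive
    values favour the positive class).
    """
    if isinstance(X_new, pd.DataFrame):
        missing = [g for g in model.genes if g not in X_new.columns]
        if missing:
            raise ValueError(f"missing genes in new data: {missing[:10]}")
        Xa = X_new[model.genes].to_numpy(dtype=float)
    else:
        Xa = np.asarray(X_new, dtype=float)
        if Xa.shape[1] != len(model.genes):
            raise ValueError(
                f"new data has {Xa.shape[1]} genes, model expects {len(model.genes)}"
            )
    Xs = (Xa - model.x_mean) / model.x_sd
    T_new = np.zeros((Xs.shape[0], model.ncomp))
    Xh = Xs
    for h in range(model.ncomp):
        t = Xh @ model.weights[:, h]
        Xh = Xh - np.outer(t, model.x_loadings[:, h])
        T_new[:, h] = t
    # score for the positive (second) class column of the dummy response
    return T_new @ model.y_loadings[:, 1]


def vip(model: SPLSDAModel) -> pd.Series:
    """Variable importance in projection.

    VIP_j = sqrt(p * sum_h SS_h w_jh^2 / sum_h SS_h) with
    SS_h = (sum_k q_hk^2) * t_h' t_h; mean(VIP^2) over genes equals 1.
    """
    p = len(model.genes)
    ss = (model.y_loadings**2).sum(axis=1) * (model.scores**2).sum(axis=0)
    w2 = model.weights**2  # columns already unit-norm
    vip2 = p * (w2 @ ss) / ss.sum()
    return pd.Series(np.sqrt(vip2), index=model.genes, name="VIP")


# ---------------------------------------------------------------------------
# cross-validated tuning
# ---------------------------------------------------------------------------


@dataclass
class CVTuningResult:
    """Mean/SD AUC over repeats for each keepX configuration."""

    table: pd.DataFrame  # columns: keepX, n_transcripts, mean_auc, sd_auc
    repeats: int
    folds: int
    seed: int


def _normalize_grid(keepX_grid, ncomp: int) -> list[tuple[int, ...]]:
    configs = []
    for cfg in keepX_grid:
        if np.isscalar(cfg):
            configs.append((int(cfg),) * ncomp)
        else:
            cfg = tuple(int(k) for k in cfg)
            if len(cfg) != ncomp:
                raise ValueError(f"keepX config {cfg} does not match ncomp={ncomp}")
            configs.append(cfg)
    return configs


def repeated_cv_auc(
    X,
    y,
    keepX_grid,
    ncomp: int = 2,
    repeats: int = 20,
    folds: int = 5,
    seed: int = 0,
) -> CVTuningResult:
    """Stratified repeated-CV AUC over a keepX grid.

    Per repeat, per configuration: fit on the training folds, score the
    test folds, pool test scores across the repeat's folds and compute one
    AUC; the table reports mean +/- SD over repeats.  Repeat ``r`` uses
    ``seed + r`` for fold assignment, so results are deterministic.
    """
    from sklearn.metrics import roc_auc_score
    from sklearn.model_selection import StratifiedKFold

    Xa, genes, ya = _as_xy(X, y)
    Xdf = pd.DataFrame(Xa, columns=genes)
    labels, counts = np.unique(ya, return_counts=True)
    if len(labels) != 2:
        raise ValueError(f"expected 2 classes, got {labels.tolist()}")
    if counts.min() < folds:
        raise ValueError(
            f"class {labels[np.argmin(counts)]!r} has {counts.min()} samples; "
            f"cannot stratify into {folds} folds"
        )
    configs = _normalize_grid(keepX_grid, ncomp)
    pos = sorted(labels)[1]
    y_bin = (ya == pos).astype(int)

    aucs = np.zeros((len(configs), repeats))
    for r in range(repeats):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed + r)
        splits = list(skf.split(Xa, ya))
        for ci, cfg in enumerate(configs):
            scores = np.empty(len(ya))
            for train, test in splits:
                model = fit_splsda(Xdf.iloc[train], ya[train], ncomp=ncomp, keepX=cfg,
                                   positive_class=pos)
                scores[test] = predict_scores(model, Xdf.iloc[test])
            aucs[ci, r] = roc_auc_score(y_bin, scores)

    table = pd.DataFrame(
        {
            "keepX": [",".join(map(str, c)) for c in configs],
            "n_transcripts": [sum(c) for c in configs],
            "mean_auc": aucs.mean(axis=1),
            "sd_auc": aucs.std(axis=1, ddof=1),
        }
    )
    return CVTuningResult(table=table, repeats=repeats, folds=folds, seed=seed)


def tune_keepx(
    X,
    y,
    grid=(5, 10, 15, 20, 25, 30),
    ncomp: int = 2,
    repeats: int = 20,
    folds: int = 5,
    seed: int = 0,
) -> CVTuningResult:
    """Sequential per-component keepX tuning over a shared grid.

    Component 1 is tuned with a one-component model; each later component
    is tuned with earlier components fixed at their best values.  The
    returned table contains every configuration evaluated.
    """
    best: list[int] = []
    tables = []
    for h in range(ncomp):
        configs = [tuple(best) + (k,) for k in grid]
        res = repeated_cv_auc(X, y, configs, ncomp=h + 1, repeats=repeats, folds=folds, seed=seed)
        idx = int(res.table["mean_auc"].idxmax())
        best.append(int(str(res.table.loc[idx, "keepX"]).split(",")[-1]))
        tables.append(res.table)
    table = pd.concat(tables, ignore_index=True)
    return CVTuningResult(table=table, repeats=repeats, folds=folds, seed=seed)


def select_panel(tuning: CVTuningResult, auc_threshold: float = 0.70):
    """Pick the qualifying configuration with the fewest transcripts.

    Qualifying = mean AUC strictly above the threshold.  Ties on size are
    broken by higher mean AUC, then lower SD.  Returns the chosen table
    row as a Series, or ``None`` when nothing qualifies.
    """
    t = tuning.table
    ok = t[t["mean_auc"] > auc_threshold]
    if ok.empty:
        return None
    ok = ok.sort_values(
        by=["n_transcripts", "mean_auc", "sd_auc"],
        ascending=[True, False, True],
        kind="mergesort",
    )
    return ok.iloc[0]


# ---------------------------------------------------------------------------
# biomarker panels
# ---------------------------------------------------------------------------


@dataclass
class PanelSpec:
    """A named biomarker panel: unique, ordered gene symbols."""

    name: str
    genes: tuple

    def __post_init__(self) -> None:
        self.genes = tuple(self.genes)
        if len(set(self.genes)) != len(self.genes):
            dupes = [g for g in self.genes if list(self.genes).count(g) > 1]
            raise ValueError(f"panel {self.name!r} has duplicate symbols: {sorted(set(dupes))}")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class MergedPanels:
    combined: PanelSpec
    total_slots: int
    overlap: pd.DataFrame  # panel x panel shared-gene counts


def merge_panels(panels: list[PanelSpec], name: str = "combined") -> MergedPanels:
    """Union panels preserving first-appearance order.

    Also reports the total slot count (sum of panel sizes, counting
    duplicates) and the pairwise overlap matrix.
    """
    if not panels:
        raise ValueError("need at least one panel")
    seen: dict = {}
    for panel in panels:
        for g in panel.genes:
            seen.setdefault(g, None)
    combined = PanelSpec(name, tuple(seen))
    total_slots = sum(len(p) for p in panels)
    names = [p.name for p in panels]
    overlap = pd.DataFrame(
        [[len(set(a.genes) & set(b.genes)) for b in panels] for a in panels],
        index=names,
        columns=names,
    )
    return MergedPanels(combined=combined, total_slots=total_slots, overlap=overlap)
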