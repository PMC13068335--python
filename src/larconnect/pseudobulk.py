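"""Cell-type-specific pseudobulk differential expression.

Single-cell counts are library-size normalized and log2(x+1) transformed,
averaged per (cell type, sample) stratum, and tested per cell type with
an empirical-Bayes moderated t-statistic (limma-trend style): per-gene
OLS residual variances are shrunk toward a prior fit by moment-matching
the scaled-F distribution of sample variances on the log scale, with an
optional mean-variance trend via a locally weighted fit.  Significance
within a biomarker list uses Benjamini-Hochberg FDR (20% by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.special import digamma, polygamma
from scipy.stats import t as t_dist
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# normalization and pseudobulk
# ---------------------------------------------------------------------------


def normalize_cells(adata, scale_factor: float | None = None):
    """Library-size normalize and log2(x+1) transform single-cell counts.

    value = log2(count / libsize * scale_factor + 1); sparse zeros stay
    zero.  ``scale_factor`` defaults to the median library size.
    """
    import anndata as ad

    X = sparse.csr_matrix(adata.X, dtype=float)
    lib = np.asarray(X.sum(axis=1)).ravel()
    zero = lib <= 0
    if zero.any():
        bad = adata.obs_names[zero].tolist()
        raise ValueError(f"cells with zero library size: {bad[:10]}")
    if scale_factor is None:
        scale_factor = float(np.median(lib))
    scaled = sparse.diags(scale_factor / lib) @ X
    scaled = scaled.tocsr()
    scaled.data = np.log2(scaled.data + 1.0)
    out = ad.AnnData(X=scaled, obs=adata.obs.copy(), var=adata.var.copy())
    out.uns["scale_factor"] = scale_factor
    return out


@dataclass
class PseudobulkMatrix:
    """Per-(cell type, sample) mean logcounts.

    ``values``: genes x strata with a (cell_type, sample_id) MultiIndex on
    columns; ``n_cells`` per stratum; ``meta``: one metadata row per
    stratum (first cell's annotations).
    """

    values: pd.DataFrame
    n_cells: pd.Series
    meta: pd.DataFrame


def pseudobulk_mean(
    adata,
    cell_type_key: str = "cell_type",
    sample_key: str = "sample_id",
    min_cells: int = 10,
) -> PseudobulkMatrix:
    """Average logcounts per (cell type, sample); strata with fewer than
    ``min_cells`` cells are dropped with their counts logged."""
    X = sparse.csr_matrix(adata.X, dtype=float)
    obs = adata.obs
    groups = obs.groupby([cell_type_key, sample_key], observed=True, sort=True).indices
    cols, counts, metas = [], [], []
    mat = np.zeros((len(groups), X.shape[1]))
    keep_rows = []
    for i, (key, idx) in enumerate(groups.items()):
        if len(idx) < min_cells:
            logger.info("dropping stratum %s with %d cells (< %d)", key, len(idx), min_cells)
            continue
        mat[i] = np.asarray(X[idx].mean(axis=0)).ravel()
        keep_rows.append(i)
        cols.append(key)
        counts.append(len(idx))
        metas.append(obs.iloc[idx[0]])
    if not cols:
        raise ValueError("no stratum passed the min_cells filter")
    columns = pd.MultiIndex.from_tuples(cols, names=["cell_type", "sample_id"])
    values = pd.DataFrame(mat[keep_rows].T, index=adata.var_names, columns=columns)
    meta = pd.DataFrame(metas)
    meta.index = columns
    return PseudobulkMatrix(
        values=values,
        n_cells=pd.Series(counts, index=columns, name="n_cells"),
        meta=meta,
    )


# ---------------------------------------------------------------------------
# empirical-Bayes moderated t
# ---------------------------------------------------------------------------


def _trigamma_inverse(y: np.ndarray) -> np.ndarray:
    """Solve trigamma(x) = y by Newton iteration (monotone, convex)."""
    y = np.asarray(y, dtype=float)
    x = np.where(y > 1e7, 1.0 / np.sqrt(y), 0.5 + 1.0 / y)
    x = np.where(y < 1e-6, 1.0 / y, x)
    for _ in range(50):
        tri = polygamma(1, x)
        dif = tri * (1.0 - tri / y) / polygamma(2, x)
        x = x + dif
        if np.all(-dif / x < 1e-8):
            break
    return x


def squeeze_var(
    s2: np.ndarray,
    df: float,
    covariate: np.ndarray | None = None,
) -> tuple[np.ndarray, float, np.ndarray]:
    """Empirical-Bayes shrinkage of sample variances toward a prior.

    Moment-matches log sample variances to a scaled-F distribution: the
    prior df ``d0`` solves trigamma(d0/2) = var(e) - trigamma(df/2) where
    e = log(s2) - digamma(df/2) + log(df/2), and the prior variance s0^2
    (a constant, or a lowess trend in ``covariate``) is recovered from the
    mean of e.  Returns (posterior variances, d0, s0^2 per gene); d0 may
    be ``inf`` (complete pooling).
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if not ok.any():
        raise ValueError("all residual variances are zero")
    z = np.log(np.where(ok, s2, np.nan))
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    if covariate is not None and ok.sum() >= 10:
        from statsmodels.nonparametric.smoothers_lowess import lowess

        cov = np.asarray(covariate, dtype=float)
        fit = lowess(e[ok], cov[ok], frac=0.5, return_sorted=False)
        e0 = np.full_like(z, np.nan)
        e0[ok] = fit
        # fill variance-less genes with the overall level
        e0[~ok] = np.nanmean(fit)
    else:
        e0 = np.full_like(z, np.nanmean(e))
    resid = e[ok] - e0[ok]
    n = int(ok.sum())
    evar = resid @ resid / max(n - 1, 1) - polygamma(1, df / 2.0)
    if evar > 0:
        d0 = float(2.0 * _trigamma_inverse(np.array([evar]))[0])
        s02 = np.exp(e0 + digamma(d0 / 2.0) - np.log(d0 / 2.0))
    else:
        d0 = np.inf
        s02 = np.exp(e0)
    if np.isinf(d0):
        s2_post = s02.copy()
    else:
        s2_post = (d0 * s02 + df * np.where(ok, s2, 0.0)) / (d0 + df)
    return s2_post, d0, s02


@dataclass
class ModeratedFit:
    """Per-gene moderated test results for the requested coefficients."""

    coef: pd.DataFrame  # genes x coefficients
    t: pd.DataFrame
    p: pd.DataFrame
    df_residual: float
    df_prior: float
    df_total: float
    s2_post: pd.Series
    avg_expr: pd.Series
    excluded: list = field(default_factory=list)  # all-constant genes


def moderated_fit(
    Y: pd.DataFrame,
    design: pd.DataFrame,
    coefs: list[str] | None = None,
    trend: bool = True,
    df_prior: float | None = None,
) -> ModeratedFit:
    """OLS fit per gene with empirical-Bayes variance moderation.

    Parameters
    ----------
    Y
        genes x samples response matrix (log scale).
    design
        samples x coefficients design matrix (full rank).
    coefs
        coefficient names to report (default: all non-intercept columns).
    trend
        let the prior variance follow average expression (limma-trend).
    df_prior
        override the estimated prior df (0 = no shrinkage, ``inf`` =
        complete pooling); mainly for validation.
    """
    genes = list(Y.index)
    Ya = Y.to_numpy(dtype=float)
    X = design.to_numpy(dtype=float)
    n, k = X.shape
    if Ya.shape[1] != n:
        raise ValueError("Y columns must match design rows")
    if np.linalg.matrix_rank(X) < k:
        raise ValueError("design matrix is rank deficient")
    df_res = n - k
    if df_res < 1:
        raise ValueError(f"no residual degrees of freedom (n={n}, k={k})")
    if df_res < 2:
        logger.warning("only %d residual df; variance estimates are unstable", df_res)

    xtx_inv = np.linalg.inv(X.T @ X)
    beta = Ya @ X @ xtx_inv  # genes x k
    resid = Ya - beta @ X.T
    s2 = (resid**2).sum(axis=1) / df_res
    avg = Ya.mean(axis=1)

    constant = (s2 == 0) & (np.ptp(Ya, axis=1) == 0)
    if constant.any():
        excluded = [g for g, c in zip(genes, constant) if c]
    else:
        excluded = []

    if df_prior is not None:
        d0 = float(df_prior)
        if d0 == 0:
            s2_post = s2.copy()
        elif np.isinf(d0):
            _, _, s02 = squeeze_var(s2, df_res, covariate=avg if trend else None)
            s2_post = s02
        else:
            _, _, s02 = squeeze_var(s2, df_res, covariate=avg if trend else None)
            s2_post = (d0 * s02 + df_res * s2) / (d0 + df_res)
    else:
        s2_post, d0, _ = squeeze_var(s2, df_res, covariate=avg if trend else None)

    df_total = df_res + d0
    if coefs is None:
        coefs = [c for c in design.columns if c.lower() not in ("intercept", "const")]
    cidx = [list(design.columns).index(c) for c in coefs]
    v = np.diag(xtx_inv)[cidx]  # unscaled coefficient variances
    coef_mat = beta[:, cidx]
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(np.outer(s2_post, v))
        tstat = coef_mat / se
    if np.isinf(df_total):
        from scipy.stats import norm

        pvals = 2.0 * norm.sf(np.abs(tstat))
    else:
        pvals = 2.0 * t_dist.sf(np.abs(tstat), df_total)
    tstat = np.where(constant[:, None], np.nan, tstat)
    pvals = np.where(constant[:, None], np.nan, pvals)

    return ModeratedFit(
        coef=pd.DataFrame(coef_mat, index=genes, columns=coefs),
        t=pd.DataFrame(tstat, index=genes, columns=coefs),
        p=pd.DataFrame(pvals, index=genes, columns=coefs),
        df_residual=float(df_res),
        df_prior=float(d0),
        df_total=float(df_total),
        s2_post=pd.Series(s2_post, index=genes, name="s2_post"),
        avg_expr=pd.Series(avg, index=genes, name="avg_expr"),
        excluded=excluded,
    )


# ---------------------------------------------------------------------------
# cell-type DE
# ---------------------------------------------------------------------------


@dataclass
class DEResult:
    """Per-(cell type, gene) differential-expression table plus counts."""

    table: pd.DataFrame  # cell_type, gene, log2fc, t, p, q, significant
    counts: pd.DataFrame  # per cell type: n_up, n_down significant
    fdr: float


def de_by_celltype(
    adata,
    biomarkers,
    group: str | None = "allergic_asthma",
    group_key: str = "group",
    condition_key: str = "condition",
    baseline: str = "baseline",
    stimulated: str = "allergen",
    cell_type_key: str = "cell_type",
    sample_key: str = "sample_id",
    fdr: float = 0.20,
    min_cells: int = 10,
    trend: bool = True,
    scale_factor: float | None = None,
) -> DEResult:
    """Allergen vs baseline differential expression per cell type.

    Cells of ``group`` are normalized, averaged per (cell type, sample),
    and per cell type a moderated fit of the condition contrast is run on
    all genes; results are then restricted to ``biomarkers`` and BH-FDR
    adjusted within each cell type.  Cell types present in only one
    condition are skipped with a log message.
    """
    obs = adata.obs
    if group is not None:
        adata = adata[np.asarray(obs[group_key] == group)].copy()
    norm = normalize_cells(adata, scale_factor=scale_factor)
    pb = pseudobulk_mean(norm, cell_type_key=cell_type_key, sample_key=sample_key,
                         min_cells=min_cells)
    cond_by_stratum = pb.meta[condition_key]

    biomarkers = [g for g in biomarkers if g in pb.values.index]
    rows = []
    for ct in pb.values.columns.get_level_values("cell_type").unique():
        sub = pb.values[ct]
        conds = cond_by_stratum.loc[ct]
        present = set(conds)
        if not {baseline, stimulated} <= present:
            logger.warning("cell type %r present in only one condition; skipped", ct)
            continue
        if len(conds) < 3:
            logger.warning("cell type %r has %d strata; no residual df, skipped", ct, len(conds))
            continue
        design = pd.DataFrame(
            {
                "intercept": 1.0,
                "condition": (conds == stimulated).astype(float).to_numpy(),
            },
            index=sub.columns,
        )
        fit = moderated_fit(sub, design, coefs=["condition"], trend=trend)
        res = pd.DataFrame(
            {
                "log2fc": fit.coef["condition"],
                "t": fit.t["condition"],
                "p": fit.p["condition"],
            }
        ).loc[biomarkers]
        res = res.dropna(subset=["p"])
        if res.empty:
            continue
        res["q"] = multipletests(res["p"], method="fdr_bh")[1]
        res["significant"] = res["q"] < fdr
        res.insert(0, "cell_type", ct)
        res.insert(1, "gene", res.index)
        rows.append(res.reset_index(drop=True))
    if not rows:
        raise ValueError("no cell type had both conditions with enough strata")
    table = pd.concat(rows, ignore_index=True)
    counts = (
        table[table["significant"]]
        .assign(direction=lambda d: np.where(d["log2fc"] > 0, "n_up", "n_down"))
        .pivot_table(index="cell_type", columns="direction", values="gene",
                     aggfunc="count", fill_value=0)
        .reindex(columns=["n_up", "n_down"], fill_value=0)
    )
    return DEResult(table=table, counts=counts, fdr=fdr)


def significant_sets(de: DEResult) -> tuple[dict, dict]:
    """Up/down significant biomarker sets per cell type (for connectivity)."""
    up, down = {}, {}
    sig = de.table[de.table["significant"]]
    for ct, sub in sig.groupby("cell_type", observed=True):
        up_genes = sub.loc[sub["log2fc"] > 0, "gene"].tolist()
        down_genes = sub.loc[sub["log2fc"] < 0, "gene"].tolist()
        if up_genes:
            up[ct] = up_genes
        if down_genes:
            down[ct] = down_genes
    return up, down
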