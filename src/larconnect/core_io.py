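"""Data model, readers/writers, and per-platform bulk preprocessing.

The common currency of the bulk stages is :class:`ExpressionMatrix`, a
genes x samples table tagged with the kind of values it holds (raw
``counts`` or ``log_intensity``).  Gene- and sample-level metadata travel
as plain :class:`pandas.DataFrame` objects with documented columns
(``GENE_TABLE_COLUMNS`` / ``SAMPLE_TABLE_COLUMNS``), validated by
:func:`validate_gene_table` / :func:`validate_sample_table`.  Single-cell
data use :class:`anndata.AnnData` (cells x genes, sparse counts).

Preprocessing operations implement the per-platform rules used for the
public asthma cohorts: probe-to-symbol averaging, transcript-count
summation, log2 with negative/missing replacement, log-CPM library-size
normalization, NanoString-style low-abundance filtering against negative
controls, empirical-Bayes (ComBat) batch correction, and sex imputation
from Y-chromosome expression.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__

logger = logging.getLogger(__name__)

VALUE_KINDS = ("counts", "log_intensity")

GENE_TABLE_COLUMNS = ("symbol", "chromosome", "is_housekeeping", "is_negative_control")
SAMPLE_TABLE_COLUMNS = ("group", "sex", "batch")

SEX_LABELS = ("male", "female", "unknown")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with a value-kind tag.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with sample ids as columns.
    value_kind
        ``"counts"`` (non-negative, linear scale) or ``"log_intensity"``.
    """

    values: pd.DataFrame
    value_kind: str = "log_intensity"

    def __post_init__(self) -> None:
        if self.value_kind not in VALUE_KINDS:
            raise ValueError(f"value_kind must be one of {VALUE_KINDS}, got {self.value_kind!r}")
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        if self.values.columns.duplicated().any():
            dups = self.values.columns[self.values.columns.duplicated()].tolist()
            raise ValueError(f"duplicated sample ids: {dups}")
        if self.value_kind == "counts":
            arr = self.values.to_numpy(dtype=float)
            if np.nanmin(arr, initial=0.0) < 0:
                raise ValueError("counts matrix contains negative values")

    @property
    def gene_ids(self) -> list:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_genes(self, genes: Sequence) -> "ExpressionMatrix":
        genes = [g for g in genes if g in self.values.index]
        return ExpressionMatrix(self.values.loc[genes], self.value_kind)

    def subset_samples(self, samples: Sequence) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values[list(samples)], self.value_kind)


@dataclass
class GeneSetLibrary:
    """Named collection of gene sets (GMT-style)."""

    name: str
    sets: dict[str, list[str]]

    def __post_init__(self) -> None:
        for set_name, genes in self.sets.items():
            if len(genes) == 0:
                raise ValueError(f"gene set {set_name!r} is empty")
            if not all(isinstance(g, str) for g in genes):
                raise ValueError(f"gene set {set_name!r} contains non-string symbols")


def validate_gene_table(gene_table: pd.DataFrame) -> pd.DataFrame:
    """Check gene-annotation invariants; returns the table unchanged."""
    missing = [c for c in GENE_TABLE_COLUMNS if c not in gene_table.columns]
    if missing:
        raise ValueError(f"gene table missing columns: {missing}")
    if (gene_table["symbol"].astype(str).str.strip() == "").any():
        raise ValueError("gene table contains empty symbols")
    both = gene_table["is_housekeeping"].astype(bool) & gene_table["is_negative_control"].astype(bool)
    if both.any():
        raise ValueError(
            "genes flagged both housekeeping and negative control: "
            f"{gene_table.index[both].tolist()}"
        )
    return gene_table


def validate_sample_table(sample_table: pd.DataFrame, vocabulary: Iterable[str] | None = None) -> pd.DataFrame:
    """Check sample-annotation invariants; returns the table unchanged."""
    missing = [c for c in SAMPLE_TABLE_COLUMNS if c not in sample_table.columns]
    if missing:
        raise ValueError(f"sample table missing columns: {missing}")
    if sample_table.index.duplicated().any():
        raise ValueError("duplicated sample ids in sample table")
    bad_sex = set(sample_table["sex"]) - set(SEX_LABELS)
    if bad_sex:
        raise ValueError(f"unknown sex labels: {sorted(bad_sex)}")
    if vocabulary is not None:
        bad = set(sample_table["group"]) - set(vocabulary)
        if bad:
            raise ValueError(f"group labels outside declared vocabulary: {sorted(bad)}")
    return sample_table


# ---------------------------------------------------------------------------
# delimited matrix I/O
# ---------------------------------------------------------------------------


def read_matrix_delim(
    path,
    orientation: str = "genes_by_samples",
    value_kind: str = "log_intensity",
    sep: str = "\t",
) -> ExpressionMatrix:
    """Read a delimited matrix with a header row of ids and a leading id column.

    Leading ``#`` comment lines (as written by :func:`write_matrix_delim`)
    are skipped.  ``orientation`` declares how the file is laid out
    (``genes_by_samples`` or ``samples_by_genes``); the result is always
    genes x samples, preserving input order.
    """
    if orientation not in ("genes_by_samples", "samples_by_genes"):
        raise ValueError(f"unknown orientation {orientation!r}")
    rows: list[list[str]] = []
    header: list[str] | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or (header is None and line.startswith("#")):
                continue
            fields = line.split(sep)
            if header is None:
                header = fields
                continue
            if len(fields) != len(header):
                raise ValueError(
                    f"{path}: line {lineno} has {len(fields)} fields, expected {len(header)}"
                )
            rows.append(fields)
    if header is None or not rows:
        raise ValueError(f"{path}: no data rows")
    col_ids = [c.strip() for c in header[1:]]
    row_ids = [r[0].strip() for r in rows]
    data = np.array([[_parse_value(v) for v in r[1:]] for r in rows], dtype=float)
    df = pd.DataFrame(data, index=row_ids, columns=col_ids)
    if orientation == "samples_by_genes":
        df = df.T
    return ExpressionMatrix(df, value_kind=value_kind)


def _parse_value(tok: str) -> float:
    tok = tok.strip()
    if tok in ("", "NA", "NaN", "nan"):
        return np.nan
    return float(tok)


def write_matrix_delim(matrix: ExpressionMatrix, path, sep: str = "\t", seed: int | None = None) -> None:
    """Write a genes x samples matrix with a version/seed comment header."""
    with open(path, "w") as fh:
        fh.write(f"# larconnect {__version__} value_kind={matrix.value_kind} seed={seed}\n")
        fh.write("gene_id" + sep + sep.join(map(str, matrix.sample_ids)) + "\n")
        for gene, row in matrix.values.iterrows():
            vals = sep.join("NA" if np.isnan(v) else format(v, ".10g") for v in row.to_numpy())
            fh.write(f"{gene}{sep}{vals}\n")


# ---------------------------------------------------------------------------
# single-cell triplet I/O
# ---------------------------------------------------------------------------


def read_mtx_triplet(
    matrix_path,
    features_path,
    barcodes_path,
    annotations_path=None,
    orientation: str = "features_by_barcodes",
    drop_unannotated: bool = False,
):
    """Read a MatrixMarket triplet plus feature/barcode lists into AnnData.

    The annotation table (TSV, first column = barcode) provides per-cell
    metadata.  Barcodes absent from it raise, or are dropped with a
    warning when ``drop_unannotated`` is set.
    """
    import anndata as ad
    from scipy import io as spio
    from scipy import sparse

    mat = sparse.csr_matrix(spio.mmread(str(matrix_path)))
    features = _read_id_list(features_path)
    barcodes = _read_id_list(barcodes_path)
    if orientation == "features_by_barcodes":
        mat = mat.T.tocsr()
    elif orientation != "barcodes_by_features":
        raise ValueError(f"unknown orientation {orientation!r}")
    n_cells, n_genes = mat.shape
    if n_genes != len(features):
        raise ValueError(f"matrix has {n_genes} features but features file lists {len(features)}")
    if n_cells != len(barcodes):
        raise ValueError(f"matrix has {n_cells} barcodes but barcodes file lists {len(barcodes)}")
    obs = pd.DataFrame(index=pd.Index(barcodes, name="barcode"))
    if annotations_path is not None:
        ann = pd.read_csv(annotations_path, sep="\t", index_col=0)
        ann.index = ann.index.astype(str)
        missing = [b for b in barcodes if b not in ann.index]
        if missing:
            if not drop_unannotated:
                raise ValueError(f"annotation key missing for barcodes: {missing}")
            logger.warning("dropping %d unannotated barcodes: %s", len(missing), missing)
            keep = [i for i, b in enumerate(barcodes) if b not in set(missing)]
            mat = mat[keep]
            barcodes = [barcodes[i] for i in keep]
        obs = ann.loc[barcodes].copy()
        obs.index.name = "barcode"
    adata = ad.AnnData(X=mat, obs=obs, var=pd.DataFrame(index=pd.Index(features, name="gene")))
    return adata


def _read_id_list(path) -> list[str]:
    with open(path) as fh:
        return [line.rstrip("\n").split("\t")[0].strip() for line in fh if line.strip()]


# ---------------------------------------------------------------------------
# GMT I/O
# ---------------------------------------------------------------------------


def read_gmt(path, name: str | None = None) -> GeneSetLibrary:
    """Read a GMT file (set name, description, tab-separated symbols)."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                continue
            sets[fields[0]] = [g.strip() for g in fields[2:] if g.strip()]
    return GeneSetLibrary(name or str(path), sets)


def write_gmt(library: GeneSetLibrary, path) -> None:
    with open(path, "w") as fh:
        for set_name, genes in library.sets.items():
            fh.write(set_name + "\t" + library.name + "\t" + "\t".join(genes) + "\n")


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------


def _probe_map(gene_table: pd.DataFrame | Mapping[str, str], probes: Sequence) -> pd.Series:
    """Resolve a probe -> symbol mapping from a gene table or plain mapping."""
    if isinstance(gene_table, pd.DataFrame):
        mapping = gene_table["symbol"].astype(str).str.strip()
    else:
        mapping = pd.Series({k: str(v).strip() for k, v in gene_table.items()})
    missing = [p for p in probes if p not in mapping.index]
    if missing:
        raise KeyError(f"probes absent from gene map: {missing}")
    return mapping


def collapse_probes_mean(matrix: ExpressionMatrix, gene_table) -> ExpressionMatrix:
    """Average probes mapping to the same gene symbol, within each sample.

    Output rows are symbols in order of first appearance.
    """
    mapping = _probe_map(gene_table, matrix.gene_ids)
    symbols = mapping.loc[matrix.gene_ids].to_numpy()
    order = pd.unique(symbols)
    grouped = matrix.values.groupby(symbols, sort=False).mean()
    return ExpressionMatrix(grouped.loc[order], matrix.value_kind)


def sum_transcripts(matrix: ExpressionMatrix, gene_table) -> ExpressionMatrix:
    """Sum transcript counts mapping to the same gene symbol.

    Only valid for counts; summing log-scale values is meaningless.
    """
    if matrix.value_kind != "counts":
        raise ValueError("sum_transcripts requires a counts matrix (summing logs is invalid)")
    mapping = _probe_map(gene_table, matrix.gene_ids)
    symbols = mapping.loc[matrix.gene_ids].to_numpy()
    order = pd.unique(symbols)
    grouped = matrix.values.groupby(symbols, sort=False).sum()
    return ExpressionMatrix(grouped.loc[order], "counts")


def log2_clip(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """log2-transform, then replace negative results and missing values with 0."""
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.log2(matrix.values.to_numpy(dtype=float))
    out = np.where(np.isnan(out) | (out < 0), 0.0, out)
    return ExpressionMatrix(
        pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns),
        "log_intensity",
    )


def log_cpm(matrix: ExpressionMatrix, prior_count: float = 0.5) -> ExpressionMatrix:
    """Per-sample log2 counts-per-million with an additive prior.

    value = log2((count + prior) / (libsize + 2*prior) * 1e6).  With the
    default prior 0.5 the denominator is libsize + 1; with prior 0 the
    transform is exactly invariant to per-sample count scaling.
    """
    if matrix.value_kind != "counts":
        raise ValueError("log_cpm requires a counts matrix")
    counts = matrix.values.to_numpy(dtype=float)
    lib = counts.sum(axis=0)
    zero = lib <= 0
    if zero.any():
        bad = [matrix.sample_ids[i] for i in np.flatnonzero(zero)]
        raise ValueError(f"samples with zero total counts: {bad}")
    vals = np.log2((counts + prior_count) / (lib + 2.0 * prior_count) * 1e6)
    return ExpressionMatrix(
        pd.DataFrame(vals, index=matrix.values.index, columns=matrix.values.columns),
        "log_intensity",
    )


def filter_low_abundance(matrix: ExpressionMatrix, gene_table: pd.DataFrame, k_sd: float = 2.0) -> list:
    """NanoString-style filter: drop housekeeping genes and low-abundance genes.

    A gene is low-abundance if its mean count is <= mean + ``k_sd`` * SD of
    the pooled negative-control counts.  Negative-control probes themselves
    are never retained.  ``k_sd = -inf`` disables the threshold.  Returns
    retained gene ids in input order.
    """
    validate_gene_table(gene_table)
    gt = gene_table.loc[matrix.gene_ids]
    hk = gt["is_housekeeping"].astype(bool)
    neg = gt["is_negative_control"].astype(bool)
    threshold = -np.inf
    if np.isfinite(k_sd):
        if not neg.any():
            raise ValueError("no negative-control genes present; threshold requires them")
        ctrl = matrix.values.loc[neg[neg].index].to_numpy(dtype=float).ravel()
        threshold = float(ctrl.mean() + k_sd * ctrl.std(ddof=1))
    gene_means = matrix.values.mean(axis=1)
    retained = [
        g
        for g in matrix.gene_ids
        if not hk[g] and not neg[g] and gene_means[g] > threshold
    ]
    return retained


def combat_adjust(
    matrix: ExpressionMatrix,
    batches: Sequence | pd.Series,
    covariate_groups: Sequence | pd.Series | None = None,
) -> ExpressionMatrix:
    """Parametric empirical-Bayes (ComBat) batch correction.

    Location/scale batch effects are shrunk toward normal / inverse-gamma
    priors fit by method of moments; biological group labels, when given,
    are protected in the standardization design.  Genes with zero pooled
    variance are passed through unchanged with a warning.
    """
    import anndata as ad

    batches = pd.Series(np.asarray(batches), index=matrix.sample_ids).astype(str)
    counts = batches.value_counts()
    if len(counts) < 2:
        raise ValueError("combat_adjust requires at least 2 batches")
    singletons = counts[counts < 2]
    if len(singletons):
        raise ValueError(f"batches with a single sample: {singletons.index.tolist()}")
    vals = matrix.values.to_numpy(dtype=float)
    pooled_var = vals.var(axis=1)
    within = np.ones(len(matrix.gene_ids), dtype=bool)
    for b in counts.index:
        sub = vals[:, (batches == b).to_numpy()]
        within &= sub.var(axis=1) > 0
    usable = (pooled_var > 0) & within
    if not usable.all():
        warnings.warn(
            f"{int((~usable).sum())} genes constant within a batch or overall; "
            "passed through unadjusted",
            UserWarning,
        )
    obs = pd.DataFrame({"batch": batches.to_numpy()}, index=[str(s) for s in matrix.sample_ids])
    covariates = None
    if covariate_groups is not None:
        groups = pd.Series(np.asarray(covariate_groups), index=matrix.sample_ids).astype(str)
        if groups.nunique() > 1:
            # drop-first numeric dummies: categorical covariates would make
            # the batch + covariate one-hot design singular
            dummies = pd.get_dummies(groups, prefix="group", drop_first=True).astype(float)
            for col in dummies.columns:
                obs[col] = dummies[col].to_numpy()
            covariates = list(dummies.columns)
    adata = ad.AnnData(X=vals[usable].T.copy(), obs=obs)
    import scanpy as sc

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sc.pp.combat(adata, key="batch", covariates=covariates)
    out = vals.copy()
    out[usable] = adata.X.T
    return ExpressionMatrix(
        pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns),
        matrix.value_kind,
    )


@dataclass
class SexImputation:
    """Per-sample imputed sex labels plus a clustering diagnostic."""

    labels: pd.Series
    separation: float
    cluster_means: dict = field(default_factory=dict)


def impute_sex(matrix: ExpressionMatrix, gene_table: pd.DataFrame, seed: int = 0) -> SexImputation:
    """Impute sex from Y-chromosome expression.

    PCA on the (centered) Y-gene submatrix, k-means (k=2, 10 restarts) on
    PC1-PC2; the cluster with higher mean Y expression is labelled male.
    """
    from sklearn.cluster import KMeans
    from sklearn.decomposition import PCA

    y_genes = gene_table.index[gene_table["chromosome"].astype(str) == "Y"]
    y_genes = [g for g in y_genes if g in matrix.values.index]
    if len(y_genes) < 2:
        raise ValueError(f"need >=2 Y-chromosome genes, found {len(y_genes)}")
    if matrix.shape[1] < 4:
        raise ValueError("need >=4 samples for sex imputation")
    X = matrix.values.loc[y_genes].to_numpy(dtype=float).T  # samples x Y genes
    Xc = X - X.mean(axis=0)
    if np.allclose(Xc, 0):
        raise ValueError("degenerate clustering: Y-gene expression is constant across samples")
    ncomp = min(2, Xc.shape[1])
    pcs = PCA(n_components=ncomp, random_state=seed).fit_transform(Xc)
    km = KMeans(n_clusters=2, n_init=10, random_state=seed).fit(pcs)
    assign = km.labels_
    if len(np.unique(assign)) < 2:
        raise ValueError("degenerate clustering: one empty cluster")
    y_mean = X.mean(axis=1)
    cluster_means = {int(c): float(y_mean[assign == c].mean()) for c in (0, 1)}
    male_cluster = max(cluster_means, key=cluster_means.get)
    labels = pd.Series(
        np.where(assign == male_cluster, "male", "female"),
        index=matrix.values.columns,
        name="sex",
    )
    centroid_dist = float(np.linalg.norm(km.cluster_centers_[0] - km.cluster_centers_[1]))
    within = np.sqrt(
        np.mean([np.sum((pcs[assign == c] - km.cluster_centers_[c]) ** 2, axis=1).mean() for c in (0, 1)])
    )
    separation = centroid_dist / within if within > 0 else np.inf
    return SexImputation(labels=labels, separation=float(separation), cluster_means=cluster_means)
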