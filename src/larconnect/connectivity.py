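"""Drug-signature matching via enrichment-based connectivity scores.

Per cell type, every compound in a perturbation screen is contrasted with
the vehicle (DMSO) in a single moderated linear model on pseudobulk
logcounts; genes are ranked per (compound, cell type) by
s = log2FC x (-log10 p).  The up- and down-regulated disease biomarker
sets are walked along each ranked list with a weighted Kolmogorov-Smirnov
running sum (GSEA-style, alpha = 1): the enrichment score ES is the
signed maximum deviation.  The connectivity score CS = ES_up - ES_down;
a negative CS means the compound moves the biomarkers opposite to the
disease signature (a candidate "reverser").  Because the raw KS ES is
bounded in [-1, 1], scores can optionally be permutation-normalized (NES)
to put magnitudes on a comparable scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .pseudobulk import moderated_fit, normalize_cells, pseudobulk_mean

logger = logging.getLogger(__name__)

DEFAULT_CELLTYPE_MAP = {
    "CD4 T": "CD4 T",
    "CD8 T": "CD8 T",
    "B": "B",
    "NK": "NK",
    "MNP": "Myeloid",
}


def ranking_score(log2fc, p):
    """s = log2FC x (-log10 p); zero fold-change or p = 1 gives s = 0."""
    log2fc = np.asarray(log2fc, dtype=float)
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return log2fc * (-np.log10(p))


@dataclass
class DrugSignatures:
    """Long table of per-(cell type, compound, gene) contrast statistics."""

    table: pd.DataFrame  # cell_type, compound, gene, log2fc, p, s
    cell_types: list
    compounds: list
    vehicle: str

    def ranked(self, compound: str, cell_type: str) -> pd.Series:
        """Ranking scores for one signature, indexed by gene."""
        sub = self.table[
            (self.table["compound"] == compound) & (self.table["cell_type"] == cell_type)
        ]
        if sub.empty:
            raise KeyError(f"no signature for {compound!r} in {cell_type!r}")
        return sub.set_index("gene")["s"]


def build_drug_signatures(
    adata,
    vehicle: str = "DMSO",
    compound_key: str = "compound",
    cell_type_key: str = "cell_type",
    donor_key: str = "donor",
    min_cells: int = 10,
    trend: bool = True,
    block_donor: bool = False,
    scale_factor: float | None = None,
) -> DrugSignatures:
    """Fit per-cell-type compound-vs-vehicle contrasts on pseudobulk means.

    One linear model per cell type with an indicator per compound (vehicle
    as reference; optional donor blocking), moderated p-values, and the
    ranking score s per gene.  Compounds absent from a cell type are
    simply missing from that cell type's signatures.
    """
    obs = adata.obs
    if vehicle not in set(obs[compound_key]):
        raise ValueError(f"vehicle {vehicle!r} absent from the screen")
    # pseudobulk per (cell type, compound x donor)
    sample = obs[compound_key].astype(str) + "|" + obs[donor_key].astype(str)
    adata = adata.copy()
    adata.obs = obs.copy()
    adata.obs["_pb_sample"] = sample.to_numpy()
    norm = normalize_cells(adata, scale_factor=scale_factor)
    pb = pseudobulk_mean(norm, cell_type_key=cell_type_key, sample_key="_pb_sample",
                         min_cells=min_cells)

    rows = []
    cell_types = list(pb.values.columns.get_level_values("cell_type").unique())
    for ct in cell_types:
        sub = pb.values[ct]
        meta = pb.meta.loc[ct]
        compounds_here = pd.unique(meta[compound_key].astype(str))
        if vehicle not in compounds_here:
            raise ValueError(f"vehicle {vehicle!r} missing in cell type {ct!r}")
        if (meta[compound_key].astype(str) == vehicle).sum() < 2:
            raise ValueError(f"need >=2 vehicle pseudobulk replicates in {ct!r}")
        others = [c for c in compounds_here if c != vehicle]
        design = pd.DataFrame({"intercept": np.ones(len(meta))}, index=sub.columns)
        for c in others:
            design[c] = (meta[compound_key].astype(str) == c).astype(float).to_numpy()
        if block_donor:
            donors = pd.unique(meta[donor_key].astype(str))
            for d in donors[1:]:
                design[f"_donor_{d}"] = (meta[donor_key].astype(str) == d).astype(float).to_numpy()
        fit = moderated_fit(sub, design, coefs=others, trend=trend)
        for c in others:
            lfc = fit.coef[c]
            p = fit.p[c].clip(lower=np.finfo(float).tiny, upper=1.0)
            s = ranking_score(lfc.to_numpy(), p.to_numpy())
            rows.append(
                pd.DataFrame(
                    {
                        "cell_type": ct,
                        "compound": c,
                        "gene": lfc.index,
                        "log2fc": lfc.to_numpy(),
                        "p": p.to_numpy(),
                        "s": s,
                    }
                )
            )
    table = pd.concat(rows, ignore_index=True)
    compounds = sorted(table["compound"].unique())
    return DrugSignatures(table=table, cell_types=cell_types, compounds=compounds,
                          vehicle=vehicle)


# ---------------------------------------------------------------------------
# enrichment / connectivity scores
# ---------------------------------------------------------------------------


def _rank_order(scores: pd.Series) -> pd.Series:
    """Sort descending by score; ties broken by stable gene-id order."""
    if scores.index.duplicated().any():
        dupes = scores.index[scores.index.duplicated()].tolist()
        raise ValueError(f"duplicate genes in ranked list: {dupes[:10]}")
    order = np.lexsort((np.asarray(scores.index.astype(str)), -scores.to_numpy()))
    return scores.iloc[order]


def enrichment_score(ranked_scores: pd.Series, gene_set, alpha: float = 1.0) -> float:
    """Weighted KS running-sum enrichment score of ``gene_set`` in a ranked list.

    Hits increment the running sum by |s|^alpha normalized over the set's
    scores; misses decrement by 1/(N - m).  ES is the running-sum value of
    largest magnitude.  Returns NaN when the set does not intersect the
    list.
    """
    ranked = _rank_order(ranked_scores)
    genes = ranked.index
    hit = np.asarray(genes.isin(set(gene_set)))
    m = int(hit.sum())
    N = len(genes)
    if m == 0:
        return float("nan")
    if m == N:
        return 1.0
    weights = np.abs(ranked.to_numpy()) ** alpha
    hit_w = np.where(hit, weights, 0.0)
    total = hit_w.sum()
    if total > 0:
        inc = hit_w / total
    else:  # all set scores zero: uniform hit weights
        inc = np.where(hit, 1.0 / m, 0.0)
    dec = np.where(hit, 0.0, 1.0 / (N - m))
    running = np.cumsum(inc - dec)
    i = int(np.argmax(np.abs(running)))
    return float(running[i])


def normalized_es(
    ranked_scores: pd.Series,
    gene_set,
    n_perm: int = 1000,
    seed: int = 0,
    alpha: float = 1.0,
) -> float:
    """ES divided by the mean |ES| of same-sign random same-size sets.

    Permutations draw gene sets uniformly from the ranked list's genes;
    the null is computed vectorized over permutations.  Returns NaN when
    no permutation matches the observed sign.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    es = enrichment_score(ranked_scores, gene_set, alpha=alpha)
    if np.isnan(es) or es == 0.0:
        return es
    ranked = _rank_order(ranked_scores)
    m = int(ranked.index.isin(set(gene_set)).sum())
    es_null = _es_null(ranked.to_numpy(), m, n_perm, seed, alpha)
    same_sign = es_null[np.sign(es_null) == np.sign(es)]
    if same_sign.size == 0:
        return float("nan")
    return float(es / np.abs(same_sign).mean())


def _es_null(sorted_scores: np.ndarray, m: int, n_perm: int, seed: int, alpha: float) -> np.ndarray:
    """Vectorized null ES for random m-gene sets on a fixed sorted score list."""
    rng = np.random.default_rng(seed)
    N = sorted_scores.size
    weights = np.abs(sorted_scores) ** alpha
    # random positions without replacement, per permutation
    pos = np.argsort(rng.random((n_perm, N)), axis=1)[:, :m]
    hit_w = np.zeros((n_perm, N))
    np.put_along_axis(hit_w, pos, weights[pos], axis=1)
    totals = hit_w.sum(axis=1, keepdims=True)
    uniform = totals.ravel() == 0
    inc = np.divide(hit_w, totals, out=np.zeros_like(hit_w), where=totals > 0)
    if uniform.any():
        mask = np.zeros((n_perm, N), dtype=bool)
        np.put_along_axis(mask, pos, True, axis=1)
        inc[uniform] = mask[uniform] / m
    ism = np.zeros((n_perm, N), dtype=bool)
    np.put_along_axis(ism, pos, True, axis=1)
    dec = np.where(ism, 0.0, 1.0 / (N - m))
    running = np.cumsum(inc - dec, axis=1)
    idx = np.argmax(np.abs(running), axis=1)
    return running[np.arange(n_perm), idx]


def connectivity_score(es_up: float, es_down: float) -> float:
    """CS = ES_up - ES_down (NaN-propagating)."""
    return float(es_up) - float(es_down)


@dataclass
class ConnectivityResult:
    """Compound x cell-type connectivity table with reverser/mimic flags."""

    table: pd.DataFrame  # compound, cell_type, es_up, es_down, cs
    report: pd.DataFrame  # rows with |cs| > threshold
    reversers: list
    mimics: list
    mode: str
    threshold: float

    def mean_cs(self) -> pd.Series:
        """Mean CS per compound (ascending: most negative = top reverser)."""
        return self.table.groupby("compound")["cs"].mean().sort_values()


def score_all(
    signatures: DrugSignatures,
    up_sets: Mapping[str, Sequence],
    down_sets: Mapping[str, Sequence],
    celltype_map: Mapping[str, str] | None = None,
    report_threshold: float = 3.0,
    mode: str = "nes",
    n_perm: int = 1000,
    seed: int = 0,
    alpha: float = 1.0,
    exclude: Sequence[str] = (),
) -> ConnectivityResult:
    """Score every (compound, cell type) signature against the disease sets.

    ``up_sets`` / ``down_sets`` are keyed by biopsy cell type; the map
    translates those to the perturbation screen's cell types (several
    biopsy types mapping to one screen type have their sets unioned).
    ``mode`` is ``"nes"`` (permutation-normalized, default; the report
    threshold of 3 is meant for this scale) or ``"raw"``.  Compounds in
    ``exclude`` (e.g., positive controls) are scored but not eligible as
    reversers/mimics.
    """
    if mode not in ("nes", "raw"):
        raise ValueError(f"unknown mode {mode!r}")
    if celltype_map is None:
        celltype_map = DEFAULT_CELLTYPE_MAP
    mapped_up: dict[str, set] = {}
    mapped_down: dict[str, set] = {}
    for biopsy_ct in set(up_sets) | set(down_sets):
        if biopsy_ct not in celltype_map:
            raise ValueError(f"biopsy cell type {biopsy_ct!r} not in the cell-type map")
        target = celltype_map[biopsy_ct]
        mapped_up.setdefault(target, set()).update(up_sets.get(biopsy_ct, ()))
        mapped_down.setdefault(target, set()).update(down_sets.get(biopsy_ct, ()))

    rows = []
    for ct in signatures.cell_types:
        if ct not in mapped_up and ct not in mapped_down:
            continue
        up = mapped_up.get(ct, set())
        down = mapped_down.get(ct, set())
        sub = signatures.table[signatures.table["cell_type"] == ct]
        for i, (compound, grp) in enumerate(sub.groupby("compound", sort=True)):
            ranked = grp.set_index("gene")["s"]
            if mode == "nes":
                es_up = normalized_es(ranked, up, n_perm=n_perm, seed=seed + i, alpha=alpha) if up else np.nan
                es_down = normalized_es(ranked, down, n_perm=n_perm, seed=seed + i + 1, alpha=alpha) if down else np.nan
            else:
                es_up = enrichment_score(ranked, up, alpha=alpha) if up else np.nan
                es_down = enrichment_score(ranked, down, alpha=alpha) if down else np.nan
            cs = connectivity_score(es_up, es_down) if up and down else np.nan
            rows.append(
                {"compound": compound, "cell_type": ct, "es_up": es_up,
                 "es_down": es_down, "cs": cs}
            )
    table = pd.DataFrame(rows)
    if table.empty:
        raise ValueError("no scoreable (compound, cell type) combinations")
    report = table[table["cs"].abs() > report_threshold].reset_index(drop=True)

    reversers, mimics = [], []
    for compound, grp in table.groupby("compound", sort=True):
        if compound in set(exclude):
            continue
        cs = grp["cs"].dropna()
        if cs.empty:
            continue
        if (cs < 0).all():
            reversers.append(compound)
        elif (cs > 0).all():
            mimics.append(compound)
    return ConnectivityResult(
        table=table, report=report, reversers=reversers, mimics=mimics,
        mode=mode, threshold=report_threshold,
    )
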