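"""Over-representation analysis of a gene list against GMT libraries.

A generic Fisher-exact ORA: for each set, the one-sided (enrichment)
p-value of the 2x2 overlap table between the query list and the set,
both intersected with a user-supplied universe, with Benjamini-Hochberg
adjustment across the library (significant at q < 0.01 by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from .core_io import GeneSetLibrary

logger = logging.getLogger(__name__)


@dataclass
class ORAResult:
    table: pd.DataFrame  # set, overlap, set_size, odds_ratio, p, q, genes
    gene_list: list
    universe_size: int
    q_threshold: float

    @property
    def significant(self) -> pd.DataFrame:
        return self.table[self.table["q"] < self.q_threshold]


def ora(
    gene_list,
    universe,
    library: GeneSetLibrary,
    q_threshold: float = 0.01,
) -> ORAResult:
    """One-sided Fisher exact over-representation of ``gene_list`` in each set.

    ``gene_list`` must be a subset of ``universe``; sets are intersected
    with the universe first, and sets left empty are skipped with a log
    message.
    """
    universe = list(dict.fromkeys(universe))
    uset = set(universe)
    gene_list = list(dict.fromkeys(gene_list))
    outside = [g for g in gene_list if g not in uset]
    if outside:
        raise ValueError(f"gene list members outside the universe: {outside[:10]}")
    lset = set(gene_list)
    n_universe = len(universe)
    n_list = len(lset)

    rows = []
    for set_name, genes in library.sets.items():
        sgenes = [g for g in dict.fromkeys(genes) if g in uset]
        if not sgenes:
            logger.info("set %r has no universe overlap; skipped", set_name)
            continue
        sset = set(sgenes)
        overlap_genes = sorted(lset & sset)
        a = len(overlap_genes)
        b = n_list - a
        c = len(sset) - a
        d = n_universe - n_list - c
        odds, p = fisher_exact([[a, b], [c, d]], alternative="greater")
        rows.append(
            {
                "set": set_name,
                "overlap": a,
                "set_size": len(sset),
                "odds_ratio": odds,
                "p": p,
                "genes": ",".join(overlap_genes),
            }
        )
    if not rows:
        raise ValueError("no library set overlaps the universe")
    table = pd.DataFrame(rows)
    table["q"] = multipletests(table["p"], method="fdr_bh")[1]
    table = table[["set", "overlap", "set_size", "odds_ratio", "p", "q", "genes"]]
    table = table.sort_values("p", kind="mergesort").reset_index(drop=True)
    return ORAResult(table=table, gene_list=gene_list, universe_size=n_universe,
                     q_threshold=q_threshold)


def frequent_genes(result: ORAResult, top_k: int | None = None) -> pd.DataFrame:
    """Count each list gene's occurrences across significant sets.

    Returns a descending-frequency table with stable tie order (list
    order); empty when nothing is significant.
    """
    sig = result.significant
    counts = {g: 0 for g in result.gene_list}
    for genes in sig["genes"]:
        for g in genes.split(","):
            if g in counts:
                counts[g] += 1
    table = pd.DataFrame(
        {"gene": list(counts), "n_sets": list(counts.values())}
    )
    table = table[table["n_sets"] > 0]
    table = table.sort_values("n_sets", ascending=False, kind="mergesort").reset_index(drop=True)
    if top_k is not None:
        table = table.head(top_k)
    return table
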