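"""Shared fixtures and independent brute-force oracles.

The oracle functions here deliberately re-derive quantities by direct
enumeration (all-pairs AUC, running-sum enrichment, step-up BH,
hypergeometric tails) so that tests compare the package's vectorized
implementations against a second, independent route.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from larconnect import simulate as sim


# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------


def mann_whitney_auc(scores, labels) -> float:
    """All-pairs AUC: P(score_pos > score_neg) + 0.5 P(tie)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    pos, neg = scores[labels], scores[~labels]
    wins = ties = 0
    for a in pos:
        for b in neg:
            if a > b:
                wins += 1
            elif a == b:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def bh_enumeration(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values by direct enumeration."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, p[i] * m / rank_from_top)
        q[i] = val
        prev = val
    return q


def es_bruteforce(scores: pd.Series, gene_set, alpha: float = 1.0) -> float:
    """O(N*m) running-sum enrichment score with explicit ordering."""
    items = sorted(scores.items(), key=lambda kv: (-kv[1], str(kv[0])))
    members = set(gene_set)
    hits = [(g in members) for g, _ in items]
    m = sum(hits)
    if m == 0:
        return float("nan")
    N = len(items)
    if m == N:
        return 1.0
    denom = sum(abs(s) ** alpha for (g, s), h in zip(items, hits) if h)
    best, running = 0.0, 0.0
    for (g, s), h in zip(items, hits):
        if h:
            running += (abs(s) ** alpha / denom) if denom > 0 else 1.0 / m
        else:
            running -= 1.0 / (N - m)
        if abs(running) > abs(best):
            best = running
    return best


def hypergeom_tail(a: int, list_size: int, set_size: int, universe: int) -> float:
    """P(overlap >= a) by direct summation of hypergeometric pmf."""
    from math import comb

    total = comb(universe, list_size)
    p = 0.0
    for k in range(a, min(list_size, set_size) + 1):
        p += comb(set_size, k) * comb(universe - set_size, list_size - k) / total
    return p


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def challenge_cohort():
    """Default-size challenge cohort with a 2-SD planted effect."""
    return sim.gen_challenge_cohort(effect=2.0, seed=11)


@pytest.fixture(scope="session")
def small_biopsy():
    """Scaled-down single-cell biopsy dataset (20 cells/stratum)."""
    return sim.gen_sc_biopsy(effect=1.5, cells_per_stratum=20, n_background=40, seed=7)


def small_screen(seed: int, effect: float = 2.0, n_compounds: int = 12):
    """Scaled-down perturbation screen for connectivity tests."""
    return sim.gen_perturbation(
        n_compounds=n_compounds,
        n_donors=2,
        cell_types=("CD4 T", "CD8 T", "B"),
        cells_per_condition=10,
        n_background=30,
        effect=effect,
        seed=seed,
    )


@pytest.fixture(scope="session")
def perturbation_screen():
    return small_screen(seed=3)
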