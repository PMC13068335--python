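"""Seeded synthetic-data generators with planted ground truth.

Four tiers, mirroring the study's data sources so that every pipeline
stage is testable without downloads:

* a NanoString-like allergen-challenge cohort (counts for 770 genes, 35
  subjects: 15 isolated early responders / 20 dual responders) with
  planted discriminative genes, FEV1 trajectories and PC20 shifts;
* multi-dataset bulk cohorts with severity/exacerbation group structure,
  batch shifts, Y-gene-driven sex signal and optional male-only effects;
* a pre/post-allergen-challenge single-cell biopsy dataset with
  cell-type-restricted planted up-regulation in the asthma group only;
* a PBMC perturbation screen (144 compounds + DMSO + 2 positive controls
  x 3 donors x 5 cell types) with planted reverser and mimic compounds.

Every generator is deterministic under a fixed seed and returns a
:class:`PlantedTruth` sufficient to compute all recovery metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import ExpressionMatrix, GeneSetLibrary
from .phenotype import SpirometryRecord
from .splsda import PanelSpec

# A few symbols from the immune-profiling vocabulary keep the synthetic
# gene space readable; the remainder are systematic placeholders.
_NAMED_BIOMARKERS = (
    "CXCL10", "LILRB1", "ARG2", "GNAS", "SF3B1", "CD4", "CD8A", "NFKBIA",
    "FOS", "IFI35", "FPR2", "TFRC", "TNFSF10", "NAPA", "CTSA", "CISH",
    "IL32", "TLR7", "RGS2", "MAP3K8",
)

Y_GENES = ("RPS4Y1", "DDX3Y", "EIF1AY", "KDM5D", "UTY", "USP9Y")

DEFAULT_CELL_TYPES = ("CD4 T", "CD8 T", "B", "NK", "MNP", "Epithelial")
PERTURBATION_CELL_TYPES = ("CD4 T", "CD8 T", "B", "NK", "Myeloid")


@dataclass
class PlantedTruth:
    """Ground truth planted by a generator."""

    informative_genes: list = field(default_factory=list)
    effect: float = 0.0
    classes: pd.Series | None = None
    sex: pd.Series | None = None
    batches: pd.Series | None = None
    low_abundance_genes: list = field(default_factory=list)
    male_only_genes: list = field(default_factory=list)
    celltype_sets: dict = field(default_factory=dict)
    reverser_ids: list = field(default_factory=list)
    mimic_ids: list = field(default_factory=list)
    extra: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# biomarker symbols and reference panels
# ---------------------------------------------------------------------------


def biomarker_symbols(n: int = 109) -> list[str]:
    """Deterministic biomarker symbol list (named genes first)."""
    syms = list(_NAMED_BIOMARKERS[:n])
    i = 1
    while len(syms) < n:
        syms.append(f"LARB{i:03d}")
        i += 1
    return syms


def make_reference_panels() -> list[PanelSpec]:
    """Five biomarker panels with the published slot arithmetic.

    Sizes 40, 33, 35, 34, 14 (156 slots in total) and a union of 109
    unique symbols.  Overlap cells: 3 genes shared PanCancer/UCSC, 9
    UCSC/UCSC-isoforms, 11 in UCSC+UCSC-isoforms+Ensembl, 9
    UCSC-isoforms/Ensembl, 4 UCSC/Trinity.
    """
    syms = biomarker_symbols(109)
    it = iter(syms)

    def take(k):
        return [next(it) for _ in range(k)]

    u1, u2, u3, u4, u5 = take(37), take(6), take(6), take(14), take(10)
    sh12, sh23, sh34, sh25, triple = take(3), take(9), take(9), take(4), take(11)
    panels = [
        PanelSpec("PanCancer", u1 + sh12),
        PanelSpec("UCSC", u2 + sh12 + sh23 + triple + sh25),
        PanelSpec("UCSC-isoforms", u3 + sh23 + sh34 + triple),
        PanelSpec("Ensembl", u4 + sh34 + triple),
        PanelSpec("Trinity", u5 + sh25),
    ]
    assert [len(p) for p in panels] == [40, 33, 35, 34, 14]
    return panels


# ---------------------------------------------------------------------------
# challenge cohort
# ---------------------------------------------------------------------------


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, size: float) -> np.ndarray:
    """Negative-binomial counts with the given mean and dispersion ``size``."""
    mean = np.maximum(np.asarray(mean, dtype=float), 1e-8)
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def gen_challenge_cohort(
    n_er: int = 15,
    n_dr: int = 20,
    n_genes: int = 770,
    n_housekeeping: int = 40,
    n_informative: int = 25,
    effect: float = 1.5,
    n_negative_controls: int = 8,
    n_low_abundance: int = 130,
    borderline_fraction: float = 0.1,
    nb_size: float = 10.0,
    seed: int = 0,
):
    """Simulate the allergen-challenge cohort.

    Negative-binomial counts for ``n_genes`` genes (including
    ``n_housekeeping`` class-independent housekeeping genes) plus
    ``n_negative_controls`` control probes.  ``n_informative`` genes are
    shifted in dual responders by ``effect`` standard deviations of the
    log2 count noise.  ``n_low_abundance`` genes fall below the
    negative-control background threshold, so the default configuration
    retains 600 of 770 genes after filtering.  FEV1 trajectories and PC20
    pairs are constructed so responder classification recovers the
    planted classes exactly: every subject drops >= 20% early, dual
    responders drop >= 15% late except a ``borderline_fraction`` who stay
    in (-15, -10) at 7 h but shift PC20 by >= 2-fold.

    Returns (ExpressionMatrix, sample table, gene table, spirometry
    records, PlantedTruth).
    """
    n_expressed = n_genes - n_housekeeping - n_low_abundance
    if n_informative > n_expressed:
        raise ValueError(
            f"n_informative={n_informative} exceeds expressed gene count {n_expressed}"
        )
    rng = np.random.default_rng(seed)
    n = n_er + n_dr

    panel_syms = biomarker_symbols(109)
    gene_syms = list(panel_syms)
    i = 1
    while len(gene_syms) < n_genes - n_housekeeping:
        gene_syms.append(f"GENE{i:04d}")
        i += 1
    gene_syms = gene_syms[: n_genes - n_housekeeping]
    hk_syms = [f"HK{i:02d}" for i in range(1, n_housekeeping + 1)]
    neg_syms = [f"NEG{i:02d}" for i in range(1, n_negative_controls + 1)]
    all_syms = gene_syms + hk_syms + neg_syms

    informative = gene_syms[:n_informative]
    low_abundance = gene_syms[n_expressed : n_expressed + n_low_abundance]

    gene_table = pd.DataFrame(
        {
            "symbol": all_syms,
            "chromosome": "1",
            "is_housekeeping": [s in set(hk_syms) for s in all_syms],
            "is_negative_control": [s in set(neg_syms) for s in all_syms],
        },
        index=all_syms,
    )

    groups = np.array(["ER"] * n_er + ["DR"] * n_dr)
    sample_ids = [f"S{i:02d}" for i in range(1, n + 1)]

    base_mean = np.empty(len(all_syms))
    for j, s in enumerate(all_syms):
        if s in set(neg_syms):
            base_mean[j] = 15.0
        elif s in set(low_abundance):
            base_mean[j] = rng.uniform(1.0, 8.0)
        elif s in set(hk_syms):
            base_mean[j] = 2.0 ** rng.uniform(6, 9)
        else:
            base_mean[j] = 2.0 ** rng.uniform(5, 9)

    sd_log2 = np.sqrt(1.0 / nb_size) / np.log(2.0)
    fold = 2.0 ** (effect * sd_log2)
    mean_mat = np.tile(base_mean[:, None], (1, n))
    inf_idx = [all_syms.index(g) for g in informative]
    mean_mat[np.ix_(inf_idx, np.flatnonzero(groups == "DR"))] *= fold

    counts = _nb_counts(rng, mean_mat, nb_size)
    matrix = ExpressionMatrix(
        pd.DataFrame(counts.astype(float), index=all_syms, columns=sample_ids), "counts"
    )

    sexes = rng.choice(["female", "male"], size=n, p=[0.7, 0.3])
    sites = rng.choice(["Laval", "McMaster", "UBC"], size=n, p=[0.57, 0.34, 0.09])
    sample_table = pd.DataFrame(
        {"group": groups, "sex": sexes, "batch": sites, "timepoint": "baseline"},
        index=sample_ids,
    )

    records = _gen_spirometry(rng, sample_ids, groups, borderline_fraction)

    truth = PlantedTruth(
        informative_genes=informative,
        effect=effect,
        classes=pd.Series(groups, index=sample_ids, name="group"),
        sex=pd.Series(sexes, index=sample_ids, name="sex"),
        low_abundance_genes=low_abundance,
        extra={"housekeeping": hk_syms, "negative_controls": neg_syms,
               "fold_change": fold},
    )
    return matrix, sample_table, gene_table, records, truth


def _gen_spirometry(rng, sample_ids, groups, borderline_fraction) -> list[SpirometryRecord]:
    times = np.array([0.0, 0.5, 1.0, 1.5, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0])
    dr_ids = [i for i, g in enumerate(groups) if g == "DR"]
    n_borderline = int(round(borderline_fraction * len(dr_ids)))
    borderline = set(dr_ids[:n_borderline])
    records = []
    for i, (sid, grp) in enumerate(zip(sample_ids, groups)):
        traj = np.zeros_like(times)
        ear = -rng.uniform(20.0, 50.0)
        traj[1] = ear * 0.8
        traj[2] = ear  # minimum at 1 h
        traj[3] = ear * 0.6
        traj[4] = ear * 0.3
        if grp == "ER":
            late = rng.uniform(-9.5, 0.0)  # never reaches the rescue zone
            for k, t in enumerate(times):
                if t >= 3:
                    traj[k] = late + rng.uniform(0, 2.0)
            traj[times == 5.0] = late
            ais = rng.uniform(0.5, 1.9)
        elif i in borderline:
            late = rng.uniform(-14.5, -10.5)  # minimum at 7 h, still falling
            for k, t in enumerate(times):
                if t >= 3:
                    traj[k] = late + (7.0 - t) * rng.uniform(0.5, 1.0)
            traj[-1] = late
            ais = rng.uniform(2.0, 6.0)
        else:
            late = -rng.uniform(15.0, 45.0)
            for k, t in enumerate(times):
                if t >= 3:
                    traj[k] = late + abs(t - 5.0) * rng.uniform(0.5, 2.0)
            traj[times == 5.0] = late
            ais = rng.uniform(2.0, 7.0)
        pc20_pre = float(2.0 ** rng.uniform(-2, 4))
        records.append(
            SpirometryRecord(
                subject_id=sid,
                times=times,
                fev1_pct_change=traj,
                pc20_pre=pc20_pre,
                pc20_post=pc20_pre / ais,
            )
        )
    return records


# ---------------------------------------------------------------------------
# bulk cohorts
# ---------------------------------------------------------------------------


def default_bulk_design() -> dict:
    """Design emulating the seven public cohorts' group structure."""
    return {
        "datasets": [
            {"name": "blood_exacerbation", "sample_type": "blood", "platform": "gaussian",
             "groups": {"quiet": 180, "exacerbation": 68, "follow_up": 60}},
            {"name": "airway_biopsy", "sample_type": "airway", "platform": "gaussian",
             "groups": {"healthy": 13, "moderate": 18, "severe": 42}},
            {"name": "airway_epithelium", "sample_type": "airway", "platform": "counts",
             "groups": {"healthy": 16, "moderate": 5, "severe": 17}},
            {"name": "sputum_microarray", "sample_type": "sputum", "platform": "gaussian",
             "groups": {"healthy": 10, "moderate": 18, "severe": 16}},
            {"name": "sputum_microarray_2", "sample_type": "sputum", "platform": "gaussian",
             "groups": {"healthy": 21, "moderate": 25, "severe": 93}},
            {"name": "balf", "sample_type": "balf", "platform": "gaussian",
             "groups": {"healthy": 12, "moderate": 28, "severe": 46}},
            {"name": "blood_severity", "sample_type": "blood", "platform": "gaussian",
             "groups": {"healthy": 87, "moderate": 77, "severe": 334}},
        ],
        "n_background": 191,
        "effect": 1.0,
        "y_effect": 5.0,
        "batch_sd": 1.0,
        "n_male_only": 0,
        "male_only_effect": 1.5,
    }


_GROUP_LEVEL = {
    "healthy": 0.0, "moderate": 1.0, "severe": 2.0,
    "quiet": 0.0, "exacerbation": 1.0, "follow_up": 0.0,
}


def gen_bulk_cohorts(design: Mapping | None = None, seed: int = 0):
    """Simulate the multi-dataset bulk cohorts.

    Gaussian log-intensities (or NB counts for RNA-seq-like platforms)
    with group effects on the biomarker panel genes, an additive batch
    shift per dataset, elevated Y-gene expression in males (``y_effect``
    in noise-SD units) and optional male-only effect genes.

    Returns (dict of name -> (ExpressionMatrix, sample table), gene
    table, PlantedTruth).
    """
    if design is None:
        design = default_bulk_design()
    rng = np.random.default_rng(seed)
    panel = biomarker_symbols(109)
    background = [f"BG{i:04d}" for i in range(1, design.get("n_background", 191) + 1)]
    genes = panel + background + list(Y_GENES)
    gene_table = pd.DataFrame(
        {
            "symbol": genes,
            "chromosome": ["Y" if g in Y_GENES else "1" for g in genes],
            "is_housekeeping": False,
            "is_negative_control": False,
        },
        index=genes,
    )

    effect = design.get("effect", 1.0)
    y_effect = design.get("y_effect", 5.0)
    batch_sd = design.get("batch_sd", 1.0)
    n_male_only = design.get("n_male_only", 0)
    male_only_effect = design.get("male_only_effect", 1.5)
    male_only = panel[:n_male_only]

    base = rng.uniform(5, 9, size=len(genes))
    panel_idx = np.array([genes.index(g) for g in panel])
    male_only_idx = np.array([genes.index(g) for g in male_only], dtype=int)
    y_idx = np.array([genes.index(g) for g in Y_GENES])

    datasets = {}
    sex_all, batch_all = {}, {}
    for ds in design["datasets"]:
        name = ds["name"]
        sizes = ds["groups"]
        n = sum(sizes.values())
        groups = np.concatenate([[g] * k for g, k in sizes.items()])
        sample_ids = [f"{name}_{i:03d}" for i in range(1, n + 1)]
        sexes = rng.choice(["male", "female"], size=n)
        males = sexes == "male"

        mean = np.tile(base[:, None], (1, n))
        levels = np.array([_GROUP_LEVEL.get(g, 0.0) for g in groups])
        mean[panel_idx[:, None], :] += effect * levels[None, :]
        if len(male_only_idx):
            boost = male_only_effect * levels * males
            mean[male_only_idx[:, None], :] += boost[None, :]
        mean[y_idx[:, None], males] += y_effect
        mean += rng.normal(0, batch_sd, size=len(genes))[:, None]  # dataset batch shift
        vals = rng.normal(mean, 1.0)
        if ds.get("platform", "gaussian") == "counts":
            counts = _nb_counts(rng, 2.0**vals, 10.0)
            matrix = ExpressionMatrix(
                pd.DataFrame(counts.astype(float), index=genes, columns=sample_ids), "counts"
            )
        else:
            matrix = ExpressionMatrix(
                pd.DataFrame(vals, index=genes, columns=sample_ids), "log_intensity"
            )
        sample_table = pd.DataFrame(
            {"group": groups, "sex": sexes, "batch": name, "sample_type": ds["sample_type"]},
            index=sample_ids,
        )
        datasets[name] = (matrix, sample_table)
        sex_all.update(dict(zip(sample_ids, sexes)))
        batch_all.update(dict(zip(sample_ids, [name] * n)))

    truth = PlantedTruth(
        informative_genes=panel,
        effect=effect,
        sex=pd.Series(sex_all, name="sex"),
        batches=pd.Series(batch_all, name="batch"),
        male_only_genes=male_only,
        extra={"y_effect": y_effect, "y_genes": list(Y_GENES), "batch_sd": batch_sd},
    )
    return datasets, gene_table, truth


# ---------------------------------------------------------------------------
# single-cell biopsy
# ---------------------------------------------------------------------------


def default_biopsy_sets(panel: Sequence[str] | None = None) -> dict:
    """Default planted biomarker response: T-cell-restricted, mostly up."""
    panel = list(panel or biomarker_symbols(109))
    return {
        "CD8 T": {"up": panel[0:55], "down": panel[105:109]},
        "CD4 T": {"up": panel[20:62], "down": panel[100:104]},
    }


def gen_sc_biopsy(
    n_subjects_per_group: int = 4,
    cell_types: Sequence[str] = DEFAULT_CELL_TYPES,
    subtype_map: Mapping[str, Sequence[str]] | None = None,
    planted_sets: Mapping[str, Mapping[str, Sequence[str]]] | None = None,
    effect: float = 1.0,
    cells_per_stratum: int = 40,
    n_background: int = 100,
    nb_size: float = 2.0,
    seed: int = 0,
):
    """Simulate the pre/post-allergen-challenge biopsy dataset.

    NB counts per cell; in the allergic-asthma group only, the allergen
    condition multiplies the planted set genes' means by 2**effect (up)
    or 2**-effect (down) in the designated cell types.  Returns
    (AnnData, PlantedTruth).
    """
    import anndata as ad
    from scipy import sparse

    rng = np.random.default_rng(seed)
    panel = biomarker_symbols(109)
    genes = panel + [f"BG{i:04d}" for i in range(1, n_background + 1)]
    if planted_sets is None:
        planted_sets = default_biopsy_sets(panel)
    unknown = set(planted_sets) - set(cell_types)
    if unknown:
        raise ValueError(f"planted sets reference unknown cell types: {sorted(unknown)}")

    base = rng.lognormal(mean=np.log(2.0), sigma=1.0, size=len(genes))
    gene_pos = {g: i for i, g in enumerate(genes)}

    obs_rows, blocks = [], []
    for group, prefix in (("allergic_asthma", "AA"), ("allergic_control", "AC")):
        for s in range(1, n_subjects_per_group + 1):
            subject = f"{prefix}{s:02d}"
            for condition in ("baseline", "allergen"):
                sample = f"{subject}_{condition}"
                for ct in cell_types:
                    mean = base.copy()
                    if (
                        group == "allergic_asthma"
                        and condition == "allergen"
                        and ct in planted_sets
                    ):
                        up = [gene_pos[g] for g in planted_sets[ct].get("up", [])]
                        down = [gene_pos[g] for g in planted_sets[ct].get("down", [])]
                        mean[up] *= 2.0**effect
                        mean[down] *= 2.0**-effect
                    counts = _nb_counts(
                        rng, np.tile(mean, (cells_per_stratum, 1)), nb_size
                    )
                    blocks.append(sparse.csr_matrix(counts.astype(float)))
                    subtypes = None
                    if subtype_map and ct in subtype_map:
                        subtypes = rng.choice(subtype_map[ct], size=cells_per_stratum)
                    for c in range(cells_per_stratum):
                        obs_rows.append(
                            {
                                "cell_type": ct,
                                "subtype": subtypes[c] if subtypes is not None else ct,
                                "sample_id": sample,
                                "subject_id": subject,
                                "condition": condition,
                                "group": group,
                            }
                        )
    X = sparse.vstack(blocks).tocsr()
    obs = pd.DataFrame(obs_rows)
    obs.index = [f"cell{i:06d}" for i in range(len(obs))]
    adata = ad.AnnData(X=X, obs=obs, var=pd.DataFrame(index=pd.Index(genes, name="gene")))
    truth = PlantedTruth(
        effect=effect,
        celltype_sets={ct: {k: list(v) for k, v in sets.items()} for ct, sets in planted_sets.items()},
        extra={"panel": panel},
    )
    return adata, truth


# ---------------------------------------------------------------------------
# perturbation screen
# ---------------------------------------------------------------------------


def gen_perturbation(
    n_compounds: int = 144,
    n_donors: int = 3,
    cell_types: Sequence[str] = PERTURBATION_CELL_TYPES,
    reverser_ids: Sequence[str] | None = None,
    mimic_ids: Sequence[str] | None = None,
    target_sets: Mapping[str, Mapping[str, Sequence[str]]] | None = None,
    effect: float = 1.0,
    cells_per_condition: int = 15,
    n_background: int = 100,
    n_offtarget: int = 10,
    nb_size: float = 2.0,
    include_positive_controls: bool = True,
    seed: int = 0,
):
    """Simulate the PBMC drug-perturbation screen.

    Vehicle (DMSO) cells follow the baseline expression; planted reverser
    compounds shift each cell type's up-set genes down and down-set genes
    up by a factor 2**effect (mimics do the opposite); all other
    compounds perturb ``n_offtarget`` random non-target genes.  Positive
    controls (dabrafenib, belinostat) perturb many random genes strongly
    and are flagged for exclusion from reverser ranking.  Returns
    (AnnData, PlantedTruth).
    """
    import anndata as ad
    from scipy import sparse

    rng = np.random.default_rng(seed)
    compounds = [f"CPD{i:03d}" for i in range(1, n_compounds + 1)]
    if reverser_ids is None:
        reverser_ids = [compounds[n_compounds // 3]]
    if mimic_ids is None:
        mimic_ids = [compounds[(2 * n_compounds) // 3]]
    reverser_ids, mimic_ids = list(reverser_ids), list(mimic_ids)
    if set(reverser_ids) & set(mimic_ids):
        raise ValueError("reverser and mimic compound ids overlap")
    missing = (set(reverser_ids) | set(mimic_ids)) - set(compounds)
    if missing:
        raise ValueError(f"planted compound ids not in the screen: {sorted(missing)}")
    positive_controls = ["dabrafenib", "belinostat"] if include_positive_controls else []
    all_conditions = ["DMSO"] + compounds + positive_controls

    panel = biomarker_symbols(109)
    genes = panel + [f"BG{i:04d}" for i in range(1, n_background + 1)]
    gene_pos = {g: i for i, g in enumerate(genes)}
    if target_sets is None:
        biopsy = default_biopsy_sets(panel)
        target_sets = {ct: biopsy[src] for src, ct in (("CD8 T", "CD8 T"), ("CD4 T", "CD4 T"))}
    target_idx = {
        ct: {
            "up": [gene_pos[g] for g in sets.get("up", []) if g in gene_pos],
            "down": [gene_pos[g] for g in sets.get("down", []) if g in gene_pos],
        }
        for ct, sets in target_sets.items()
    }
    all_target = sorted({i for d in target_idx.values() for k in d.values() for i in k})
    non_target = [i for i in range(len(genes)) if i not in set(all_target)]

    base = rng.lognormal(mean=np.log(2.0), sigma=1.0, size=len(genes))
    offtarget: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for c in compounds:
        if c in reverser_ids or c in mimic_ids:
            continue
        idx = rng.choice(non_target, size=min(n_offtarget, len(non_target)), replace=False)
        signs = rng.choice([-1.0, 1.0], size=len(idx))
        offtarget[c] = (idx, signs)
    for c in positive_controls:
        idx = rng.choice(len(genes), size=min(50, len(genes)), replace=False)
        signs = rng.choice([-1.0, 1.0], size=len(idx))
        offtarget[c] = (idx, signs)

    obs_rows, blocks = [], []
    for compound in all_conditions:
        for ct in cell_types:
            mean = base.copy()
            if compound in reverser_ids and ct in target_idx:
                mean[target_idx[ct]["up"]] *= 2.0**-effect
                mean[target_idx[ct]["down"]] *= 2.0**effect
            elif compound in mimic_ids and ct in target_idx:
                mean[target_idx[ct]["up"]] *= 2.0**effect
                mean[target_idx[ct]["down"]] *= 2.0**-effect
            elif compound in offtarget:
                idx, signs = offtarget[compound]
                mean[idx] *= 2.0 ** (signs * effect)
            for donor in range(1, n_donors + 1):
                counts = _nb_counts(
                    rng, np.tile(mean, (cells_per_condition, 1)), nb_size
                )
                blocks.append(sparse.csr_matrix(counts.astype(float)))
                obs_rows.extend(
                    {
                        "compound": compound,
                        "donor": f"D{donor}",
                        "cell_type": ct,
                    }
                    for _ in range(cells_per_condition)
                )
    X = sparse.vstack(blocks).tocsr()
    obs = pd.DataFrame(obs_rows)
    obs.index = [f"cell{i:06d}" for i in range(len(obs))]
    adata = ad.AnnData(X=X, obs=obs, var=pd.DataFrame(index=pd.Index(genes, name="gene")))
    truth = PlantedTruth(
        effect=effect,
        celltype_sets={ct: {k: [genes[i] for i in v] for k, v in d.items()} for ct, d in target_idx.items()},
        reverser_ids=reverser_ids,
        mimic_ids=mimic_ids,
        extra={"positive_controls": positive_controls, "vehicle": "DMSO",
               "panel": panel},
    )
    return adata, truth


# ---------------------------------------------------------------------------
# gene-set library
# ---------------------------------------------------------------------------


def gen_gene_set_library(
    universe: Sequence[str],
    enriched_list: Sequence[str],
    n_sets: int = 20,
    n_enriched_sets: int = 3,
    set_size: int = 25,
    seed: int = 0,
    name: str = "synthetic",
) -> GeneSetLibrary:
    """Random gene-set library with a few sets loaded with list genes.

    The first ``n_enriched_sets`` sets draw 60% of their members from
    ``enriched_list``; the rest are uniform draws from the universe.
    """
    rng = np.random.default_rng(seed)
    universe = list(universe)
    enriched = [g for g in enriched_list if g in set(universe)]
    sets = {}
    for i in range(n_sets):
        if i < n_enriched_sets and enriched:
            k = min(int(0.6 * set_size), len(enriched))
            members = list(rng.choice(enriched, size=k, replace=False))
            rest = [g for g in universe if g not in set(members)]
            members += list(rng.choice(rest, size=set_size - k, replace=False))
        else:
            members = list(rng.choice(universe, size=set_size, replace=False))
        sets[f"SET{i + 1:02d}"] = members
    return GeneSetLibrary(name, sets)
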