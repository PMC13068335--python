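"""Config-driven orchestration of the analysis stages.

``run_pipeline`` executes simulate -> select-panel -> evaluate -> scde ->
connect -> ora in order, writing each stage's outputs plus a JSON
manifest (parameters, seed, output checksums) under the output
directory.  A single global seed derives per-stage seeds by fixed
offsets so stages are independently reproducible; reruns with an
identical config produce identical checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core_io import filter_low_abundance, log_cpm, write_gmt
from .cohort import aggregate_ranks, evaluate_grid, results_table
from .connectivity import build_drug_signatures, score_all
from .ora import frequent_genes, ora
from .pseudobulk import de_by_celltype, significant_sets
from .splsda import PanelSpec, merge_panels, select_panel, tune_keepx
from . import simulate as sim

logger = logging.getLogger(__name__)

STAGE_ORDER = ["simulate", "select_panel", "evaluate", "scde", "connect", "ora"]
STAGE_SEED_OFFSET = {name: i for i, name in enumerate(STAGE_ORDER)}


class PipelineError(RuntimeError):
    pass


def default_config(outdir: str = "larconnect_run") -> dict:
    """A small, fast demonstration configuration (synthetic defaults,
    scaled-down sample counts)."""
    return {
        "seed": 7,
        "outdir": outdir,
        "stages": list(STAGE_ORDER),
        "simulate": {
            "challenge": {"n_er": 15, "n_dr": 20, "n_genes": 770, "n_informative": 25,
                          "effect": 2.0},
            "bulk": {
                "datasets": [
                    {"name": "balf", "sample_type": "balf", "platform": "gaussian",
                     "groups": {"healthy": 12, "moderate": 28, "severe": 46}},
                    {"name": "sputum", "sample_type": "sputum", "platform": "gaussian",
                     "groups": {"healthy": 10, "moderate": 18, "severe": 16}},
                ],
                "n_background": 50,
                "effect": 1.5,
            },
            "sc_biopsy": {"cells_per_stratum": 20, "n_background": 40, "effect": 1.5},
            "perturbation": {"n_compounds": 20, "n_donors": 2,
                             "cells_per_condition": 10, "n_background": 40,
                             "effect": 2.0},
        },
        "select_panel": {"keepx_grid": [5, 10, 15, 20, 25, 30], "repeats": 5,
                         "folds": 5, "auc_threshold": 0.70},
        "evaluate": {"repeats": 5, "folds": 5, "n_trees": 100,
                     "comparisons": {"healthy_vs_severe": ["healthy", "severe"],
                                     "moderate_vs_severe": ["moderate", "severe"]},
                     "strata": ["combined"], "auc_min": 0.70,
                     "panels": ["combined", "discovered"]},
        "scde": {"fdr": 0.20, "min_cells": 10},
        "connect": {"mode": "raw", "n_perm": 200, "threshold": 0.5},
        "ora": {"q_threshold": 0.01, "n_sets": 20, "set_size": 25},
    }


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_manifest(stage_dir: Path, stage: str, params: dict, seed: int) -> dict:
    outputs = {
        str(p.relative_to(stage_dir)): _sha256(p)
        for p in sorted(stage_dir.rglob("*"))
        if p.is_file() and p.name != "manifest.json"
    }
    manifest = {
        "stage": stage,
        "version": __version__,
        "seed": seed,
        "params": params,
        "outputs": outputs,
    }
    with open(stage_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return manifest


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")


def load_config(path_or_dict) -> dict:
    if isinstance(path_or_dict, (str, Path)):
        with open(path_or_dict) as fh:
            return yaml.safe_load(fh)
    return dict(path_or_dict)


def preflight(config: dict) -> None:
    """Validate the config before any stage runs."""
    unknown = [s for s in config.get("stages", []) if s not in STAGE_ORDER]
    if unknown:
        raise PipelineError(f"unknown stages: {unknown}")
    for path in config.get("inputs", {}).values():
        if not Path(path).exists():
            raise PipelineError(f"input file does not exist: {path}")
    if "seed" not in config:
        raise PipelineError("config must declare a global seed")


def run_pipeline(config, outdir=None) -> dict:
    """Run the configured stages; returns the run manifest.

    Stage failure raises :class:`PipelineError` naming the stage; outputs
    of completed stages are retained.
    """
    config = load_config(config)
    preflight(config)
    seed = int(config["seed"])
    out = Path(outdir or config.get("outdir", "larconnect_run"))
    out.mkdir(parents=True, exist_ok=True)
    stages = config.get("stages", list(STAGE_ORDER))
    stages = [s for s in STAGE_ORDER if s in stages]

    state: dict = {}
    run_manifest = {"version": __version__, "seed": seed, "stages": []}
    for stage in stages:
        stage_seed = seed + STAGE_SEED_OFFSET[stage]
        stage_dir = out / stage
        stage_dir.mkdir(parents=True, exist_ok=True)
        params = config.get(stage, {}) or {}
        logger.info("running stage %s (seed %d)", stage, stage_seed)
        try:
            _STAGES[stage](state, params, stage_seed, stage_dir)
        except Exception as exc:  # halt with the failing stage named
            raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
        run_manifest["stages"].append(_write_manifest(stage_dir, stage, params, stage_seed))
    with open(out / "manifest.json", "w") as fh:
        json.dump(run_manifest, fh, indent=2, sort_keys=True, default=str)
    return run_manifest


# ---------------------------------------------------------------------------
# stage implementations
# ---------------------------------------------------------------------------


def _stage_simulate(state, params, seed, stage_dir):
    ch = params.get("challenge", {})
    matrix, samples, gene_table, records, truth = sim.gen_challenge_cohort(seed=seed, **ch)
    state["challenge"] = (matrix, samples, gene_table, records, truth)
    _write_tsv(samples, stage_dir / "challenge_samples.tsv", index=True)

    bulk_design = params.get("bulk")
    if bulk_design is not None:
        bulk_design = {**sim.default_bulk_design(), **bulk_design}
    datasets, bulk_genes, bulk_truth = sim.gen_bulk_cohorts(bulk_design, seed=seed + 100)
    state["bulk"] = (datasets, bulk_genes, bulk_truth)

    adata, sc_truth = sim.gen_sc_biopsy(seed=seed + 200, **params.get("sc_biopsy", {}))
    state["sc_biopsy"] = (adata, sc_truth)

    pert, pert_truth = sim.gen_perturbation(seed=seed + 300, **params.get("perturbation", {}))
    state["perturbation"] = (pert, pert_truth)
    summary = pd.DataFrame(
        {
            "tier": ["challenge", "bulk", "sc_biopsy", "perturbation"],
            "n_units": [matrix.shape[1], sum(m.shape[1] for m, _ in datasets.values()),
                        adata.n_obs, pert.n_obs],
        }
    )
    _write_tsv(summary, stage_dir / "summary.tsv")


def _stage_select_panel(state, params, seed, stage_dir):
    matrix, samples, gene_table, _, truth = state["challenge"]
    retained = filter_low_abundance(matrix, gene_table, k_sd=params.get("k_sd", 2.0))
    logcpm = log_cpm(matrix.subset_genes(retained))
    X = logcpm.values.T
    y = samples["group"].to_numpy()
    tuning = tune_keepx(
        X, y,
        grid=params.get("keepx_grid", (5, 10, 15, 20, 25, 30)),
        ncomp=2,
        repeats=params.get("repeats", 20),
        folds=params.get("folds", 5),
        seed=seed,
    )
    _write_tsv(tuning.table, stage_dir / "tuning.tsv")
    chosen = select_panel(tuning, params.get("auc_threshold", 0.70))
    if chosen is None:
        raise PipelineError("no keepX configuration cleared the AUC threshold")
    keepx = tuple(int(k) for k in str(chosen["keepX"]).split(","))
    from .splsda import fit_splsda

    model = fit_splsda(X, y, ncomp=len(keepx), keepX=keepx)
    discovered = PanelSpec("discovered", model.selected_genes)
    reference = sim.make_reference_panels()
    merged = merge_panels([discovered] + reference[1:])
    state["panels"] = {"combined": merged.combined, "discovered": discovered,
                       **{p.name: p for p in reference[1:]}}
    state["panel_model"] = model
    _write_tsv(
        pd.DataFrame({"gene": discovered.genes}), stage_dir / "panel_discovered.tsv"
    )
    _write_tsv(
        pd.DataFrame({"gene": merged.combined.genes}), stage_dir / "panel_combined.tsv"
    )
    _write_tsv(merged.overlap, stage_dir / "panel_overlap.tsv", index=True)


def _stage_evaluate(state, params, seed, stage_dir):
    datasets, gene_table, truth = state["bulk"]
    panels = state.get("panels") or {
        p.name: p for p in sim.make_reference_panels()
    }
    wanted = params.get("panels")
    if wanted:
        panels = {name: panels[name] for name in wanted if name in panels}
    comparisons = {
        k: tuple(v) for k, v in params.get(
            "comparisons", {"healthy_vs_severe": ("healthy", "severe")}
        ).items()
    }
    results = evaluate_grid(
        datasets,
        comparisons,
        panels,
        strata=params.get("strata", ("combined",)),
        classifiers=params.get("classifiers", ("plsda", "random_forest")),
        repeats=params.get("repeats", 20),
        folds=params.get("folds", 5),
        seed=seed,
        n_trees=params.get("n_trees", 500),
    )
    state["eval_results"] = results
    _write_tsv(results_table(results), stage_dir / "results.tsv")
    ranks = aggregate_ranks(results, auc_min=params.get("auc_min", 0.70))
    _write_tsv(ranks.reset_index(names="gene"), stage_dir / "biomarker_ranks.tsv")


def _stage_scde(state, params, seed, stage_dir):
    adata, truth = state["sc_biopsy"]
    panel = state.get("panels", {}).get("combined")
    biomarkers = list(panel.genes) if panel is not None else truth.extra["panel"]
    de = de_by_celltype(
        adata,
        biomarkers,
        fdr=params.get("fdr", 0.20),
        min_cells=params.get("min_cells", 10),
    )
    state["de"] = de
    _write_tsv(de.table, stage_dir / "de_results.tsv")
    _write_tsv(de.counts.reset_index(), stage_dir / "significant_counts.tsv")


def _stage_connect(state, params, seed, stage_dir):
    pert, pert_truth = state["perturbation"]
    signatures = build_drug_signatures(pert, vehicle=pert_truth.extra.get("vehicle", "DMSO"))
    de = state.get("de")
    up_sets, down_sets = significant_sets(de) if de is not None else ({}, {})
    if not up_sets and not down_sets:
        logger.warning("no significant DE sets; falling back to planted sets")
        sc_truth = state["sc_biopsy"][1]
        up_sets = {ct: d.get("up", []) for ct, d in sc_truth.celltype_sets.items()}
        down_sets = {ct: d.get("down", []) for ct, d in sc_truth.celltype_sets.items()}
    from .connectivity import DEFAULT_CELLTYPE_MAP

    celltype_map = params.get("celltype_map", DEFAULT_CELLTYPE_MAP)
    dropped = (set(up_sets) | set(down_sets)) - set(celltype_map)
    if dropped:
        logger.warning("dropping unmapped biopsy cell types: %s", sorted(dropped))
        up_sets = {ct: v for ct, v in up_sets.items() if ct in celltype_map}
        down_sets = {ct: v for ct, v in down_sets.items() if ct in celltype_map}
    result = score_all(
        signatures,
        up_sets,
        down_sets,
        celltype_map=celltype_map,
        report_threshold=params.get("threshold", 3.0),
        mode=params.get("mode", "nes"),
        n_perm=params.get("n_perm", 1000),
        seed=seed,
        exclude=pert_truth.extra.get("positive_controls", []),
    )
    state["connectivity"] = result
    _write_tsv(result.table, stage_dir / "connectivity.tsv")
    summary = {
        "mode": result.mode,
        "threshold": result.threshold,
        "reversers": result.reversers,
        "mimics": result.mimics,
        "top_reversers": result.mean_cs().head(5).to_dict(),
    }
    with open(stage_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)


def _stage_ora(state, params, seed, stage_dir):
    panel = state.get("panels", {}).get("combined")
    gene_list = list(panel.genes) if panel is not None else sim.biomarker_symbols(109)
    matrix = state["challenge"][0]
    universe = list(dict.fromkeys(list(matrix.gene_ids) + gene_list))
    library = sim.gen_gene_set_library(
        universe,
        gene_list,
        n_sets=params.get("n_sets", 20),
        set_size=params.get("set_size", 25),
        seed=seed,
    )
    write_gmt(library, stage_dir / "library.gmt")
    result = ora(gene_list, universe, library, q_threshold=params.get("q_threshold", 0.01))
    state["ora"] = result
    _write_tsv(result.table, stage_dir / "ora.tsv")
    _write_tsv(frequent_genes(result), stage_dir / "frequent_genes.tsv")


_STAGES = {
    "simulate": _stage_simulate,
    "select_panel": _stage_select_panel,
    "evaluate": _stage_evaluate,
    "scde": _stage_scde,
    "connect": _stage_connect,
    "ora": _stage_ora,
}
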