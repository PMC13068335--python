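"""I/O round-trips and per-platform bulk preprocessing rules."""

import numpy as np
import pandas as pd
import pytest

from larconnect import simulate as sim
from larconnect.core_io import (
    ExpressionMatrix,
    GeneSetLibrary,
    collapse_probes_mean,
    combat_adjust,
    filter_low_abundance,
    impute_sex,
    log2_clip,
    log_cpm,
    read_gmt,
    read_matrix_delim,
    read_mtx_triplet,
    sum_transcripts,
    validate_gene_table,
    write_gmt,
    write_matrix_delim,
)


def _matrix(values, genes=None, samples=None, kind="log_intensity"):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples), kind)


def _gene_table(index, symbols=None, chrom="1", hk=(), neg=()):
    return pd.DataFrame(
        {
            "symbol": symbols or list(index),
            "chromosome": chrom,
            "is_housekeeping": [g in set(hk) for g in index],
            "is_negative_control": [g in set(neg) for g in index],
        },
        index=list(index),
    )


class TestDelimitedMatrix:
    def test_round_trip_preserves_values_and_order(self, tmp_path):
        mx = _matrix(np.arange(6.0).reshape(3, 2))
        path = tmp_path / "m.tsv"
        write_matrix_delim(mx, path, seed=1)
        back = read_matrix_delim(path)
        pd.testing.assert_frame_equal(back.values, mx.values)

    def test_orientation_transposed_input(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text("sample\tgA\tgB\ts1\t1\t2\ns2\t3\t4\n".replace("\\t", "\t"))
        path.write_text("sample\tgA\tgB\ns1\t1\t2\ns2\t3\t4\n")
        mx = read_matrix_delim(path, orientation="samples_by_genes")
        assert mx.gene_ids == ["gA", "gB"]
        assert mx.values.loc["gB", "s1"] == 2

    def test_ragged_row_names_line(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("gene\ts1\ts2\ng1\t1\t2\ng2\t3\n")
        with pytest.raises(ValueError, match="line 3"):
            read_matrix_delim(path)

    def test_duplicate_sample_ids_rejected(self, tmp_path):
        path = tmp_path / "dup.tsv"
        path.write_text("gene\ts1\ts1\ng1\t1\t2\n")
        with pytest.raises(ValueError, match="duplicated sample"):
            read_matrix_delim(path)

    def test_na_values_parse_as_nan(self, tmp_path):
        path = tmp_path / "na.tsv"
        path.write_text("gene\ts1\ts2\ng1\tNA\t2\n")
        mx = read_matrix_delim(path)
        assert np.isnan(mx.values.loc["g1", "s1"])

    def test_counts_kind_rejects_negatives(self):
        with pytest.raises(ValueError, match="negative"):
            _matrix([[-1.0, 2.0]], kind="counts")


class TestMtxTriplet:
    def _write_triplet(self, tmp_path, n_cells=4, n_genes=3, entries=None, barcodes=None):
        entries = entries or [(1, 1, 5), (2, 3, 2), (3, 2, 1), (1, 4, 7)]
        mtx = tmp_path / "matrix.mtx"
        mtx.write_text(
            "%%MatrixMarket matrix coordinate integer general\n"
            f"{n_genes} {n_cells} {len(entries)}\n"
            + "".join(f"{g} {c} {v}\n" for g, c, v in entries)
        )
        genes = [f"G{i}" for i in range(1, n_genes + 1)]
        cells = barcodes or [f"BC{i}" for i in range(1, n_cells + 1)]
        (tmp_path / "features.tsv").write_text("\n".join(genes) + "\n")
        (tmp_path / "barcodes.tsv").write_text("\n".join(cells) + "\n")
        return mtx, tmp_path / "features.tsv", tmp_path / "barcodes.tsv", cells

    def test_toy_triplet_reads_annotated_cells(self, tmp_path):
        mtx, feats, bcs, cells = self._write_triplet(tmp_path)
        ann = tmp_path / "ann.tsv"
        ann.write_text("barcode\tcell_type\n" + "".join(f"{c}\tT\n" for c in cells))
        adata = read_mtx_triplet(mtx, feats, bcs, ann)
        assert adata.shape == (4, 3)
        assert list(adata.obs["cell_type"]) == ["T"] * 4
        assert adata.X[0, 0] == 5

    def test_dimension_mismatch_errors(self, tmp_path):
        mtx, feats, bcs, _ = self._write_triplet(tmp_path)
        (tmp_path / "features.tsv").write_text("G1\nG2\n")
        with pytest.raises(ValueError, match="features"):
            read_mtx_triplet(mtx, feats, bcs)

    def test_missing_annotation_errors_or_drops(self, tmp_path):
        mtx, feats, bcs, cells = self._write_triplet(tmp_path)
        ann = tmp_path / "ann.tsv"
        ann.write_text("barcode\tcell_type\n" + "".join(f"{c}\tT\n" for c in cells[:3]))
        with pytest.raises(ValueError, match="BC4"):
            read_mtx_triplet(mtx, feats, bcs, ann)
        adata = read_mtx_triplet(mtx, feats, bcs, ann, drop_unannotated=True)
        assert adata.n_obs == 3


def test_gmt_round_trip(tmp_path):
    lib = GeneSetLibrary("demo", {"S1": ["A", "B"], "S2": ["B", "C", "D"]})
    path = tmp_path / "lib.gmt"
    write_gmt(lib, path)
    back = read_gmt(path)
    assert back.sets == lib.sets


def test_gene_table_rejects_double_flag():
    gt = _gene_table(["a"], hk=["a"], neg=["a"])
    with pytest.raises(ValueError, match="both"):
        validate_gene_table(gt)


class TestCollapseAndSum:
    def test_probe_mean_within_sample(self):
        mx = _matrix([[2.0, 10.0], [4.0, 20.0], [1.0, 2.0]], genes=["p1", "p2", "p3"])
        gt = _gene_table(["p1", "p2", "p3"], symbols=["G", "G", "H"])
        out = collapse_probes_mean(mx, gt)
        assert out.values.loc["G", "s0"] == 3.0
        assert out.values.loc["G", "s1"] == 15.0
        assert out.values.loc["H", "s0"] == 1.0

    def test_three_probe_mean(self):
        mx = _matrix([[1.0], [2.0], [6.0]], genes=["p1", "p2", "p3"])
        gt = _gene_table(["p1", "p2", "p3"], symbols=["G", "G", "G"])
        assert collapse_probes_mean(mx, gt).values.loc["G", "s0"] == pytest.approx(3.0)

    def test_distinct_symbols_identity(self):
        mx = _matrix(np.arange(6.0).reshape(3, 2), genes=["p1", "p2", "p3"])
        gt = _gene_table(["p1", "p2", "p3"], symbols=["A", "B", "C"])
        out = collapse_probes_mean(mx, gt)
        assert np.array_equal(out.values.to_numpy(), mx.values.to_numpy())

    def test_unmapped_probe_listed(self):
        mx = _matrix([[1.0]], genes=["p1"])
        gt = _gene_table(["other"], symbols=["G"])
        with pytest.raises(KeyError, match="p1"):
            collapse_probes_mean(mx, gt)

    def test_transcript_sum_preserves_sample_totals(self):
        mx = _matrix([[3.0, 1.0], [5.0, 2.0], [4.0, 7.0]], genes=["t1", "t2", "t3"],
                     kind="counts")
        gt = _gene_table(["t1", "t2", "t3"], symbols=["G", "G", "H"])
        out = sum_transcripts(mx, gt)
        assert out.values.loc["G", "s0"] == 8.0
        assert out.value_kind == "counts"
        np.testing.assert_allclose(out.values.sum(axis=0), mx.values.sum(axis=0))

    def test_sum_rejects_log_intensity(self):
        mx = _matrix([[1.0]], genes=["t1"])
        gt = _gene_table(["t1"], symbols=["G"])
        with pytest.raises(ValueError, match="counts"):
            sum_transcripts(mx, gt)


class TestLogTransforms:
    def test_log2_clip_rules(self):
        mx = _matrix([[8.0, 0.5, np.nan, 0.0]], kind="counts")
        out = log2_clip(mx)
        np.testing.assert_allclose(out.values.to_numpy()[0], [3.0, 0.0, 0.0, 0.0])
        assert out.value_kind == "log_intensity"

    def test_log_cpm_formula(self):
        counts = np.full((2, 1), 0.0)
        counts[0, 0] = 100.0
        counts[1, 0] = 1e6 - 100.0
        out = log_cpm(_matrix(counts, kind="counts"), prior_count=0.5)
        expected = np.log2((100 + 0.5) / (1e6 + 1) * 1e6)
        assert out.values.iloc[0, 0] == pytest.approx(expected, rel=1e-12)

    def test_log_cpm_prior_zero_scale_invariant(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(1, 100, size=(20, 3)).astype(float)
        doubled = counts.copy()
        doubled[:, 1] *= 2
        a = log_cpm(_matrix(counts, kind="counts"), prior_count=0.0)
        b = log_cpm(_matrix(doubled, kind="counts"), prior_count=0.0)
        np.testing.assert_allclose(a.values.to_numpy(), b.values.to_numpy(), atol=1e-12)

    def test_log_cpm_zero_library_names_sample(self):
        mx = _matrix([[0.0, 1.0]], kind="counts")
        with pytest.raises(ValueError, match="s0"):
            log_cpm(mx)


class TestLowAbundanceFilter:
    def test_toy_filter(self):
        # controls: mean 10, sd ~0 -> threshold ~10; g_low below, hk removed
        vals = [[100.0, 100.0], [50.0, 50.0], [5.0, 5.0], [80.0, 80.0],
                [10.0, 10.0], [10.0, 10.2]]
        genes = ["g1", "g2", "g_low", "hk1", "n1", "n2"]
        mx = _matrix(vals, genes=genes, kind="counts")
        gt = _gene_table(genes, hk=["hk1"], neg=["n1", "n2"])
        assert filter_low_abundance(mx, gt, k_sd=2.0) == ["g1", "g2"]

    def test_disabled_threshold_keeps_all_non_housekeeping(self):
        vals = [[1.0], [2.0], [3.0]]
        genes = ["a", "hk", "n"]
        mx = _matrix(vals, genes=genes, kind="counts")
        gt = _gene_table(genes, hk=["hk"], neg=["n"])
        assert filter_low_abundance(mx, gt, k_sd=-np.inf) == ["a"]

    def test_planted_threshold_exact_set(self):
        rng = np.random.default_rng(5)
        n = 200
        ctrl = rng.normal(20, 4, size=(6, n))
        thr_genes = [("above", 60.0), ("below", 5.0)]
        vals = np.vstack([np.full((1, n), v) for _, v in thr_genes] + [ctrl])
        genes = [g for g, _ in thr_genes] + [f"n{i}" for i in range(6)]
        mx = _matrix(np.abs(vals), genes=genes, kind="counts")
        gt = _gene_table(genes, neg=[g for g in genes if g.startswith("n")])
        assert filter_low_abundance(mx, gt, k_sd=2.0) == ["above"]

    def test_missing_controls_error(self):
        mx = _matrix([[1.0]], genes=["a"], kind="counts")
        gt = _gene_table(["a"])
        with pytest.raises(ValueError, match="negative-control"):
            filter_low_abundance(mx, gt)

    def test_default_cohort_retains_600_of_770(self, challenge_cohort):
        matrix, _, gene_table, _, _ = challenge_cohort
        assert len(filter_low_abundance(matrix, gene_table)) == 600


class TestCombat:
    def _uniform_shift(self, delta=3.0, G=60, n=16, seed=0):
        rng = np.random.default_rng(seed)
        mu = rng.uniform(4, 9, G)
        z = rng.normal(0, 1, n)  # shared noise pattern -> constant standardized effect
        A = mu[:, None] + z[None, :]
        return _matrix(np.hstack([A, A + delta])), ["A"] * n + ["B"] * n, A

    def test_uniform_planted_shift_removed_exactly(self):
        mx, batches, _ = self._uniform_shift()
        adj = combat_adjust(mx, batches).values.to_numpy()
        resid = np.abs(adj[:, :16].mean(axis=1) - adj[:, 16:].mean(axis=1))
        assert resid.max() < 1e-6

    def test_varying_shift_strongly_reduced(self):
        rng = np.random.default_rng(1)
        G, n = 80, 20
        delta = rng.normal(0, 2, G)
        A = rng.normal(6, 1, (G, n))
        B = rng.normal(6, 1, (G, n)) + delta[:, None]
        mx = _matrix(np.hstack([A, B]))
        adj = combat_adjust(mx, ["A"] * n + ["B"] * n).values.to_numpy()
        resid = np.abs(adj[:, :n].mean(axis=1) - adj[:, n:].mean(axis=1))
        pre = np.abs(delta)
        assert resid.max() < 0.15 * pre.max()
        assert resid.mean() < 0.15 * pre.mean()

    def test_identical_batches_keep_batch_means_equal(self):
        mx, batches, A = self._uniform_shift(delta=0.0)
        adj = combat_adjust(mx, batches).values.to_numpy()
        resid = np.abs(adj[:, :16].mean(axis=1) - adj[:, 16:].mean(axis=1))
        assert resid.max() < 1e-8

    def test_group_covariate_protected(self):
        rng = np.random.default_rng(2)
        G, n = 50, 20
        groups = np.array((["x"] * (n // 2) + ["y"] * (n // 2)) * 2)
        A = rng.normal(6, 1, (G, 2 * n))
        A[:10, groups == "y"] += 2.0  # biological effect aligned within batches
        A[:, n:] += 1.5  # batch shift
        mx = _matrix(A)
        adj = combat_adjust(mx, ["A"] * n + ["B"] * n, covariate_groups=groups)
        av = adj.values.to_numpy()
        effect = av[:10][:, groups == "y"].mean() - av[:10][:, groups == "x"].mean()
        assert effect == pytest.approx(2.0, abs=0.4)

    def test_singleton_batch_rejected(self):
        mx = _matrix(np.random.default_rng(0).normal(size=(5, 5)))
        with pytest.raises(ValueError, match="single sample"):
            combat_adjust(mx, ["A", "A", "A", "A", "B"])

    def test_constant_gene_passed_through_with_warning(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(5, 1, (10, 12))
        vals[0] = 7.0  # constant everywhere
        mx = _matrix(vals)
        with pytest.warns(UserWarning, match="constant"):
            adj = combat_adjust(mx, ["A"] * 6 + ["B"] * 6)
        np.testing.assert_allclose(adj.values.to_numpy()[0], 7.0)


class TestSexImputation:
    def _data(self, n=100, y_effect=5.0, seed=0, extra_genes=0):
        rng = np.random.default_rng(seed)
        male = rng.random(n) < 0.5
        y_genes = ["RPS4Y1", "DDX3Y", "KDM5D"]
        vals = rng.normal(0, 1, (3 + extra_genes, n))
        vals[:3, male] += y_effect
        genes = y_genes + [f"auto{i}" for i in range(extra_genes)]
        gt = _gene_table(genes, chrom=["Y"] * 3 + ["1"] * extra_genes)
        return _matrix(vals, genes=genes), gt, male

    def test_planted_truth_recovered(self):
        mx, gt, male = self._data()
        res = impute_sex(mx, gt, seed=0)
        assert (res.labels == np.where(male, "male", "female")).all()

    def test_sample_permutation_invariance(self):
        mx, gt, male = self._data(seed=1)
        res = impute_sex(mx, gt, seed=0)
        perm = np.random.default_rng(9).permutation(mx.shape[1])
        mx2 = ExpressionMatrix(mx.values.iloc[:, perm], mx.value_kind)
        res2 = impute_sex(mx2, gt, seed=0)
        assert (res2.labels.loc[res.labels.index] == res.labels).all()

    def test_non_y_genes_do_not_change_labels(self):
        mx, gt, male = self._data(seed=2)
        res = impute_sex(mx, gt, seed=0)
        mx2, gt2, _ = self._data(seed=2, extra_genes=20)
        res2 = impute_sex(mx2, gt2, seed=0)
        assert (res2.labels == res.labels).all()

    def test_identical_samples_degenerate(self):
        genes = ["RPS4Y1", "DDX3Y"]
        mx = _matrix(np.ones((2, 6)), genes=genes)
        gt = _gene_table(genes, chrom="Y")
        with pytest.raises(ValueError, match="degenerate"):
            impute_sex(mx, gt)

    def test_too_few_y_genes(self):
        mx = _matrix(np.random.default_rng(0).normal(size=(1, 6)), genes=["RPS4Y1"])
        gt = _gene_table(["RPS4Y1"], chrom="Y")
        with pytest.raises(ValueError, match=">=2"):
            impute_sex(mx, gt)
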