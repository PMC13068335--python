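"""Normalization, pseudobulk averaging, and moderated differential expression."""

import anndata as ad
import numpy as np
import pandas as pd
import pytest
from scipy import sparse

from larconnect.pseudobulk import (
    de_by_celltype,
    moderated_fit,
    normalize_cells,
    pseudobulk_mean,
    significant_sets,
    squeeze_var,
)


def _adata(counts, **obs_cols):
    counts = np.asarray(counts, dtype=float)
    obs = pd.DataFrame(obs_cols, index=[f"c{i}" for i in range(counts.shape[0])])
    var = pd.DataFrame(index=pd.Index([f"g{j}" for j in range(counts.shape[1])], name="gene"))
    return ad.AnnData(X=sparse.csr_matrix(counts), obs=obs, var=var)


class TestNormalizeCells:
    def test_formula_and_zero_preservation(self):
        adata = _adata([[10, 990, 0]], cell_type=["T"], sample_id=["s"])
        out = normalize_cells(adata, scale_factor=1e4)
        x = out.X.toarray()[0]
        assert x[0] == pytest.approx(np.log2(10 / 1000 * 1e4 + 1))
        assert x[0] == pytest.approx(6.658, abs=1e-3)
        assert x[2] == 0.0

    def test_cell_depth_invariance(self):
        base = np.array([[5, 20, 0, 75]])
        a = normalize_cells(_adata(base, cell_type=["T"], sample_id=["s"]), 1e4)
        b = normalize_cells(_adata(base * 2, cell_type=["T"], sample_id=["s"]), 1e4)
        np.testing.assert_allclose(a.X.toarray(), b.X.toarray(), atol=1e-12)

    def test_zero_library_cell_listed(self):
        adata = _adata([[1, 1], [0, 0]], cell_type=["T", "T"], sample_id=["s", "s"])
        with pytest.raises(ValueError, match="c1"):
            normalize_cells(adata)

    def test_default_scale_is_median_library(self):
        adata = _adata([[10, 0], [30, 10], [50, 50]], cell_type=list("TTT"),
                       sample_id=list("sss"))
        out = normalize_cells(adata)
        assert out.uns["scale_factor"] == 40.0


class TestPseudobulk:
    def test_stratum_mean_matches_groupby_oracle(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 20, size=(30, 8)).astype(float)
        cts = rng.choice(["T", "B"], 30)
        samples = rng.choice(["s1", "s2"], 30)
        adata = _adata(counts, cell_type=cts, sample_id=samples)
        pb = pseudobulk_mean(adata, min_cells=1)
        df = pd.DataFrame(counts, columns=[f"g{j}" for j in range(8)])
        df["ct"], df["s"] = cts, samples
        oracle = df.groupby(["ct", "s"]).mean()
        for (ct, s) in oracle.index:
            np.testing.assert_allclose(
                pb.values[(ct, s)].to_numpy(), oracle.loc[(ct, s)].to_numpy(),
                atol=1e-12,
            )

    def test_three_cell_mean(self):
        adata = _adata([[1], [2], [3]], cell_type=["T"] * 3, sample_id=["s"] * 3)
        pb = pseudobulk_mean(adata, min_cells=1)
        assert pb.values[("T", "s")].iloc[0] == 2.0

    def test_single_cell_stratum_identity(self):
        adata = _adata([[7]], cell_type=["T"], sample_id=["s"])
        pb = pseudobulk_mean(adata, min_cells=1)
        assert pb.values[("T", "s")].iloc[0] == 7.0
        assert pb.n_cells[("T", "s")] == 1

    def test_small_strata_dropped(self):
        adata = _adata(
            np.ones((5, 2)),
            cell_type=["T"] * 4 + ["B"],
            sample_id=["s"] * 5,
        )
        pb = pseudobulk_mean(adata, min_cells=2)
        assert list(pb.values.columns) == [("T", "s")]


class TestModeratedFit:
    def _data(self, G=200, n=8, effect_genes=0, effect=1.0, seed=0):
        rng = np.random.default_rng(seed)
        Y = rng.normal(5, 1, (G, n)) * rng.uniform(0.6, 1.8, G)[:, None]
        cond = np.array([0.0] * (n // 2) + [1.0] * (n // 2))
        Y[:effect_genes, cond == 1] += effect
        design = pd.DataFrame({"intercept": np.ones(n), "cond": cond})
        return pd.DataFrame(Y, index=[f"g{i}" for i in range(G)]), design

    def test_matches_limma_reference(self):
        """Frozen reference values from limma::eBayes (trend=FALSE) on the
        same deterministic fixture."""
        rng = np.random.default_rng(42)
        G, n = 80, 8
        Y = rng.normal(6, 1, (G, n)) * rng.uniform(0.5, 2.0, G)[:, None]
        Y[:10, 4:] += 1.5
        design = pd.DataFrame({"intercept": np.ones(n), "cond": [0.0] * 4 + [1.0] * 4})
        fit = moderated_fit(pd.DataFrame(Y), design, coefs=["cond"], trend=False)
        assert fit.df_prior == pytest.approx(4.3224844692, abs=1e-6)
        expected_t = {0: -0.2620217801, 1: 1.7348151726, 2: 1.5432126322,
                      9: 2.1889218398, 39: -1.3180281343, 79: 1.2513525732}
        for g, t in expected_t.items():
            assert fit.t["cond"].iloc[g] == pytest.approx(t, abs=1e-8)
        assert fit.p["cond"].iloc[9] == pytest.approx(0.05261737616, abs=1e-9)

    def test_no_shrinkage_limit_is_ordinary_t(self):
        Y, design = self._data()
        fit = moderated_fit(Y, design, coefs=["cond"], trend=False, df_prior=0.0)
        # ordinary t by hand for one gene
        y = Y.iloc[3].to_numpy()
        a, b = y[:4], y[4:]
        se = np.sqrt((np.var(a, ddof=1) * 3 + np.var(b, ddof=1) * 3) / 6 * (1 / 4 + 1 / 4))
        t_ref = (b.mean() - a.mean()) / se
        assert fit.t["cond"].iloc[3] == pytest.approx(t_ref, rel=1e-10)

    def test_complete_pooling_limit_uses_common_variance(self):
        Y, design = self._data()
        fit = moderated_fit(Y, design, coefs=["cond"], trend=False, df_prior=np.inf)
        assert fit.s2_post.std() / fit.s2_post.mean() < 1e-12

    def test_moderated_t_interpolates_monotonically(self):
        Y, design = self._data(G=50)
        t_by_prior = [
            moderated_fit(Y, design, coefs=["cond"], trend=False, df_prior=d0).t["cond"]
            for d0 in (0.0, 2.0, 10.0, np.inf)
        ]
        fit0 = moderated_fit(Y, design, coefs=["cond"], trend=False, df_prior=0.0)
        s2 = fit0.s2_post
        # genes with variance above the pool shrink downward -> |t| grows, and
        # vice versa; check monotone |t| along the d0 path per gene
        pooled = moderated_fit(Y, design, coefs=["cond"], trend=False, df_prior=np.inf).s2_post
        for g in Y.index[:20]:
            seq = [abs(t[g]) for t in t_by_prior]
            if s2[g] > pooled[g]:
                assert all(a <= b + 1e-12 for a, b in zip(seq, seq[1:]))
            else:
                assert all(a >= b - 1e-12 for a, b in zip(seq, seq[1:]))

    def test_trend_prior_tracks_mean_variance_relation(self):
        rng = np.random.default_rng(1)
        G, n = 300, 8
        avg = rng.uniform(1, 10, G)
        noise_sd = 0.2 + 1.0 / np.sqrt(avg)  # variance decreasing with abundance
        Y = avg[:, None] + rng.normal(0, 1, (G, n)) * noise_sd[:, None]
        design = pd.DataFrame({"intercept": np.ones(n), "cond": [0.0] * 4 + [1.0] * 4})
        fit = moderated_fit(pd.DataFrame(Y), design, coefs=["cond"], trend=True)
        s2_post = fit.s2_post.to_numpy()
        low, high = avg < np.median(avg), avg >= np.median(avg)
        assert s2_post[low].mean() > s2_post[high].mean()

    def test_rank_deficient_design_rejected(self):
        Y, design = self._data()
        design["dup"] = design["cond"]
        with pytest.raises(ValueError, match="rank"):
            moderated_fit(Y, design, coefs=["cond"])

    def test_constant_gene_flagged(self):
        Y, design = self._data(G=20)
        Y.iloc[0] = 3.0
        fit = moderated_fit(Y, design, coefs=["cond"], trend=False)
        assert fit.excluded == ["g0"]
        assert np.isnan(fit.t["cond"].iloc[0])

    def test_null_fdr_controlled(self):
        """With no planted effect, the q<0.20 flag rate stays near nominal."""
        rates = []
        for seed in range(5):
            Y, design = self._data(G=400, seed=seed)
            fit = moderated_fit(Y, design, coefs=["cond"], trend=False)
            from statsmodels.stats.multitest import multipletests

            q = multipletests(fit.p["cond"], method="fdr_bh")[1]
            rates.append((q < 0.20).mean())
        assert np.mean(rates) <= 0.25


class TestDeByCelltype:
    def test_planted_celltype_restricted_upregulation(self, small_biopsy):
        adata, truth = small_biopsy
        panel = truth.extra["panel"]
        de = de_by_celltype(adata, panel)
        cd8 = de.table[de.table["cell_type"] == "CD8 T"]
        up = set(truth.celltype_sets["CD8 T"]["up"])
        hits = cd8[cd8["gene"].isin(up) & cd8["significant"] & (cd8["log2fc"] > 0)]
        assert len(hits) / len(up) >= 0.8
        # the same genes stay quiet in the allergic-control group
        de_ctrl = de_by_celltype(adata, panel, group="allergic_control")
        ctrl_cd8 = de_ctrl.table[de_ctrl.table["cell_type"] == "CD8 T"]
        flagged = ctrl_cd8[ctrl_cd8["gene"].isin(up) & ctrl_cd8["significant"]]
        assert len(flagged) / len(up) <= 0.10

    def test_log2fc_sign_matches_mean_difference(self, small_biopsy):
        adata, truth = small_biopsy
        de = de_by_celltype(adata, truth.extra["panel"])
        norm = normalize_cells(adata[np.asarray(adata.obs["group"] == "allergic_asthma")].copy())
        pb = pseudobulk_mean(norm)
        for _, row in de.table.sample(25, random_state=0).iterrows():
            sub = pb.values[row.cell_type].loc[row.gene]
            conds = pb.meta.loc[row.cell_type]["condition"]
            diff = sub[(conds == "allergen").to_numpy()].mean() - sub[(conds == "baseline").to_numpy()].mean()
            assert np.sign(row.log2fc) == np.sign(diff) or diff == 0

    def test_counts_table_consistent_with_flags(self, small_biopsy):
        adata, truth = small_biopsy
        de = de_by_celltype(adata, truth.extra["panel"])
        sig = de.table[de.table["significant"]]
        for ct, row in de.counts.iterrows():
            sub = sig[sig["cell_type"] == ct]
            assert row["n_up"] == (sub["log2fc"] > 0).sum()
            assert row["n_down"] == (sub["log2fc"] < 0).sum()

    def test_single_condition_celltype_skipped(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 10, size=(160, 20)).astype(float) + 1
        obs = {
            "cell_type": ["T"] * 80 + ["B"] * 80,
            "sample_id": (["s1"] * 20 + ["s2"] * 20 + ["s3"] * 20 + ["s4"] * 20) * 2,
            "condition": (["baseline"] * 40 + ["allergen"] * 40) + ["baseline"] * 80,
            "group": ["g"] * 160,
        }
        adata = _adata(counts, **obs)
        de = de_by_celltype(adata, [f"g{j}" for j in range(20)], group="g")
        assert set(de.table["cell_type"]) == {"T"}

    def test_significant_sets_split_by_sign(self, small_biopsy):
        adata, truth = small_biopsy
        de = de_by_celltype(adata, truth.extra["panel"])
        up, down = significant_sets(de)
        sig = de.table[de.table["significant"]]
        for ct, genes in up.items():
            rows = sig[(sig["cell_type"] == ct) & sig["gene"].isin(genes)]
            assert (rows["log2fc"] > 0).all()


def test_bh_adjustment_matches_enumeration_oracle():
    from statsmodels.stats.multitest import multipletests

    from conftest import bh_enumeration

    p = np.array([0.01, 0.02, 0.04])
    q = multipletests(p, method="fdr_bh")[1]
    np.testing.assert_allclose(q, [0.03, 0.03, 0.04], atol=1e-12)
    np.testing.assert_allclose(q, bh_enumeration(p), atol=1e-12)
    rng = np.random.default_rng(0)
    for _ in range(10):
        p = rng.random(rng.integers(2, 40))
        np.testing.assert_allclose(
            multipletests(p, method="fdr_bh")[1], bh_enumeration(p), atol=1e-12
        )
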