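"""CPM filtering, TMM, logCPM, moderated t and the DEG x DMG table."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from meripdm.core_io import CountMatrix, SampleDesign
from meripdm.expression_de import (
    cpm_filter,
    fit_f_dist,
    intersect_deg_dmg,
    log_cpm,
    moderated_t,
    nb_de,
    tmm_factors,
)
from meripdm.peak_merge import DmRegion


def _cm(mat, prefix="g"):
    mat = np.asarray(mat, float)
    return CountMatrix([f"{prefix}{i}" for i in range(mat.shape[0])],
                       [f"s{j}" for j in range(mat.shape[1])], mat)


class TestCpm:
    def test_cpm_value(self):
        # 2 reads in a 1000-read library -> CPM 2000
        cm = _cm([[2], [998]])
        from meripdm.expression_de import cpm
        assert cpm(cm.counts)[0, 0] == pytest.approx(2000.0)

    def test_filter_rule_boundary(self):
        """CPM (1.2, 1.2, 0.8) under rule (>1 in >=3) is removed; a third
        sample above 1 keeps the gene."""
        libs = 1_000_000.0
        removed = np.array([1.2, 1.2, 0.8])
        kept_gene = np.array([1.2, 1.2, 1.2])
        filler = libs - removed - kept_gene
        cm = CountMatrix(["removed", "kept", "filler"], ["s1", "s2", "s3"],
                         np.vstack([removed, kept_gene, filler]),
                         allow_fractional=True)
        kept = cpm_filter(cm, min_cpm=1.0, min_samples=3)
        assert "removed" not in kept
        assert "kept" in kept

    def test_filter_matches_definition_oracle(self):
        rng = np.random.default_rng(0)
        mat = rng.poisson(3, size=(200, 5)).astype(float)
        mat[mat.sum(axis=1) == 0, 0] = 1
        cm = _cm(mat)
        kept = set(cpm_filter(cm, min_cpm=1.0, min_samples=3))
        c = mat / mat.sum(axis=0, keepdims=True) * 1e6
        expected = {f"g{i}" for i in range(200) if (c[i] > 1).sum() >= 3}
        assert kept == expected

    def test_min_samples_exceeding_count_rejected(self):
        with pytest.raises(ValueError):
            cpm_filter(_cm([[1, 1]]), min_samples=3)


class TestTmm:
    def test_identical_libraries(self):
        mat = np.tile(np.arange(1, 101, dtype=float)[:, None], (1, 4))
        np.testing.assert_allclose(tmm_factors(_cm(mat)), 1.0)

    def test_pure_depth_scaling_absorbed_by_libsize(self):
        """A library equal to the reference scaled by 2 has factor 1: all
        M-values are 0 once library size is divided out."""
        rng = np.random.default_rng(1)
        ref = rng.poisson(50, size=300).astype(float) + 1
        mat = np.column_stack([ref, ref * 2, ref, ref])
        f = tmm_factors(_cm(mat))
        np.testing.assert_allclose(f, 1.0, atol=1e-12)

    def test_trim_restores_non_outlier_genes_to_parity(self):
        """5% of genes hugely up in one sample: the double trimming
        excludes them, so the factor-corrected effective library size
        brings the *other* genes back to parity within 2%."""
        rng = np.random.default_rng(2)
        base = rng.poisson(100, size=400).astype(float) + 1
        mat = np.column_stack([base, base.copy(), base.copy(), base.copy()])
        idx = rng.choice(400, size=20, replace=False)
        mat[idx, 1] *= 50
        f = tmm_factors(_cm(mat))
        lib = mat.sum(axis=0)
        eff = lib * f
        other = np.setdiff1d(np.arange(400), idx)
        # non-outlier genes have identical raw counts across samples, so the
        # spiked sample's effective libsize must match the others'
        assert abs(eff[1] / eff[0] - 1) < 0.02
        norm = mat[other, 1] / eff[1] * eff[0]
        np.testing.assert_allclose(norm, mat[other, 0], rtol=0.02)


class TestLogCpm:
    def test_zero_count_value(self):
        cm = _cm(np.vstack([[0.0], [999_999.0]]))
        lc = log_cpm(cm, prior=0.5)
        expected = np.log2(0.5 / (1e6 + 1) * 1e6)
        assert lc[0, 0] == pytest.approx(expected, abs=1e-5)

    def test_doubling_large_count_adds_one(self):
        cm = _cm(np.array([[1000.0, 2000.0], [1e6, 1e6]]))
        lc = log_cpm(cm)
        # same effective libsizes are not equal, so compare within tolerance
        assert lc[0, 1] - lc[0, 0] == pytest.approx(1.0, abs=0.01)

    def test_monotone_in_count(self):
        cm = _cm(np.array([[0.0, 5.0, 50.0], [100.0, 100.0, 100.0]]))
        lc = log_cpm(CountMatrix(cm.feature_ids, cm.sample_ids,
                                 np.column_stack([cm.counts[:, 0]] * 3)))
        # increasing the count within one library increases logCPM
        vals = [log_cpm(_cm([[c], [100.0]]))[0, 0] for c in (0, 5, 50)]
        assert vals[0] < vals[1] < vals[2]


class TestModeratedT:
    def _null(self, G=2000, n=10, seed=5):
        rng = np.random.default_rng(seed)
        X = np.column_stack([np.ones(n), np.repeat([0.0, 1.0], n // 2)])
        Y = rng.normal(size=(G, n))
        return Y, X

    def test_d0_zero_equals_ordinary_t(self):
        Y, X = self._null(G=200)
        res = moderated_t(Y, X, [f"g{i}" for i in range(200)], d0_override=0.0)
        # ordinary two-sample equal-variance t oracle
        a, b = Y[:, :5], Y[:, 5:]
        sp = ((a.var(axis=1, ddof=1) + b.var(axis=1, ddof=1)) / 2)
        t_ord = (b.mean(axis=1) - a.mean(axis=1)) / np.sqrt(sp * (2 / 5))
        np.testing.assert_allclose(res.table["t"].to_numpy(), t_ord, atol=1e-10)

    def test_d0_infinite_pools_variances(self):
        Y, X = self._null(G=100)
        res = moderated_t(Y, X, [f"g{i}" for i in range(100)], d0_override=np.inf)
        assert res.table["s2_post"].nunique() == 1

    def test_global_null_type_one_error(self):
        """Gaussian global null, 2000 genes: empirical type-I at p<0.05
        within [0.035, 0.065]."""
        Y, X = self._null()
        res = moderated_t(Y, X, [f"g{i}" for i in range(2000)])
        frac = (res.table["pvalue"] < 0.05).mean()
        assert 0.035 <= frac <= 0.065

    def test_prior_estimation_recovers_heterogeneous_variances(self):
        """Variances drawn from a scaled inverse-chi-square: fitted d0 is
        finite and s0^2 near the prior scale."""
        rng = np.random.default_rng(7)
        G, n, d0_true, s02_true = 3000, 8, 6.0, 2.0
        s2g = s02_true * d0_true / stats.chi2.rvs(d0_true, size=G, random_state=1)
        Y = rng.normal(scale=np.sqrt(s2g)[:, None], size=(G, n))
        X = np.column_stack([np.ones(n), np.repeat([0.0, 1.0], n // 2)])
        res = moderated_t(Y, X, [f"g{i}" for i in range(G)])
        assert 3 < res.d0 < 12
        assert res.s02 == pytest.approx(s02_true, rel=0.2)


class TestNbDe:
    def test_planted_genes_recovered_with_correct_sign(self, paired_design):
        rng = np.random.default_rng(8)
        G = 300
        base = np.exp(rng.normal(np.log(200), 0.4, size=G))
        lfc = np.zeros(G)
        lfc[:30] = rng.choice([-1.0, 1.0], size=30)
        input_ids = paired_design.sample_ids(assay="INPUT")
        info = paired_design.subset(assay="INPUT").table.reset_index(drop=True)
        r = 10.0
        Y = np.empty((G, len(input_ids)))
        for j in range(len(input_ids)):
            case = 1.0 if info.loc[j, "condition"] == "CASE" else 0.0
            mu = base * 2.0 ** (lfc * case)
            Y[:, j] = rng.negative_binomial(r, r / (r + mu))
        cm = CountMatrix([f"g{i}" for i in range(G)], input_ids, Y)
        res = nb_de(cm, paired_design, assay="INPUT")
        sig = res[res["qvalue"] < 0.05]
        planted = sig[sig["feature_id"].isin([f"g{i}" for i in range(30)])]
        assert len(planted) >= 20
        for _, row in planted.iterrows():
            i = int(row["feature_id"][1:])
            assert np.sign(row["logFC"]) == np.sign(lfc[i])


class TestIntersection:
    def _dm(self, gid, direction, fdr=0.01):
        return DmRegion(gene_id=gid, bin_start=0, bin_end=0, tx_start=0, tx_end=50,
                        direction=direction, bin_pvalues=[0.001], mean_log2fc=1.0,
                        combined_p=0.001, fdr=fdr)

    def test_single_hyper_up_gene(self):
        de = pd.DataFrame({"gene_id": ["a"], "logFC": [2.0], "qvalue": [0.001]})
        out = intersect_deg_dmg(de, [self._dm("a", "hyper")])
        cell = out[(out["methylation"] == "hyper") & (out["expression"] == "up")]
        assert cell["n_genes"].iloc[0] == 1
        assert out["n_genes"].sum() == 1

    def test_disjoint_sets_all_zero(self):
        de = pd.DataFrame({"gene_id": ["a"], "logFC": [2.0], "qvalue": [0.001]})
        out = intersect_deg_dmg(de, [self._dm("b", "hypo")])
        assert out["n_genes"].sum() == 0

    def test_matches_set_algebra_oracle(self):
        rng = np.random.default_rng(9)
        genes = [f"g{i}" for i in range(50)]
        de = pd.DataFrame({
            "gene_id": genes,
            "logFC": rng.normal(size=50),
            "qvalue": rng.random(50) * 0.1,
        })
        regions = [self._dm(g, rng.choice(["hyper", "hypo"]), rng.random() * 0.1)
                   for g in rng.choice(genes, size=30)]
        out = intersect_deg_dmg(de, regions, de_q=0.05, dm_q=0.05)
        for _, row in out.iterrows():
            meth = {r.gene_id for r in regions
                    if r.fdr < 0.05 and r.direction == row["methylation"]}
            expr_sign = 1 if row["expression"] == "up" else -1
            expr = set(de[(de["qvalue"] < 0.05)
                          & (np.sign(de["logFC"]) == expr_sign)]["gene_id"])
            assert row["n_genes"] == len(meth & expr)


class TestFitFDist:
    def test_underdispersed_variances_give_infinite_prior_df(self):
        s2 = np.full(100, 2.0)
        d0, s02 = fit_f_dist(s2, np.full(100, 6.0))
        assert np.isinf(d0)
        assert s02 == pytest.approx(2.0, rel=0.3)
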