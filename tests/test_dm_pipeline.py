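"""Normalization, input adjustment, filtering and the NB Wald test."""

import numpy as np
import pandas as pd
import pytest

from meripdm.core_io import CountMatrix, SampleDesign, ValidationError
from meripdm.dm_pipeline import (
    adjust_ip_by_input,
    build_design_matrix,
    estimate_size_factors,
    filter_bins,
    nb_wald_test,
    pca,
    remove_batch_for_pca,
)


class TestSizeFactors:
    def test_hand_example(self):
        """Features (100,200) and (50,100): geomeans 141.42 / 70.71, both
        per-sample ratios 1/sqrt2 and sqrt2; rescaling is a no-op."""
        f = estimate_size_factors(np.array([[100.0, 200.0], [50.0, 100.0]]))
        np.testing.assert_allclose(f, [1 / np.sqrt(2), np.sqrt(2)], rtol=1e-12)

    def test_identical_columns_give_unit_factors(self):
        mat = np.tile(np.arange(1, 11, dtype=float)[:, None], (1, 4))
        np.testing.assert_allclose(estimate_size_factors(mat), 1.0)

    def test_recovers_simulated_library_ratios(self):
        rng = np.random.default_rng(2)
        base = rng.gamma(3, 50, size=500)
        true = np.array([0.5, 1.0, 2.0, 1.5])
        true = true / np.exp(np.mean(np.log(true)))
        mat = rng.poisson(base[:, None] * true[None, :]).astype(float)
        f = estimate_size_factors(mat)
        np.testing.assert_allclose(f, true, rtol=0.05)

    def test_fallback_without_allpositive_feature(self, caplog):
        mat = np.array([[10.0, 0.0], [0.0, 10.0]])
        f = estimate_size_factors(mat)
        np.testing.assert_allclose(f, 1.0)


class TestAdjustment:
    def _setup(self, paired_design, input_counts):
        bins = CountMatrix(["g1:0", "g1:1"], paired_design.sample_ids(assay="IP"),
                           np.full((2, 12), 100.0))
        genes = CountMatrix(["g1"], paired_design.sample_ids(assay="INPUT"),
                            np.asarray(input_counts, float).reshape(1, -1))
        return bins, genes

    def test_equal_inputs_are_identity(self, paired_design):
        bins, genes = self._setup(paired_design, [200.0] * 12)
        adj = adjust_ip_by_input(bins, genes, paired_design,
                                 ip_factors=np.ones(12), input_factors=np.ones(12))
        np.testing.assert_allclose(adj.counts, 100.0)

    def test_double_expression_halves_ip(self, paired_design):
        """A subject whose input gene level is 2x the cross-sample mean has
        its adjusted IP scaled by mean/(2x) (pseudo-counts shift slightly)."""
        inputs = [200.0] * 12
        inputs[0] = 400.0  # first INPUT sample
        bins, genes = self._setup(paired_design, inputs)
        adj = adjust_ip_by_input(bins, genes, paired_design,
                                 ip_factors=np.ones(12), input_factors=np.ones(12))
        first_ip = genes.sample_ids[0].replace("_INPUT", "_IP")
        j = adj.sample_ids.index(first_ip)
        mean_rel = np.mean(np.array(inputs) + 1.0)
        expected = 100.0 / ((400.0 + 1.0) / mean_rel)
        assert adj.counts[0, j] == pytest.approx(expected)
        assert adj.counts[0, j] == pytest.approx(50.0, rel=0.1)

    def test_missing_input_partner_raises(self, paired_design):
        t = paired_design.table
        broken = SampleDesign(t[t["sample_id"] != "S0_CASE_INPUT"].copy())
        bins, genes = self._setup(paired_design, [200.0] * 12)
        genes = genes.subset_samples(broken.sample_ids(assay="INPUT"))
        with pytest.raises(ValidationError, match="INPUT"):
            adjust_ip_by_input(bins, genes, broken)


class TestFilters:
    def _adjusted(self, paired_design, rows):
        ids = [f"g{i}:0" for i in range(len(rows))]
        return CountMatrix(ids, paired_design.sample_ids(assay="IP"),
                           np.asarray(rows, float), allow_fractional=True)

    def test_low_in_both_groups_removed(self, paired_design):
        # columns alternate CTRL, CASE per subject
        both_low = [9.0] * 12
        one_low = [9.0, 11.0] * 6
        kept = [20.0] * 12
        adj = self._adjusted(paired_design, [both_low, one_low, kept])
        res = filter_bins(adj, paired_design, enrich_ratio=None)
        assert res.flags.tolist() == ["low_count", "kept", "kept"]

    def test_rule_enumeration_oracle(self, paired_design):
        """Kept set of a 6-bin toy table equals brute-force application of
        the low-count and enrichment rules."""
        rng = np.random.default_rng(4)
        rows = rng.uniform(0, 40, size=(6, 12))
        adj = self._adjusted(paired_design, rows)
        genes = CountMatrix([f"g{i}" for i in range(6)],
                            paired_design.sample_ids(assay="INPUT"),
                            np.full((6, 12), 600.0))
        widths = {f: 50 for f in adj.feature_ids}
        glens = {f"g{i}": 500 for i in range(6)}
        res = filter_bins(adj, paired_design, genes, widths, glens,
                          min_mean=10, enrich_ratio=1.0,
                          input_factors=np.ones(12))
        ctrl_cols = [j for j, s in enumerate(adj.sample_ids) if "CTRL" in s]
        case_cols = [j for j, s in enumerate(adj.sample_ids) if "CASE" in s]
        for i, f in enumerate(adj.feature_ids):
            mc, mt = rows[i, ctrl_cols].mean(), rows[i, case_cols].mean()
            if mc < 10 and mt < 10:
                expect = "low_count"
            elif (mc / 50) / (600.0 / 500) < 1 and (mt / 50) / (600.0 / 500) < 1:
                expect = "not_enriched"
            else:
                expect = "kept"
            assert res.flags[f] == expect

    def test_negative_min_mean_rejected(self, paired_design):
        adj = self._adjusted(paired_design, [[20.0] * 12])
        with pytest.raises(ValueError):
            filter_bins(adj, paired_design, min_mean=-1, enrich_ratio=None)


class TestNbWald:
    def test_doubling_recovered_at_low_dispersion(self, paired_design):
        """CASE counts exactly 2x CTRL at large means: beta_hat -> 1 log2
        unit as alpha -> 0."""
        ctrl, case = 10000.0, 20000.0
        row = [ctrl, case] * 6
        cm = CountMatrix(["g:0"], paired_design.sample_ids(assay="IP"),
                         np.array([row]))
        res = nb_wald_test(cm, paired_design)
        assert res.table.loc[0, "log2fc"] == pytest.approx(1.0, abs=1e-3)
        assert res.table.loc[0, "pvalue"] < 1e-6

    def test_null_type_one_error_calibrated(self, nb_paired_counts, paired_design):
        """Global-null NB counts (2000 bins, alpha=0.1, 6 pairs): empirical
        type-I error at p<0.05 in [0.035, 0.065]."""
        res = nb_wald_test(nb_paired_counts, paired_design)
        p = res.table["pvalue"].dropna().to_numpy()
        assert len(p) > 1900
        frac = np.mean(p < 0.05)
        assert 0.035 <= frac <= 0.065

    def test_paired_beats_unpaired_with_subject_effects(self, paired_design):
        """With strong subject effects the paired design yields smaller
        median condition SE than ignoring pairing."""
        rng = np.random.default_rng(9)
        B = 300
        mu0 = np.full(B, 80.0)
        subj = rng.normal(0, 0.8, size=(B, 6))
        ip_ids = paired_design.sample_ids(assay="IP")
        Y = np.empty((B, 12))
        info = paired_design.subset(assay="IP").table.reset_index(drop=True)
        r = 10.0
        for j in range(12):
            si = int(info.loc[j, "subject"][1:])
            mu = mu0 * np.exp(subj[:, si])
            Y[:, j] = rng.negative_binomial(r, r / (r + mu))
        cm = CountMatrix([f"g{i}:0" for i in range(B)], ip_ids, Y)
        paired = nb_wald_test(cm, paired_design, mode="paired")
        unpaired = nb_wald_test(cm, paired_design, mode="covariate", covariates=[])
        assert (paired.table["se"].median() < unpaired.table["se"].median())

    def test_all_zero_bin_is_na(self, paired_design):
        cm = CountMatrix(["g:0", "g:1"], paired_design.sample_ids(assay="IP"),
                         np.vstack([np.zeros(12), np.full(12, 30.0)]))
        res = nb_wald_test(cm, paired_design)
        assert np.isnan(res.table.loc[0, "pvalue"])
        assert np.isfinite(res.table.loc[1, "pvalue"])

    def test_rank_deficient_design_rejected(self, paired_design):
        t = paired_design.table.copy()
        t["dup"] = (t["condition"] == "CASE").astype(float)
        d = SampleDesign(t)
        with pytest.raises(ValidationError):
            build_design_matrix(d, "covariate", covariates=["dup"])


class TestBatchRemovalAndPca:
    def test_pure_subject_shift_removed_exactly(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=(20, 1))
        shift = np.array([0.0, 0.0, 3.0, 3.0])
        Y = base + shift[None, :]
        nuis = np.column_stack([(shift > 0).astype(float)])
        out = remove_batch_for_pca(Y, nuis)
        assert np.allclose(out.std(axis=1), 0, atol=1e-10)

    def test_orthogonal_condition_means_preserved(self):
        """Condition effect orthogonal to batch: group means unchanged."""
        rng = np.random.default_rng(2)
        n = 8
        cond = np.array([0, 1] * 4, float)
        batch = np.array([0, 0, 1, 1] * 2, float)
        Y = rng.normal(size=(30, n)) + 2.0 * cond[None, :] + 5.0 * batch[None, :]
        out = remove_batch_for_pca(Y, batch[:, None],
                                   retained=np.column_stack([np.ones(n), cond]))
        for y_in, y_out in zip(Y, out):
            din = y_in[cond == 1].mean() - y_in[cond == 0].mean()
            dout = y_out[cond == 1].mean() - y_out[cond == 0].mean()
            assert dout == pytest.approx(din, abs=1e-10)

    def test_idempotent(self):
        rng = np.random.default_rng(3)
        Y = rng.normal(size=(15, 6))
        nuis = rng.normal(size=(6, 2))
        once = remove_batch_for_pca(Y, nuis)
        twice = remove_batch_for_pca(once, nuis)
        np.testing.assert_allclose(once, twice, atol=1e-10)

    def test_pca_separates_shifted_clusters(self):
        rng = np.random.default_rng(4)
        a = rng.normal(0, 1, size=(10, 50))
        b = rng.normal(8, 1, size=(10, 50))
        scores, var = pca(np.vstack([a, b]), 2)
        pc1 = scores[:, 0]
        assert (pc1[:10].max() < pc1[10:].min()) or (pc1[:10].min() > pc1[10:].max())
        assert var[0] >= var[1]

    def test_pca_score_orthogonality_and_variance(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(12, 30))
        scores, var = pca(X, 5)
        gram = scores.T @ scores
        assert np.allclose(gram - np.diag(np.diag(gram)), 0, atol=1e-8)
        total = ((X - X.mean(0)) ** 2).sum() / (X.shape[0] - 1)
        assert var.sum() <= total + 1e-8

    def test_constant_matrix_rejected(self):
        with pytest.raises(ValueError):
            pca(np.ones((5, 5)), 2)
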