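"""Single-cell QC, normalization, HVG selection and beta-cell calling."""

import numpy as np
import pytest

from meripdm import synthetic_data as sd
from meripdm.core_io import CountMatrix
from meripdm.scrna_beta import (
    beta_de,
    cluster_normalize,
    gmm_beta_call,
    hvg_select,
    qc_filter,
)


def _cm(mat, gene_prefix="g"):
    mat = np.asarray(mat, float)
    genes = [f"{gene_prefix}{i}" for i in range(mat.shape[0])]
    cells = [f"c{j}" for j in range(mat.shape[1])]
    return CountMatrix(genes, cells, mat, allow_fractional=True)


class TestQc:
    def _matrix(self):
        """3 cells: exact-boundary pass, libsize-fail, mito-fail."""
        n_genes = 1200
        mat = np.zeros((n_genes, 3))
        # cell 0: libsize exactly 2000, exactly 1000 detected genes,
        # mito fraction exactly 10% (gene 0 is the mito gene)
        mat[0, 0] = 200
        mat[1:1000, 0] = 1
        mat[1:802, 0] += 1  # 200 + 999 + 801 = 2000
        # cell 1: libsize 1999 with 1000 genes, low mito -> fail on depth
        mat[1:1000, 1] = 2
        mat[1000, 1] = 1
        # cell 2: deep and complex but 15% mito -> fail on mito
        mat[1:1101, 2] = 3
        mat[0, 2] = 582  # 582 / (3300 + 582) = 0.15
        return CountMatrix([f"g{i}" for i in range(n_genes)],
                           ["pass", "lowlib", "himito"], mat)

    def test_boundary_values_pass(self):
        cm = self._matrix()
        res = qc_filter(cm, {"g0"})
        qc = res.cell_qc.set_index("cell_id")
        assert qc.loc["pass", "libsize"] == 2000
        assert qc.loc["pass", "n_genes"] == 1000
        assert qc.loc["pass", "mito_fraction"] == pytest.approx(0.10)
        assert bool(qc.loc["pass", "passed"])

    def test_failures_flagged(self):
        res = qc_filter(self._matrix(), {"g0"})
        qc = res.cell_qc.set_index("cell_id")
        assert not qc.loc["lowlib", "passed"]
        assert not qc.loc["himito", "passed"]

    def test_survivors_equal_rule_oracle(self):
        counts, _ = sd.simulate_scrna(n_cells=300, seed=5)
        mito = {g for g in counts.feature_ids if g.startswith("MT-")}
        res = qc_filter(counts, mito)
        mat = counts.counts
        lib = mat.sum(axis=0)
        ng = (mat > 0).sum(axis=0)
        mrows = [i for i, g in enumerate(counts.feature_ids) if g in mito]
        mf = mat[mrows].sum(axis=0) / lib
        expected = (lib >= 2000) & (ng >= 1000) & (mf <= 0.10)
        np.testing.assert_array_equal(res.cell_qc["passed"].to_numpy(), expected)
        assert res.filtered.sample_ids == [c for c, k in zip(counts.sample_ids, expected) if k]

    def test_zero_total_genes_dropped(self):
        counts, _ = sd.simulate_scrna(n_cells=200, seed=6)
        res = qc_filter(counts, {g for g in counts.feature_ids if g.startswith("MT-")})
        assert np.all(res.filtered.counts.sum(axis=1) > 0)


class TestClusterNormalize:
    def test_identical_cells_unit_factors(self):
        col = np.arange(1, 51, dtype=float)
        mat = np.tile(col[:, None], (1, 30))
        f, log_norm, _ = cluster_normalize(_cm(mat), n_clusters=1)
        np.testing.assert_allclose(f, 1.0)

    def test_scaled_pseudo_cell_recovers_constants(self):
        """Cells that are the pseudo-cell scaled by known constants yield
        factors proportional to those constants."""
        rng = np.random.default_rng(1)
        pseudo = rng.gamma(3, 10, size=80)
        consts = np.array([0.5, 1.0, 1.5, 2.0, 4.0] * 4)
        mat = pseudo[:, None] * consts[None, :]
        f, _, _ = cluster_normalize(_cm(mat), n_clusters=1)
        np.testing.assert_allclose(f, consts / consts.mean(), rtol=1e-10)

    def test_recovers_simulated_depths(self):
        """Estimated factors track true per-cell depths within 10% median
        absolute relative error."""
        rng = np.random.default_rng(2)
        base = np.exp(rng.normal(np.log(5), 0.7, size=400))
        depth = np.exp(rng.normal(0, 0.4, size=200))
        mat = rng.poisson(base[:, None] * depth[None, :]).astype(float)
        cm = _cm(mat)
        f, _, _ = cluster_normalize(cm, n_clusters=2, seed=0)
        rel = depth / depth.mean()
        err = np.abs(f - rel) / rel
        assert np.median(err) < 0.10


class TestHvg:
    def test_poisson_null_has_near_zero_biological_variance(self):
        rng = np.random.default_rng(3)
        base = np.exp(rng.uniform(np.log(2), np.log(50), size=500))
        mat = rng.poisson(np.tile(base[:, None], (1, 400))).astype(float)
        cm = _cm(mat)
        hv = hvg_select(cm, np.ones(400), n=100)
        # delta-method technical variance is approximate at low means, so
        # "near zero" allows a small residual relative to total variances ~0.5
        assert abs(hv["bio_var"].median()) < 0.05

    def test_overdispersed_genes_outrank_poisson_genes(self):
        rng = np.random.default_rng(4)
        n_cells = 300
        base = np.full(200, 10.0)
        lam = np.tile(base[:, None], (1, n_cells))
        # first 20 genes: lognormal extra variation
        lam[:20] *= np.exp(rng.normal(0, 0.8, size=(20, n_cells)))
        mat = rng.poisson(lam).astype(float)
        hv = hvg_select(_cm(mat), np.ones(n_cells), n=20)
        top = set(hv[hv["selected"]]["gene_id"])
        planted = {f"g{i}" for i in range(20)}
        assert len(top & planted) >= 19

    def test_requesting_too_many_genes_rejected(self):
        with pytest.raises(ValueError):
            hvg_select(_cm(np.ones((5, 10))), np.ones(10), n=6)


class TestGmm:
    def test_well_separated_modes_recovered(self):
        rng = np.random.default_rng(5)
        comp = rng.integers(0, 4, size=800)
        x = rng.normal(np.array([0.0, 2.0, 4.0, 6.0])[comp], 0.3)
        calls = gmm_beta_call(x, [f"c{i}" for i in range(800)], seed=0)
        truth_beta = comp >= 2
        agree = (calls["is_beta"].to_numpy() == truth_beta).mean()
        assert agree >= 0.99

    def test_component_ranking_by_mean(self):
        rng = np.random.default_rng(6)
        x = np.concatenate([rng.normal(0, 0.2, 100), rng.normal(5, 0.2, 100)])
        calls = gmm_beta_call(x, [f"c{i}" for i in range(200)], n_components=2, seed=1)
        assert (calls.loc[calls["insulin_log"] > 2.5, "component"] == 2).all()

    def test_k_below_two_rejected(self):
        with pytest.raises(ValueError):
            gmm_beta_call(np.zeros(100), [f"c{i}" for i in range(100)], n_components=1)

    def test_too_few_cells_rejected(self):
        with pytest.raises(ValueError):
            gmm_beta_call(np.zeros(10), [f"c{i}" for i in range(10)], n_components=4)


class TestBetaDe:
    def test_gene_below_min_cells_excluded(self):
        rng = np.random.default_rng(7)
        mat = rng.poisson(5, size=(30, 40)).astype(float)
        mat[0, :] = 0
        mat[0, :9] = 1  # expressed in 9 beta cells only
        cm = _cm(mat)
        log_norm = np.log2(mat + 1)
        is_beta = np.ones(40, bool)
        cond = np.array(["CTRL"] * 20 + ["CASE"] * 20)
        res = beta_de(cm, log_norm, is_beta, cond)
        assert "g0" not in set(res.table["gene_id"])

    def test_one_condition_rejected(self):
        mat = np.ones((20, 30))
        with pytest.raises(ValueError):
            beta_de(_cm(mat), np.log2(mat + 1), np.ones(30, bool),
                    np.array(["CTRL"] * 30))

    def test_planted_beta_de_sign_accuracy(self):
        counts, truth = sd.simulate_scrna(seed=11, fraction_de=0.1, de_lfc=1.5)
        mito = {g for g in counts.feature_ids if g.startswith("MT-")}
        qc = qc_filter(counts, mito)
        f, log_norm, _ = cluster_normalize(qc.filtered, seed=11)
        tl = truth.cell_labels.set_index("cell_id").loc[qc.filtered.sample_ids]
        res = beta_de(qc.filtered, log_norm, tl["is_beta"].to_numpy(),
                      tl["condition"].to_numpy())
        sig = res.table[res.table["qvalue"] < 0.05]
        planted = truth.de_genes.set_index("gene_id")
        hits = sig[sig["gene_id"].isin(planted.index)]
        assert len(hits) >= 0.5 * len(planted)
        for _, row in hits.iterrows():
            assert np.sign(row["logFC"]) == np.sign(planted.loc[row["gene_id"], "lfc"])
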