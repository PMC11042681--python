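"""Single-cell beta-cell identification and beta-cell differential expression.

QC drops cells with library size < 2000, fewer than 1000 detected genes,
or > 10% mitochondrial counts (boundary values pass), and genes with zero
total count.  Cells are normalized with cluster-level pseudo-cell
median-ratio size factors (a simplified two-level deconvolution scheme:
within-cluster factors against the cluster pseudo-cell, rescaled across
clusters by pseudo-cell library sums).  Highly variable genes are ranked
by total variance minus a Poisson technical component; insulin
log-expression is fit with a 4-component univariate Gaussian mixture and
cells in the two highest-mean components are called beta.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA as SkPCA
from sklearn.mixture import GaussianMixture

from .core_io import CountMatrix
from .expression_de import DeResult, moderated_t

logger = logging.getLogger(__name__)

LN2_SQ = np.log(2.0) ** 2


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------


@dataclass
class QcResult:
    cell_qc: pd.DataFrame  # cell_id, libsize, n_genes, mito_fraction, passed
    filtered: CountMatrix  # passing cells x nonzero genes


def qc_filter(counts: CountMatrix, mito_genes: set[str],
              min_libsize: float = 2000, min_genes: int = 1000,
              max_mito: float = 0.10) -> QcResult:
    """Apply the library-size / detected-genes / mito-fraction cell filters
    (inclusive boundaries) and drop genes with zero total count."""
    unknown = mito_genes - set(counts.feature_ids)
    if unknown:
        raise ValueError(f"mito genes absent from matrix: {sorted(unknown)[:3]}...")
    mat = counts.counts
    lib = mat.sum(axis=0)
    n_genes = (mat > 0).sum(axis=0)
    mito_rows = [i for i, g in enumerate(counts.feature_ids) if g in mito_genes]
    mito_frac = mat[mito_rows, :].sum(axis=0) / np.maximum(lib, 1)
    passed = (lib >= min_libsize) & (n_genes >= min_genes) & (mito_frac <= max_mito)
    qc = pd.DataFrame({
        "cell_id": counts.sample_ids, "libsize": lib, "n_genes": n_genes,
        "mito_fraction": mito_frac, "passed": passed,
    })
    if not passed.any():
        raise ValueError("no cell passes QC")
    kept_cells = [c for c, p in zip(counts.sample_ids, passed) if p]
    sub = counts.subset_samples(kept_cells)
    nonzero = sub.counts.sum(axis=1) > 0
    kept_genes = [g for g, k in zip(sub.feature_ids, nonzero) if k]
    return QcResult(qc, sub.subset_features(kept_genes))


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------


def cluster_normalize(counts: CountMatrix, n_clusters: int = 4, seed: int = 0,
                      n_pcs: int = 20) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Cluster-pseudo-cell median-ratio size factors.

    Returns (size_factors (cells,), log_norm (genes x cells), cluster
    labels).  Factors have mean 1; log_norm = log2(count/factor + 1).
    """
    mat = counts.counts  # genes x cells
    n_cells = mat.shape[1]
    lib = mat.sum(axis=0)
    logcpm = np.log2(mat / np.maximum(lib, 1)[None, :] * 1e4 + 1)
    if n_clusters > 1 and n_cells >= 2 * n_clusters:
        k = min(n_pcs, n_cells - 1, mat.shape[0] - 1)
        pcs = SkPCA(n_components=k, random_state=seed).fit_transform(logcpm.T)
        labels = KMeans(n_clusters=n_clusters, random_state=seed, n_init=10).fit_predict(pcs)
    else:
        labels = np.zeros(n_cells, dtype=int)

    factors = np.empty(n_cells)
    pseudo_lib = {}
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        if idx.size < 1:
            continue
        pseudo = mat[:, idx].mean(axis=1)
        if pseudo.sum() <= 0:
            raise ValueError(f"cluster {c}: all-zero pseudo-cell")
        pos = pseudo > 0
        ratios = mat[np.ix_(pos, idx)] / pseudo[pos, None]
        factors[idx] = np.median(ratios, axis=0)
        pseudo_lib[c] = pseudo.sum()
    # rescale across clusters so factors track absolute depth
    mean_pseudo = np.mean(list(pseudo_lib.values()))
    for c, pl in pseudo_lib.items():
        factors[labels == c] *= pl / mean_pseudo
    if np.any(factors <= 0):
        n_bad = int((factors <= 0).sum())
        logger.warning("cluster_normalize: %d non-positive factors floored", n_bad)
        factors[factors <= 0] = factors[factors > 0].min()
    factors = factors / factors.mean()
    log_norm = np.log2(mat / factors[None, :] + 1)
    return factors, log_norm, labels


# ---------------------------------------------------------------------------
# Highly variable genes
# ---------------------------------------------------------------------------


def hvg_select(counts: CountMatrix, factors: np.ndarray, n: int = 1000) -> pd.DataFrame:
    """Rank genes by biological variance = total - Poisson technical.

    The technical component is the delta-method variance of
    log2(count/factor + 1) under count ~ Poisson(mu * factor).
    Returns the full ranked table with a ``selected`` flag for the top n.
    """
    mat = counts.counts
    if n > mat.shape[0]:
        raise ValueError(f"requested {n} HVGs from {mat.shape[0]} genes")
    y = mat / factors[None, :]
    mu = y.mean(axis=1)
    total_var = np.log2(y + 1).var(axis=1, ddof=1)
    inv_f = np.mean(1.0 / factors)
    tech_var = mu / (LN2_SQ * (mu + 1.0) ** 2) * inv_f
    bio = total_var - tech_var
    out = pd.DataFrame({
        "gene_id": counts.feature_ids, "mean": mu,
        "total_var": total_var, "tech_var": tech_var, "bio_var": bio,
    }).sort_values("bio_var", ascending=False, kind="mergesort").reset_index(drop=True)
    out["selected"] = np.arange(len(out)) < n
    return out


# ---------------------------------------------------------------------------
# Beta-cell calling
# ---------------------------------------------------------------------------


def gmm_beta_call(insulin_log: np.ndarray, cell_ids: list[str], n_components: int = 4,
                  seed: int = 0, n_init: int = 20) -> pd.DataFrame:
    """Fit a K-mode univariate Gaussian mixture to insulin log-expression
    and call cells in the two highest-mean components beta.

    Components are re-ranked by mean so output is invariant to EM label
    order.  Requires K >= 2 and at least 4*K cells.
    """
    x = np.asarray(insulin_log, float).reshape(-1, 1)
    if n_components < 2:
        raise ValueError("beta calling needs >= 2 mixture components")
    if x.shape[0] < 4 * n_components:
        raise ValueError("too few cells for the requested number of components")
    gm = GaussianMixture(n_components=n_components, n_init=n_init,
                         init_params="k-means++", random_state=seed,
                         covariance_type="full", reg_covar=1e-6)
    gm.fit(x)
    raw_labels = gm.predict(x)
    order = np.argsort(gm.means_.ravel())  # rank components by mean, 0 = lowest
    rank_of = np.empty_like(order)
    rank_of[order] = np.arange(n_components)
    component = rank_of[raw_labels] + 1  # 1-based, 1 = lowest mean
    is_beta = component >= n_components - 1  # two highest-mean modes
    return pd.DataFrame({
        "cell_id": cell_ids, "insulin_log": x.ravel(),
        "component": component, "is_beta": is_beta,
    })


def beta_de(counts: CountMatrix, log_norm: np.ndarray, is_beta: np.ndarray,
            condition: np.ndarray, min_cells: int = 10) -> DeResult:
    """Moderated-t DE between conditions within beta cells.

    Genes expressed (count > 0) in fewer than ``min_cells`` beta cells are
    dropped before testing.
    """
    is_beta = np.asarray(is_beta, bool)
    cond = np.asarray(condition)
    sub = counts.counts[:, is_beta]
    lc = log_norm[:, is_beta]
    cond_b = cond[is_beta]
    groups = list(np.unique(cond_b))
    if len(groups) != 2:
        raise ValueError("beta DE needs exactly two conditions among beta cells")
    # logFC is CASE vs CTRL when those labels are used; otherwise the
    # lexicographically later group vs the earlier one
    test_level = "CASE" if set(groups) == {"CTRL", "CASE"} else groups[1]
    expressed = (sub > 0).sum(axis=1) >= min_cells
    if not expressed.any():
        raise ValueError("no gene expressed in enough beta cells")
    genes = [g for g, k in zip(counts.feature_ids, expressed) if k]
    X = np.column_stack([np.ones(cond_b.size), (cond_b == test_level).astype(float)])
    return moderated_t(lc[expressed], X, genes)
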