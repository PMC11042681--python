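"""Differential expression for input libraries and count RNA-seq arms.

Two testing routes are provided, matching how the corresponding arms of a
MeRIP-seq study are usually analyzed:

* ``moderated_t`` — limma-style per-gene linear models on logCPM after a
  CPM filter and TMM normalization, with empirical-Bayes variance
  shrinkage (the scaled-F moment-matching estimator of the prior df).
* ``nb_de`` — negative-binomial Wald tests with covariates, reusing the
  bin-level GLM machinery on gene-level counts (the input-library route).

Named presets carry the filter thresholds of the study arms: ``nod-beta``
(CPM > 1 in >= 3 samples) and ``oas-oe`` (CPM > 0.49 in >= 4 samples).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, polygamma

from .core_io import CountMatrix, SampleDesign
from .dm_pipeline import nb_wald_test
from .peak_merge import DmRegion, bh_adjust

logger = logging.getLogger(__name__)

PRESETS = {
    "nod-beta": {"min_cpm": 1.0, "min_samples": 3},
    "oas-oe": {"min_cpm": 0.49, "min_samples": 4},
}


# ---------------------------------------------------------------------------
# Filtering and normalization
# ---------------------------------------------------------------------------


def cpm(counts: np.ndarray, lib_sizes: np.ndarray | None = None) -> np.ndarray:
    mat = np.asarray(counts, float)
    if lib_sizes is None:
        lib_sizes = mat.sum(axis=0)
    return mat / lib_sizes[None, :] * 1e6


def cpm_filter(counts: CountMatrix, min_cpm: float = 1.0, min_samples: int = 3) -> list[str]:
    """Genes with CPM > ``min_cpm`` in at least ``min_samples`` samples."""
    if min_samples > len(counts.sample_ids):
        raise ValueError("min_samples exceeds the number of samples")
    c = cpm(counts.counts)
    keep = (c > min_cpm).sum(axis=1) >= min_samples
    return [g for g, k in zip(counts.feature_ids, keep) if k]


def tmm_factors(counts: CountMatrix | np.ndarray, logratio_trim: float = 0.3,
                abs_trim: float = 0.05) -> np.ndarray:
    """Weighted trimmed mean of M-values normalization factors.

    Doubly trimmed (30% on log-ratios, 5% on absolute intensity),
    precision-weighted mean of per-gene log2 ratios against a reference
    sample (the one whose upper-quartile CPM is closest to the mean),
    exponentiated and rescaled to geometric mean 1.
    """
    mat = counts.counts if isinstance(counts, CountMatrix) else np.asarray(counts, float)
    lib = mat.sum(axis=0)
    if np.any(lib <= 0):
        raise ValueError("sample with zero library size")
    uq = np.array([np.quantile(mat[:, j][mat[:, j] > 0] / lib[j], 0.75) if (mat[:, j] > 0).any() else 0
                   for j in range(mat.shape[1])])
    ref = int(np.argmin(np.abs(uq - uq.mean())))

    factors = np.ones(mat.shape[1])
    yr, Nr = mat[:, ref], lib[ref]
    for j in range(mat.shape[1]):
        if j == ref:
            continue
        ys, Ns = mat[:, j], lib[j]
        ok = (ys > 0) & (yr > 0)
        if not ok.any():
            raise ValueError(f"sample {j} shares no positive genes with the reference")
        ps, pr = ys[ok] / Ns, yr[ok] / Nr
        M = np.log2(ps / pr)
        A = 0.5 * np.log2(ps * pr)
        w = (Ns - ys[ok]) / (Ns * ys[ok]) + (Nr - yr[ok]) / (Nr * yr[ok])
        n = M.size
        loM, hiM = np.quantile(M, [logratio_trim, 1 - logratio_trim])
        loA, hiA = np.quantile(A, [abs_trim, 1 - abs_trim])
        keep = (M >= loM) & (M <= hiM) & (A >= loA) & (A <= hiA)
        if not keep.any():
            keep = np.ones(n, bool)
        f = np.sum(M[keep] / w[keep]) / np.sum(1.0 / w[keep])
        factors[j] = 2.0 ** f
    factors = factors / np.exp(np.mean(np.log(factors)))
    return factors


def log_cpm(counts: CountMatrix | np.ndarray, factors: np.ndarray | None = None,
            prior: float = 0.5) -> np.ndarray:
    """log2 CPM with a prior count and TMM-effective library sizes."""
    mat = counts.counts if isinstance(counts, CountMatrix) else np.asarray(counts, float)
    lib = mat.sum(axis=0)
    if factors is not None:
        lib = lib * np.asarray(factors, float)
    return np.log2((mat + prior) / (lib[None, :] + 2 * prior) * 1e6)


# ---------------------------------------------------------------------------
# Moderated t
# ---------------------------------------------------------------------------


def _inv_trigamma(y: float) -> float:
    """Solve trigamma(x) = y by Newton iteration (y > 0)."""
    if y <= 0:
        return np.inf
    x = 0.5 + 1.0 / y
    for _ in range(100):
        step = (polygamma(1, x) - y) / polygamma(2, x)
        x_new = x - step
        if x_new <= 0:
            x_new = x / 2.0
        if abs(x_new - x) < 1e-10 * x:
            x = x_new
            break
        x = x_new
    return float(x)


def fit_f_dist(s2: np.ndarray, df: np.ndarray) -> tuple[float, float]:
    """Moment-match log residual variances to a scaled F distribution.

    Returns (d0, s0^2): the prior degrees of freedom and prior variance of
    the empirical-Bayes variance model.  d0 = inf when the observed
    variances are under-dispersed relative to pure chi-square noise.
    """
    ok = (s2 > 0) & (df > 0)
    if ok.sum() < 2:
        raise ValueError("need >= 2 positive variances to fit the prior")
    z = np.log(s2[ok])
    d = df[ok].astype(float)
    e = z - digamma(d / 2.0) + np.log(d / 2.0)
    emean = e.mean()
    n = e.size
    evar = np.sum((e - emean) ** 2) / (n - 1) - np.mean(polygamma(1, d / 2.0))
    if evar > 0:
        d0 = 2.0 * _inv_trigamma(evar)
        s02 = float(np.exp(emean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s02 = float(np.exp(emean))
    return d0, s02


@dataclass
class DeResult:
    table: pd.DataFrame
    d0: float = np.nan
    s02: float = np.nan


def moderated_t(logcpm: np.ndarray, design: np.ndarray, feature_ids: list[str],
                coef: int = -1, d0_override: float | None = None) -> DeResult:
    """Per-gene linear model with empirical-Bayes shrunk residual variance.

    ``logcpm``: genes x samples; ``design``: samples x p with the tested
    coefficient at index ``coef``.  ``d0_override`` forces the prior df
    (0 recovers the ordinary t-test; inf fully pools variances).
    """
    Y = np.asarray(logcpm, float)
    X = np.asarray(design, float)
    n, p = X.shape
    dof = n - p
    if dof < 1:
        raise ValueError("no residual degrees of freedom")
    XtX_inv = np.linalg.inv(X.T @ X)
    H = XtX_inv @ X.T
    beta = Y @ H.T
    resid = Y - beta @ X.T
    s2 = np.sum(resid ** 2, axis=1) / dof
    cgg = XtX_inv[coef, coef]

    if d0_override is not None:
        d0 = float(d0_override)
        if d0 > 0:
            s02 = float(np.median(s2[s2 > 0])) if np.any(s2 > 0) else 1.0
        else:
            s02 = 0.0
    else:
        try:
            d0, s02 = fit_f_dist(s2, np.full(s2.shape, dof))
        except ValueError:
            logger.warning("moderated_t: prior estimation failed; using ordinary t")
            d0, s02 = 0.0, 0.0

    if np.isinf(d0):
        s2_post = np.full_like(s2, s02)
        df_total = np.inf
    else:
        s2_post = (d0 * s02 + dof * s2) / (d0 + dof)
        df_total = d0 + dof

    se = np.sqrt(s2_post * cgg)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta[:, coef] / se
    if np.isinf(df_total):
        pvals = 2.0 * stats.norm.sf(np.abs(t))
    else:
        pvals = 2.0 * stats.t.sf(np.abs(t), df=df_total)
    table = pd.DataFrame({
        "gene_id": feature_ids,
        "logFC": beta[:, coef],
        "t": t,
        "pvalue": pvals,
        "qvalue": bh_adjust(pvals),
        "ave_expr": Y.mean(axis=1),
        "s2": s2,
        "s2_post": s2_post,
    })
    return DeResult(table, d0=d0, s02=s02)


def condition_design(design: SampleDesign, assay: str = "INPUT",
                     covariates: list[str] | None = None) -> tuple[np.ndarray, list[str], list[str]]:
    """Intercept + optional covariates + condition design over one assay."""
    t = design.subset(assay=assay).table
    cols = [np.ones(len(t))]
    names = ["intercept"]
    for cov in covariates or []:
        vals = t[cov]
        if vals.dtype.kind in "if":
            v = vals.to_numpy(float)
            cols.append((v - v.mean()) / (v.std() if v.std() > 0 else 1.0))
            names.append(cov)
        else:
            for lev in list(dict.fromkeys(vals))[1:]:
                cols.append((vals == lev).to_numpy(float))
                names.append(f"{cov}[{lev}]")
    cols.append((t["condition"] == "CASE").to_numpy(float))
    names.append("condition")
    return np.column_stack(cols), names, list(t["sample_id"])


def run_moderated_de(counts: CountMatrix, design: SampleDesign, assay: str = "INPUT",
                     covariates: list[str] | None = None, min_cpm: float = 1.0,
                     min_samples: int = 3) -> DeResult:
    """CPM filter -> TMM -> logCPM -> moderated t, end to end."""
    X, _, sample_ids = condition_design(design, assay, covariates)
    sub = counts.subset_samples(sample_ids)
    kept = cpm_filter(sub, min_cpm, min_samples)
    sub = sub.subset_features(kept)
    factors = tmm_factors(sub)
    lc = log_cpm(sub, factors)
    return moderated_t(lc, X, kept)


def nb_de(counts: CountMatrix, design: SampleDesign, assay: str = "INPUT",
          covariates: list[str] | None = None) -> pd.DataFrame:
    """Gene-level NB Wald DE with covariates (input-library route)."""
    mode = "covariate" if covariates else "paired"
    res = nb_wald_test(counts, design, mode=mode, covariates=covariates, assay=assay)
    t = res.table.drop(columns=["gene_id", "ordinal"]).rename(
        columns={"bin_id": "feature_id", "log2fc": "logFC"})
    ok = t["pvalue"].notna()
    q = np.full(len(t), np.nan)
    q[ok.to_numpy()] = bh_adjust(t.loc[ok, "pvalue"].to_numpy())
    t["qvalue"] = q
    return t


# ---------------------------------------------------------------------------
# DEG x DMG intersection
# ---------------------------------------------------------------------------


def intersect_deg_dmg(de_table: pd.DataFrame, dm_regions: list[DmRegion],
                      de_q: float = 0.05, dm_q: float = 0.05) -> pd.DataFrame:
    """Classify genes into hyper/hypo x up/down cells.

    A gene with significant regions in both directions contributes to each
    matching cell and is flagged ``both_directions``.
    """
    de_sig = de_table[(de_table["qvalue"] < de_q)]
    up = set(de_sig.loc[de_sig["logFC"] > 0, "gene_id"])
    down = set(de_sig.loc[de_sig["logFC"] < 0, "gene_id"])
    hyper = {r.gene_id for r in dm_regions if r.fdr < dm_q and r.direction == "hyper"}
    hypo = {r.gene_id for r in dm_regions if r.fdr < dm_q and r.direction == "hypo"}
    rows = []
    for meth_dir, meth_set in (("hyper", hyper), ("hypo", hypo)):
        for expr_dir, expr_set in (("up", up), ("down", down)):
            genes = sorted(meth_set & expr_set)
            rows.append({
                "methylation": meth_dir, "expression": expr_dir,
                "n_genes": len(genes), "genes": ",".join(genes),
            })
    both = hyper & hypo
    out = pd.DataFrame(rows)
    out.attrs["both_directions"] = sorted(both)
    return out
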