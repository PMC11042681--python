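"""Normalization, input adjustment, filtering and NB Wald testing of bins.

The testing model is a per-bin negative-binomial GLM with log link fitted
by IRLS on the normalized, input-adjusted, filtered IP counts.  The design
is either *paired* (intercept + subject indicators + condition, so each
treated library is compared against its own paired baseline) or
*covariate* (intercept + covariates + condition, e.g. batch/gender/age/BMI
adjustment).  Per-bin dispersions are estimated by Cox-Reid adjusted
profile likelihood on a log-spaced grid and shrunk 50/50 (in log space)
toward a lowess mean-dispersion trend before the final Wald fit; the Wald
statistic is referred to the standard normal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln
from statsmodels.nonparametric.smoothers_lowess import lowess

from .bin_quant import bin_gene_ids, bin_ordinals, parse_bin_id
from .core_io import CountMatrix, SampleDesign, ValidationError

logger = logging.getLogger(__name__)

MIN_ALPHA = 1e-4
MAX_ALPHA = 10.0


# ---------------------------------------------------------------------------
# Library-size normalization
# ---------------------------------------------------------------------------


def estimate_size_factors(counts: CountMatrix | np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    For each sample, the factor is the median over all-positive features of
    count / (feature geometric mean).  If no feature is positive in every
    sample, falls back to total-count ratios with a warning.
    """
    mat = counts.counts if isinstance(counts, CountMatrix) else np.asarray(counts, float)
    pos = np.all(mat > 0, axis=1)
    if not pos.any():
        logger.warning("no feature positive in all samples; using total-count size factors")
        totals = mat.sum(axis=0)
        if np.any(totals <= 0):
            raise ValidationError("sample with zero total count")
        factors = totals / np.exp(np.mean(np.log(totals)))
        return factors
    sub = mat[pos]
    log_geo = np.mean(np.log(sub), axis=1, keepdims=True)
    ratios = np.log(sub) - log_geo
    factors = np.exp(np.median(ratios, axis=0))
    factors = factors / np.exp(np.mean(np.log(factors)))
    return factors


# ---------------------------------------------------------------------------
# Input adjustment
# ---------------------------------------------------------------------------


def adjust_ip_by_input(
    ip_bins: CountMatrix,
    input_genes: CountMatrix,
    design: SampleDesign,
    ip_factors: np.ndarray | None = None,
    input_factors: np.ndarray | None = None,
    pseudocount: float = 1.0,
) -> CountMatrix:
    """Rescale normalized IP bin counts by each subject's relative gene
    expression in its matched input library.

    For bin b in gene g and IP sample s with matched input m(s):

        A[b,s] = (IP[b,s]/f_s) / r[g,s],
        r[g,s] = (INPUT[g,m(s)]/f_m + c) / mean_s'(INPUT[g,s']/f_s' + c)

    so methylation signal is not confounded by expression differences.
    """
    ip_ids = design.sample_ids(assay="IP")
    if not ip_ids:
        raise ValidationError("design has no IP samples")
    ip = ip_bins.subset_samples(ip_ids)
    if ip_factors is None:
        ip_factors = estimate_size_factors(ip)
    if input_factors is None:
        input_factors = estimate_size_factors(input_genes)
    input_norm = input_genes.counts / np.asarray(input_factors)[None, :]
    rel = input_norm + pseudocount
    rel = rel / rel.mean(axis=1, keepdims=True)
    gene_row = {g: i for i, g in enumerate(input_genes.feature_ids)}

    partner_col = []
    for s in ip_ids:
        m = design.input_partner(s)
        partner_col.append(input_genes.sample_ids.index(m))

    adjusted = ip.counts / np.asarray(ip_factors)[None, :]
    for bi, f in enumerate(ip.feature_ids):
        gid, _ = parse_bin_id(f)
        if gid not in gene_row:
            raise ValidationError(f"bin {f}: gene {gid} missing from input gene counts")
        adjusted[bi, :] /= rel[gene_row[gid], partner_col]
    return CountMatrix(list(ip.feature_ids), list(ip_ids), adjusted, allow_fractional=True)


# ---------------------------------------------------------------------------
# Bin filtering
# ---------------------------------------------------------------------------


@dataclass
class FilterResult:
    kept: CountMatrix
    flags: pd.Series  # per input bin: kept / low_count / not_enriched


def filter_bins(
    adjusted_ip: CountMatrix,
    design: SampleDesign,
    input_genes: CountMatrix | None = None,
    bin_widths: dict[str, int] | None = None,
    gene_lengths: dict[str, int] | None = None,
    min_mean: float = 10.0,
    enrich_ratio: float | None = 1.0,
    input_factors: np.ndarray | None = None,
) -> FilterResult:
    """Apply the two bin filters.

    1. low_count: mean adjusted IP count < ``min_mean`` in *both* the CTRL
       and CASE groups.
    2. not_enriched: per-base adjusted IP signal divided by per-base
       normalized input gene signal < ``enrich_ratio`` in both groups
       (skipped when ``enrich_ratio`` or the input reference is None).
    """
    if min_mean < 0:
        raise ValueError("min_mean must be >= 0")
    ctrl = [s for s in adjusted_ip.sample_ids if s in set(design.sample_ids(assay="IP", condition="CTRL"))]
    case = [s for s in adjusted_ip.sample_ids if s in set(design.sample_ids(assay="IP", condition="CASE"))]
    if not ctrl or not case:
        raise ValidationError("both CTRL and CASE IP groups must be non-empty")
    cols = {s: j for j, s in enumerate(adjusted_ip.sample_ids)}
    mat = adjusted_ip.counts
    mean_ctrl = mat[:, [cols[s] for s in ctrl]].mean(axis=1)
    mean_case = mat[:, [cols[s] for s in case]].mean(axis=1)
    low = (mean_ctrl < min_mean) & (mean_case < min_mean)

    flags = np.where(low, "low_count", "kept").astype(object)

    if enrich_ratio is not None and input_genes is not None:
        if bin_widths is None or gene_lengths is None:
            raise ValueError("bin_widths and gene_lengths required for enrichment filter")
        if input_factors is None:
            input_factors = estimate_size_factors(input_genes)
        input_norm = input_genes.counts / np.asarray(input_factors)[None, :]
        gene_row = {g: i for i, g in enumerate(input_genes.feature_ids)}
        widths = np.array([bin_widths[f] for f in adjusted_ip.feature_ids], float)
        gids = bin_gene_ids(adjusted_ip.feature_ids)
        glens = np.array([gene_lengths[g] for g in gids], float)
        input_mean = input_norm.mean(axis=1)
        input_density = np.array([input_mean[gene_row[g]] for g in gids]) / glens
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio_ctrl = (mean_ctrl / widths) / input_density
            ratio_case = (mean_case / widths) / input_density
        not_enr = (ratio_ctrl < enrich_ratio) & (ratio_case < enrich_ratio)
        not_enr &= ~low
        flags[not_enr] = "not_enriched"

    keep_mask = flags == "kept"
    kept_ids = [f for f, k in zip(adjusted_ip.feature_ids, keep_mask) if k]
    kept = CountMatrix(kept_ids, list(adjusted_ip.sample_ids), mat[keep_mask], allow_fractional=True)
    return FilterResult(kept=kept, flags=pd.Series(flags, index=adjusted_ip.feature_ids, name="filter_flag"))


# ---------------------------------------------------------------------------
# Design matrices
# ---------------------------------------------------------------------------


def build_design_matrix(design: SampleDesign, mode: str,
                        covariates: list[str] | None = None,
                        assay: str = "IP") -> tuple[np.ndarray, list[str]]:
    """Design matrix over one assay's samples for the NB GLM.

    paired: intercept + subject indicators (first subject as reference) +
    condition.  covariate: intercept + covariate columns (categoricals
    dummy-coded) + condition.  The condition column is always last.
    """
    t = design.subset(assay=assay).table
    cols = [np.ones(len(t))]
    names = ["intercept"]
    if mode == "paired":
        subjects = list(dict.fromkeys(t["subject"]))
        for subj in subjects[1:]:
            cols.append((t["subject"] == subj).to_numpy(float))
            names.append(f"subject[{subj}]")
    elif mode == "covariate":
        for cov in covariates or design.covariate_names:
            vals = t[cov]
            if vals.dtype.kind in "if":
                v = vals.to_numpy(float)
                cols.append((v - v.mean()) / (v.std() if v.std() > 0 else 1.0))
                names.append(cov)
            else:
                levels = list(dict.fromkeys(vals))
                for lev in levels[1:]:
                    cols.append((vals == lev).to_numpy(float))
                    names.append(f"{cov}[{lev}]")
    else:
        raise ValueError(f"unknown mode {mode!r}; expected 'paired' or 'covariate'")
    cols.append((t["condition"] == "CASE").to_numpy(float))
    names.append("condition")
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValidationError("design matrix is not full rank")
    if X.shape[0] - X.shape[1] < 1:
        raise ValidationError("no residual degrees of freedom")
    return X, names


# ---------------------------------------------------------------------------
# NB GLM machinery (vectorized across bins)
# ---------------------------------------------------------------------------


def _irls(Y: np.ndarray, X: np.ndarray, alpha: np.ndarray,
          eta0: np.ndarray | None = None, max_iter: int = 100,
          tol: float = 1e-8) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Batched IRLS for NB log-link GLMs sharing one design matrix.

    Y: (B, n) counts; X: (n, p); alpha: (B,) dispersions.
    Returns (beta (B,p), mu (B,n), converged (B,) bool).
    """
    B, n = Y.shape
    p = X.shape[1]
    alpha = np.broadcast_to(np.asarray(alpha, float), (B,)).copy()
    eta = np.log(Y + 0.5) if eta0 is None else eta0.copy()
    beta = np.zeros((B, p))
    converged = np.zeros(B, dtype=bool)
    last_dev = np.full(B, np.inf)
    active = np.ones(B, dtype=bool)
    for _ in range(max_iter):
        mu = np.exp(np.clip(eta, -30, 30))
        W = mu / (1.0 + alpha[:, None] * mu)
        z = eta + (Y - mu) / mu
        XtWX = np.einsum("ni,bn,nj->bij", X, W[active], X, optimize=True)
        XtWz = np.einsum("ni,bn,bn->bi", X, W[active], z[active], optimize=True)
        XtWX += 1e-10 * np.eye(p)[None, :, :]
        try:
            beta_new = np.linalg.solve(XtWX, XtWz[..., None])[..., 0]
        except np.linalg.LinAlgError:
            beta_new = np.stack([np.linalg.lstsq(XtWX[i], XtWz[i], rcond=None)[0]
                                 for i in range(XtWX.shape[0])])
        beta[active] = beta_new
        eta_new = beta_new @ X.T
        eta_new = np.clip(eta_new, -30, 30)
        mu_new = np.exp(eta_new)
        dev = _nb_deviance(Y[active], mu_new, alpha[active])
        done = np.abs(dev - last_dev[active]) < tol * (np.abs(dev) + 0.1)
        eta[active] = eta_new
        last_dev[active] = dev
        idx = np.flatnonzero(active)
        converged[idx[done]] = True
        active[idx[done]] = False
        if not active.any():
            break
    mu = np.exp(np.clip(beta @ X.T, -30, 30))
    return beta, mu, converged


def _nb_deviance(Y: np.ndarray, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    a = alpha[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(Y > 0, Y * np.log(Y / mu), 0.0)
        t2 = (Y + 1.0 / a) * np.log((1.0 + a * Y) / (1.0 + a * mu))
    return 2.0 * np.sum(t1 - t2, axis=1)


def _nb_loglik(Y: np.ndarray, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """NB log-likelihood summed over samples; Y, mu (B, n); alpha (B,)."""
    r = 1.0 / alpha[:, None]
    return np.sum(
        gammaln(Y + r) - gammaln(r) - gammaln(Y + 1.0)
        + r * np.log(r / (r + mu)) + Y * np.log(mu / (r + mu) + 1e-300),
        axis=1,
    )


def _cr_adjustment(X: np.ndarray, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Cox-Reid term: -0.5 * logdet(X^T W X)."""
    W = mu / (1.0 + alpha[:, None] * mu)
    XtWX = np.einsum("ni,bn,nj->bij", X, W, X, optimize=True)
    sign, logdet = np.linalg.slogdet(XtWX + 1e-12 * np.eye(X.shape[1])[None])
    return -0.5 * logdet


def _profile_grid(Y: np.ndarray, X: np.ndarray, n_grid: int = 25
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Cox-Reid adjusted profile log-likelihood on a log-alpha grid.

    Beta is re-fit at every grid alpha (warm-started).  Returns
    (grid (n_grid,), apl (n_grid, B)).
    """
    grid = np.exp(np.linspace(np.log(MIN_ALPHA), np.log(MAX_ALPHA), n_grid))
    B = Y.shape[0]
    apl = np.empty((n_grid, B))
    eta0 = np.log(Y + 0.5)
    for k, a in enumerate(grid):
        beta, mu, _ = _irls(Y, X, np.full(B, a), eta0=eta0, max_iter=50, tol=1e-6)
        eta0 = np.clip(beta @ X.T, -30, 30)
        apl[k] = _nb_loglik(Y, mu, np.full(B, a)) + _cr_adjustment(X, mu, np.full(B, a))
    return grid, apl


def estimate_dispersions(Y: np.ndarray, X: np.ndarray, n_grid: int = 25,
                         apl: tuple[np.ndarray, np.ndarray] | None = None) -> np.ndarray:
    """Per-bin dispersion by Cox-Reid adjusted profile likelihood.

    The grid maximum is refined by quadratic interpolation in log-alpha.
    """
    grid, apl_mat = _profile_grid(Y, X, n_grid) if apl is None else apl
    n_grid = grid.size
    best = np.argmax(apl_mat, axis=0)
    log_grid = np.log(grid)
    log_alpha = log_grid[best].copy()
    interior = (best > 0) & (best < n_grid - 1)
    i = best[interior]
    cols = np.flatnonzero(interior)
    y0, y1, y2 = apl_mat[i - 1, cols], apl_mat[i, cols], apl_mat[i + 1, cols]
    h = log_grid[1] - log_grid[0]
    denom = y0 - 2 * y1 + y2
    shift = np.where(np.abs(denom) > 1e-12, 0.5 * (y0 - y2) / denom, 0.0)
    log_alpha[interior] += np.clip(shift, -1, 1) * h
    return np.exp(np.clip(log_alpha, np.log(MIN_ALPHA), np.log(MAX_ALPHA)))


def dispersion_trend(Y: np.ndarray, X: np.ndarray, alpha_raw: np.ndarray,
                     base_mean: np.ndarray, frac: float = 0.5,
                     n_offsets: int = 21) -> np.ndarray:
    """Mean-dispersion trend: lowess shape recentered by pooled likelihood.

    Per-bin dispersion MLEs at small n are noisy and left-skewed, so a
    lowess through their logs is biased low; only its *shape* is kept and
    a constant log-offset is chosen to maximize the summed Cox-Reid
    adjusted profile likelihood across bins (the offset that would give
    the common-dispersion MLE for a flat trend).
    """
    ok = base_mean > 0
    log_mean = np.log(np.maximum(base_mean, 1e-8))
    if ok.sum() >= 10:
        fit = lowess(np.log(alpha_raw[ok]), log_mean[ok], frac=frac, return_sorted=True)
        shape = np.interp(log_mean, fit[:, 0], fit[:, 1])
    else:
        shape = np.full(base_mean.shape, np.median(np.log(alpha_raw)))
    offsets = np.linspace(-2.0, 2.0, n_offsets)
    pooled = np.empty(n_offsets)
    eta0 = np.log(Y + 0.5)
    for k, d in enumerate(offsets):
        a = np.exp(np.clip(shape + d, np.log(MIN_ALPHA), np.log(MAX_ALPHA)))
        beta, mu, _ = _irls(Y, X, a, eta0=eta0, max_iter=50, tol=1e-6)
        eta0 = np.clip(beta @ X.T, -30, 30)
        pooled[k] = np.sum(_nb_loglik(Y, mu, a) + _cr_adjustment(X, mu, a))
    k = int(np.argmax(pooled))
    delta = offsets[k]
    if 0 < k < n_offsets - 1:  # quadratic refinement
        y0, y1, y2 = pooled[k - 1], pooled[k], pooled[k + 1]
        denom = y0 - 2 * y1 + y2
        if abs(denom) > 1e-12:
            delta += np.clip(0.5 * (y0 - y2) / denom, -1, 1) * (offsets[1] - offsets[0])
    return np.exp(np.clip(shape + delta, np.log(MIN_ALPHA), np.log(MAX_ALPHA)))


def shrink_dispersions(alpha_raw: np.ndarray, trend: np.ndarray,
                       weight: float = 0.5, floor_at_trend: bool = True) -> np.ndarray:
    """Shrink log-dispersions toward the mean-dispersion trend.

    ``weight`` is the trend's share (0.5 = 50/50).  With
    ``floor_at_trend`` the shrunk value never falls below the trend:
    downward per-bin deviations at a dozen observations are dominated by
    sampling noise, and trusting them deflates Wald standard errors.
    """
    shrunk = (1 - weight) * np.log(alpha_raw) + weight * np.log(trend)
    if floor_at_trend:
        shrunk = np.maximum(shrunk, np.log(trend))
    return np.exp(np.clip(shrunk, np.log(MIN_ALPHA), np.log(MAX_ALPHA)))


@dataclass
class BinTestResult:
    """Per-bin Wald test table plus fit diagnostics."""

    table: pd.DataFrame
    design_columns: list[str] = field(default_factory=list)
    n_nonconverged: int = 0


def nb_wald_test(
    counts: CountMatrix,
    design: SampleDesign,
    mode: str = "paired",
    covariates: list[str] | None = None,
    shrink_weight: float = 0.5,
    round_counts: bool = True,
    assay: str = "IP",
) -> BinTestResult:
    """Per-bin NB Wald test of the condition effect.

    ``counts`` is the filtered, input-adjusted IP matrix (fractional values
    are rounded half-even to integers before the likelihood fit unless
    ``round_counts`` is False, in which case the continuous values enter a
    quasi-likelihood-style fit directly).  Returns log2 fold changes
    (CASE vs CTRL), Wald z and two-sided normal p-values.
    """
    X, names = build_design_matrix(design, mode, covariates, assay=assay)
    ip_ids = design.sample_ids(assay=assay)
    mat = counts.subset_samples(ip_ids).counts
    Y = np.rint(mat) if round_counts else mat
    B = Y.shape[0]

    nonzero = Y.sum(axis=1) > 0
    res = pd.DataFrame({
        "bin_id": counts.feature_ids,
        "gene_id": bin_gene_ids(counts.feature_ids),
        "ordinal": bin_ordinals(counts.feature_ids),
        "base_mean": Y.mean(axis=1),
        "log2fc": np.nan, "se": np.nan, "wald_z": np.nan,
        "pvalue": np.nan, "alpha": np.nan, "converged": False,
    })
    if not nonzero.any():
        return BinTestResult(res, names, 0)

    Yn = Y[nonzero]
    grid_apl = _profile_grid(Yn, X)
    alpha_raw = estimate_dispersions(Yn, X, apl=grid_apl)
    trend = dispersion_trend(Yn, X, alpha_raw, Yn.mean(axis=1))
    alpha = shrink_dispersions(alpha_raw, trend, weight=shrink_weight)
    beta, mu, converged = _irls(Yn, X, alpha)

    W = mu / (1.0 + alpha[:, None] * mu)
    XtWX = np.einsum("ni,bn,nj->bij", X, W, X, optimize=True)
    cov = np.linalg.inv(XtWX + 1e-12 * np.eye(X.shape[1])[None])
    ci = len(names) - 1  # condition column is last
    se_nat = np.sqrt(np.maximum(cov[:, ci, ci], 0.0))
    b_nat = beta[:, ci]
    with np.errstate(divide="ignore", invalid="ignore"):
        z = b_nat / se_nat
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.clip(p, np.finfo(float).tiny, 1.0)

    ln2 = np.log(2.0)
    idx = np.flatnonzero(nonzero)
    res.loc[idx, "log2fc"] = b_nat / ln2
    res.loc[idx, "se"] = se_nat / ln2
    res.loc[idx, "wald_z"] = z
    res.loc[idx, "pvalue"] = p
    res.loc[idx, "alpha"] = alpha
    res.loc[idx, "converged"] = converged
    bad = idx[~converged]
    res.loc[bad, ["log2fc", "se", "wald_z", "pvalue"]] = np.nan
    n_bad = len(bad)
    if n_bad:
        logger.warning("nb_wald_test: %d bins did not converge", n_bad)
    return BinTestResult(res, names, n_bad)


# ---------------------------------------------------------------------------
# Batch removal and PCA
# ---------------------------------------------------------------------------


def remove_batch_for_pca(log_matrix: np.ndarray, nuisance: np.ndarray,
                         retained: np.ndarray | None = None) -> np.ndarray:
    """Subtract fitted nuisance effects from a features x samples matrix.

    Each feature is regressed on [retained | nuisance] jointly (retained
    defaults to an intercept); only the nuisance component of the fit is
    removed, so retained effects and the grand mean survive.
    """
    Y = np.asarray(log_matrix, float)
    n = Y.shape[1]
    if retained is None:
        retained = np.ones((n, 1))
    retained = np.atleast_2d(np.asarray(retained, float))
    nuisance = np.atleast_2d(np.asarray(nuisance, float))
    if nuisance.shape[0] != n:
        nuisance = nuisance.T
    if retained.shape[0] != n:
        retained = retained.T
    # center nuisance columns against retained space so shared structure
    # stays with the retained effects
    Z = np.hstack([retained, nuisance])
    if np.linalg.matrix_rank(Z) < Z.shape[1]:
        raise ValidationError("retained and nuisance designs are confounded")
    coef, *_ = np.linalg.lstsq(Z, Y.T, rcond=None)
    k = retained.shape[1]
    return Y - (nuisance @ coef[k:]).T


def pca(matrix: np.ndarray, n_components: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """Column-centered PCA of a samples x features matrix.

    Returns (scores (n_samples, k), explained variance per component).
    """
    X = np.asarray(matrix, float)
    if n_components > min(X.shape):
        raise ValueError("n_components exceeds matrix rank bound")
    Xc = X - X.mean(axis=0, keepdims=True)
    if np.allclose(Xc, 0):
        raise ValueError("constant matrix has no principal components")
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    scores = U[:, :n_components] * s[:n_components]
    var = (s ** 2) / (X.shape[0] - 1 if X.shape[0] > 1 else 1)
    return scores, var[:n_components]
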