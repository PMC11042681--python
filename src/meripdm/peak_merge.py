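"""Merge adjacent significant bins into DM regions and control FDR.

A region ("site") is a maximal run of same-gene, consecutive-ordinal bins
that are individually significant at a raw p threshold and share the sign
of their fold change.  Region p-values are Fisher-combined and adjusted by
Benjamini-Hochberg.  Because candidate regions are pre-selected at the bin
threshold, the BH multiplicity defaults to the total number of *tested*
bins rather than the number of candidates — without this the combined
p-values of selected regions are all below the bin threshold by
construction and region-level FDR is not controlled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dm_pipeline import BinTestResult

logger = logging.getLogger(__name__)


@dataclass
class DmRegion:
    """A merged run of significant bins with combined statistics."""

    gene_id: str
    bin_start: int  # first bin ordinal (inclusive)
    bin_end: int    # last bin ordinal (inclusive)
    tx_start: int
    tx_end: int
    direction: str  # hyper / hypo
    bin_pvalues: list[float]
    mean_log2fc: float
    combined_p: float
    fdr: float = np.nan

    @property
    def n_bins(self) -> int:
        return self.bin_end - self.bin_start + 1


def fisher_combine(p_list) -> float:
    """Fisher's method: combined p = chi2_{2k} upper tail of -2*sum(ln p)."""
    p = np.asarray(list(p_list), float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any(p > 1) or np.any(p < 0):
        raise ValueError("p-values must lie in [0, 1]")
    if np.any(p == 0):
        logger.warning("fisher_combine: p=0 clamped to smallest positive float")
        p = np.maximum(p, np.finfo(float).tiny)
    x = -2.0 * np.sum(np.log(p))
    return float(stats.chi2.sf(x, df=2 * p.size))


def bh_adjust(p_vector, n_tests: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved.

    ``n_tests`` overrides the multiplicity m (default: length of the
    vector) for the selection-aware region-level correction.
    """
    p = np.asarray(list(p_vector), float)
    k = p.size
    if k == 0:
        return p
    m = k if n_tests is None else int(n_tests)
    if m < k:
        raise ValueError("n_tests cannot be smaller than the vector length")
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, k + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty_like(p)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def merge_adjacent_significant(results: BinTestResult | pd.DataFrame,
                               bin_p_threshold: float = 0.05,
                               ignore_sign: bool = False,
                               bin_width: int = 50) -> list[DmRegion]:
    """Merge runs of significant bins into candidate DM regions.

    Bins merge when they share a gene, have consecutive ordinals, pass the
    raw p threshold, and (unless ``ignore_sign``) agree in fold-change
    sign.  Singleton significant bins become singleton regions.
    """
    table = results.table if isinstance(results, BinTestResult) else results
    t = table.dropna(subset=["pvalue"]).sort_values(["gene_id", "ordinal"], kind="mergesort")
    sig = t[t["pvalue"] < bin_p_threshold]
    regions: list[DmRegion] = []
    run: list[pd.Series] = []

    def flush():
        if not run:
            return
        ps = [float(r["pvalue"]) for r in run]
        lfcs = [float(r["log2fc"]) for r in run]
        mean_lfc = float(np.mean(lfcs))
        first, last = run[0], run[-1]
        regions.append(DmRegion(
            gene_id=str(first["gene_id"]),
            bin_start=int(first["ordinal"]), bin_end=int(last["ordinal"]),
            tx_start=int(first["ordinal"]) * bin_width,
            tx_end=(int(last["ordinal"]) + 1) * bin_width,
            direction="hyper" if mean_lfc > 0 else "hypo",
            bin_pvalues=ps, mean_log2fc=mean_lfc,
            combined_p=fisher_combine(ps),
        ))

    for _, row in sig.iterrows():
        if run:
            prev = run[-1]
            contiguous = (row["gene_id"] == prev["gene_id"]
                          and int(row["ordinal"]) == int(prev["ordinal"]) + 1)
            same_sign = ignore_sign or np.sign(row["log2fc"]) == np.sign(prev["log2fc"])
            if not (contiguous and same_sign):
                flush()
                run.clear()
        run.append(row)
    flush()
    return regions


def adjust_region_fdr(regions: list[DmRegion], n_bins_tested: int | None = None) -> list[DmRegion]:
    """BH-adjust region combined p-values in place and return the list.

    ``n_bins_tested`` sets the BH multiplicity; pass the number of bins
    that entered testing (selection-aware).  None falls back to the number
    of regions.
    """
    if not regions:
        return regions
    q = bh_adjust([r.combined_p for r in regions], n_tests=n_bins_tested)
    for r, qi in zip(regions, q):
        r.fdr = float(qi)
    return regions


def call_regions(results: BinTestResult, bin_p_threshold: float = 0.05,
                 ignore_sign: bool = False, bin_width: int = 50) -> list[DmRegion]:
    """merge + selection-aware BH in one step."""
    n_tested = int(results.table["pvalue"].notna().sum())
    regions = merge_adjacent_significant(results, bin_p_threshold, ignore_sign, bin_width)
    return adjust_region_fdr(regions, n_bins_tested=max(n_tested, len(regions)))


def summarize_dm(regions: list[DmRegion], q_cutoff: float = 0.05) -> dict:
    """Counts of significant sites and genes, split by direction."""
    sig = [r for r in regions if r.fdr < q_cutoff]
    hyper = [r for r in sig if r.direction == "hyper"]
    hypo = [r for r in sig if r.direction == "hypo"]
    return {
        "n_sites": len(sig),
        "n_genes": len({r.gene_id for r in sig}),
        "n_hyper": len(hyper),
        "n_hypo": len(hypo),
        "n_hyper_genes": len({r.gene_id for r in hyper}),
        "n_hypo_genes": len({r.gene_id for r in hypo}),
    }


def regions_to_frame(regions: list[DmRegion]) -> pd.DataFrame:
    return pd.DataFrame([{
        "gene_id": r.gene_id, "bin_start": r.bin_start, "bin_end": r.bin_end,
        "tx_start": r.tx_start, "tx_end": r.tx_end, "direction": r.direction,
        "n_bins": r.n_bins, "mean_log2fc": r.mean_log2fc,
        "combined_p": r.combined_p, "fdr": r.fdr,
    } for r in regions], columns=[
        "gene_id", "bin_start", "bin_end", "tx_start", "tx_end", "direction",
        "n_bins", "mean_log2fc", "combined_p", "fdr"])
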