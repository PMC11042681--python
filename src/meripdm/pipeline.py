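"""End-to-end workflows over the module surface, plus truth scoring.

``dm_workflow`` chains the differential-methylation stages on a
:class:`~meripdm.synthetic_data.MeripExperiment`: size factors ->
input adjustment -> bin filters -> NB Wald tests -> merge/Fisher/BH.
``score_regions`` compares called regions with planted truth (a call is a
true positive when it overlaps a truth region of the same gene in bin
space with the same direction).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bin_quant import parse_bin_id
from .core_io import CountMatrix
from .dm_pipeline import (
    BinTestResult,
    adjust_ip_by_input,
    estimate_size_factors,
    filter_bins,
    nb_wald_test,
)
from .peak_merge import DmRegion, call_regions, summarize_dm
from .synthetic_data import MeripExperiment, SimTruth


@dataclass
class DmWorkflowResult:
    adjusted: CountMatrix
    filter_flags: pd.Series
    tests: BinTestResult
    regions: list[DmRegion]
    summary: dict


def dm_workflow(exp: MeripExperiment, mode: str = "paired",
                covariates: list[str] | None = None,
                min_mean: float = 10.0, enrich_ratio: float | None = 1.0,
                bin_p: float = 0.05, q_cutoff: float = 0.05,
                adjust_input: bool = True) -> DmWorkflowResult:
    """Run the full bin-level DM pipeline on one experiment.

    ``adjust_input=False`` skips the expression adjustment (normalized IP
    counts go straight to filtering/testing) — used to quantify what the
    adjustment buys.
    """
    ip_ids = exp.design.sample_ids(assay="IP")
    ip = exp.ip_bins.subset_samples(ip_ids)
    ip_factors = estimate_size_factors(ip)
    input_factors = estimate_size_factors(exp.input_genes)
    if adjust_input:
        adjusted = adjust_ip_by_input(exp.ip_bins, exp.input_genes, exp.design,
                                      ip_factors, input_factors)
    else:
        adjusted = CountMatrix(list(ip.feature_ids), list(ip_ids),
                               ip.counts / ip_factors[None, :], allow_fractional=True)

    widths = {f: exp.bin_width for f in adjusted.feature_ids}
    glens = {g: m.tx_length for g, m in exp.models.items()}
    filt = filter_bins(adjusted, exp.design, exp.input_genes, widths, glens,
                       min_mean=min_mean, enrich_ratio=enrich_ratio,
                       input_factors=input_factors)
    tests = nb_wald_test(filt.kept, exp.design, mode=mode, covariates=covariates)
    regions = call_regions(tests, bin_p_threshold=bin_p, bin_width=exp.bin_width)
    summary = summarize_dm(regions, q_cutoff=q_cutoff)
    return DmWorkflowResult(adjusted=adjusted, filter_flags=filt.flags,
                            tests=tests, regions=regions, summary=summary)


# ---------------------------------------------------------------------------
# Truth scoring
# ---------------------------------------------------------------------------


def score_regions(regions: list[DmRegion], truth: SimTruth,
                  q_cutoff: float = 0.05) -> dict:
    """Sensitivity / realized FDR / sign accuracy of region calls.

    A called region is a true positive if its bin span overlaps a planted
    region of the same gene; sign accuracy additionally requires the
    matched directions to agree.
    """
    truth_by_gene: dict[str, list[tuple[int, int, str]]] = {}
    for row in truth.dm_regions.itertuples(index=False):
        truth_by_gene.setdefault(row.gene_id, []).append(
            (int(row.bin_start), int(row.bin_end), row.direction))

    called = [r for r in regions if r.fdr < q_cutoff]
    tp = fp = sign_ok = 0
    hit_truth: set[tuple[str, int, int]] = set()
    for r in called:
        match = None
        for (s, e, d) in truth_by_gene.get(r.gene_id, []):
            if r.bin_start <= e and r.bin_end >= s:
                match = (s, e, d)
                break
        if match is None:
            fp += 1
        else:
            tp += 1
            hit_truth.add((r.gene_id, match[0], match[1]))
            if r.direction == match[2]:
                sign_ok += 1
    n_truth = len(truth.dm_regions)
    n_called = len(called)
    return {
        "n_called": n_called,
        "n_truth": n_truth,
        "true_positives": tp,
        "false_positives": fp,
        "sensitivity": len(hit_truth) / n_truth if n_truth else np.nan,
        "fdr": fp / n_called if n_called else 0.0,
        "sign_accuracy": sign_ok / tp if tp else np.nan,
    }


def null_region_rates(workflows: list[DmWorkflowResult], q_cutoff: float = 0.05) -> dict:
    """Pooled false-call rate over replicate null runs.

    Returns the fraction of merged candidate regions reaching q < cutoff
    across all replicates, with its binomial Monte-Carlo SE.
    """
    n_regions = sum(len(w.regions) for w in workflows)
    n_sig = sum(sum(1 for r in w.regions if r.fdr < q_cutoff) for w in workflows)
    frac = n_sig / n_regions if n_regions else 0.0
    se = np.sqrt(frac * (1 - frac) / n_regions) if n_regions else 0.0
    return {"n_regions": n_regions, "n_significant": n_sig,
            "fraction_significant": frac, "mc_se": se}
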