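#!/usr/bin/env python
"""Differential expression of the input libraries and DEG x DMG overlap.

Runs the NB Wald route (with covariates where the design has them) on the
gene-level input counts of both cohorts, scores planted DE genes, and
crosses DE calls with the DM regions of 02_differential_methylation.py
into the hyper/hypo x up/down table.
"""

import argparse
from pathlib import Path

import pandas as pd

from meripdm.core_io import SampleDesign, read_counts
from meripdm.expression_de import intersect_deg_dmg, nb_de
from meripdm.peak_merge import DmRegion


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--simdir", type=Path, default=Path("results/sim"))
    ap.add_argument("--dmdir", type=Path, default=Path("results/dm"))
    ap.add_argument("--outdir", type=Path, default=Path("results/de"))
    args = ap.parse_args()

    covs = {"cytokine-paired": None,
            "t1d-covariate": ["batch", "gender", "age"]}
    for preset, cov in covs.items():
        out = args.outdir / preset
        out.mkdir(parents=True, exist_ok=True)
        counts = read_counts(str(args.simdir / preset / "input_genes.tsv"))
        design = SampleDesign.from_tsv(str(args.simdir / preset / "design.tsv"))
        de = nb_de(counts, design, assay="INPUT", covariates=cov)
        de = de.rename(columns={"feature_id": "gene_id"})
        de.to_csv(out / "de_results.tsv", sep="\t", index=False)

        truth = pd.read_csv(args.simdir / preset / "truth.de_truth.tsv", sep="\t")
        sig = de[de["qvalue"] < 0.05]
        hits = sig[sig["gene_id"].isin(truth["gene_id"])]
        sens = len(hits) / len(truth) if len(truth) else float("nan")

        rtab = pd.read_csv(args.dmdir / preset / "regions.tsv", sep="\t")
        regions = [DmRegion(gene_id=r.gene_id, bin_start=r.bin_start,
                            bin_end=r.bin_end, tx_start=r.tx_start,
                            tx_end=r.tx_end, direction=r.direction,
                            bin_pvalues=[], mean_log2fc=r.mean_log2fc,
                            combined_p=r.combined_p, fdr=r.fdr)
                   for r in rtab.itertuples(index=False)]
        overlap = intersect_deg_dmg(de, regions, de_q=0.05, dm_q=0.05)
        overlap.to_csv(out / "deg_dmg_table.tsv", sep="\t", index=False)
        cells = {f"{r.methylation}-{r.expression}": int(r.n_genes)
                 for r in overlap.itertuples(index=False)}
        print(f"{preset}: {len(sig)} DE genes (q<0.05), DE sensitivity "
              f"{sens:.2f} over {len(truth)} planted | DEGxDMG {cells}")


if __name__ == "__main__":
    main()
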