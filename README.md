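# meripdm

Bin-level differential methylation for MeRIP-seq (m⁶A-seq), with the
companion analyses an epitranscriptomic study runs around it — and a
synthetic-data generator so the whole pipeline can be built, tested and
demonstrated without any sequencing download.

## Who this is for

MeRIP-seq measures N⁶-methyladenosine by sequencing an antibody-enriched
(IP) library next to its input library; methylation signal is IP
enrichment over input.  Detecting *differential* methylation between
conditions — e.g. cytokine-treated vs vehicle-treated islets, or T1D vs
control donors — is confounded by expression changes and by small,
paired designs.  This package implements that analysis as a tested
Python library plus thin analysis drivers:

1. **Binning** — 50-bp consecutive bins over each gene body
   (transcript coordinates of the union-exon model); reads are assigned
   to the bin containing the midpoint of their projected span.
2. **Normalization and input adjustment** — median-of-ratios size
   factors; each IP bin count is divided by its subject's *relative*
   gene-level input abundance
   `A[b,s] = (IP[b,s]/f_s) / [(INPUT[g,m(s)]/f_m + 1) / mean_s'(INPUT[g,s']/f + 1)]`,
   so expression changes do not masquerade as methylation changes.
3. **Filtering** — bins with mean adjusted counts < 10 in *both* groups
   are dropped, then bins not enriched in IP over the per-base input
   signal.
4. **Testing** — per-bin negative-binomial GLM (log link, IRLS) with
   design `intercept + subject + condition` (paired) or
   `intercept + batch + gender + age + BMI + condition` (covariate);
   Cox–Reid dispersion estimation with trend shrinkage; Wald z against
   the standard normal.
5. **Region calling** — maximal runs of adjacent, same-direction bins
   with p < 0.05 merge into regions ("sites"); per-bin p-values combine
   by Fisher's method, `p = P(χ²₂ₖ ≥ −2Σln pᵢ)`, and regions get
   Benjamini–Hochberg FDR with selection-aware multiplicity.
6. **Annotation** — 5′UTR/CDS/3′UTR metagene of region midpoints and
   exhaustive 5-mer + RRACH motif enrichment (hypergeometric, BH).
7. **Expression DE** — NB Wald with covariates for input libraries;
   CPM filter → TMM → logCPM → moderated t (empirical-Bayes variance
   shrinkage) for count RNA-seq arms; DEG×DMG intersection table.
8. **Single cell** — QC (library ≥ 2000, genes ≥ 1000, mito ≤ 10%),
   cluster-pseudo-cell size factors, Poisson-technical-noise HVGs, and a
   4-mode Gaussian mixture on insulin log-expression calling cells in
   the two highest modes β-cells; moderated-t DE within β-cells.
9. **Bench formulas** — ΔΔCt (`fold = 2^−ΔΔCt`), colorimetric
   `m⁶A% = ((OD_s−OD_NC)/S)/((OD_PC−OD_NC)/p)·100`, LC-MS m⁶A/A via
   standard curves, and actinomycin-D decay `ln A = −kt`,
   half-life `ln2/k`.

Every generator in `meripdm.synthetic_data` emits known ground truth
(planted DM regions, DE genes, cell labels, decay rates), so every call
above is scored, not eyeballed.

## Worked example

```bash
python analysis/01_simulate_cohorts.py        # paired + covariate cohorts
python analysis/02_differential_methylation.py
python analysis/03_annotate_regions.py
```

prints (seed 0):

```
cytokine-paired: 200 genes, 60 libraries, 42 planted DM regions -> results/sim/cytokine-paired
t1d-covariate: 200 genes, 54 libraries, 35 planted DM regions -> results/sim/t1d-covariate
cytokine-paired (paired): 41 sites in 41 genes at FDR<0.05 | sensitivity 0.95, realized FDR 0.02, sign accuracy 1.00
t1d-covariate (covariate): 37 sites in 37 genes at FDR<0.05 | sensitivity 0.89, realized FDR 0.16, sign accuracy 1.00
41 significant regions | segment mass {'utr5': 0.122, 'cds': 0.537, 'utr3': 0.341} | top enriched motif GGACT (fold 7.8, q 3.7e-32; 7 motifs at q<0.05)
```

Reading this: the paired cohort (15 donors, each treated library tested
against its own baseline) recovers 95% of planted methylation regions at
2% realized false discovery, every call with the planted direction; the
unpaired covariate cohort (20 controls vs 7 cases) is noisier.  The
annotation step finds the canonical GGACU m⁶A motif (written as GGACT in
DNA alphabet) as the top enriched 5-mer under called regions.  Drivers
04–06 run the expression-DE arm with the DEG×DMG table, the single-cell
β-cell pipeline (recall/precision 1.00 on 4-mode insulin expression),
and the bench formulas (`ddCt folds {'METTL3': 0.47, 'OAS1': 2.11, ...}`,
half-lives, the 2.50% ELISA worked example).

The same stages are available as a CLI:
`meripdm {simulate,dm,de,scrna,assays,run}`; e.g.
`meripdm run --preset cytokine-paired --seed 11 --outdir out/` writes
region, DE and score tables plus a manifest with output digests.

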