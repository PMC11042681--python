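"""Synthetic-data generators with known ground truth for every stage.

The generators emulate the study designs the pipeline targets: a paired
cytokine-vs-vehicle MeRIP-seq design (default 15 donors, each treated
library compared to its own baseline), an unpaired case-control design
with batch/gender/age/BMI covariates (20 controls vs 7 cases), a
single-cell matrix whose insulin expression has 4 modes, and noisy bench
readouts (Ct tables, decay time courses, OD plates).

Counts follow the same negative-binomial structure the tests assume:
input gene counts NB(q_g * f_s * exp(u_{g,subject} + DE effect), alpha);
IP bin counts NB(pi_b * input gene mean * f^IP_s * exp(beta_b * CASE),
alpha) with beta_b = dm_lfc * ln2 on planted bins.  Gene-wise subject
effects are Normal(0, 0.2^2) on the log scale — visible but not dominant,
which is what makes the paired test demonstrably more powerful than the
unpaired one on the same data.

Every generator is a pure function of (config, seed); the root seed is
split deterministically per generator via numpy SeedSequence spawn keys.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core_io import CountMatrix, GeneModel, SampleDesign

LN2 = np.log(2.0)

# spawn-key registry: each generator pulls an independent stream from the
# root seed so runs can be regenerated module by module
STREAMS = {"gene_models": 0, "merip": 1, "scrna": 2, "assays": 3, "motifs": 4}


def child_rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(STREAMS[stream],)))


# ---------------------------------------------------------------------------
# Configuration and truth containers
# ---------------------------------------------------------------------------


@dataclass
class SimConfig:
    """Design points for the MeRIP-seq simulator.

    Defaults mirror the paired cytokine design: 15 subjects, each with a
    baseline (CTRL) and treated (CASE) pair of IP/input libraries.
    """

    n_genes: int = 200
    bins_per_gene: tuple[int, int] = (8, 12)
    n_subjects: int = 15
    paired: bool = True
    lib_size_range_input: tuple[float, float] = (0.7, 1.4)
    lib_size_range_ip: tuple[float, float] = (0.7, 1.4)
    alpha: float = 0.1
    fraction_dm: float = 0.2
    dm_lfc: float = 1.0          # log2 methylation effect in CASE
    dm_bins: tuple[int, int] = (1, 3)  # planted run length range
    dm_direction: str = "both"   # both / hyper / hypo
    fraction_de: float = 0.0
    de_lfc: float = 1.0          # log2 expression effect in CASE
    subject_sd: float = 0.2      # gene-wise subject effect sd (ln scale)
    gene_mean_log: float = np.log(300.0)
    gene_mean_sd: float = 0.5
    peak_weight: float = 4.0     # per-bin IP propensity multiple for peaks
    background_weight: float = 0.5
    covariate_effect: float = 0.0  # ln-scale batch effect for covariate mode
    seed: int = 0

    def __post_init__(self) -> None:
        for frac in (self.fraction_dm, self.fraction_de):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if self.alpha <= 0:
            raise ValueError("dispersion alpha must be > 0")
        for lo, hi in (self.lib_size_range_input, self.lib_size_range_ip):
            if lo <= 0 or hi < lo:
                raise ValueError("library-size range must be positive and ordered")
        if self.n_subjects < 1:
            raise ValueError("need at least one subject")


@dataclass
class SimTruth:
    """Planted ground truth sufficient to score any downstream call."""

    dm_regions: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["gene_id", "bin_start", "bin_end", "direction", "lfc"]))
    de_genes: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["gene_id", "lfc"]))
    peak_bins: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["gene_id", "bin_start", "bin_end"]))
    cell_labels: pd.DataFrame = field(default_factory=pd.DataFrame)
    decay_k: dict = field(default_factory=dict)

    def write(self, prefix: str) -> None:
        self.dm_regions.to_csv(f"{prefix}.dm_truth.tsv", sep="\t", index=False)
        self.de_genes.to_csv(f"{prefix}.de_truth.tsv", sep="\t", index=False)
        if len(self.peak_bins):
            self.peak_bins.to_csv(f"{prefix}.peak_bins.tsv", sep="\t", index=False)
        if len(self.cell_labels):
            self.cell_labels.to_csv(f"{prefix}.cell_truth.tsv", sep="\t", index=False)


@dataclass
class MeripExperiment:
    """Paired IP bin counts and input gene counts plus the sample sheet."""

    ip_bins: CountMatrix
    input_genes: CountMatrix
    design: SampleDesign
    models: dict[str, GeneModel]
    bin_width: int = 50


# ---------------------------------------------------------------------------
# Gene models and sequences
# ---------------------------------------------------------------------------


def simulate_gene_models(n_genes: int, seed: int = 0, bin_width: int = 50,
                         bins_per_gene: tuple[int, int] = (8, 12),
                         ) -> tuple[dict[str, GeneModel], dict[str, str]]:
    """Random single-exon genes with UTR/CDS partitions and uniform-random
    sequence.

    Gene length is bins_per_gene * bin_width (within the 600-3000 nt
    range at the defaults); 5'UTR takes ~15% of the transcript, CDS ~60%,
    3'UTR the rest.  Returns (models, transcript sequences).
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = child_rng(seed, "gene_models")
    models: dict[str, GeneModel] = {}
    seqs: dict[str, str] = {}
    cursor = 1000
    for i in range(n_genes):
        gid = f"G{i:04d}"
        n_bins = int(rng.integers(bins_per_gene[0], bins_per_gene[1] + 1))
        length = n_bins * bin_width
        strand = "+" if rng.random() < 0.5 else "-"
        u5 = max(1, int(round(length * float(rng.uniform(0.10, 0.20)))))
        cds = max(3, int(round(length * float(rng.uniform(0.50, 0.70)))))
        u3 = length - u5 - cds
        start = cursor
        if strand == "+":
            iv5 = [(start, start + u5)]
            ivc = [(start + u5, start + u5 + cds)]
            iv3 = [(start + u5 + cds, start + length)]
        else:  # 5' end is the genomic right edge
            iv3 = [(start, start + u3)]
            ivc = [(start + u3, start + u3 + cds)]
            iv5 = [(start + u3 + cds, start + length)]
        models[gid] = GeneModel(gid, "chrS", strand, utr5=iv5, cds=ivc, utr3=iv3)
        seqs[gid] = "".join(rng.choice(list("ACGT"), size=length))
        cursor += length + int(rng.integers(200, 500))
    return models, seqs


def plant_motif_in_spans(seqs: dict[str, str], spans: pd.DataFrame, seed: int = 0,
                         motif: str = "GGACT", rate: float = 1.0) -> dict[str, str]:
    """Insert a motif occurrence into each (gene_id, tx_start, tx_end) span
    with probability ``rate`` (in-place overwrite at a random offset)."""
    rng = child_rng(seed, "motifs")
    out = dict(seqs)
    for row in spans.itertuples(index=False):
        if rng.random() > rate:
            continue
        seq = out[row.gene_id]
        lo, hi = int(row.tx_start), min(int(row.tx_end), len(seq))
        if hi - lo < len(motif):
            continue
        pos = int(rng.integers(lo, hi - len(motif) + 1))
        out[row.gene_id] = seq[:pos] + motif + seq[pos + len(motif):]
    return out


def write_fasta(seqs: dict[str, str], path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in seqs:
            fh.write(f">{name}\n")
            s = seqs[name]
            for i in range(0, len(s), width):
                fh.write(s[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# MeRIP counts
# ---------------------------------------------------------------------------


def _paired_design(n_subjects: int) -> SampleDesign:
    rows = []
    for i in range(n_subjects):
        subj = f"S{i:02d}"
        for cond in ("CTRL", "CASE"):
            for assay in ("IP", "INPUT"):
                rows.append({"sample_id": f"{subj}_{cond}_{assay}", "subject": subj,
                             "condition": cond, "assay": assay})
    return SampleDesign(pd.DataFrame(rows))


def _covariate_design(n_ctrl: int = 20, n_case: int = 7, seed: int = 0) -> SampleDesign:
    """Unpaired case-control sheet with batch/gender/age/BMI covariates."""
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(9,)))
    rows = []
    k = 0
    for cond, n in (("CTRL", n_ctrl), ("CASE", n_case)):
        for _ in range(n):
            subj = f"D{k:02d}"
            for assay in ("IP", "INPUT"):
                rows.append({
                    "sample_id": f"{subj}_{assay}", "subject": subj,
                    "condition": cond, "assay": assay,
                    "batch": f"B{int(rng.integers(0, 3))}",
                    "gender": "F" if rng.random() < 0.5 else "M",
                    "age": float(np.round(rng.uniform(20, 70), 1)),
                    "bmi": float(np.round(rng.uniform(18, 35), 1)),
                })
            k += 1
    return SampleDesign(pd.DataFrame(rows))


def simulate_merip_counts(models: dict[str, GeneModel], config: SimConfig,
                          design: SampleDesign | None = None,
                          ) -> tuple[MeripExperiment, SimTruth]:
    """Generate paired IP/input NB counts over the given gene models.

    Peak bins (runs of 1-3 adjacent bins per gene) concentrate IP signal;
    a ``fraction_dm`` subset of genes carries a differential-methylation
    effect of ``dm_lfc`` log2 units on one peak run in CASE IP libraries.
    ``fraction_de`` genes carry an expression effect in CASE in both
    assays (through the input-proportional IP mean).
    """
    rng = child_rng(config.seed, "merip")
    if design is None:
        design = _paired_design(config.n_subjects)
    gene_ids = list(models)
    n_genes = len(gene_ids)
    bin_width = 50

    dtab = design.table
    subjects = list(dict.fromkeys(dtab["subject"]))
    subj_idx = {s: i for i, s in enumerate(subjects)}

    # gene baselines, subject effects, DE assignment
    q = np.exp(rng.normal(config.gene_mean_log, config.gene_mean_sd, size=n_genes))
    u = rng.normal(0.0, config.subject_sd, size=(n_genes, len(subjects)))
    de_mask = rng.random(n_genes) < config.fraction_de
    de_sign = rng.choice([-1.0, 1.0], size=n_genes)
    de_beta = np.where(de_mask, config.de_lfc * de_sign * LN2, 0.0)

    # batch effect for covariate designs (additive ln-scale shift by batch)
    batch_shift = {}
    if config.covariate_effect != 0 and "batch" in dtab.columns:
        for b in sorted(set(dtab["batch"])):
            batch_shift[b] = rng.normal(0.0, config.covariate_effect)

    # per-gene peak structure and DM truth
    peak_rows, dm_rows = [], []
    n_bins_per_gene = {g: models[g].tx_length // bin_width for g in gene_ids}
    dm_mask = rng.random(n_genes) < config.fraction_dm
    pi: dict[str, np.ndarray] = {}
    dm_beta: dict[str, np.ndarray] = {}
    for gi, g in enumerate(gene_ids):
        nb = n_bins_per_gene[g]
        w = np.full(nb, config.background_weight)
        run_len = int(rng.integers(config.dm_bins[0], config.dm_bins[1] + 1))
        run_len = min(run_len, nb)
        start = int(rng.integers(0, nb - run_len + 1))
        w[start:start + run_len] = config.peak_weight
        peak_rows.append({"gene_id": g, "bin_start": start, "bin_end": start + run_len - 1})
        beta = np.zeros(nb)
        if dm_mask[gi]:
            if config.dm_direction == "both":
                sign = float(rng.choice([-1.0, 1.0]))
            else:
                sign = 1.0 if config.dm_direction == "hyper" else -1.0
            beta[start:start + run_len] = sign * config.dm_lfc * LN2
            dm_rows.append({"gene_id": g, "bin_start": start, "bin_end": start + run_len - 1,
                            "direction": "hyper" if sign > 0 else "hypo",
                            "lfc": sign * config.dm_lfc})
        pi[g] = w / nb
        dm_beta[g] = beta

    # library size factors
    input_ids = design.sample_ids(assay="INPUT")
    ip_ids = design.sample_ids(assay="IP")
    f_input = rng.uniform(*config.lib_size_range_input, size=len(input_ids))
    f_ip = rng.uniform(*config.lib_size_range_ip, size=len(ip_ids))

    info = dtab.set_index("sample_id")

    def sample_terms(sid: str) -> tuple[int, float, float]:
        row = info.loc[sid]
        si = subj_idx[row["subject"]]
        case = 1.0 if row["condition"] == "CASE" else 0.0
        shift = batch_shift.get(row.get("batch"), 0.0) if batch_shift else 0.0
        return si, case, shift

    r = 1.0 / config.alpha

    # input gene counts
    input_mean = np.empty((n_genes, len(input_ids)))
    for j, sid in enumerate(input_ids):
        si, case, shift = sample_terms(sid)
        input_mean[:, j] = q * f_input[j] * np.exp(u[:, si] + de_beta * case + shift)
    input_counts = rng.negative_binomial(r, r / (r + input_mean))
    input_genes = CountMatrix(gene_ids, input_ids, input_counts.astype(float))

    # IP bin counts: mean proportional to the *input gene mean* of the same
    # subject/condition (at unit input library factor)
    bin_ids = [f"{g}:{b}" for g in gene_ids for b in range(n_bins_per_gene[g])]
    ip_mean = np.empty((len(bin_ids), len(ip_ids)))
    for j, sid in enumerate(ip_ids):
        si, case, shift = sample_terms(sid)
        gene_expr = q * np.exp(u[:, si] + de_beta * case + shift)
        col = []
        for gi, g in enumerate(gene_ids):
            col.append(pi[g] * gene_expr[gi] * f_ip[j] * np.exp(dm_beta[g] * case))
        ip_mean[:, j] = np.concatenate(col)
    ip_counts = rng.negative_binomial(r, r / (r + ip_mean))
    ip_bins = CountMatrix(bin_ids, ip_ids, ip_counts.astype(float))

    truth = SimTruth(
        dm_regions=pd.DataFrame(dm_rows, columns=["gene_id", "bin_start", "bin_end", "direction", "lfc"]),
        de_genes=pd.DataFrame({"gene_id": np.array(gene_ids)[de_mask],
                               "lfc": (config.de_lfc * de_sign)[de_mask]}),
        peak_bins=pd.DataFrame(peak_rows),
    )
    exp = MeripExperiment(ip_bins=ip_bins, input_genes=input_genes, design=design,
                          models=models, bin_width=bin_width)
    return exp, truth


# ---------------------------------------------------------------------------
# Single-cell counts
# ---------------------------------------------------------------------------


def simulate_scrna(n_cells: int = 1000, n_genes: int = 1500,
                   mode_means: tuple[float, ...] = (0.0, 2.0, 4.0, 6.0),
                   mode_sd: float = 0.3,
                   mode_weights: tuple[float, ...] = (0.25, 0.25, 0.25, 0.25),
                   insulin_gene: str = "INS",
                   n_mito: int = 5,
                   frac_low_libsize: float = 0.05,
                   frac_low_genes: float = 0.05,
                   frac_high_mito: float = 0.10,
                   fraction_de: float = 0.0, de_lfc: float = 1.0,
                   seed: int = 0) -> tuple[CountMatrix, SimTruth]:
    """Single-cell counts whose insulin log-expression has 4 modes.

    Cells drawn from components 3 and 4 (the two highest means) are beta
    in truth.  Configurable fractions of cells are made to fail each QC
    rule (low depth, few detected genes, high mito).  Optional DE genes
    differ between CTRL and CASE cells within the beta population.
    """
    if list(mode_means) != sorted(mode_means) or len(set(mode_means)) != len(mode_means):
        raise ValueError("mode means must be strictly increasing")
    if len(mode_weights) != len(mode_means):
        raise ValueError("one weight per mode required")
    rng = child_rng(seed, "scrna")
    k = len(mode_means)
    weights = np.asarray(mode_weights, float)
    weights = weights / weights.sum()

    comp = rng.choice(k, size=n_cells, p=weights)
    insulin_log = rng.normal(np.asarray(mode_means)[comp], mode_sd)
    is_beta = comp >= k - 2
    condition = np.where(rng.random(n_cells) < 0.5, "CASE", "CTRL")

    genes = [insulin_gene] + [f"MT-{i}" for i in range(n_mito)] + [
        f"SC{i:04d}" for i in range(n_genes - 1 - n_mito)]
    base = np.exp(rng.normal(np.log(2.0), 0.8, size=len(genes)))
    base[0] = 0.0  # insulin handled separately
    base[1:1 + n_mito] = 25.0  # mito genes carry a visible share of depth

    de_mask = np.zeros(len(genes), bool)
    de_sign = rng.choice([-1.0, 1.0], size=len(genes))
    if fraction_de > 0:
        candidates = np.arange(1 + n_mito, len(genes))
        n_de = int(round(fraction_de * candidates.size))
        de_mask[rng.choice(candidates, size=n_de, replace=False)] = True

    depth = np.exp(rng.normal(np.log(1.0), 0.25, size=n_cells))
    low_lib = rng.random(n_cells) < frac_low_libsize
    depth[low_lib] *= 0.25
    mito_boost = np.ones(n_cells)
    high_mito = rng.random(n_cells) < frac_high_mito
    mito_boost[high_mito] = 4.0

    lam = np.outer(base, depth)
    de_factor = np.where(condition == "CASE", 1.0, 0.0)[None, :] * de_mask[:, None]
    lam = lam * np.exp(de_factor * de_lfc * LN2 * de_sign[:, None] * is_beta[None, :])
    mito_rows = slice(1, 1 + n_mito)
    lam[mito_rows, :] *= mito_boost[None, :]
    counts = rng.poisson(lam).astype(float)

    # low-detected-gene cells: zero out a large random subset of genes
    low_genes = rng.random(n_cells) < frac_low_genes
    for j in np.flatnonzero(low_genes):
        drop = rng.random(len(genes)) < 0.8
        counts[drop, j] = 0.0

    # insulin counts reproduce the drawn log2-expression after depth scaling
    counts[0, :] = np.maximum(np.rint((2.0 ** insulin_log - 1.0) * depth), 0.0)

    cell_ids = [f"C{i:04d}" for i in range(n_cells)]
    truth = SimTruth(cell_labels=pd.DataFrame({
        "cell_id": cell_ids, "component": comp + 1, "is_beta": is_beta,
        "condition": condition, "insulin_log": insulin_log,
        "low_libsize": low_lib, "low_genes": low_genes, "high_mito": high_mito,
    }), de_genes=pd.DataFrame({"gene_id": np.array(genes)[de_mask],
                               "lfc": (de_lfc * de_sign)[de_mask]}))
    return CountMatrix(genes, cell_ids, counts), truth


# ---------------------------------------------------------------------------
# Bench assay tables
# ---------------------------------------------------------------------------


@dataclass
class AssayTables:
    ct: pd.DataFrame      # sample, group, gene, ct
    decay: pd.DataFrame   # transcript, time_h, abundance
    od: pd.DataFrame      # analyte_conc, od


def simulate_assay_tables(seed: int = 0, n_replicates: int = 4,
                          ct_noise_sd: float = 0.1,
                          truth_folds: dict[str, float] | None = None,
                          decay_k: dict[str, float] | None = None,
                          decay_times: tuple[float, ...] = (0.0, 4.0, 8.0),
                          decay_noise_cv: float = 0.05,
                          od_slope: float = 0.02, od_intercept: float = 0.1,
                          od_noise_sd: float = 0.0,
                          reference_gene: str = "GAPDH",
                          ) -> tuple[AssayTables, SimTruth]:
    """Noisy Ct tables, actinomycin-D decay series and a linear OD plate.

    Ct = c0 - log2(expression) + noise; decay abundance =
    exp(-k t)(1 + eps), normalized to t=0; OD linear in analyte amount.
    """
    rng = child_rng(seed, "assays")
    if truth_folds is None:
        truth_folds = {"OAS1": 2.0, "OAS2": 4.0, "METTL3": 0.5}
    if decay_k is None:
        decay_k = {"OAS1": np.log(2.0) / 4.0, "OAS2": np.log(2.0) / 2.0}
    if any(k < 0 for k in decay_k.values()):
        raise ValueError("decay rates must be non-negative")

    ct_rows = []
    c0 = 22.0
    for gene, fold in truth_folds.items():
        for grp, expr in (("control", 1.0), ("treated", fold)):
            for rep in range(n_replicates):
                sid = f"{grp}{rep}"
                ct_rows.append({"sample": sid, "group": grp, "gene": gene,
                                "ct": c0 - np.log2(expr) + rng.normal(0, ct_noise_sd)})
                ct_rows.append({"sample": sid, "group": grp, "gene": reference_gene,
                                "ct": 18.0 + rng.normal(0, ct_noise_sd)})
    ct = pd.DataFrame(ct_rows).drop_duplicates(subset=["sample", "gene"], keep="first")

    decay_rows = []
    for tx, kk in decay_k.items():
        raw = np.exp(-kk * np.asarray(decay_times)) * (
            1.0 + rng.normal(0, decay_noise_cv, size=len(decay_times)))
        raw = raw / raw[0]
        for t, a in zip(decay_times, raw):
            decay_rows.append({"transcript": tx, "time_h": t, "abundance": a})
    decay = pd.DataFrame(decay_rows)

    conc = np.linspace(0, 50, 6)
    od = pd.DataFrame({"analyte_conc": conc,
                       "od": od_intercept + od_slope * conc
                       + rng.normal(0, od_noise_sd, size=conc.size)})

    truth = SimTruth(decay_k=dict(decay_k))
    truth.de_genes = pd.DataFrame({"gene_id": list(truth_folds),
                                   "lfc": np.log2(list(truth_folds.values()))})
    return AssayTables(ct=ct, decay=decay, od=od), truth


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------


def cytokine_paired_config(seed: int = 0, **overrides) -> SimConfig:
    """Paired cytokine-vs-vehicle design: 15 donors, paired libraries."""
    return replace(SimConfig(seed=seed), **overrides)


def t1d_covariate_setup(seed: int = 0, n_ctrl: int = 20, n_case: int = 7,
                        **overrides) -> tuple[SimConfig, SampleDesign]:
    """Unpaired case-control design (20 controls vs 7 cases) with
    batch/gender/age/BMI covariates on the sample sheet."""
    cfg = replace(SimConfig(seed=seed, paired=False, covariate_effect=0.15), **overrides)
    return cfg, _covariate_design(n_ctrl, n_case, seed)
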