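import numpy as np
import pandas as pd
import pytest

from meripdm.core_io import CountMatrix, GeneModel, SampleDesign


@pytest.fixture
def plus_gene():
    """Single-exon plus-strand gene: exon [0,300), CDS [100,250)."""
    return GeneModel("gplus", "chr1", "+",
                     utr5=[(0, 100)], cds=[(100, 250)], utr3=[(250, 300)])


@pytest.fixture
def minus_gene():
    """Same structure on the minus strand (5'UTR at the genomic right)."""
    return GeneModel("gminus", "chr1", "-",
                     utr3=[(0, 50)], cds=[(50, 200)], utr5=[(200, 300)])


@pytest.fixture
def paired_design():
    """6 subjects x {CTRL, CASE} x {IP, INPUT}."""
    rows = []
    for i in range(6):
        subj = f"S{i}"
        for cond in ("CTRL", "CASE"):
            for assay in ("IP", "INPUT"):
                rows.append({"sample_id": f"{subj}_{cond}_{assay}", "subject": subj,
                             "condition": cond, "assay": assay})
    return SampleDesign(pd.DataFrame(rows))


def nb_draw(rng, mean, alpha):
    """NB draw parameterized by mean and dispersion alpha (var = m + a m^2)."""
    r = 1.0 / alpha
    return rng.negative_binomial(r, r / (r + mean))


@pytest.fixture
def nb_paired_counts(paired_design):
    """Null NB bin counts (2000 bins, alpha=0.1) over the paired design."""
    rng = np.random.default_rng(12345)
    B = 2000
    mu0 = np.exp(rng.normal(np.log(60), 0.5, size=B))
    subj = rng.normal(0, 0.2, size=(B, 6))
    ip_ids = paired_design.sample_ids(assay="IP")
    Y = np.empty((B, len(ip_ids)))
    info = paired_design.subset(assay="IP").table.reset_index(drop=True)
    for j in range(len(ip_ids)):
        si = int(info.loc[j, "subject"][1:])
        Y[:, j] = nb_draw(rng, mu0 * np.exp(subj[:, si]), 0.1)
    return CountMatrix([f"g{i}:0" for i in range(B)], ip_ids, Y)
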