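"""Bench-side computations: ddCt qPCR, colorimetric m6A%, LC-MS m6A/A,
and actinomycin-D mRNA decay kinetics.

All four are deterministic closed forms or small least-squares fits:

* delta-delta-Ct: dCt = Ct_gene - Ct_ref per sample; ddCt is the mean dCt
  difference between test and control groups; fold = 2^-ddCt.
* colorimetric m6A%: ((sample OD - NC OD)/S) / ((PC OD - NC OD)/p) * 100
  with S = ng of sample RNA and p = ng of positive control.
* m6A/A ratio: per-nucleoside OLS standard curves (with intercept),
  inverse prediction of concentrations, then their ratio.
* decay: ln(relative abundance) regressed through the origin on time;
  half-life = ln2 / k.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# delta-delta-Ct
# ---------------------------------------------------------------------------


@dataclass
class DdctResult:
    gene: str
    control_group: str
    test_group: str
    ddct: float
    fold_change: float
    per_sample: pd.DataFrame  # sample, group, dct, rel_quantity


def delta_delta_ct(table: pd.DataFrame, reference_gene: str, control_group: str,
                   gene: str | None = None) -> list[DdctResult]:
    """Relative qPCR quantification against a reference gene and a control
    group.

    ``table`` is long format with columns sample, group, gene, ct.
    Replicate Ct values are aggregated by arithmetic mean (Ct is already a
    log-scale quantity).  Returns one result per (target gene, non-control
    group).
    """
    required = {"sample", "group", "gene", "ct"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"Ct table missing columns {sorted(missing)}")
    if (table["ct"] <= 0).any():
        raise ValueError("Ct values must be positive")
    ref = table[table["gene"] == reference_gene].groupby("sample")["ct"].mean()
    targets = [gene] if gene else sorted(set(table["gene"]) - {reference_gene})
    results: list[DdctResult] = []
    for g in targets:
        sub = table[table["gene"] == g].groupby(["sample", "group"])["ct"].mean().reset_index()
        if not set(sub["sample"]).issubset(set(ref.index)):
            raise ValueError(f"{g}: some samples lack reference-gene Ct")
        sub["dct"] = sub["ct"] - ref.loc[sub["sample"]].to_numpy()
        ctrl = sub[sub["group"] == control_group]
        if ctrl.empty:
            raise ValueError(f"{g}: control group {control_group!r} absent")
        ctrl_mean = ctrl["dct"].mean()
        sub["rel_quantity"] = 2.0 ** -(sub["dct"] - ctrl_mean)
        for grp in sorted(set(sub["group"]) - {control_group}):
            ddct = sub.loc[sub["group"] == grp, "dct"].mean() - ctrl_mean
            results.append(DdctResult(
                gene=g, control_group=control_group, test_group=grp,
                ddct=float(ddct), fold_change=float(2.0 ** -ddct),
                per_sample=sub[["sample", "group", "dct", "rel_quantity"]].copy(),
            ))
    return results


# ---------------------------------------------------------------------------
# colorimetric m6A%
# ---------------------------------------------------------------------------


def m6a_percent(sample_od: float, nc_od: float, pc_od: float,
                sample_ng: float, pc_ng: float) -> float:
    """Percentage m6A from the colorimetric plate assay.

    m6A% = ((sample OD - NC OD) / S) / ((PC OD - NC OD) / p) * 100 with
    S = ng of input sample RNA and p = ng of positive control.  A sample
    OD below the negative control clamps to 0% with a warning.
    """
    if sample_ng <= 0 or pc_ng <= 0:
        raise ValueError("RNA amounts must be positive")
    if pc_od <= nc_od:
        raise ValueError("positive-control OD must exceed negative-control OD")
    num = sample_od - nc_od
    if num < 0:
        warnings.warn("sample OD below negative control; clamping m6A% to 0")
        num = 0.0
    return (num / sample_ng) / ((pc_od - nc_od) / pc_ng) * 100.0


# ---------------------------------------------------------------------------
# LC-MS m6A/A ratio
# ---------------------------------------------------------------------------


def _inverse_predict(standards: np.ndarray, signal: float) -> float:
    """Concentration from an OLS standard curve (conc, signal) pairs."""
    st = np.asarray(standards, float)
    if st.shape[0] < 2:
        raise ValueError("need >= 2 standards per nucleoside")
    conc, sig = st[:, 0], st[:, 1]
    slope, intercept = np.polyfit(conc, sig, 1)
    if abs(slope) < 1e-12:
        raise ValueError("standard curve has zero slope; calibration not invertible")
    return (signal - intercept) / slope


def m6a_over_a(m6a_signal: float, a_signal: float,
               m6a_standards, a_standards) -> float:
    """m6A/A concentration ratio from per-nucleoside standard curves."""
    c_m6a = _inverse_predict(np.asarray(m6a_standards), m6a_signal)
    c_a = _inverse_predict(np.asarray(a_standards), a_signal)
    if c_a == 0:
        raise ValueError("adenosine concentration estimated as zero")
    return c_m6a / c_a


# ---------------------------------------------------------------------------
# mRNA decay
# ---------------------------------------------------------------------------


@dataclass
class DecayFit:
    k_per_h: float
    half_life_h: float  # inf when stable
    r_squared: float
    n_points: int


def decay_fit(times_h, abundance, through_origin: bool = True) -> DecayFit:
    """First-order decay fit of a transcription-blocked time course.

    ``abundance`` is relative to t=0 (so the regression of ln(abundance)
    on time is forced through the origin by default).  Non-positive
    abundances are dropped with a warning; k <= 0 is reported as stable
    (half-life inf).
    """
    t = np.asarray(times_h, float)
    a = np.asarray(abundance, float)
    if t.shape != a.shape:
        raise ValueError("times and abundances differ in length")
    if np.any(np.diff(t) <= 0):
        raise ValueError("time points must be strictly increasing")
    if np.any(t < 0):
        raise ValueError("negative time point")
    ok = a > 0
    if not ok.all():
        warnings.warn(f"dropping {int((~ok).sum())} non-positive abundance points")
    t, a = t[ok], a[ok]
    if t.size < 2:
        raise ValueError("need >= 2 usable time points")
    y = np.log(a)
    if through_origin:
        k = -float(np.sum(t * y) / np.sum(t * t)) if np.any(t > 0) else 0.0
        fitted = -k * t
    else:
        slope, intercept = np.polyfit(t, y, 1)
        k = -float(slope)
        fitted = slope * t + intercept
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 and ss_res < 1e-12 else (1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0)
    if ss_tot == 0 and ss_res >= 1e-12:
        r2 = 0.0
    half_life = np.inf if k <= 0 else float(np.log(2.0) / k)
    if k <= 0:
        logger.info("decay_fit: non-positive rate; transcript reported stable")
    return DecayFit(k_per_h=k, half_life_h=half_life, r_squared=r2, n_points=int(t.size))


def fit_decay_table(series: pd.DataFrame, through_origin: bool = True) -> pd.DataFrame:
    """Fit decay per transcript from a long table (transcript, time_h,
    abundance), abundance pre-normalized to t=0."""
    rows = []
    for tx, grp in series.groupby("transcript"):
        grp = grp.sort_values("time_h")
        fit = decay_fit(grp["time_h"].to_numpy(), grp["abundance"].to_numpy(), through_origin)
        rows.append({"transcript": tx, "k_per_h": fit.k_per_h,
                     "half_life_h": fit.half_life_h, "r_squared": fit.r_squared})
    return pd.DataFrame(rows)
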