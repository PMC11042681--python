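"""Metagene positioning of DM regions and k-mer motif enrichment.

The metagene maps each region's midpoint to a fractional position within
its transcript segment (5'UTR, CDS or 3'UTR) and accumulates a density
over three fixed-resolution grids; m6A peaks concentrate near the stop
codon, i.e. the CDS/3'UTR boundary.  Motif enrichment is exhaustive
k-mer counting with a sequence-level hypergeometric test (peak vs
background presence/absence), plus the degenerate m6A consensus RRACH
(R = A/G, H = A/C/U) scored as a class.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import GeneModel
from .peak_merge import DmRegion, bh_adjust

SEGMENTS = ("utr5", "cds", "utr3")

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "H": "ACT", "D": "AGT", "V": "ACG", "B": "CGT",
    "S": "CG", "W": "AT", "K": "GT", "M": "AC", "N": "ACGT",
}


@dataclass
class MetageneProfile:
    """Densities over 5'UTR / CDS / 3'UTR grids, summing to 1 overall."""

    utr5: np.ndarray
    cds: np.ndarray
    utr3: np.ndarray

    @property
    def concatenated(self) -> np.ndarray:
        return np.concatenate([self.utr5, self.cds, self.utr3])


def metagene_profile(regions: list[DmRegion], models: dict[str, GeneModel],
                     cells_per_segment: int = 50) -> MetageneProfile:
    """Accumulate region midpoints into a length-normalized metagene.

    Each region's transcript midpoint falls in one segment of its gene;
    the fractional position within that segment selects a grid cell.
    Genes missing a segment simply never contribute to it.
    """
    grids = {s: np.zeros(cells_per_segment) for s in SEGMENTS}
    for r in regions:
        model = models[r.gene_id]
        mid = (r.tx_start + min(r.tx_end, model.tx_length)) // 2
        if not 0 <= mid < model.tx_length:
            raise ValueError(f"region midpoint {mid} outside transcript of {r.gene_id}")
        seg = model.segment_of(mid)
        seg_start = {"utr5": 0,
                     "cds": model.utr5_length,
                     "utr3": model.utr5_length + model.cds_length}[seg]
        seg_len = getattr(model, f"{seg}_length")
        frac = (mid - seg_start) / seg_len
        cell = min(int(frac * cells_per_segment), cells_per_segment - 1)
        grids[seg][cell] += 1
    total = sum(g.sum() for g in grids.values())
    if total > 0:
        for s in SEGMENTS:
            grids[s] /= total
    return MetageneProfile(grids["utr5"], grids["cds"], grids["utr3"])


# ---------------------------------------------------------------------------
# Motif enrichment
# ---------------------------------------------------------------------------


def _normalize_seq(seq: str) -> str:
    return seq.upper().replace("U", "T")


def pattern_count(seq: str, pattern: str) -> int:
    """Occurrences of an IUPAC degenerate pattern in a sequence (T==U)."""
    seq = _normalize_seq(seq)
    pat = [set(IUPAC[c]) for c in _normalize_seq(pattern)]
    k = len(pat)
    n = 0
    for i in range(len(seq) - k + 1):
        if all(seq[i + j] in pat[j] for j in range(k)):
            n += 1
    return n


def _presence_counts(seqs: list[str], k: int) -> dict[str, int]:
    """Number of sequences containing each observed k-mer at least once."""
    counts: dict[str, int] = {}
    for seq in seqs:
        seq = _normalize_seq(seq)
        seen = {seq[i:i + k] for i in range(len(seq) - k + 1)}
        for kmer in seen:
            counts[kmer] = counts.get(kmer, 0) + 1
    return counts


def motif_enrichment(peak_seqs: list[str], background_seqs: list[str], k: int = 5,
                     degenerate_patterns: tuple[str, ...] = ("RRACH",)) -> pd.DataFrame:
    """Rank k-mers by fold enrichment of sequence-level presence in peaks.

    For each k-mer present in any peak sequence (and each degenerate
    pattern as a class), tests whether peak sequences contain it more
    often than background sequences via the hypergeometric upper tail on
    presence/absence, BH-adjusted across all tested motifs.  Output is
    ranked by fold enrichment (U reported as T).
    """
    if not background_seqs:
        raise ValueError("background sequence set is empty")
    min_len = min(len(s) for s in list(peak_seqs) + list(background_seqs))
    if k > min_len:
        raise ValueError(f"k={k} longer than shortest sequence ({min_len})")

    n_peak, n_bg = len(peak_seqs), len(background_seqs)
    peak_counts = _presence_counts(list(peak_seqs), k)
    bg_counts = _presence_counts(list(background_seqs), k)

    rows = []
    motifs = sorted(set(peak_counts) | set(bg_counts))
    for motif in motifs:
        a = peak_counts.get(motif, 0)
        b = bg_counts.get(motif, 0)
        rows.append((motif, "kmer", a, b))
    for pat in degenerate_patterns:
        a = sum(1 for s in peak_seqs if pattern_count(s, pat) > 0)
        b = sum(1 for s in background_seqs if pattern_count(s, pat) > 0)
        rows.append((_normalize_seq(pat), "class", a, b))

    out = pd.DataFrame(rows, columns=["motif", "kind", "n_peak", "n_background"])
    # hypergeometric: population = all sequences, successes = sequences
    # containing the motif, draws = peak set
    M = n_peak + n_bg
    K = out["n_peak"] + out["n_background"]
    out["pvalue"] = stats.hypergeom.sf(out["n_peak"] - 1, M, K, n_peak)
    peak_frac = out["n_peak"] / n_peak
    bg_frac = out["n_background"] / n_bg
    pseudo = 0.5
    out["fold_enrichment"] = ((out["n_peak"] + pseudo) / (n_peak + pseudo)) / (
        (out["n_background"] + pseudo) / (n_bg + pseudo))
    out["peak_fraction"] = peak_frac
    out["background_fraction"] = bg_frac
    out["qvalue"] = bh_adjust(out["pvalue"].to_numpy())
    out = out.sort_values(["fold_enrichment", "pvalue"], ascending=[False, True],
                          kind="mergesort").reset_index(drop=True)
    return out


def extract_region_sequences(regions: list[DmRegion], models: dict[str, GeneModel],
                             tx_sequences: dict[str, str]) -> list[str]:
    """Transcript-orientation sequences under each region's span."""
    out = []
    for r in regions:
        seq = tx_sequences[r.gene_id]
        out.append(seq[r.tx_start:min(r.tx_end, len(seq))])
    return out


def all_kmers(k: int) -> list[str]:
    return ["".join(p) for p in product("ACGT", repeat=k)]
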