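"""Shared data model and readers/writers for the standard formats.

All interval arithmetic is 0-based, half-open.  Transcript-relative
coordinates always run 5'->3': position 0 of a minus-strand gene is its
highest genomic exonic base.  Genes without annotated UTRs carry
zero-width UTR segments so every downstream consumer can assume the
5'UTR/CDS/3'UTR partition exists.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import io as scipy_io
from scipy import sparse

logger = logging.getLogger(__name__)


class ParseError(ValueError):
    """A malformed line in an input file; message names the line number."""


class ValidationError(ValueError):
    """Input parsed but violates a data-model invariant."""


# ---------------------------------------------------------------------------
# Gene models
# ---------------------------------------------------------------------------

Interval = tuple[int, int]


def _merge_intervals(ivs: list[Interval]) -> list[Interval]:
    """Union of intervals, returned sorted by genomic start."""
    if not ivs:
        return []
    ivs = sorted(ivs)
    out = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def _width(ivs: list[Interval]) -> int:
    return sum(e - s for s, e in ivs)


@dataclass
class GeneModel:
    """A gene's stranded exonic structure split into 5'UTR / CDS / 3'UTR.

    ``utr5``, ``cds`` and ``utr3`` are disjoint genomic interval lists; in
    transcript orientation they appear in that order.  Interval lists are
    stored sorted by genomic start regardless of strand.
    """

    gene_id: str
    chrom: str
    strand: str
    utr5: list[Interval] = field(default_factory=list)
    cds: list[Interval] = field(default_factory=list)
    utr3: list[Interval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"{self.gene_id}: strand must be '+' or '-'")
        self.utr5 = _merge_intervals(self.utr5)
        self.cds = _merge_intervals(self.cds)
        self.utr3 = _merge_intervals(self.utr3)
        if self.tx_length == 0:
            raise ValidationError(f"{self.gene_id}: gene has no exonic bases")

    # -- derived geometry ---------------------------------------------------

    @property
    def exons(self) -> list[Interval]:
        return _merge_intervals(self.utr5 + self.cds + self.utr3)

    @property
    def tx_length(self) -> int:
        return _width(self.utr5) + _width(self.cds) + _width(self.utr3)

    @property
    def utr5_length(self) -> int:
        return _width(self.utr5)

    @property
    def cds_length(self) -> int:
        return _width(self.cds)

    @property
    def utr3_length(self) -> int:
        return _width(self.utr3)

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    # -- coordinate mapping -------------------------------------------------

    def genomic_to_tx(self, pos: int) -> int:
        """Transcript coordinate of genomic base ``pos`` (must be exonic)."""
        before = 0
        for s, e in self.exons:
            if s <= pos < e:
                if self.strand == "+":
                    return before + (pos - s)
                return self.tx_length - 1 - (before + (pos - s))
            before += e - s
        raise ValueError(f"{self.gene_id}: genomic position {pos} is not exonic")

    def tx_to_genomic(self, tpos: int) -> int:
        """Genomic base of transcript coordinate ``tpos``."""
        if not 0 <= tpos < self.tx_length:
            raise ValueError(f"{self.gene_id}: transcript position {tpos} out of range")
        if self.strand == "-":
            tpos = self.tx_length - 1 - tpos
        for s, e in self.exons:
            w = e - s
            if tpos < w:
                return s + tpos
            tpos -= w
        raise AssertionError("unreachable")

    def tx_span_to_genomic(self, t_start: int, t_end: int) -> Interval:
        """Genomic bounding interval of a transcript span [t_start, t_end)."""
        if not 0 <= t_start < t_end <= self.tx_length:
            raise ValueError(
                f"{self.gene_id}: transcript span [{t_start},{t_end}) outside [0,{self.tx_length})"
            )
        a = self.tx_to_genomic(t_start)
        b = self.tx_to_genomic(t_end - 1)
        lo, hi = (a, b) if a <= b else (b, a)
        return lo, hi + 1

    def segment_of(self, tpos: int) -> str:
        """Which segment ('utr5'/'cds'/'utr3') a transcript position lies in."""
        if tpos < self.utr5_length:
            return "utr5"
        if tpos < self.utr5_length + self.cds_length:
            return "cds"
        if tpos < self.tx_length:
            return "utr3"
        raise ValueError(f"{self.gene_id}: transcript position {tpos} out of range")


def _partition_exons_by_cds(
    gene_id: str, strand: str, exons: list[Interval], cds: list[Interval]
) -> tuple[list[Interval], list[Interval], list[Interval]]:
    """Split exonic intervals into genomic 5'UTR / CDS / 3'UTR pieces."""
    cds_lo = cds[0][0]
    cds_hi = cds[-1][1]
    left: list[Interval] = []
    right: list[Interval] = []
    inner: list[Interval] = []
    for s, e in exons:
        if s < cds_lo:
            left.append((s, min(e, cds_lo)))
        if e > cds_hi:
            right.append((max(s, cds_hi), e))
        mid = (max(s, cds_lo), min(e, cds_hi))
        if mid[0] < mid[1]:
            inner.append(mid)
    if _width(inner) != _width(cds):
        raise ValidationError(f"{gene_id}: CDS extends outside annotated exons")
    if strand == "+":
        return left, inner, right
    return right, inner, left


_GTF_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def read_gene_models(path: str) -> dict[str, GeneModel]:
    """Read gene models from a GTF (exon + CDS features) or BED file.

    Returns a mapping gene_id -> :class:`GeneModel`.  Format is chosen by
    file extension (``.gtf`` vs ``.bed``).
    """
    path = str(path)
    if path.endswith((".bed", ".bed6", ".bed12")):
        return _read_bed_models(path)
    return _read_gtf_models(path)


def _read_gtf_models(path: str) -> dict[str, GeneModel]:
    exons: dict[str, list[Interval]] = {}
    cds: dict[str, list[Interval]] = {}
    meta: dict[str, tuple[str, str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 9:
                raise ParseError(f"{path} line {lineno}: expected 9 tab-separated fields")
            chrom, _src, feature, start, end, _score, strand, _frame, attrs = parts[:9]
            if feature not in ("exon", "CDS"):
                continue
            try:
                iv = (int(start) - 1, int(end))  # GTF is 1-based closed
            except ValueError as exc:
                raise ParseError(f"{path} line {lineno}: non-integer coordinates") from exc
            if iv[0] < 0 or iv[0] >= iv[1]:
                raise ParseError(f"{path} line {lineno}: invalid interval {start}-{end}")
            m = dict(_GTF_ATTR_RE.findall(attrs))
            gid = m.get("gene_id")
            if gid is None:
                raise ParseError(f"{path} line {lineno}: missing gene_id attribute")
            prev = meta.setdefault(gid, (chrom, strand))
            if prev != (chrom, strand):
                raise ValidationError(f"{gid}: inconsistent chrom/strand across GTF lines")
            bucket = exons if feature == "exon" else cds
            lst = bucket.setdefault(gid, [])
            if iv in lst:
                logger.warning("%s line %d: duplicate %s line for %s ignored", path, lineno, feature, gid)
                continue
            lst.append(iv)
    models: dict[str, GeneModel] = {}
    for gid, (chrom, strand) in meta.items():
        ex = _merge_intervals(exons.get(gid, []))
        if not ex:
            raise ValidationError(f"{gid}: no exon features")
        cd = _merge_intervals(cds.get(gid, []))
        if not cd:
            logger.warning("%s: no CDS feature; treating whole gene body as CDS", gid)
            cd = ex
        u5, inner, u3 = _partition_exons_by_cds(gid, strand, ex, cd)
        models[gid] = GeneModel(gid, chrom, strand, utr5=u5, cds=inner, utr3=u3)
    return models


def _read_bed_models(path: str) -> dict[str, GeneModel]:
    models: dict[str, GeneModel] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ParseError(f"{path} line {lineno}: need >= 6 BED columns")
            chrom, start, end, name, _score, strand = parts[:6]
            try:
                s, e = int(start), int(end)
            except ValueError as exc:
                raise ParseError(f"{path} line {lineno}: non-integer coordinates") from exc
            if s >= e:
                raise ParseError(f"{path} line {lineno}: start >= end")
            if name in models:
                raise ValidationError(f"{path} line {lineno}: duplicate gene id {name}")
            if len(parts) >= 8:
                thick = (int(parts[6]), int(parts[7]))
            else:
                thick = (s, e)
            exons = [(s, e)]
            if len(parts) >= 12:  # BED12 blocks
                sizes = [int(x) for x in parts[10].rstrip(",").split(",")]
                starts = [int(x) for x in parts[11].rstrip(",").split(",")]
                exons = [(s + bs, s + bs + sz) for bs, sz in zip(starts, sizes)]
            if thick[0] == thick[1]:
                cds = exons
            else:
                cds = [
                    (max(a, thick[0]), min(b, thick[1]))
                    for a, b in exons
                    if max(a, thick[0]) < min(b, thick[1])
                ]
            u5, inner, u3 = _partition_exons_by_cds(name, strand, _merge_intervals(exons), _merge_intervals(cds))
            models[name] = GeneModel(name, chrom, strand, utr5=u5, cds=inner, utr3=u3)
    return models


def write_gene_models_gtf(models: dict[str, GeneModel], path: str) -> None:
    """Write models as an Ensembl-dialect GTF (exon + CDS features)."""
    with open(path, "w") as fh:
        for gid in sorted(models):
            m = models[gid]
            attrs = f'gene_id "{gid}"; transcript_id "{gid}.t1";'
            for s, e in m.exons:
                fh.write(f"{m.chrom}\tmeripdm\texon\t{s + 1}\t{e}\t.\t{m.strand}\t.\t{attrs}\n")
            for s, e in m.cds:
                fh.write(f"{m.chrom}\tmeripdm\tCDS\t{s + 1}\t{e}\t.\t{m.strand}\t0\t{attrs}\n")


# ---------------------------------------------------------------------------
# Sample design
# ---------------------------------------------------------------------------

CONDITIONS = ("CTRL", "CASE")
ASSAYS = ("IP", "INPUT")


@dataclass
class SampleDesign:
    """Sample sheet: one row per library, plus arbitrary covariate columns.

    Required columns: sample_id, subject, condition (CTRL/CASE),
    assay (IP/INPUT).  Everything else is treated as a covariate.
    """

    table: pd.DataFrame

    REQUIRED = ("sample_id", "subject", "condition", "assay")

    def __post_init__(self) -> None:
        t = self.table
        for col in self.REQUIRED:
            if col not in t.columns:
                raise ValidationError(f"design table missing column {col!r}")
        if t["sample_id"].duplicated().any():
            raise ValidationError("duplicate sample_id in design table")
        bad = set(t["condition"]) - set(CONDITIONS)
        if bad:
            raise ValidationError(f"unknown condition values {bad}; expected {CONDITIONS}")
        bad = set(t["assay"]) - set(ASSAYS)
        if bad:
            raise ValidationError(f"unknown assay values {bad}; expected {ASSAYS}")
        dup = t.groupby(["subject", "condition", "assay"]).size()
        if (dup > 1).any():
            key = dup[dup > 1].index[0]
            raise ValidationError(f"more than one {key[2]} library for subject={key[0]} condition={key[1]}")
        self.table = t.reset_index(drop=True)

    @property
    def covariate_names(self) -> list[str]:
        return [c for c in self.table.columns if c not in self.REQUIRED]

    def subset(self, assay: str | None = None, condition: str | None = None) -> "SampleDesign":
        t = self.table
        if assay is not None:
            t = t[t["assay"] == assay]
        if condition is not None:
            t = t[t["condition"] == condition]
        return SampleDesign(t.copy())

    def sample_ids(self, assay: str | None = None, condition: str | None = None) -> list[str]:
        return list(self.subset(assay, condition).table["sample_id"])

    def input_partner(self, ip_sample_id: str) -> str:
        """Input library of the same subject and condition as an IP library."""
        t = self.table
        row = t[t["sample_id"] == ip_sample_id]
        if row.empty:
            raise KeyError(ip_sample_id)
        subj, cond = row.iloc[0]["subject"], row.iloc[0]["condition"]
        match = t[(t["subject"] == subj) & (t["condition"] == cond) & (t["assay"] == "INPUT")]
        if match.empty:
            raise ValidationError(f"subject {subj} ({cond}) has no INPUT library")
        return match.iloc[0]["sample_id"]

    @classmethod
    def from_tsv(cls, path: str) -> "SampleDesign":
        return cls(pd.read_csv(path, sep="\t", dtype={"sample_id": str, "subject": str}))

    def to_tsv(self, path: str) -> None:
        self.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Count matrices
# ---------------------------------------------------------------------------


@dataclass
class CountMatrix:
    """Features x samples numeric matrix with ordered id lists.

    Counts are integers at ingest; fractional values appear only after
    input adjustment (``allow_fractional``).
    """

    feature_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray
    allow_fractional: bool = False

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValidationError(
                f"matrix shape {self.counts.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValidationError("duplicate feature ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample ids")
        if np.any(self.counts < 0):
            raise ValidationError("negative counts")
        if not np.all(np.isfinite(self.counts)):
            raise ValidationError("non-finite counts")
        if not self.allow_fractional and np.any(self.counts != np.round(self.counts)):
            raise ValidationError("fractional counts not permitted at ingest")

    # -- conversions --------------------------------------------------------

    def to_df(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.feature_ids, columns=self.sample_ids)

    @classmethod
    def from_df(cls, df: pd.DataFrame, allow_fractional: bool = False) -> "CountMatrix":
        return cls(list(df.index.astype(str)), list(df.columns.astype(str)), df.to_numpy(float), allow_fractional)

    def subset_samples(self, sample_ids: list[str]) -> "CountMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return CountMatrix(list(self.feature_ids), list(sample_ids), self.counts[:, idx], self.allow_fractional)

    def subset_features(self, feature_ids: list[str]) -> "CountMatrix":
        pos = {f: i for i, f in enumerate(self.feature_ids)}
        idx = [pos[f] for f in feature_ids]
        return CountMatrix(list(feature_ids), list(self.sample_ids), self.counts[idx, :], self.allow_fractional)

    # -- IO -----------------------------------------------------------------

    @classmethod
    def from_tsv(cls, path: str, allow_fractional: bool = False) -> "CountMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if df.index.duplicated().any():
            raise ValidationError(f"{path}: duplicate feature id")
        try:
            mat = df.to_numpy(dtype=float)
        except ValueError as exc:
            raise ValidationError(f"{path}: non-numeric cell") from exc
        if np.isnan(mat).any():
            raise ValidationError(f"{path}: non-numeric or missing cell")
        return cls(list(df.index.astype(str)), list(df.columns.astype(str)), mat, allow_fractional)

    def to_tsv(self, path: str) -> None:
        df = self.to_df()
        if not self.allow_fractional:
            df = df.astype(int)
        df.to_csv(path, sep="\t", index_label="feature_id")

    @classmethod
    def from_mtx(cls, mtx_path: str, features_path: str, samples_path: str,
                 allow_fractional: bool = False) -> "CountMatrix":
        mat = scipy_io.mmread(mtx_path)
        feats = [line.strip() for line in open(features_path) if line.strip()]
        samps = [line.strip() for line in open(samples_path) if line.strip()]
        return cls(feats, samps, np.asarray(sparse.coo_matrix(mat).todense(), dtype=float),
                   allow_fractional)

    def to_mtx(self, mtx_path: str, features_path: str, samples_path: str) -> None:
        scipy_io.mmwrite(mtx_path, sparse.coo_matrix(self.counts))
        with open(features_path, "w") as fh:
            fh.write("\n".join(self.feature_ids) + "\n")
        with open(samples_path, "w") as fh:
            fh.write("\n".join(self.sample_ids) + "\n")


def read_counts(path: str, allow_fractional: bool = False) -> CountMatrix:
    """Read a count matrix from TSV (or MTX if given the .mtx path with
    sibling ``<stem>.features.txt`` / ``<stem>.samples.txt`` files)."""
    path = str(path)
    if path.endswith(".mtx"):
        stem = path[:-4]
        return CountMatrix.from_mtx(path, stem + ".features.txt", stem + ".samples.txt", allow_fractional)
    return CountMatrix.from_tsv(path, allow_fractional)


# ---------------------------------------------------------------------------
# Region output
# ---------------------------------------------------------------------------


def bed_score(fdr: float) -> int:
    """BED score: -10*log10(FDR), rounded, capped at 1000."""
    if fdr <= 0:
        return 1000
    return min(1000, int(round(-10.0 * math.log10(fdr))))


def write_regions(regions, models: dict[str, GeneModel], bed_path: str, tsv_path: str,
                  bin_width: int = 50) -> None:
    """Write DM regions as a genomic BED6 plus a statistics TSV.

    ``regions`` is a list of :class:`meripdm.peak_merge.DmRegion`.  The BED
    interval is the genomic bounding span of the region's transcript span;
    score is -10*log10(FDR) capped at 1000.
    """
    rows = []
    bed_lines = []
    for r in regions:
        model = models[r.gene_id]
        g_start, g_end = model.tx_span_to_genomic(r.tx_start, r.tx_end)
        score = bed_score(r.fdr)
        name = f"{r.gene_id}:{r.bin_start}-{r.bin_end}:{r.direction}"
        bed_lines.append(f"{model.chrom}\t{g_start}\t{g_end}\t{name}\t{score}\t{model.strand}")
        rows.append({
            "gene_id": r.gene_id, "bin_start": r.bin_start, "bin_end": r.bin_end,
            "tx_start": r.tx_start, "tx_end": r.tx_end,
            "chrom": model.chrom, "genomic_start": g_start, "genomic_end": g_end,
            "strand": model.strand, "direction": r.direction, "n_bins": r.n_bins,
            "mean_log2fc": r.mean_log2fc, "combined_p": r.combined_p, "fdr": r.fdr,
        })
    with open(bed_path, "w") as fh:
        fh.write("\n".join(bed_lines) + ("\n" if bed_lines else ""))
    pd.DataFrame(rows, columns=[
        "gene_id", "bin_start", "bin_end", "tx_start", "tx_end", "chrom",
        "genomic_start", "genomic_end", "strand", "direction", "n_bins",
        "mean_log2fc", "combined_p", "fdr",
    ]).to_csv(tsv_path, sep="\t", index=False)
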