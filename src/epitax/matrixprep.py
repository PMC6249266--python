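"""View-matrix construction: CPM filtering, TMM normalization, consensus peaksets,
read-in-region counting, occupancy curves, FRiP QC and MAD feature selection.

Counts are modelled as sequencing-depth-confounded; normalization follows the
trimmed-mean-of-M-values (TMM) scheme: per-sample scaling factors estimated
from log ratios of library-size-normalized proportions against a reference
library, after two-sided trimming of extreme log-ratios (M) and extreme
average abundances (A), with inverse-variance (precision) weighting. Factors
are rescaled to geometric mean 1.

All genomic intervals are 0-based half-open and unstranded.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

logger = logging.getLogger("epitax")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    score: float | None = None

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"requires 0 <= start < end, got [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class NormalizedMatrix:
    """Log2-normalized feature-by-sample matrix with its normalization provenance."""

    values: pd.DataFrame            # features x samples, log2 units
    lib_size: pd.Series             # per-sample library size
    tmm_factors: pd.Series          # per-sample TMM factor, geometric mean 1
    provenance: str = "log2-CPM-TMM"

    def __post_init__(self):
        if not (self.tmm_factors > 0).all():
            raise ValueError("TMM factors must be strictly positive")
        gm = float(np.exp(np.mean(np.log(self.tmm_factors.to_numpy(float)))))
        if abs(gm - 1.0) > 1e-9:
            raise ValueError(f"TMM factors must have geometric mean 1, got {gm}")
        if not self.values.columns.equals(self.lib_size.index):
            raise ValueError("sample IDs of values and lib_size disagree")

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def feature_ids(self) -> pd.Index:
        return self.values.index


@dataclass
class FeatureSelection:
    """Most-variable-feature selection by median absolute deviation."""

    mad: pd.Series                  # per-feature MAD
    selected: np.ndarray            # positional indices into the input feature axis
    top_n: int


@dataclass
class QCMetrics:
    """Per-sample ChIP enrichment QC: FRiP, peak count, read count."""

    frip: pd.Series
    n_peaks: pd.Series
    n_reads: pd.Series

    def __post_init__(self):
        ok = self.frip.dropna()
        if ((ok < 0) | (ok > 1)).any():
            raise ValueError("FRiP must lie in [0, 1]")


# ---------------------------------------------------------------------------
# count-matrix operations
# ---------------------------------------------------------------------------

def cpm_filter(counts: pd.DataFrame, min_cpm: float = 1.0, min_samples: int = 10) -> np.ndarray:
    """Indices of features with CPM strictly greater than ``min_cpm`` in at
    least ``min_samples`` samples.

    CPM = count / library size * 1e6, library size = column sum. The
    inequality is strict: a gene at exactly ``min_cpm`` everywhere is removed.
    """
    mat = counts.to_numpy(float)
    if (mat < 0).any():
        raise ValueError("counts must be non-negative")
    lib = mat.sum(axis=0)
    if (lib == 0).any():
        bad = counts.columns[np.flatnonzero(lib == 0)[0]]
        raise ValueError(f"sample {bad!r} has an all-zero library")
    cpm = mat / lib * 1e6
    keep = (cpm > min_cpm).sum(axis=1) >= min_samples
    return np.flatnonzero(keep)


def _tmm_one(obs: np.ndarray, ref: np.ndarray, n_obs: float, n_ref: float,
             trim_m: float = 0.30, trim_a: float = 0.05) -> float:
    """TMM factor of one library against the reference (before geometric-mean rescaling)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        log_r = np.log2((obs / n_obs) / (ref / n_ref))
        abs_e = (np.log2(obs / n_obs) + np.log2(ref / n_ref)) / 2.0
        v = (n_obs - obs) / n_obs / obs + (n_ref - ref) / n_ref / ref
    fin = np.isfinite(log_r) & np.isfinite(abs_e)
    if not fin.any():
        warnings.warn("no features nonzero in both libraries; TMM factor set to 1")
        return 1.0
    log_r, abs_e, v = log_r[fin], abs_e[fin], v[fin]
    if np.max(np.abs(log_r)) < 1e-6:
        return 1.0
    n = log_r.size
    lo_l = np.floor(n * trim_m) + 1
    hi_l = n + 1 - lo_l
    lo_s = np.floor(n * trim_a) + 1
    hi_s = n + 1 - lo_s
    rank_m = rankdata(log_r)
    rank_a = rankdata(abs_e)
    keep = (rank_m >= lo_l) & (rank_m <= hi_l) & (rank_a >= lo_s) & (rank_a <= hi_s)
    if not keep.any():
        return 1.0
    f = np.sum(log_r[keep] / v[keep]) / np.sum(1.0 / v[keep])
    if not np.isfinite(f):
        f = 0.0
    return float(2.0 ** f)


def tmm_factors(counts: pd.DataFrame, ref_sample: int | None = None) -> pd.Series:
    """Per-sample TMM normalization factors, rescaled to geometric mean 1.

    Reference sample (when not given): the library whose upper-quartile
    count proportion is closest to the mean upper-quartile proportion.
    """
    mat = counts.to_numpy(float)
    if mat.shape[1] < 2:
        raise ValueError("TMM needs at least 2 samples")
    if (mat < 0).any():
        raise ValueError("counts must be non-negative")
    lib = mat.sum(axis=0)
    if ref_sample is None:
        uq = np.quantile(mat / lib, 0.75, axis=0)
        ref_sample = int(np.argmin(np.abs(uq - uq.mean())))
    ref = mat[:, ref_sample]
    f = np.array([
        _tmm_one(mat[:, j], ref, lib[j], lib[ref_sample]) for j in range(mat.shape[1])
    ])
    f = f / np.exp(np.mean(np.log(f)))
    return pd.Series(f, index=counts.columns, name="tmm_factor")


def normalize_log(counts: pd.DataFrame, factors: pd.Series | None = None,
                  pseudocount: float = 0.5) -> NormalizedMatrix:
    """log2( count / (library size * TMM factor) * 1e6 + pseudocount )."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    if factors is None:
        factors = tmm_factors(counts)
    factors = factors.reindex(counts.columns)
    lib = counts.sum(axis=0).astype(float)
    eff = lib * factors
    vals = np.log2(counts.to_numpy(float) / eff.to_numpy() * 1e6 + pseudocount)
    return NormalizedMatrix(
        values=pd.DataFrame(vals, index=counts.index, columns=counts.columns),
        lib_size=lib,
        tmm_factors=factors,
        provenance=f"log2-CPM-TMM(pseudocount={pseudocount})",
    )


def mad_select(matrix: NormalizedMatrix | pd.DataFrame, top_n: int) -> FeatureSelection:
    """Select the ``top_n`` most variable features by median absolute deviation.

    MAD(x) = median(|x - median(x)|), unscaled. Sort is descending and stable,
    so ties keep input order; sample order cannot affect the selection.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    values = matrix.values if isinstance(matrix, NormalizedMatrix) else matrix
    x = values.to_numpy(float)
    med = np.median(x, axis=1, keepdims=True)
    mad = np.median(np.abs(x - med), axis=1)
    n_usable = int(np.isfinite(mad).sum())
    if top_n > x.shape[0]:
        warnings.warn(f"top_n={top_n} exceeds feature count {x.shape[0]}; returning all")
    order = np.argsort(-np.where(np.isfinite(mad), mad, -np.inf), kind="stable")
    selected = order[: min(top_n, n_usable)]
    return FeatureSelection(mad=pd.Series(mad, index=values.index, name="mad"),
                            selected=selected, top_n=top_n)


# ---------------------------------------------------------------------------
# interval operations (event sweeps; all coordinates 0-based half-open)
# ---------------------------------------------------------------------------

def _merge_intervals(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Merge overlapping (not merely abutting) intervals; returns sorted arrays."""
    if starts.size == 0:
        return starts, ends
    order = np.argsort(starts, kind="stable")
    starts, ends = starts[order], ends[order]
    out_s, out_e = [starts[0]], [ends[0]]
    for s, e in zip(starts[1:], ends[1:]):
        if s < out_e[-1]:
            out_e[-1] = max(out_e[-1], e)
        else:
            out_s.append(s)
            out_e.append(e)
    return np.asarray(out_s), np.asarray(out_e)


def _support_profile(peak_sets: dict[str, pd.DataFrame], chrom: str):
    """Breakpoints and per-segment sample-support counts for one chromosome.

    Returns (pos, support): support[i] holds over [pos[i], pos[i+1]).
    Each sample contributes 0/1 coverage (its peaks are merged first).
    """
    events = []
    for df in peak_sets.values():
        sub = df[df["chrom"] == chrom]
        if sub.empty:
            continue
        s, e = _merge_intervals(sub["start"].to_numpy(int), sub["end"].to_numpy(int))
        events.append((s, e))
    if not events:
        return np.array([], dtype=int), np.array([], dtype=int)
    starts = np.concatenate([s for s, _ in events])
    ends = np.concatenate([e for _, e in events])
    pos = np.unique(np.concatenate([starts, ends]))
    delta = np.zeros(pos.size, dtype=int)
    np.add.at(delta, np.searchsorted(pos, starts), 1)
    np.add.at(delta, np.searchsorted(pos, ends), -1)
    support = np.cumsum(delta)
    return pos, support


def consensus_peaks(peak_sets: dict[str, pd.DataFrame], min_support: int) -> pd.DataFrame:
    """Maximal regions supported by peaks from >= ``min_support`` samples.

    A sample supports a base if any of its peaks covers it; qualifying base
    ranges that touch are merged into maximal runs. Output is sorted and
    disjoint; empty input yields an empty frame.
    """
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    chroms = sorted({c for df in peak_sets.values() for c in df["chrom"].unique()})
    rows = []
    for chrom in chroms:
        pos, support = _support_profile(peak_sets, chrom)
        if pos.size == 0:
            continue
        ok = support >= min_support
        # maximal runs of qualifying segments
        i = 0
        while i < len(ok) - 1:
            if ok[i]:
                j = i
                while j < len(ok) - 1 and ok[j]:
                    j += 1
                rows.append((chrom, int(pos[i]), int(pos[j])))
                i = j
            else:
                i += 1
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def occupancy_curve(peak_sets: dict[str, pd.DataFrame]) -> pd.Series:
    """c(n) = number of consensus regions at support threshold n, n = 1..N samples.

    Non-increasing in n; c(1) equals the union-level region count.
    """
    n_samples = len(peak_sets)
    if n_samples < 1:
        raise ValueError("need at least one sample")
    counts = np.zeros(n_samples + 2, dtype=int)
    chroms = sorted({c for df in peak_sets.values() for c in df["chrom"].unique()})
    for chrom in chroms:
        pos, support = _support_profile(peak_sets, chrom)
        if pos.size == 0:
            continue
        prev = 0
        for s in support:
            if s > prev:  # upcrossing: a new region begins for thresholds (prev, s]
                counts[prev + 1] += 1
                counts[min(s, n_samples) + 1] -= 1
            prev = s
    c = np.cumsum(counts)[1 : n_samples + 1]
    return pd.Series(c, index=pd.RangeIndex(1, n_samples + 1, name="support"), name="n_regions")


def count_reads_in_regions(reads: dict[str, pd.DataFrame],
                           regions: pd.DataFrame) -> pd.DataFrame:
    """Count reads overlapping each region by >= 1 base (regions x samples).

    A read overlapping two regions is counted in both. Half-open convention:
    a read abutting a region boundary does not overlap. Reads on chromosomes
    absent from ``regions`` are skipped with a warning.
    """
    region_chroms = set(regions["chrom"].unique())
    out = np.zeros((len(regions), len(reads)), dtype=int)
    for j, (sample, df) in enumerate(reads.items()):
        unknown = set(df["chrom"].unique()) - region_chroms
        if unknown:
            warnings.warn(
                f"sample {sample!r}: skipping reads on chromosomes without regions: "
                f"{sorted(unknown)}"
            )
        for chrom, sub in df.groupby("chrom", sort=False):
            mask = (regions["chrom"] == chrom).to_numpy()
            if not mask.any():
                continue
            rs = np.sort(sub["start"].to_numpy(int))
            re_ = np.sort(sub["end"].to_numpy(int))
            gs = regions.loc[mask, "start"].to_numpy(int)
            ge = regions.loc[mask, "end"].to_numpy(int)
            # overlap count = #(read start < region end) - #(read end <= region start)
            out[mask, j] = (
                np.searchsorted(rs, ge, side="left")
                - np.searchsorted(re_, gs, side="right")
            )
    index = [f"{c}:{s}-{e}" for c, s, e in
             zip(regions["chrom"], regions["start"], regions["end"])]
    return pd.DataFrame(out, index=index, columns=list(reads.keys()))


def frip(reads: dict[str, pd.DataFrame], peaks: dict[str, pd.DataFrame] | pd.DataFrame) -> pd.Series:
    """Fraction of reads overlapping any peak, per sample; each read counted once.

    ``peaks`` may be per-sample (each sample scored against its own peaks) or a
    single shared interval set. Samples with zero reads get NaN.
    """
    out = {}
    for sample, df in reads.items():
        pk = peaks[sample] if isinstance(peaks, dict) else peaks
        total = len(df)
        if total == 0:
            warnings.warn(f"sample {sample!r} has zero reads; FRiP undefined")
            out[sample] = np.nan
            continue
        hits = 0
        for chrom, sub in df.groupby("chrom", sort=False):
            psub = pk[pk["chrom"] == chrom]
            if psub.empty:
                continue
            ps, pe = _merge_intervals(psub["start"].to_numpy(int), psub["end"].to_numpy(int))
            rs = sub["start"].to_numpy(int)
            re_ = sub["end"].to_numpy(int)
            idx = np.searchsorted(pe, rs, side="right")  # first peak ending after read start
            ok = idx < ps.size
            hit = np.zeros(rs.size, dtype=bool)
            hit[ok] = ps[idx[ok]] < re_[ok]
            hits += int(hit.sum())
        out[sample] = hits / total
    return pd.Series(out, name="frip")


def qc_metrics(reads: dict[str, pd.DataFrame], peaks: dict[str, pd.DataFrame]) -> QCMetrics:
    """Per-sample FRiP (against the sample's own peaks), peak and read counts."""
    return QCMetrics(
        frip=frip(reads, peaks),
        n_peaks=pd.Series({s: len(df) for s, df in peaks.items()}, name="n_peaks"),
        n_reads=pd.Series({s: len(df) for s, df in reads.items()}, name="n_reads"),
    )
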