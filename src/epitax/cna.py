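"""Copy-number profiles from off-target reads.

Reads overlapping (padded) peaks are discarded as on-target; the rest are
counted in a fixed genome-wide bin grid (400 kb by default). Per-bin log2
ratios are median-centered over autosomal bins. Segmentation is a
permutation-tested circular binary segmentation (CBS): per chromosome the
arc maximizing the circular two-sample t-statistic is split off when its
within-segment permutation p-value clears alpha, recursively. Gain/loss
calls come from fixed segment-mean thresholds, and the CNA burden of a
sample is the fraction of bins called gained or lost.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

SEX_CHROMS = {"chrx", "chry", "x", "y"}


@dataclass
class BinnedProfile:
    """Fixed-grid binned off-target read counts with median-centered log2 ratios."""

    bins: pd.DataFrame       # chrom, start, end
    counts: np.ndarray       # per-bin off-target read count
    log2: np.ndarray         # log2(count + 0.5) - autosomal median

    def __post_init__(self):
        if len(self.bins) != len(self.counts) or len(self.counts) != len(self.log2):
            raise ValueError("bins, counts and log2 must be parallel")


@dataclass
class SegmentedProfile:
    """CBS segments, per-bin gain/loss calls and the resulting burden."""

    bins: pd.DataFrame
    segments: pd.DataFrame   # chrom, start_bin, end_bin (half-open, per-chrom), start, end, mean_log2
    calls: np.ndarray        # per-bin: -1 loss, 0 neutral, +1 gain
    burden: float

    def __post_init__(self):
        if not (0.0 <= self.burden <= 1.0):
            raise ValueError("burden must lie in [0, 1]")


def make_bins(genome: pd.Series, bin_size: int = 400_000) -> pd.DataFrame:
    """Tile each chromosome with fixed-size bins (last bin truncated)."""
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    rows = []
    for chrom, size in genome.items():
        size = int(size)
        edges = list(range(0, size, bin_size)) + [size]
        for s, e in zip(edges[:-1], edges[1:]):
            if e > s:
                rows.append((chrom, s, e))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def _is_autosome(chroms: pd.Series) -> np.ndarray:
    return ~chroms.str.lower().isin(SEX_CHROMS).to_numpy()


def offtarget_bin_counts(reads: pd.DataFrame, peaks: pd.DataFrame,
                         genome: pd.Series, bin_size: int = 400_000,
                         peak_pad: int = 1000) -> BinnedProfile:
    """Bin off-target reads of one sample.

    Peaks are padded by ``peak_pad`` on both sides; reads overlapping any
    padded peak are removed. Remaining reads are assigned to the bin
    containing their start. log2 ratio = log2(count + 0.5) centered at the
    median over autosomal bins.
    """
    from .matrixprep import _merge_intervals

    bins = make_bins(genome, bin_size)
    keep = np.ones(len(reads), dtype=bool)
    for chrom, psub in peaks.groupby("chrom", sort=False):
        ps, pe = _merge_intervals(
            np.maximum(psub["start"].to_numpy(int) - peak_pad, 0),
            psub["end"].to_numpy(int) + peak_pad,
        )
        sel = (reads["chrom"] == chrom).to_numpy()
        if not sel.any():
            continue
        rs = reads.loc[sel, "start"].to_numpy(int)
        re_ = reads.loc[sel, "end"].to_numpy(int)
        idx = np.searchsorted(pe, rs, side="right")
        hit = np.zeros(rs.size, dtype=bool)
        ok = idx < ps.size
        hit[ok] = ps[idx[ok]] < re_[ok]
        keep[sel] = ~hit
    off = reads[keep]

    counts = np.zeros(len(bins), dtype=int)
    for chrom, sub in off.groupby("chrom", sort=False):
        sel = (bins["chrom"] == chrom).to_numpy()
        if not sel.any():
            warnings.warn(f"reads on {chrom!r} fall outside the genome table; skipped")
            continue
        offset = int(np.flatnonzero(sel)[0])
        n_chrom_bins = int(sel.sum())
        b = sub["start"].to_numpy(int) // bin_size
        b = b[(b >= 0) & (b < n_chrom_bins)]
        counts[offset:offset + n_chrom_bins] += np.bincount(b, minlength=n_chrom_bins)

    log2 = np.log2(counts + 0.5)
    auto = _is_autosome(bins["chrom"])
    log2 = log2 - np.median(log2[auto]) if auto.any() else log2 - np.median(log2)
    return BinnedProfile(bins=bins, counts=counts, log2=log2)


# ---------------------------------------------------------------------------
# circular binary segmentation
# ---------------------------------------------------------------------------

def _max_arc_t(x_cum: np.ndarray, x2_cum: np.ndarray, n: int, min_width: int):
    """Maximum |t| over arcs [i, j) with all resulting pieces >= min_width.

    ``x_cum``/``x2_cum`` are (n_perm, n+1) prefix sums of values and squares.
    Returns (max_abs_t per row, (i, j) of the best arc for row 0).
    """
    total = x_cum[:, -1]
    total2 = x2_cum[:, -1]
    best = np.zeros(x_cum.shape[0])
    best_arc = (0, n)
    for L in range(1, n):
        m = n - L
        # windows [i, i+L) for i = 0..n-L
        w = x_cum[:, L:] - x_cum[:, :-L]
        w2 = x2_cum[:, L:] - x2_cum[:, :-L]
        i_arr = np.arange(n - L + 1)
        # piece widths: before = i, arc = L, after = n - L - i
        valid = (L >= min_width) & (m >= min_width) \
            & ((i_arr == 0) | (i_arr >= min_width)) \
            & ((i_arr == n - L) | (n - L - i_arr >= min_width))
        if not valid.any():
            continue
        mean1 = w / L
        mean2 = (total[:, None] - w) / m
        ss1 = w2 - w * w / L
        ss2 = (total2[:, None] - w2) - (total[:, None] - w) ** 2 / m
        varp = (ss1 + ss2) / max(n - 2, 1)
        denom = np.sqrt(np.maximum(varp, 0.0) * (1.0 / L + 1.0 / m))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.abs(mean1 - mean2) / denom
        t = np.where(np.isfinite(t) & valid[None, :], t, 0.0)
        row_best = t.max(axis=1)
        improved = row_best > best
        if improved[0]:
            j = int(np.argmax(t[0]))
            best_arc = (j, j + L)
        best = np.maximum(best, row_best)
    return best, best_arc


def _split_segment(x: np.ndarray, alpha: float, n_perm: int, min_width: int,
                   rng: np.random.Generator):
    """One CBS decision on a contiguous stretch: best arc + permutation p."""
    n = x.size
    if n < 2 * min_width:
        return None
    cum = np.concatenate([[0.0], np.cumsum(x)])[None, :]
    cum2 = np.concatenate([[0.0], np.cumsum(x * x)])[None, :]
    obs, arc = _max_arc_t(cum, cum2, n, min_width)
    if obs[0] <= 0:
        return None
    perms = np.empty((n_perm, n))
    for r in range(n_perm):
        perms[r] = rng.permutation(x)
    p_cum = np.concatenate([np.zeros((n_perm, 1)), np.cumsum(perms, axis=1)], axis=1)
    p_cum2 = np.concatenate([np.zeros((n_perm, 1)), np.cumsum(perms * perms, axis=1)], axis=1)
    null, _ = _max_arc_t(p_cum, p_cum2, n, min_width)
    p = (1.0 + float(np.sum(null >= obs[0]))) / (n_perm + 1.0)
    if p < alpha:
        return arc
    return None


def cbs_segment(profile: BinnedProfile, alpha: float = 0.01, n_perm: int = 1000,
                min_width: int = 3, seed: int | None = None) -> pd.DataFrame:
    """Segment the binned log2 profile per chromosome by recursive CBS.

    Each accepted arc introduces up to two breakpoints; recursion continues
    inside every resulting piece until no split clears the permutation test.
    Permutations are seeded deterministically per (chromosome, piece), so the
    same seed yields the same segmentation and a smaller alpha can only
    remove splits.
    """
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives unstable permutation p-values")
    rows = []
    chroms = profile.bins["chrom"].unique()
    for ci, chrom in enumerate(chroms):
        sel = (profile.bins["chrom"] == chrom).to_numpy()
        x = profile.log2[sel]
        if x.size < min_width:
            warnings.warn(f"{chrom!r} has fewer than min_width bins; single segment")
        pieces = [(0, x.size)]
        final = []
        while pieces:
            lo, hi = pieces.pop()
            rng = np.random.default_rng([0 if seed is None else seed, ci, lo, hi])
            arc = _split_segment(x[lo:hi], alpha, n_perm, min_width, rng)
            if arc is None:
                final.append((lo, hi))
            else:
                i, j = arc
                for piece in ((lo, lo + i), (lo + i, lo + j), (lo + j, hi)):
                    if piece[1] > piece[0]:
                        pieces.append(piece)
        starts = profile.bins.loc[sel, "start"].to_numpy()
        ends = profile.bins.loc[sel, "end"].to_numpy()
        for lo, hi in sorted(final):
            rows.append({"chrom": chrom, "start_bin": lo, "end_bin": hi,
                         "start": int(starts[lo]), "end": int(ends[hi - 1]),
                         "mean_log2": float(x[lo:hi].mean())})
    return pd.DataFrame(rows, columns=["chrom", "start_bin", "end_bin",
                                       "start", "end", "mean_log2"])


def call_bins(profile: BinnedProfile, segments: pd.DataFrame,
              gain_thr: float = 0.2, loss_thr: float = -0.2,
              include_sex: bool = False) -> SegmentedProfile:
    """Per-bin gain/loss calls from segment means, plus CNA burden.

    A bin is called gained when its segment mean >= ``gain_thr``, lost when
    <= ``loss_thr``. Burden = (#gain + #loss) / #bins, over autosomal bins
    unless ``include_sex``.
    """
    if not (gain_thr > 0 > loss_thr):
        raise ValueError("requires gain_thr > 0 > loss_thr")
    calls = np.zeros(len(profile.bins), dtype=int)
    for chrom, segs in segments.groupby("chrom", sort=False):
        sel = (profile.bins["chrom"] == chrom).to_numpy()
        offset = int(np.flatnonzero(sel)[0])
        for _, seg in segs.iterrows():
            lo, hi = offset + int(seg["start_bin"]), offset + int(seg["end_bin"])
            if seg["mean_log2"] >= gain_thr:
                calls[lo:hi] = 1
            elif seg["mean_log2"] <= loss_thr:
                calls[lo:hi] = -1
    use = np.ones(len(profile.bins), dtype=bool) if include_sex \
        else _is_autosome(profile.bins["chrom"])
    burden = float(np.mean(calls[use] != 0)) if use.any() else 0.0
    return SegmentedProfile(bins=profile.bins, segments=segments,
                            calls=calls, burden=burden)
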