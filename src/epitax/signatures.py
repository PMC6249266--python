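"""Expression-based tumor characterization.

Weighted signature scores (androgen-receptor activity, CD49f and the like)
are signed sums of weights times per-gene z-standardized log2 expression.
Centroid classification (PAM50-style) assigns each sample the class whose
centroid profile correlates best with it. Neuroendocrine-likeness is a
Pearson concordance of fold-change vectors. ERG status is derived two ways:
a two-component Gaussian mixture split of its expression, and the 5'-3'
transcript ratio against a fixed threshold. The printed reference ERG exon
coordinates (hg19, 1-based inclusive) ship as defaults, converted to 0-based
half-open on ingestion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.mixture import GaussianMixture

from .matrixprep import GenomicInterval, NormalizedMatrix

# Reference ERG exon intervals (converted from 1-based inclusive hg19 print to
# 0-based half-open): five 5' exons and one 3' exon. ERG is minus-strand, so
# the 5' end of the transcript sits at the higher genomic coordinates.
ERG_FIVE_PRIME_EXONS = (
    GenomicInterval("chr21", 39_870_286, 39_870_428),
    GenomicInterval("chr21", 39_947_585, 39_947_671),
    GenomicInterval("chr21", 39_956_767, 39_956_869),
    GenomicInterval("chr21", 40_033_581, 40_033_704),
    GenomicInterval("chr21", 40_032_445, 40_032_591),
)
ERG_THREE_PRIME_EXON = GenomicInterval("chr21", 39_751_949, 39_755_845)
ERG_RATIO_THRESHOLD = 0.3


@dataclass
class SignatureDefinition:
    """A named, weighted gene signature."""

    name: str
    weights: pd.Series          # index: gene ID; values: signed weights

    def __post_init__(self):
        self.weights = pd.Series(self.weights, dtype=float)
        if len(self.weights) < 1:
            raise ValueError("signature needs >= 1 gene")
        if not np.isfinite(self.weights.to_numpy()).all():
            raise ValueError("signature weights must be finite")

    @classmethod
    def from_tsv(cls, path, name: str | None = None) -> "SignatureDefinition":
        df = pd.read_csv(path, sep="\t")
        return cls(name=name or str(path), weights=pd.Series(
            df.iloc[:, 1].to_numpy(float), index=df.iloc[:, 0]))


@dataclass
class SignatureScore:
    """Per-sample score S_s = sum_g w_g * z_{g,s} over signature genes present."""

    name: str
    scores: pd.Series
    genes_used: int
    genes_missing: int


@dataclass
class ErgStatus:
    """Per-sample ERG expression class and 5'-3' transcript-ratio class."""

    expression_class: pd.Series | None = None   # "low"/"high"
    ratio: pd.Series | None = None
    ratio_class: pd.Series | None = None        # "high" iff ratio > threshold (strict)
    threshold: float = ERG_RATIO_THRESHOLD
    exons: tuple = field(default=(ERG_FIVE_PRIME_EXONS, ERG_THREE_PRIME_EXON))


@dataclass
class ConcordanceResult:
    rho: float
    n_genes: int

    def __post_init__(self):
        if np.isfinite(self.rho) and not (-1 - 1e-12 <= self.rho <= 1 + 1e-12):
            raise ValueError("correlation out of range")


def score_signature(expr: NormalizedMatrix | pd.DataFrame,
                    sig: SignatureDefinition) -> SignatureScore:
    """Weighted z-score signature sum.

    Each signature gene present in the matrix is z-standardized across
    samples (population sd); zero-variance genes contribute 0 with a warning.
    The scores sum to ~0 across the cohort by construction.
    """
    values = expr.values if isinstance(expr, NormalizedMatrix) else expr
    present = sig.weights.index.intersection(values.index)
    if len(present) == 0:
        raise ValueError(f"no genes of signature {sig.name!r} present in the matrix")
    missing = len(sig.weights) - len(present)
    if missing:
        warnings.warn(f"signature {sig.name!r}: {missing} genes absent from the matrix")
    x = values.loc[present].to_numpy(float)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    flat = sd.ravel() == 0
    if flat.any():
        warnings.warn(f"signature {sig.name!r}: {int(flat.sum())} zero-variance genes contribute 0")
    z = np.where(sd > 0, (x - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    w = sig.weights.loc[present].to_numpy()
    scores = pd.Series(w @ z, index=values.columns, name=sig.name)
    return SignatureScore(name=sig.name, scores=scores,
                          genes_used=len(present), genes_missing=missing)


def centroid_classify(expr: NormalizedMatrix | pd.DataFrame, centroids: pd.DataFrame,
                      method: str = "spearman") -> pd.Series:
    """Nearest-centroid classification by rank (Spearman) or Pearson correlation.

    ``centroids``: genes x classes. Classes are compared over the genes shared
    with the expression matrix (>= 3 required); ties resolve to the first
    class in centroid column order.
    """
    if centroids.shape[1] < 2:
        raise ValueError("need >= 2 classes")
    if method not in ("spearman", "pearson"):
        raise ValueError("method must be 'spearman' or 'pearson'")
    values = expr.values if isinstance(expr, NormalizedMatrix) else expr
    shared = centroids.index.intersection(values.index)
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} genes shared with the centroids (need >= 3)")
    x = values.loc[shared].to_numpy(float)
    c = centroids.loc[shared].to_numpy(float)
    if method == "spearman":
        x = stats.rankdata(x, axis=0)
        c = stats.rankdata(c, axis=0)
    xz = (x - x.mean(axis=0)) / np.where(x.std(axis=0) > 0, x.std(axis=0), 1.0)
    cz = (c - c.mean(axis=0)) / np.where(c.std(axis=0) > 0, c.std(axis=0), 1.0)
    corr = xz.T @ cz / len(shared)           # samples x classes
    best = np.argmax(corr, axis=1)           # argmax takes the first on ties
    return pd.Series(centroids.columns[best], index=values.columns, name="class")


def foldchange_concordance(fc_a: pd.Series, fc_b: pd.Series) -> ConcordanceResult:
    """Pearson correlation of two per-gene log fold-change vectors over shared genes."""
    shared = fc_a.index.intersection(fc_b.index)
    if len(shared) < 3:
        raise ValueError("need >= 3 shared genes")
    a = fc_a.loc[shared].to_numpy(float)
    b = fc_b.loc[shared].to_numpy(float)
    if np.std(a) == 0 or np.std(b) == 0:
        warnings.warn("constant fold-change vector; concordance undefined")
        return ConcordanceResult(rho=np.nan, n_genes=len(shared))
    return ConcordanceResult(rho=float(np.corrcoef(a, b)[0, 1]), n_genes=len(shared))


def erg_ratio(coverage: pd.DataFrame, five_prime_ids: list[str], three_prime_id: str,
              tau: float = ERG_RATIO_THRESHOLD) -> ErgStatus:
    """5'-3' transcript ratio r = mean(5' exon depths) / 3' exon depth.

    Class is "high" iff r > tau (strict). Samples with zero 3' depth get a
    missing ratio with a warning. The ratio is invariant to scaling all of a
    sample's depths.
    """
    five = coverage[list(five_prime_ids)].mean(axis=1)
    three = coverage[three_prime_id].astype(float)
    zero = three == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} samples have zero 3' exon depth; ratio missing")
    ratio = five / three.where(~zero)
    cls = pd.Series(np.where(ratio > tau, "high", "low"), index=coverage.index)
    cls[ratio.isna()] = np.nan
    return ErgStatus(ratio=ratio, ratio_class=cls, threshold=tau)


def bimodal_split(values: pd.Series | np.ndarray, seed: int = 0,
                  n_restarts: int = 10) -> tuple[float | None, pd.Series]:
    """Split one gene's log2 expression by a two-component Gaussian mixture.

    Fits 1- and 2-component mixtures; the distribution is declared unimodal
    (threshold None, all samples "low", with a warning) when the 1-component
    fit has the better BIC or the two fitted means coincide within 1e-6.
    Otherwise the threshold is the point between the component means where
    the posteriors cross, and samples above it are "high".
    """
    s = pd.Series(values)
    if len(s) < 4:
        raise ValueError("need >= 4 samples")
    x = s.to_numpy(float).reshape(-1, 1)
    gm2 = GaussianMixture(n_components=2, n_init=n_restarts, random_state=seed).fit(x)
    gm1 = GaussianMixture(n_components=1, random_state=seed).fit(x)
    mu = gm2.means_.ravel()
    if gm1.bic(x) <= gm2.bic(x) or abs(mu[0] - mu[1]) < 1e-6:
        warnings.warn("expression looks unimodal; all samples classed 'low'")
        return None, pd.Series("low", index=s.index)
    lo_c, hi_c = (0, 1) if mu[0] < mu[1] else (1, 0)
    grid = np.linspace(mu.min(), mu.max(), 2001).reshape(-1, 1)
    post = gm2.predict_proba(grid)
    crossing = np.flatnonzero(np.diff(np.sign(post[:, hi_c] - post[:, lo_c])))
    if crossing.size:
        threshold = float((grid[crossing[0], 0] + grid[crossing[0] + 1, 0]) / 2.0)
    else:
        threshold = float(mu.mean())
    labels = pd.Series(np.where(s.to_numpy(float) > threshold, "high", "low"),
                       index=s.index)
    return threshold, labels
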