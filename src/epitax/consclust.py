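"""Per-view resampling consensus clustering (consensus-matrix method).

Each iteration subsamples the cohort without replacement, hierarchically
clusters the subsample (distance 1 - Pearson correlation between sample
profiles, average linkage) and cuts at k. The consensus matrix M records,
for every sample pair, the fraction of co-sampled iterations in which the
pair co-clustered. Final labels come from average-linkage clustering of
1 - M.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .matrixprep import NormalizedMatrix


@dataclass
class ConsensusMatrix:
    """Co-clustering frequency matrix with final labels and sampling counts."""

    sample_ids: pd.Index
    M: np.ndarray              # symmetric, in [0, 1]
    counts: np.ndarray         # times each pair was co-sampled
    k: int
    labels: np.ndarray         # 1..k per sample

    def __post_init__(self):
        if not np.allclose(self.M, self.M.T):
            raise ValueError("consensus matrix must be symmetric")
        if (self.M < -1e-12).any() or (self.M > 1 + 1e-12).any():
            raise ValueError("consensus frequencies must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.M, index=self.sample_ids, columns=self.sample_ids)


def _correlation_distance(x: np.ndarray) -> np.ndarray:
    """1 - Pearson correlation between columns; zero-variance columns get distance 1."""
    with np.errstate(invalid="ignore"):
        c = np.corrcoef(x, rowvar=False)
    c = np.nan_to_num(c, nan=0.0)
    np.fill_diagonal(c, 1.0)
    d = 1.0 - c
    np.fill_diagonal(d, 0.0)
    return np.clip(d, 0.0, None)


def _hclust_labels(dist: np.ndarray, k: int) -> np.ndarray:
    z = linkage(squareform(dist, checks=False), method="average")
    return fcluster(z, t=k, criterion="maxclust")


def consensus_cluster(matrix: NormalizedMatrix | pd.DataFrame, k: int,
                      n_iter: int = 100, subsample: float = 0.8,
                      seed: int | None = None) -> ConsensusMatrix:
    """Resampling consensus clustering of samples (columns).

    Parameters follow the clustering protocol: ``n_iter`` resampling
    iterations, each drawing ``ceil(subsample * n)`` samples without
    replacement. Pairs never co-sampled get consensus 0 with a warning.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if not (0 < subsample <= 1):
        raise ValueError("subsample must lie in (0, 1]")
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    values = matrix.values if isinstance(matrix, NormalizedMatrix) else matrix
    x = values.to_numpy(float)
    n = x.shape[1]
    m = int(np.ceil(subsample * n))
    rng = np.random.default_rng(seed)

    conn = np.zeros((n, n))
    cnt = np.zeros((n, n))
    for _ in range(n_iter):
        idx = np.sort(rng.choice(n, size=m, replace=False))
        sub = x[:, idx]
        labels = _hclust_labels(_correlation_distance(sub), k)
        same = labels[:, None] == labels[None, :]
        conn[np.ix_(idx, idx)] += same
        cnt[np.ix_(idx, idx)] += 1

    never = cnt == 0
    if never.any() and n_iter > 1:
        off_diag_never = never & ~np.eye(n, dtype=bool)
        if off_diag_never.any():
            warnings.warn(
                f"{int(off_diag_never.sum()) // 2} sample pairs were never co-sampled; "
                "their consensus is reported as 0"
            )
    with np.errstate(invalid="ignore"):
        M = np.where(never, 0.0, conn / np.where(never, 1, cnt))
    M = (M + M.T) / 2.0

    final = _hclust_labels(np.clip(1.0 - M, 0.0, None), k)
    return ConsensusMatrix(sample_ids=values.columns, M=M, counts=cnt, k=k, labels=final)


def cluster_stability_summary(consensus_by_k: dict[int, ConsensusMatrix]) -> pd.DataFrame:
    """Per-k stability report: mean within-cluster consensus, mean
    between-cluster consensus, consensus-CDF area and its change between
    successive k (the usual elbow diagnostic).
    """
    if not consensus_by_k:
        raise ValueError("need at least one consensus matrix")
    rows = []
    for k in sorted(consensus_by_k):
        cm = consensus_by_k[k]
        n = cm.M.shape[0]
        iu = np.triu_indices(n, 1)
        vals = cm.M[iu]
        same = (cm.labels[:, None] == cm.labels[None, :])[iu]
        within = float(vals[same].mean()) if same.any() else 1.0
        between = float(vals[~same].mean()) if (~same).any() else 0.0
        # area under the empirical CDF of consensus values
        xs = np.sort(vals)
        cdf = np.arange(1, xs.size + 1) / xs.size
        area = float(np.trapezoid(cdf, xs) + xs[0] * 0.0) if xs.size else 0.0
        rows.append({"k": k, "within_consensus": within, "between_consensus": between,
                     "stability": within - between, "cdf_area": area})
    df = pd.DataFrame(rows).set_index("k")
    prev = df["cdf_area"].shift(1)
    df["delta_area"] = (df["cdf_area"] - prev) / prev.replace(0, np.nan)
    df.loc[df.index.min(), "delta_area"] = df.loc[df.index.min(), "cdf_area"]
    return df
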