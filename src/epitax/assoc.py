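"""Cluster-covariate association tests and gene-set enrichment.

Categorical covariates: Pearson chi-square on the observed contingency table
(no continuity correction at any table size). Continuous covariates: one-way
linear-model F test (between/within mean squares). Differential ranking is
the signal-to-noise statistic s2n = (mu_in - mu_out) / (sd_in + sd_out) with
the usual sd floor. Gene-set enrichment follows the weighted
Kolmogorov-Smirnov running-sum scheme with phenotype-label permutation for
the null, sign-matched normalization for NES, and a permutation-based FDR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class ContingencyResult:
    """Pearson chi-square test of an r x c contingency table."""

    observed: pd.DataFrame
    chi2: float
    df: int
    p: float

    def __post_init__(self):
        if self.chi2 < 0 or not (0 <= self.p <= 1) or self.df < 1:
            raise ValueError("invalid chi-square result")


@dataclass
class AnovaResult:
    f: float
    df_between: int
    df_within: int
    p: float


@dataclass
class EnrichmentResult:
    """Per-set enrichment table plus the per-gene ranking metric that fed it."""

    table: pd.DataFrame      # index: set name; columns: ES, NES, p, q, size
    ranking: pd.Series       # s2n per gene, descending order of the ranked list


def contingency_chisq(table: np.ndarray | pd.DataFrame) -> ContingencyResult:
    """Pearson chi-square of a printed/observed contingency table.

    chi2 = sum (O - E)^2 / E with E from row/column margins; p is the upper
    tail of the chi-square distribution at (r-1)(c-1) df. Zero margins raise
    an error naming the offending level.
    """
    obs = pd.DataFrame(table)
    o = obs.to_numpy(float)
    if (o < 0).any():
        raise ValueError("contingency counts must be non-negative")
    row = o.sum(axis=1)
    col = o.sum(axis=0)
    for margin, labels, kind in ((row, obs.index, "row"), (col, obs.columns, "column")):
        if (margin == 0).any():
            bad = labels[np.flatnonzero(margin == 0)[0]]
            raise ValueError(f"{kind} level {bad!r} has a zero margin")
    e = np.outer(row, col) / o.sum()
    chi2 = float(np.sum((o - e) ** 2 / e))
    df = (o.shape[0] - 1) * (o.shape[1] - 1)
    p = float(stats.chi2.sf(chi2, df))
    return ContingencyResult(observed=obs, chi2=chi2, df=df, p=p)


def chisq_association(labels, covariate, drop_levels=None) -> ContingencyResult:
    """Cross-tabulate cluster labels against a categorical covariate and run
    the Pearson chi-square test. ``drop_levels`` (e.g. NA markers) are removed
    from the covariate before tabulation; missing values are always dropped.
    """
    s_lab = pd.Series(labels).reset_index(drop=True)
    s_cov = pd.Series(covariate).reset_index(drop=True)
    keep = s_lab.notna() & s_cov.notna()
    if drop_levels:
        keep &= ~s_cov.isin(list(drop_levels))
    tab = pd.crosstab(s_cov[keep], s_lab[keep])
    if tab.shape[0] < 2 or tab.shape[1] < 2:
        raise ValueError("need >= 2 levels of both variables after dropping")
    return contingency_chisq(tab)


def anova_association(labels, covariate) -> AnovaResult:
    """One-way linear-model F test of a continuous covariate across clusters."""
    s_lab = pd.Series(labels).reset_index(drop=True)
    s_cov = pd.to_numeric(pd.Series(covariate).reset_index(drop=True))
    keep = s_lab.notna() & s_cov.notna()
    s_lab, s_cov = s_lab[keep], s_cov[keep]
    groups = [g.to_numpy(float) for _, g in s_cov.groupby(s_lab) if len(g) > 0]
    if len(groups) < 2:
        raise ValueError("need >= 2 non-empty groups")
    n = sum(len(g) for g in groups)
    k = len(groups)
    if n - k < 1:
        raise ValueError("no residual degrees of freedom")
    grand = s_cov.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_b, df_w = k - 1, n - k
    ms_b = ss_between / df_b
    ms_w = ss_within / df_w
    if ms_w == 0:
        f = np.inf if ms_b > 0 else 0.0
    else:
        f = float(ms_b / ms_w)
    p = float(stats.f.sf(f, df_b, df_w)) if np.isfinite(f) else 0.0
    return AnovaResult(f=f, df_between=df_b, df_within=df_w, p=p)


def _s2n(x: np.ndarray, in_group: np.ndarray) -> np.ndarray:
    """Signal-to-noise per gene (rows of x), one group vs the rest.

    Each group's sd is floored at max(0.2 * |group mean|, 0.2).
    """
    a, b = x[:, in_group], x[:, ~in_group]
    mu_a, mu_b = a.mean(axis=1), b.mean(axis=1)
    sd_a = np.maximum(a.std(axis=1, ddof=1), np.maximum(0.2 * np.abs(mu_a), 0.2))
    sd_b = np.maximum(b.std(axis=1, ddof=1), np.maximum(0.2 * np.abs(mu_b), 0.2))
    return (mu_a - mu_b) / (sd_a + sd_b)


def de_rank(expr: pd.DataFrame, labels, target_cluster) -> pd.Series:
    """Per-gene signal-to-noise score of one cluster versus all others."""
    labels = np.asarray(pd.Series(labels))
    in_group = labels == target_cluster
    if in_group.sum() < 2 or (~in_group).sum() < 2:
        raise ValueError("both groups need >= 2 samples")
    s2n = _s2n(expr.to_numpy(float), in_group)
    return pd.Series(s2n, index=expr.index, name="s2n").sort_values(ascending=False)


def _es_from_positions(pos: np.ndarray, w: np.ndarray, n_genes: int) -> float:
    """Weighted-KS enrichment score from sorted 0-based hit positions.

    Hits add w_i / sum(w); misses subtract 1 / (N - m). The ES is the signed
    extremum of the running sum, evaluated at hit points (candidates for the
    maximum) and just before them (candidates for the minimum).
    """
    m = pos.size
    nr = w.sum()
    if nr <= 0:
        w = np.ones(m)
        nr = float(m)
    cw = np.cumsum(w) / nr
    miss = (pos - np.arange(m)) / (n_genes - m)
    up = cw - miss                      # running sum right after each hit
    down = np.concatenate([[0.0], cw[:-1]]) - miss  # just before each hit
    hi, lo = up.max(), down.min()
    return float(hi if hi >= -lo else lo)


def _es_all_sets(order: np.ndarray, scores: np.ndarray,
                 set_masks: np.ndarray, weight: float) -> np.ndarray:
    """ES of every gene set for one ranking (``order`` sorts scores descending)."""
    n = order.size
    ranked_sets = set_masks[:, order]
    absw = np.abs(scores[order]) ** weight
    out = np.empty(set_masks.shape[0])
    for s in range(set_masks.shape[0]):
        pos = np.flatnonzero(ranked_sets[s])
        out[s] = _es_from_positions(pos, absw[pos], n)
    return out


def gsea(expr: pd.DataFrame, labels, target_cluster,
         gene_sets: dict[str, list[str]], n_perm: int = 1000,
         weight: float = 1.0, seed: int | None = None) -> EnrichmentResult:
    """Weighted-KS gene-set enrichment of one cluster versus the rest.

    Genes are ranked by signal-to-noise; the null is phenotype-label
    permutation (the s2n ranking is recomputed per permutation). NES divides
    ES by the mean |permutation ES| of matching sign; nominal p and FDR q are
    the standard sign-matched permutation estimates. Sets smaller than 5 or
    larger than n_genes - 5 after intersecting with the expression index are
    skipped with a warning.
    """
    labels = np.asarray(pd.Series(labels))
    in_group = labels == target_cluster
    if in_group.sum() < 2 or (~in_group).sum() < 2:
        raise ValueError("both groups need >= 2 samples")
    genes = expr.index
    n_genes = len(genes)
    gene_pos = {g: i for i, g in enumerate(genes)}

    names, masks = [], []
    for name, members in gene_sets.items():
        idx = [gene_pos[g] for g in dict.fromkeys(members) if g in gene_pos]
        if len(idx) < 5 or len(idx) > n_genes - 5:
            warnings.warn(f"gene set {name!r} has {len(idx)} usable members; skipped")
            continue
        row = np.zeros(n_genes, dtype=bool)
        row[idx] = True
        names.append(name)
        masks.append(row)
    if not names:
        raise ValueError("no usable gene sets after intersection")
    set_masks = np.asarray(masks)

    x = expr.to_numpy(float)
    scores = _s2n(x, in_group)
    order = np.argsort(-scores, kind="stable")
    es_obs = _es_all_sets(order, scores, set_masks, weight)

    rng = np.random.default_rng(seed)
    es_null = np.empty((n_perm, len(names)))
    for r in range(n_perm):
        perm = rng.permutation(in_group)
        s = _s2n(x, perm)
        es_null[r] = _es_all_sets(np.argsort(-s, kind="stable"), s, set_masks, weight)

    pos_mean = np.where(es_null > 0, es_null, np.nan)
    neg_mean = np.where(es_null < 0, -es_null, np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_pos = np.nanmean(pos_mean, axis=0)
        mean_neg = np.nanmean(neg_mean, axis=0)
    mean_pos = np.where(np.isnan(mean_pos) | (mean_pos == 0), 1.0, mean_pos)
    mean_neg = np.where(np.isnan(mean_neg) | (mean_neg == 0), 1.0, mean_neg)
    nes_obs = np.where(es_obs >= 0, es_obs / mean_pos, es_obs / mean_neg)
    nes_null = np.where(es_null >= 0, es_null / mean_pos[None, :],
                        es_null / mean_neg[None, :])

    # nominal p: sign-matched permutation tail
    p_nom = np.empty(len(names))
    for s in range(len(names)):
        null = es_null[:, s]
        if es_obs[s] >= 0:
            same = null[null >= 0]
            p_nom[s] = (1.0 + np.sum(same >= es_obs[s])) / (1.0 + same.size)
        else:
            same = null[null < 0]
            p_nom[s] = (1.0 + np.sum(same <= es_obs[s])) / (1.0 + same.size)

    # FDR q: pooled sign-matched NES comparison (observed vs permutation pools)
    q = np.empty(len(names))
    pool = nes_null.ravel()
    pool_pos = pool[pool >= 0]
    pool_neg = pool[pool < 0]
    obs_pos = nes_obs[nes_obs >= 0]
    obs_neg = nes_obs[nes_obs < 0]
    for s in range(len(names)):
        v = nes_obs[s]
        if v >= 0:
            num = np.mean(pool_pos >= v) if pool_pos.size else 0.0
            den = np.mean(obs_pos >= v) if obs_pos.size else 1.0
        else:
            num = np.mean(pool_neg <= v) if pool_neg.size else 0.0
            den = np.mean(obs_neg <= v) if obs_neg.size else 1.0
        q[s] = min(1.0, num / max(den, 1e-12))

    table = pd.DataFrame({
        "ES": es_obs, "NES": nes_obs, "p": p_nom, "q": q,
        "size": set_masks.sum(axis=1),
    }, index=pd.Index(names, name="gene_set"))
    ranking = pd.Series(scores[order], index=genes[order], name="s2n")
    return EnrichmentResult(table=table, ranking=ranking)


def fdr_flag(result: EnrichmentResult | pd.DataFrame, threshold: float = 0.2) -> pd.DataFrame:
    """Gene sets with FDR q below ``threshold``, sorted by |NES| descending."""
    table = result.table if isinstance(result, EnrichmentResult) else result
    hit = table[table["q"] < threshold].copy()
    return hit.reindex(hit["NES"].abs().sort_values(ascending=False).index)
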