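"""Multi-view non-negative matrix factorization with incomplete views (MIV-NMF).

Given V non-negative feature-by-sample matrices X_v over a shared sample
roster, with per-view observation indicators D_v (samples can be missing
from some views), the model factorizes each view as X_v ~ W_v H_v and couples
the per-view sample-factor matrices H_v to a consensus factor matrix H*
through the objective

    J = sum_v ||(X_v - W_v H_v) D_v||_F^2
      + alpha * sum_v ||(H_v - H*) D_v||_F^2
      + beta  * sum_v ||H_v||_1

minimized by alternating multiplicative updates of W_v and H_v and a
closed-form update of H* (the observation-weighted mean of the H_v columns).
W_v columns carry unit L2 norm at every measurement point, with the scale
absorbed into H_v, so the H_v are on a common scale before coupling; the
coupling term is evaluated in that normalized parametrization, which makes
the rescaling step objective-invariant and keeps the trace non-increasing.

Cluster labels are the argmax factor of each H* column. Restart and
subsampling consensus matrices quantify stability; per-view contribution is
the Pearson correlation between H_v and H* over observed samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

_EPS = 1e-12


@dataclass
class FactorizationProblem:
    """Inputs of one MIV-NMF fit.

    ``views`` maps view name -> non-negative feature x sample array (shared
    sample order; missing samples' columns are ignored — conventionally
    zero-filled). ``masks`` maps view name -> boolean observation vector per
    sample (True = observed).
    """

    views: dict[str, np.ndarray]
    masks: dict[str, np.ndarray]
    k: int
    alpha: float = 0.001
    beta: float = 0.0
    max_iter: int = 500
    tol: float = 1e-6
    seed: int | None = None

    def __post_init__(self):
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be non-negative")
        if set(self.views) != set(self.masks):
            raise ValueError("views and masks must cover the same view names")
        n = None
        for name, x in self.views.items():
            x = np.asarray(x, float)
            if np.isnan(x).any():
                raise ValueError(f"view {name!r} contains NaN")
            mask = np.asarray(self.masks[name], bool)
            if n is None:
                n = x.shape[1]
            if x.shape[1] != n or mask.shape != (n,):
                raise ValueError("all views must share the sample axis")
            if (x[:, mask] < 0).any():
                raise ValueError(f"view {name!r} has negative observed entries")
            self.views[name] = x
            self.masks[name] = mask
        observed_any = np.zeros(n, dtype=bool)
        for mask in self.masks.values():
            observed_any |= mask
        if not observed_any.all():
            missing = np.flatnonzero(~observed_any)
            raise ValueError(f"samples observed in no view: {missing.tolist()}")

    @property
    def n_samples(self) -> int:
        return next(iter(self.views.values())).shape[1]


@dataclass
class FactorizationResult:
    """Factors of one fit: per-view basis W_v, per-view H_v, consensus H*."""

    W: dict[str, np.ndarray]
    H: dict[str, np.ndarray]
    Hstar: np.ndarray
    objective: np.ndarray
    converged: bool
    labels: np.ndarray          # 1..k per sample; -1 where H* column is all zero


@dataclass
class IntegrationReport:
    """Restart consensus, final labels and per-view contribution diagnostics."""

    consensus: np.ndarray
    labels: np.ndarray
    contribution: pd.DataFrame          # per view: mean, sd of Pearson r(H_v, H*)
    restart_labels: np.ndarray = field(repr=False, default=None)


def _init_factors(problem: FactorizationProblem, rng: np.random.Generator):
    """Random init, scaled to data magnitude. One H draw is shared by all
    views (per view, rescaled to its magnitude) so the factor order is seeded
    consistently across views; the consensus coupling is far too weak to
    repair an arbitrary per-view factor permutation after the fact."""
    k = problem.k
    n = problem.n_samples
    h_shared = rng.uniform(0.0, 1.0, size=(k, n))
    W, H = {}, {}
    for name, x in problem.views.items():
        f, _ = x.shape
        mask = problem.masks[name]
        scale = np.sqrt(max(x[:, mask].mean(), _EPS) / k)
        W[name] = rng.uniform(0.0, 1.0, size=(f, k)) * scale + _EPS
        H[name] = h_shared * scale + _EPS
        H[name][:, ~mask] = 0.0
    return W, H


def _normalize(W: np.ndarray, H: np.ndarray):
    """Scale W columns to unit L2, absorbing the scale into H rows."""
    q = np.linalg.norm(W, axis=0)
    q = np.maximum(q, _EPS)
    return W / q, H * q[:, None]


def _hstar_update(H: dict[str, np.ndarray], masks: dict[str, np.ndarray]) -> np.ndarray:
    """Observation-weighted mean of the per-view factor columns."""
    k, n = next(iter(H.values())).shape
    num = np.zeros((k, n))
    den = np.zeros(n)
    for name, h in H.items():
        m = masks[name]
        num[:, m] += h[:, m]
        den[m] += 1.0
    return num / np.maximum(den, 1.0)


def _objective(problem: FactorizationProblem, W, H, Hstar) -> float:
    j = 0.0
    for name, x in problem.views.items():
        m = problem.masks[name]
        r = x[:, m] - W[name] @ H[name][:, m]
        j += float(np.sum(r * r))
        d = H[name][:, m] - Hstar[:, m]
        j += problem.alpha * float(np.sum(d * d))
        j += problem.beta * float(np.sum(H[name]))
    return j


def mivnmf_fit(problem: FactorizationProblem,
               init: tuple[dict, dict] | None = None) -> FactorizationResult:
    """Fit MIV-NMF by alternating multiplicative updates.

    Per sweep and view: multiplicative W update (including the coupling term,
    which touches W through the column norms), exact renormalization of W
    columns into H, multiplicative H update on observed columns, then the
    closed-form H* update. The recorded objective is non-increasing per sweep
    up to floating-point round-off.
    """
    rng = np.random.default_rng(problem.seed)
    if init is None:
        W, H = _init_factors(problem, rng)
    else:
        W = {k_: v.copy() for k_, v in init[0].items()}
        H = {k_: v.copy() for k_, v in init[1].items()}
    for name in problem.views:
        W[name], H[name] = _normalize(W[name], H[name])
        H[name][:, ~problem.masks[name]] = 0.0
    Hstar = _hstar_update(H, problem.masks)

    alpha, beta = problem.alpha, problem.beta
    trace = [_objective(problem, W, H, Hstar)]
    converged = False
    for _ in range(problem.max_iter):
        for name, x in problem.views.items():
            m = problem.masks[name]
            xo = x[:, m]
            ho = H[name][:, m]
            hso = Hstar[:, m]
            w = W[name]
            # W update; the coupling enters via q_k = ||w_k||_2 (unit at entry)
            if alpha > 0:
                a = np.sum(ho * ho, axis=1)          # per factor
                b = np.sum(ho * hso, axis=1)
                q = np.maximum(np.linalg.norm(w, axis=0), _EPS)
                num = xo @ ho.T + alpha * w * (b / q)[None, :]
                den = w @ (ho @ ho.T) + alpha * w * a[None, :] + _EPS
            else:
                num = xo @ ho.T
                den = w @ (ho @ ho.T) + _EPS
            w = w * (num / den)
            w, h = _normalize(w, H[name])
            ho = h[:, m]
            # H update on observed columns (W has unit columns here)
            num = w.T @ xo + alpha * hso
            den = (w.T @ w) @ ho + alpha * ho + beta / 2.0 + _EPS
            ho = ho * (num / den)
            h[:, m] = ho
            h[:, ~m] = 0.0
            W[name], H[name] = w, h
        Hstar = _hstar_update(H, problem.masks)
        j = _objective(problem, W, H, Hstar)
        trace.append(j)
        if trace[-2] - j <= problem.tol * max(abs(trace[-2]), _EPS):
            converged = True
            break

    labels = assign_clusters(Hstar)
    return FactorizationResult(W=W, H=H, Hstar=Hstar,
                               objective=np.asarray(trace), converged=converged,
                               labels=labels)


def assign_clusters(Hstar: np.ndarray) -> np.ndarray:
    """Label each sample by its largest consensus factor (1-based).

    Ties go to the lowest factor index; all-zero columns get label -1
    (missing) with a warning.
    """
    Hstar = np.asarray(Hstar, float)
    if (Hstar < 0).any():
        raise ValueError("consensus factor matrix must be non-negative")
    labels = np.argmax(Hstar, axis=0) + 1
    dead = ~(Hstar > 0).any(axis=0)
    if dead.any():
        warnings.warn(f"{int(dead.sum())} samples have an all-zero factor column; "
                      "their label is undefined (-1)")
        labels = labels.copy()
        labels[dead] = -1
    return labels


def _restart_seeds(seed: int | None, n: int) -> list[np.random.SeedSequence]:
    return np.random.SeedSequence(seed).spawn(n)


def _consensus_from_labels(label_runs: np.ndarray) -> np.ndarray:
    """C[i,j] = fraction of runs assigning i and j the same label."""
    r, n = label_runs.shape
    c = np.zeros((n, n))
    for labels in label_runs:
        c += labels[:, None] == labels[None, :]
    return c / r


def _labels_from_consensus(c: np.ndarray, k: int) -> np.ndarray:
    d = np.clip(1.0 - c, 0.0, None)
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    z = linkage(squareform(d, checks=False), method="average")
    return fcluster(z, t=k, criterion="maxclust")


def view_contribution(results: list[FactorizationResult],
                      masks: dict[str, np.ndarray]) -> pd.DataFrame:
    """Per-view mean +/- sd (over restarts) of the Pearson correlation between
    the view's factor matrix and the consensus factor matrix, computed over
    observed-sample entries only. Constant matrices give NaN with a warning.
    """
    if not results:
        raise ValueError("need at least one restart result")
    rows = {}
    for name in results[0].H:
        rs = []
        m = masks[name]
        for res in results:
            a = res.H[name][:, m].ravel()
            b = res.Hstar[:, m].ravel()
            if np.std(a) == 0 or np.std(b) == 0:
                warnings.warn(f"view {name!r}: constant factor matrix; r undefined")
                rs.append(np.nan)
            else:
                rs.append(float(np.corrcoef(a, b)[0, 1]))
        rs = np.asarray(rs)
        rows[name] = {"mean_r": float(np.nanmean(rs)),
                      "sd_r": float(np.nanstd(rs)) if len(rs) > 1 else 0.0,
                      "n_restarts": len(rs)}
    return pd.DataFrame(rows).T


def integrate_with_restarts(problem: FactorizationProblem,
                            n_restarts: int = 20) -> IntegrationReport:
    """Run MIV-NMF ``n_restarts`` times from random initializations; build the
    co-assignment consensus matrix over restarts and derive final labels by
    average-linkage clustering of 1 - C cut at k.
    """
    if n_restarts < 2:
        raise ValueError("n_restarts must be >= 2")
    seeds = _restart_seeds(problem.seed, n_restarts)
    results = []
    label_runs = []
    for ss in seeds:
        sub = FactorizationProblem(
            views=problem.views, masks=problem.masks, k=problem.k,
            alpha=problem.alpha, beta=problem.beta,
            max_iter=problem.max_iter, tol=problem.tol,
            seed=int(ss.generate_state(1)[0] % (2**31)),
        )
        res = mivnmf_fit(sub)
        results.append(res)
        label_runs.append(res.labels)
    label_runs = np.asarray(label_runs)
    c = _consensus_from_labels(label_runs)
    final = _labels_from_consensus(c, problem.k)
    contrib = view_contribution(results, problem.masks)
    return IntegrationReport(consensus=c, labels=final, contribution=contrib,
                             restart_labels=label_runs)


def stability_subsample(problem: FactorizationProblem, n_repeats: int = 100,
                        frac: float = 0.8) -> np.ndarray:
    """Consensus matrix over subsampled cohorts: each repeat fits MIV-NMF on a
    ``frac`` subsample and records co-clustering; entries are normalized by
    co-sampling counts. Pairs never co-sampled are NaN.
    """
    if not (0 < frac < 1):
        raise ValueError("frac must lie strictly inside (0, 1)")
    n = problem.n_samples
    m = int(np.ceil(frac * n))
    rng = np.random.default_rng(problem.seed)
    seeds = _restart_seeds(problem.seed, n_repeats)
    conn = np.zeros((n, n))
    cnt = np.zeros((n, n))
    for ss in seeds:
        idx = np.sort(rng.choice(n, size=m, replace=False))
        views = {name: x[:, idx] for name, x in problem.views.items()}
        masks = {name: mk[idx] for name, mk in problem.masks.items()}
        if not np.logical_or.reduce([mk for mk in masks.values()]).all():
            continue  # a drawn sample lost all views; skip this repeat
        sub = FactorizationProblem(
            views=views, masks=masks, k=problem.k, alpha=problem.alpha,
            beta=problem.beta, max_iter=problem.max_iter, tol=problem.tol,
            seed=int(ss.generate_state(1)[0] % (2**31)),
        )
        labels = mivnmf_fit(sub).labels
        same = labels[:, None] == labels[None, :]
        conn[np.ix_(idx, idx)] += same
        cnt[np.ix_(idx, idx)] += 1
    with np.errstate(invalid="ignore"):
        return np.where(cnt > 0, conn / np.where(cnt > 0, cnt, 1), np.nan)
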