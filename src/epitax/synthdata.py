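"""Synthetic multi-view cohort generator.

Emulates the structure of a multi-omics tumor cohort: k latent subtypes, five
data views (one expression-like, four chromatin-like) over a shared sample
roster with per-view missingness, negative-binomial count noise with
log2-scale subtype effects on cluster-informative features, one bimodal
"ERG-like" gene (two-component mixture on the log scale), exon-level coverage
for 5'-3' transcript-ratio testing, and clustered copy-number segment
profiles that drive off-target read densities.

Counts are negative binomial with variance mu + phi * mu^2 (phi = dispersion).
A single master seed drives independent substreams per view and stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class ViewSpec:
    """One data view: feature count, share of cluster-informative features,
    subtype effect size (log2 units) and NB dispersion."""

    name: str
    n_features: int = 400
    informative_frac: float = 0.3
    effect_size: float = 1.5
    dispersion: float = 0.3
    missing_fraction: float = 0.2

    def __post_init__(self):
        if self.n_features < 1:
            raise ValueError("n_features must be >= 1")
        if not (0 <= self.informative_frac <= 1):
            raise ValueError("informative_frac must lie in [0, 1]")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if not (0 <= self.missing_fraction < 1):
            raise ValueError("missing_fraction must lie in [0, 1)")


@dataclass(frozen=True)
class ErgSpec:
    """Bimodal ERG-like gene: log2 shift of the high mode and its mixing proportion."""

    high_shift: float = 3.0
    mixing: float = 0.5


@dataclass(frozen=True)
class CnaSpec:
    """Copy-number truth: segments per subtype, gain/loss magnitudes (log2), bin noise."""

    segments_per_subtype: tuple[int, ...] = (4, 8, 0)
    gain_log2: float = 0.58
    loss_log2: float = -1.0
    noise_sd: float = 0.2


DEFAULT_VIEWS = (
    ViewSpec("rna"),
    ViewSpec("ar"),
    ViewSpec("h3k27ac"),
    ViewSpec("h3k4me3"),
    ViewSpec("h3k27me3"),
)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of the synthetic cohort."""

    n_samples: int = 90
    k_true: int = 3
    views: tuple[ViewSpec, ...] = DEFAULT_VIEWS
    erg_spec: ErgSpec = ErgSpec()
    cna_spec: CnaSpec = CnaSpec()
    base_mean_range: tuple[float, float] = (20.0, 500.0)
    seed: int = 0

    def __post_init__(self):
        if self.k_true < 1:
            raise ValueError("k_true must be >= 1")
        if self.n_samples < 2 * self.k_true:
            raise ValueError("n_samples must be >= 2 * k_true")
        if len(self.cna_spec.segments_per_subtype) < self.k_true:
            object.__setattr__(
                self, "cna_spec",
                CnaSpec(segments_per_subtype=tuple(
                    self.cna_spec.segments_per_subtype[i % len(self.cna_spec.segments_per_subtype)]
                    for i in range(self.k_true)),
                    gain_log2=self.cna_spec.gain_log2,
                    loss_log2=self.cna_spec.loss_log2,
                    noise_sd=self.cna_spec.noise_sd),
            )


@dataclass
class Truth:
    """Ground truth of a simulated cohort."""

    labels: np.ndarray                         # subtype per sample, 0..k-1
    observed: pd.DataFrame                     # views x samples boolean
    informative: dict[str, dict[int, np.ndarray]]  # view -> subtype -> feature idx
    erg_class: np.ndarray                      # True = ERG-high / fusion-like
    cna_segments: pd.DataFrame                 # subtype, chrom, start, end, log2
    sample_ids: list[str] = field(default_factory=list)


@dataclass
class MultiViewDataset:
    """Shared sample roster with per-view count matrices and observation mask."""

    sample_ids: list[str]
    views: dict[str, pd.DataFrame]             # features x samples counts
    mask: pd.DataFrame                         # views x samples boolean

    def write(self, outdir) -> None:
        from pathlib import Path
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, df in self.views.items():
            df.to_csv(outdir / f"counts_{name}.tsv", sep="\t")
        self.mask.astype(int).to_csv(outdir / "mask.tsv", sep="\t")


# default synthetic genome for copy-number work: two autosomes + one sex chrom
DEFAULT_GENOME = pd.Series({"chr1": 40_000_000, "chr2": 32_000_000, "chrX": 12_000_000})

ERG_GENE = "ERG_like"


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial draw with var = mu + dispersion * mu^2."""
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def _substream(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=tuple(key)))


def simulate_cohort(config: SimConfig) -> tuple[MultiViewDataset, Truth]:
    """Simulate per-view NB count matrices with known subtype structure.

    Cluster-informative features are shifted by the view's effect size
    (log2 units) in exactly one subtype. Missingness is MCAR per (sample,
    view), with a guard that every sample keeps at least one observed view.
    Deterministic given the config seed.
    """
    k = config.k_true
    n = config.n_samples
    rng_labels = _substream(config.seed, 0)
    labels = np.repeat(np.arange(k), np.diff(np.linspace(0, n, k + 1).astype(int)))
    rng_labels.shuffle(labels)
    sample_ids = [f"S{i:03d}" for i in range(n)]

    views: dict[str, pd.DataFrame] = {}
    informative: dict[str, dict[int, np.ndarray]] = {}
    observed = {}
    erg_rng = _substream(config.seed, 1)
    erg_class = erg_rng.random(n) < config.erg_spec.mixing

    for vi, spec in enumerate(config.views):
        rng = _substream(config.seed, 10 + vi)
        f = spec.n_features
        lo, hi = config.base_mean_range
        base = np.exp(rng.uniform(np.log(lo), np.log(hi), size=f))
        n_info = int(round(spec.informative_frac * f))
        info_idx = rng.choice(f, size=n_info, replace=False)
        per_subtype = {c: info_idx[np.arange(n_info) % k == c] for c in range(k)}
        informative[spec.name] = per_subtype

        log2fc = np.zeros((f, n))
        for c in range(k):
            cols = labels == c
            log2fc[np.ix_(per_subtype[c], cols)] = spec.effect_size
        mean = base[:, None] * (2.0 ** log2fc)

        counts = _nb_counts(rng, mean, spec.dispersion)
        df = pd.DataFrame(counts, columns=sample_ids,
                          index=[f"{spec.name}_f{i}" for i in range(f)])
        if vi == 0:
            # bimodal ERG-like gene appended to the expression-like view
            erg_mean = np.where(erg_class, 50.0 * 2.0 ** config.erg_spec.high_shift, 50.0)
            erg_counts = _nb_counts(rng, erg_mean[None, :], spec.dispersion)
            df.loc[ERG_GENE] = erg_counts.ravel()
        views[spec.name] = df
        observed[spec.name] = _substream(config.seed, 100 + vi).random(n) >= spec.missing_fraction

    mask = pd.DataFrame(observed, index=sample_ids).T
    # guard: no sample may lose every view
    lost = ~mask.to_numpy().any(axis=0)
    if lost.any():
        guard_rng = _substream(config.seed, 2)
        view_names = list(mask.index)
        for j in np.flatnonzero(lost):
            mask.iloc[guard_rng.integers(len(view_names)), j] = True

    cna_segments = _simulate_cna_truth(config)
    truth = Truth(labels=labels, observed=mask, informative=informative,
                  erg_class=erg_class, cna_segments=cna_segments,
                  sample_ids=sample_ids)
    return MultiViewDataset(sample_ids=sample_ids, views=views, mask=mask), truth


def _simulate_cna_truth(config: SimConfig, genome: pd.Series = DEFAULT_GENOME,
                        bin_size: int = 400_000) -> pd.DataFrame:
    """Per-subtype segment tables on the default genome (autosomes only)."""
    rng = _substream(config.seed, 3)
    rows = []
    autosomes = [c for c in genome.index if c.lower() not in ("chrx", "chry", "x", "y")]
    for c, n_seg in enumerate(config.cna_spec.segments_per_subtype[: config.k_true]):
        for _ in range(n_seg):
            chrom = autosomes[rng.integers(len(autosomes))]
            n_bins = int(genome[chrom] // bin_size)
            width = int(rng.integers(5, max(6, n_bins // 3)))
            start_bin = int(rng.integers(0, max(1, n_bins - width)))
            log2 = config.cna_spec.gain_log2 if rng.random() < 0.5 else config.cna_spec.loss_log2
            rows.append({"subtype": c, "chrom": chrom,
                         "start": start_bin * bin_size,
                         "end": (start_bin + width) * bin_size,
                         "log2": log2})
    return pd.DataFrame(rows, columns=["subtype", "chrom", "start", "end", "log2"])


def simulate_exon_coverage(truth: Truth, exon_intervals: list,
                           depth: float = 100.0,
                           pos_five_prime_factor: float = 1.0,
                           neg_five_prime_factor: float = 0.1,
                           seed: int | None = None) -> pd.DataFrame:
    """Mean read depth per (sample, exon) for 5'-3' transcript-ratio testing.

    The last interval is the 3' exon; the preceding intervals are the 5'
    group. Fusion-like (ERG-high) samples have 5' depth equal to
    ``pos_five_prime_factor`` x the 3' depth; others
    ``neg_five_prime_factor`` x. Depths carry Poisson sampling noise scaled
    by exon length (mean depth = Poisson(depth * length) / length).
    """
    if len(exon_intervals) < 2:
        raise ValueError("need >= 2 exon intervals (5' group + one 3' exon)")
    rng = np.random.default_rng(seed)
    n = len(truth.labels)
    lengths = np.array([iv.length for iv in exon_intervals], dtype=float)
    names = [f"{iv.chrom}:{iv.start}-{iv.end}" for iv in exon_intervals]
    factor = np.where(truth.erg_class, pos_five_prime_factor, neg_five_prime_factor)
    exp_depth = np.tile(depth * factor[:, None], (1, len(exon_intervals)))
    exp_depth[:, -1] = depth  # 3' exon at baseline for every sample
    lam = exp_depth * lengths[None, :]
    cov = rng.poisson(lam) / lengths[None, :]
    return pd.DataFrame(cov, index=truth.sample_ids or range(n), columns=names)


def simulate_offtarget_reads(truth: Truth, genome: pd.Series = DEFAULT_GENOME,
                             n_reads: int = 100_000, on_target_frac: float = 0.3,
                             n_peaks: int = 50, read_length: int = 65,
                             bin_size: int = 400_000,
                             seed: int | None = None):
    """Per-sample read intervals whose off-target density follows the true
    copy-number profile, plus the shared true peak set.

    ``on_target_frac`` of each sample's reads land uniformly inside peaks;
    the rest are multinomial over ``bin_size`` bins with weight
    2^(segment log2 ratio) per bin. Returns (reads dict, peaks DataFrame).
    """
    if len(genome) == 0:
        raise ValueError("genome must contain at least one chromosome")
    if n_reads < 0:
        raise ValueError("n_reads must be >= 0")
    rng = np.random.default_rng(seed)

    # shared peak set
    peak_rows = []
    chroms = list(genome.index)
    probs = genome.to_numpy(float) / genome.sum()
    for _ in range(n_peaks):
        chrom = chroms[rng.choice(len(chroms), p=probs)]
        width = int(rng.integers(200, 2000))
        start = int(rng.integers(0, genome[chrom] - width))
        peak_rows.append((chrom, start, start + width))
    peaks = pd.DataFrame(peak_rows, columns=["chrom", "start", "end"]).sort_values(
        ["chrom", "start"]).reset_index(drop=True)

    # genome-wide bin grid
    bins = []
    for chrom in chroms:
        size = int(genome[chrom])
        edges = list(range(0, size, bin_size)) + [size]
        for s, e in zip(edges[:-1], edges[1:]):
            bins.append((chrom, s, e))
    bin_df = pd.DataFrame(bins, columns=["chrom", "start", "end"])

    reads: dict[str, pd.DataFrame] = {}
    for i, sample in enumerate(truth.sample_ids or range(len(truth.labels))):
        weights = np.ones(len(bin_df))
        segs = truth.cna_segments[truth.cna_segments["subtype"] == truth.labels[i]]
        for _, seg in segs.iterrows():
            inside = ((bin_df["chrom"] == seg["chrom"])
                      & (bin_df["start"] >= seg["start"])
                      & (bin_df["end"] <= seg["end"])).to_numpy()
            weights[inside] *= 2.0 ** seg["log2"]
        weights *= (bin_df["end"] - bin_df["start"]).to_numpy(float) / bin_size
        if n_reads == 0:
            reads[str(sample)] = pd.DataFrame(columns=["chrom", "start", "end"])
            continue
        n_on = rng.binomial(n_reads, on_target_frac)
        n_off = n_reads - n_on
        per_bin = rng.multinomial(n_off, weights / weights.sum())
        chrom_list, start_list = [], []
        for b, cnt in enumerate(per_bin):
            if cnt == 0:
                continue
            lo, hi = bin_df.at[b, "start"], bin_df.at[b, "end"]
            starts = rng.integers(lo, max(lo + 1, hi - read_length), size=cnt)
            chrom_list.append(np.full(cnt, bin_df.at[b, "chrom"], dtype=object))
            start_list.append(starts)
        if n_on > 0 and len(peaks):
            pk = peaks.iloc[rng.integers(0, len(peaks), size=n_on)]
            starts = (pk["start"].to_numpy()
                      + (rng.random(n_on) * (pk["end"] - pk["start"]).to_numpy()).astype(int))
            chrom_list.append(pk["chrom"].to_numpy(object))
            start_list.append(starts)
        chrom_arr = np.concatenate(chrom_list) if chrom_list else np.array([], dtype=object)
        start_arr = np.concatenate(start_list) if start_list else np.array([], dtype=int)
        reads[str(sample)] = pd.DataFrame({
            "chrom": chrom_arr,
            "start": start_arr.astype(int),
            "end": start_arr.astype(int) + read_length,
        })
    return reads, peaks
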