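"""End-to-end pipeline: simulate -> prep -> cluster-view -> integrate ->
characterize -> cna -> assoc, with a reproducibility manifest.

The pipeline is deterministic given its config: every stochastic stage draws
its seed from the config's seed registry, and the manifest records config
hash, per-stage output checksums and wall times.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import assoc, cna, consclust, io, matrixprep, mivnmf, signatures, synthdata

logger = logging.getLogger("epitax")


@dataclass
class PipelineConfig:
    """Validated parameters of a full run."""

    outdir: str = "epitax_run"
    seed: int = 0
    # simulation
    n_samples: int = 90
    k_true: int = 3
    effect_size: float = 1.5
    missing_fraction: float = 0.2
    n_features: int = 400
    # prep
    top_n: int = 300
    pseudocount: float = 1.0
    min_cpm: float = 1.0
    min_cpm_samples: int = 10
    # per-view consensus clustering
    k_range: tuple[int, ...] = (2, 3, 4, 5)
    cc_iters: int = 100
    cc_subsample: float = 0.8
    # integration
    k: int = 3
    alpha: float = 0.001
    beta: float = 0.0
    restarts: int = 20
    stability_repeats: int = 100
    stability_frac: float = 0.8
    # copy number
    bin_size: int = 400_000
    cbs_alpha: float = 0.01
    cbs_n_perm: int = 500
    n_reads: int = 50_000
    # association
    gsea_n_perm: int = 200

    def __post_init__(self):
        if self.k < 1 or self.k_true < 1:
            raise ValueError("cluster counts must be >= 1")
        if not (0 < self.cc_subsample <= 1) or not (0 < self.stability_frac < 1):
            raise ValueError("subsampling fractions out of range")
        if self.restarts < 2 or self.cc_iters < 1:
            raise ValueError("restarts must be >= 2 and cc_iters >= 1")
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha/beta must be non-negative")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = io.load_config(path)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "k_range" in raw:
            raw["k_range"] = tuple(raw["k_range"])
        return cls(**raw)


@dataclass
class RunManifest:
    """Reproducibility record of one pipeline run."""

    config_hash: str
    seeds: dict = field(default_factory=dict)
    checksums: dict = field(default_factory=dict)
    wall_time: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"config_hash": self.config_hash, "seeds": self.seeds,
                "checksums": self.checksums, "wall_time": self.wall_time}


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_hash(config: PipelineConfig) -> str:
    payload = json.dumps({k: getattr(config, k) for k in config.__dataclass_fields__},
                         sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()


def prepare_views(dataset: synthdata.MultiViewDataset, config: PipelineConfig):
    """Normalize each view (log2 CPM, TMM) on its observed samples, select the
    top-MAD features, and assemble zero-filled, masked non-negative matrices
    for integration (pseudocount >= 1 keeps log2(CPM + pc) non-negative)."""
    views, masks = {}, {}
    sample_ids = dataset.sample_ids
    for name, counts in dataset.views.items():
        observed = dataset.mask.loc[name].to_numpy(bool)
        obs_counts = counts.loc[:, observed]
        norm = matrixprep.normalize_log(obs_counts, pseudocount=config.pseudocount)
        sel = matrixprep.mad_select(norm, top_n=config.top_n)
        vals = norm.values.iloc[sel.selected]
        full = pd.DataFrame(0.0, index=vals.index, columns=sample_ids)
        full.loc[:, vals.columns] = vals
        views[name] = np.clip(full.to_numpy(float), 0.0, None)
        masks[name] = observed
    return views, masks


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute all stages in dependency order, halting with a stage-scoped
    error (and a FAILED marker beside the partial outputs) if any stage fails.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config_hash=_config_hash(config))
    root_ss = np.random.SeedSequence(config.seed)
    stage_seeds = {name: int(ss.generate_state(1)[0] % (2**31))
                   for name, ss in zip(
                       ["simulate", "cluster", "integrate", "cna", "assoc"],
                       root_ss.spawn(5))}
    manifest.seeds = stage_seeds

    state: dict = {}

    def stage(name, fn):
        logger.info("stage %s: start", name)
        t0 = time.perf_counter()
        try:
            fn()
        except Exception as exc:
            (outdir / "FAILED").write_text(f"{name}: {exc}\n")
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        manifest.wall_time[name] = round(time.perf_counter() - t0, 3)
        logger.info("stage %s: done in %.1fs", name, manifest.wall_time[name])

    def do_simulate():
        sim = synthdata.SimConfig(
            n_samples=config.n_samples, k_true=config.k_true,
            views=tuple(
                synthdata.ViewSpec(v.name, n_features=config.n_features,
                                   effect_size=config.effect_size,
                                   missing_fraction=config.missing_fraction)
                for v in synthdata.DEFAULT_VIEWS),
            seed=stage_seeds["simulate"])
        dataset, truth = synthdata.simulate_cohort(sim)
        dataset.write(outdir / "simulated")
        pd.DataFrame({"sample": dataset.sample_ids, "subtype": truth.labels,
                      "erg_class": truth.erg_class}).to_csv(
            outdir / "truth.tsv", sep="\t", index=False)
        state["dataset"], state["truth"] = dataset, truth

    def do_prep():
        state["views"], state["masks"] = prepare_views(state["dataset"], config)

    def do_cluster_views():
        labels = {}
        for vi, (name, x) in enumerate(state["views"].items()):
            obs = state["masks"][name]
            df = pd.DataFrame(x[:, obs],
                              columns=np.asarray(state["dataset"].sample_ids)[obs])
            cm = consclust.consensus_cluster(df, k=config.k, n_iter=config.cc_iters,
                                             subsample=config.cc_subsample,
                                             seed=stage_seeds["cluster"] + vi)
            labels[name] = pd.Series(cm.labels, index=df.columns)
        pd.DataFrame(labels).to_csv(outdir / "view_labels.tsv", sep="\t")
        state["view_labels"] = labels

    def do_integrate():
        problem = mivnmf.FactorizationProblem(
            views=state["views"], masks=state["masks"], k=config.k,
            alpha=config.alpha, beta=config.beta, seed=stage_seeds["integrate"])
        report = mivnmf.integrate_with_restarts(problem, n_restarts=config.restarts)
        labels = pd.Series(report.labels, index=state["dataset"].sample_ids,
                           name="cluster")
        labels.to_csv(outdir / "integrated_labels.tsv", sep="\t")
        report.contribution.to_csv(outdir / "view_contribution.tsv", sep="\t")
        pd.DataFrame(report.consensus, index=state["dataset"].sample_ids,
                     columns=state["dataset"].sample_ids).to_csv(
            outdir / "integration_consensus.tsv", sep="\t")
        state["integration"] = report

    def do_characterize():
        dataset, truth = state["dataset"], state["truth"]
        rna_name = next(iter(dataset.views))
        rna = dataset.views[rna_name]
        obs = dataset.mask.loc[rna_name].to_numpy(bool)
        norm = matrixprep.normalize_log(rna.loc[:, obs], pseudocount=config.pseudocount)
        erg_expr = norm.values.loc[synthdata.ERG_GENE]
        thr, erg_labels = signatures.bimodal_split(erg_expr, seed=config.seed)
        exons = list(signatures.ERG_FIVE_PRIME_EXONS) + [signatures.ERG_THREE_PRIME_EXON]
        coverage = synthdata.simulate_exon_coverage(truth, exons,
                                                    seed=stage_seeds["simulate"] + 1)
        status = signatures.erg_ratio(coverage,
                                      five_prime_ids=list(coverage.columns[:-1]),
                                      three_prime_id=coverage.columns[-1])
        out = pd.DataFrame({"erg_expression": erg_labels.reindex(dataset.sample_ids),
                            "erg_ratio": status.ratio,
                            "erg_ratio_class": status.ratio_class})
        out.to_csv(outdir / "erg_status.tsv", sep="\t")
        state["erg"] = out

    def do_cna():
        truth = state["truth"]
        reads, peaks = synthdata.simulate_offtarget_reads(
            truth, n_reads=config.n_reads, seed=stage_seeds["cna"])
        burdens = {}
        for sample, df in reads.items():
            prof = cna.offtarget_bin_counts(df, peaks, synthdata.DEFAULT_GENOME,
                                            bin_size=config.bin_size)
            segs = cna.cbs_segment(prof, alpha=config.cbs_alpha,
                                   n_perm=config.cbs_n_perm,
                                   seed=stage_seeds["cna"])
            burdens[sample] = cna.call_bins(prof, segs).burden
        io.write_json(burdens, outdir / "cna_burden.json")
        state["burden"] = pd.Series(burdens)

    def do_assoc():
        truth = state["truth"]
        labels = pd.Series(state["integration"].labels,
                           index=state["dataset"].sample_ids)
        res = assoc.chisq_association(labels.to_numpy(),
                                      np.where(truth.erg_class, "high", "low"))
        table = [{"variable": "erg_class", "statistic": res.chi2,
                  "df": res.df, "p": res.p}]
        a = assoc.anova_association(labels.to_numpy(), state["burden"].to_numpy())
        table.append({"variable": "cna_burden", "statistic": a.f,
                      "df": a.df_between, "p": a.p})
        pd.DataFrame(table).to_csv(outdir / "associations.tsv", sep="\t", index=False)

    stage("simulate", do_simulate)
    stage("prep", do_prep)
    stage("cluster-view", do_cluster_views)
    stage("integrate", do_integrate)
    stage("characterize", do_characterize)
    stage("cna", do_cna)
    stage("assoc", do_assoc)

    for path in sorted(outdir.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            manifest.checksums[str(path.relative_to(outdir))] = _sha256(path)
    io.write_json(manifest.to_dict(), outdir / "manifest.json")
    return manifest
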