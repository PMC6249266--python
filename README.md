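# epitax

Integrative multi-view subtyping of tumor cohorts from transcriptomic and
epigenomic data, built around **multiple incomplete-view non-negative matrix
factorization (MIV-NMF)**.

Molecular subtyping of cancer increasingly rests on several genome-wide data
streams per patient — RNA-seq expression plus ChIP-seq profiles of
transcription-factor binding (e.g. the androgen receptor in prostate cancer)
and histone marks (H3K27ac, H3K4me3, H3K27me3). In practice no cohort has
every assay for every patient. `epitax` is for computational biologists who
want to cluster such incomplete multi-omics cohorts without discarding
samples, and to characterize the resulting clusters: ERG status, copy-number
burden from off-target ChIP-seq reads, signature scores, covariate
associations and gene-set enrichment.

## The model

Given `V` non-negative feature-by-sample view matrices `X_v` over a shared
roster of `n` samples, with diagonal observation indicators `D_v`
(`D_v[s] = 0` when sample `s` lacks view `v`; its column in `X_v` is
zero-filled and masked), MIV-NMF minimizes

    J = Σ_v ‖(X_v − W_v H_v) D_v‖²_F  +  α Σ_v ‖(H_v − H*) D_v‖²_F  +  β Σ_v ‖H_v‖₁

over non-negative per-view bases `W_v` (features × k), per-view sample-factor
matrices `H_v` (k × n) and a consensus factor matrix `H*`, by multiplicative
updates of `W_v`, `H_v` and the closed-form update
`H*[·,s] = Σ_v D_v[s] H_v[·,s] / Σ_v D_v[s]`. Columns of `W_v` are kept at
unit L2 norm (scale absorbed into `H_v`) so the per-view factors are
comparable before coupling. Defaults: `α = 0.001`, `β = 0`. Each sample's
cluster is the argmax factor of its `H*` column; stability is quantified by a
consensus matrix over 20 random restarts and over 100 × 80% subsampling runs,
and each view's contribution is the Pearson correlation between `H_v` and
`H*` on observed samples.

Around this core the package provides, as separate modules:

| module      | contents |
| ----------- | -------- |
| `synthdata` | synthetic multi-view cohort generator (NB counts, latent subtypes, missing views, bimodal ERG-like gene, exon coverage, CNA-driven off-target reads) |
| `matrixprep`| CPM filtering, TMM normalization, log2-CPM matrices, consensus peaksets, occupancy curves, read-in-region counting, FRiP, MAD feature selection |
| `consclust` | per-view resampling consensus clustering (1 − Pearson, average linkage) with per-k stability summaries |
| `mivnmf`    | the integrative core described above |
| `signatures`| weighted z-score signatures, centroid (PAM50-style) classification, fold-change concordance, ERG 5′–3′ transcript ratio (τ = 0.3), Gaussian-mixture bimodality split |
| `cna`       | off-target-read binning (400 kb), peak exclusion (±1 kb), permutation-tested circular binary segmentation, gain/loss calls, CNA burden |
| `assoc`     | Pearson chi-square and one-way F association tests, signal-to-noise ranking, weighted-KS gene-set enrichment with phenotype permutation and FDR |
| `pipeline` / `cli` | YAML-configured end-to-end driver with a reproducibility manifest; `epitax` console script |

## Worked example

Simulate the default synthetic cohort (90 samples, 3 latent subtypes, five
views with 20% missing samples each, 1.5 log2 subtype effects), integrate it,
and compare the recovered clusters to the simulated truth:

```python
from sklearn.metrics import adjusted_rand_score
from epitax import SimConfig, simulate_cohort, FactorizationProblem, integrate_with_restarts
from epitax.pipeline import PipelineConfig, prepare_views

dataset, truth = simulate_cohort(SimConfig(seed=1))
views, masks = prepare_views(dataset, PipelineConfig())
problem = FactorizationProblem(views=views, masks=masks, k=3, alpha=0.001, seed=1)
report = integrate_with_restarts(problem, n_restarts=20)
print("ARI vs simulated truth:", round(adjusted_rand_score(truth.labels, report.labels), 3))
print(report.contribution.round(3))
```

prints

```
ARI vs simulated truth: 1.0
          mean_r   sd_r  n_restarts
rna        0.766  0.240        20.0
ar         0.796  0.221        20.0
h3k27ac    0.768  0.138        20.0
h3k4me3    0.792  0.161        20.0
h3k27me3   0.792  0.121        20.0
```

The adjusted Rand index of 1.0 means the three subtypes were recovered
exactly despite the missing views; `mean_r` is each view's contribution (all
five views carry equal signal in this simulation, so the contributions are
similar — on real data they separate informative from uninformative assays).
A pure-noise view added to the same cohort scores markedly lower (~0.4).

The same analysis end-to-end, from the shell:

```sh
epitax run --seed 1 --out run_out/
```

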