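# Methods

This note records the models and procedures implemented in `epitax`, the
defaults and why they were chosen, the numerical decisions that matter for
reproducibility, and what the synthetic-data tests do and do not demonstrate.

## Multi-view NMF with incomplete views

**Objective.** For views `X_v ≥ 0` (features × samples, shared sample order)
with per-sample observation indicators `D_v`,

    J = Σ_v ‖(X_v − W_v H_v) D_v‖²_F + α Σ_v ‖(H_v − H*) D_v‖²_F + β Σ_v ‖H_v‖₁ .

Missing samples' columns are zero-filled on input and *masked* by `D_v`: they
enter no term of the objective, so garbage in a masked column cannot move the
fit (this is verified bit-for-bit in the tests). The alternative — letting
zero columns participate in the reconstruction term — is a plausible reading
of zero-filling conventions; we mask because an unobserved assay carries no
evidence that every feature is absent. Samples observed in **no** view are
rejected.

**Updates.** Alternating multiplicative updates on observed columns:

* `W_v ← W_v ⊙ (X_v H_vᵀ + α W_v (b/q)) / (W_v H_v H_vᵀ + α W_v a + ε)` where
  `a_k = Σ_s H_v[k,s]²`, `b_k = Σ_s H_v[k,s] H*[k,s]`, `q_k = ‖W_v[:,k]‖₂`;
* column renormalization `W_v[:,k] ← W_v[:,k]/q_k`, `H_v[k,:] ← q_k H_v[k,:]`;
* `H_v ← H_v ⊙ (W_vᵀ X_v + α H*) / (W_vᵀ W_v H_v + α H_v + β/2 + ε)`;
* `H*[·,s] = Σ_{v ∋ s} H_v[·,s] / #{v ∋ s}` (the exact minimizer of the
  coupling term).

The renormalization is needed because NMF is scale-indeterminate per factor:
without it the coupling `‖H_v − H*‖²` compares factors on arbitrary scales.
Naively rescaling *after* measuring the objective can increase `J` between
sweeps. We therefore treat the coupling as acting on the scale-folded factor
(`q_k H_v[k,·]`): in that parametrization the renormalization is exactly
objective-invariant, the `W` update above includes the coupling's dependence
on the column norms, and the recorded objective — always evaluated at
unit-norm `W` states, where both parametrizations coincide — is
non-increasing per sweep. The trace is audited to 1e-9 relative tolerance in
the tests; observed violations are zero.

**Initialization.** Entries i.i.d. uniform(0,1) scaled to
`sqrt(mean(X_v)/k)`, with a per-restart seed drawn from the master seed. One
`H` draw is shared across views (rescaled per view): the coupling weight
`α = 0.001` is orders of magnitude below the reconstruction gradients on
these data, so it cannot repair an arbitrary per-view factor permutation
after each view has locked onto its own factor order; seeding a common order
costs nothing and makes the per-view contribution diagnostic meaningful.
This was adopted after observing factor-permutation misalignment (a view's
`H_v` anti-correlating with `H*` until rows were permuted) under fully
independent inits.

**Defaults.** `α = 0.001`, `β = 0`, 20 restarts, 100 × 80% subsampling for
stability, `max_iter = 500`, relative tolerance 1e-6. `α` and `β` and the
restart/subsampling schedule are the published analysis settings; the
iteration cap and tolerance are our choices (multiplicative updates converge
slowly near optima; the exact-factorization test uses 5000 iterations for
this reason).

**Labels and diagnostics.** Cluster of sample `s` = argmax of `H*[·,s]`
(ties → lowest factor; all-zero column → missing). Restart consensus
`C[i,j]` = fraction of restarts co-assigning `i` and `j`; final labels by
average-linkage hierarchical clustering of `1 − C` cut at `k` (label
co-assignment, not factor-matrix similarity, defines the consensus).
Contribution `r_v` = Pearson correlation of vectorized `H_v` and `H*` over
observed samples, mean ± sd over restarts.

## Per-view consensus clustering

Each of `n_iter = 100` iterations draws `⌈0.8 n⌉` samples without
replacement, clusters them hierarchically (distance `1 − r` on sample
profiles, average linkage — the common defaults of the standard
consensus-clustering tool; the published analysis names only "hierarchical
clustering") and cuts at `k`. `M[i,j]` = co-clustered / co-sampled. Pairs
never co-sampled are reported as 0 with a warning. The per-k summary reports
mean within- and between-cluster consensus (by the final labels), their
difference, and the consensus-CDF area with its successive-k change.

A caveat the tests make explicit: on a *fixed* noise dataset the final labels
are derived from `M` itself, so within-label consensus exceeds between-label
consensus even without structure — the honest null check compares consensus
within vs between *truth* groups of a zero-effect simulation, which agree to
< 0.1.

## Matrix preparation

* **CPM filter**: keep features with `count/libsize·1e6 > 1` (strict) in
  ≥ 10 samples.
* **TMM**: trimmed mean of M-values against a reference library (the one
  whose upper-quartile proportion is closest to the cohort mean), trimming
  30% by M and 5% by A two-sided, precision-weighted, factors rescaled to
  geometric mean 1. Matches the canonical implementation to 1e-8 on a frozen
  composition-biased example.
* **log2 normalization**: `log2(count/(libsize·f_s)·1e6 + pseudocount)`;
  pseudocount 0.5 by default, 1.0 in the integration pipeline so log2-CPM is
  non-negative without further shifting (NMF input must be ≥ 0).
* **Consensus peaks**: maximal base runs covered by peaks of ≥ `min_support`
  samples (each sample's peaks merged first). Implemented as an event sweep;
  verified against a literal base-resolution coverage oracle. Region *bases*
  shrink monotonically as support rises; the region *count* need not (a
  union-level region can fragment), though for site-centered peak sets —
  the realistic case — the occupancy curve is non-increasing.
* **Read counting / FRiP**: half-open, unstranded, overlap ≥ 1 bp; a read in
  two regions counts in both, FRiP counts each read once.
* **MAD selection**: unscaled `median(|x − median|)`, stable descending sort
  (ties keep input order), top 3000 genes / 1000 regions by convention,
  exposed as `top_n`.

## Tumor characterization

* **Signature scores**: `S_s = Σ_g w_g z_{g,s}` with per-gene population
  z-scores across the cohort; zero-variance genes contribute 0. Cohort-wide
  standardization is used (fixed reference moments would be an alternative;
  nothing in scope depends on the choice). Real signature gene lists (20-gene
  AR activity, 91-gene CD49f, PAM50 centroids) are user-supplied data files;
  the repository ships only synthetic fixtures.
* **Centroid classification**: argmax Spearman correlation over shared genes
  (≥ 3 required; Pearson available by option); missing centroid genes are
  handled by intersection.
* **ERG 5′–3′ ratio**: mean of the five 5′ exon depths over the 3′ exon
  depth; "high" iff ratio > 0.3 strictly. The printed 1-based inclusive exon
  coordinates ship as 0-based half-open constants. The biological orientation
  of the ratio (why fusion-like tumors show the *high* ratio given the
  minus-strand coordinates) is left to the user; we implement the printed
  arithmetic exactly.
* **Bimodality split**: 2-component 1-D Gaussian mixture (10 restarts, fixed
  seed); threshold at the posterior crossing between the means. Declared
  unimodal when the 1-component fit wins on BIC or the means coincide within
  1e-6 — the BIC rule is what makes the degenerate path fire reliably on
  genuinely unimodal data, where a free 2-component fit almost never yields
  coincident means.

## Copy number from off-target reads

Reads overlapping peaks padded by 1 kb are discarded; the rest are binned at
400 kb by read start. `log2(count + 0.5)` is centered at the autosomal
median. Segmentation is a deliberately simple, fully seeded CBS variant: per
chromosome, the arc maximizing the circular two-sample t-statistic is tested
by within-segment permutation (`n_perm = 1000`, accept if `p < 0.01`, pieces
≥ 3 bins) and recursion continues inside each piece. Permutations are seeded
per (chromosome, piece), so a smaller alpha can only remove splits. Gain/loss
calls use fixed ±0.2 log2 segment-mean thresholds (the published analysis
delegated calling to a mixture-model tool that is out of scope; ±0.2 is a
conventional desk-scale default, exposed in config). Burden = altered bins /
autosomal bins; sex chromosomes excluded unless requested.

## Association and enrichment

Pearson chi-square without continuity correction at any table size (required
to reproduce the published worked-example p-values; indeterminate covariate
levels are dropped first). Continuous covariates use the one-way
linear-model F test. Two published worked-example p-values (T-stage 0.932
and discovery-cohort PAM50 0.01343) are **not** reproduced by plain Pearson
chi-square on their printed tables under any missing-level handling we
tried, and are excluded from the reproduced set.

Differential ranking is signal-to-noise `(μ_in − μ_out)/(σ_in + σ_out)` with
each group's sd floored at `max(0.2·|μ|, 0.2)`; a moderated-statistic
pipeline is out of scope and unnecessary here because enrichment consumes
only the ranking. GSEA uses the weighted-KS running sum (hit weights
`|s2n|^p / Σ|s2n|^p` with `p = 1`, miss penalty `1/(N − m)`), phenotype-label
permutation (the ranking is recomputed per permutation), sign-matched NES
normalization, sign-matched nominal p with add-one smoothing, and the pooled
sign-matched permutation FDR; sets are flagged at FDR < 0.2. Set sizes are
restricted to `[5, N − 5]` after intersection.

## Synthetic cohorts: what they emulate, and what they don't

`synthdata.simulate_cohort` draws negative-binomial counts
(`var = μ + φμ²`, `φ = 0.3` by default) with log-uniform base means in
[20, 500]; a fraction (default 0.3) of each view's features is
cluster-informative, shifted by the view's effect size (default 1.5 log2) in
exactly one subtype. Missingness is MCAR per (sample, view) at 0.2 by
default, with a guard that no sample loses every view. One "ERG-like" gene
is a two-component mixture (50/50, +3 log2). CNA truth assigns (4, 8, 0)
gain/loss segments to the three subtypes (+0.58 / −1.0 log2, bin noise sd
0.2), mirroring a low-burden subtype; off-target reads follow
`2^(log2 ratio)` bin densities. Exon coverage gives fusion-like samples 5′
depth equal to the 3′ depth and others 10% of it, with Poisson sampling
noise. The default cohort (n = 90, k = 3, five views) is the study condition
for the headline recovery test; unit tests use smaller versions of the same
structure (n = 40–60, 3 views, 80–150 features) to stay fast.

Not emulated: batch effects, library-size variation between samples,
correlated features, GC/mappability bias, realistic genome sequence,
fragment-level reads, informative missingness. Passing tests therefore show
the *machinery* is correct and recoverable signal is recovered; they say
nothing about robustness to those real-data phenomena.

## Worked-example statistics

The published cluster-by-covariate contingency tables are shipped as input
data in the acceptance script; their chi-square p-values are recomputed at
run time and match the printed values to printed precision (e.g. ERG status
6.642e-12, Gleason 0.357, death 0.07688, validation-cohort PAM50 7.2e-15).
The TMM worked example freezes reference factors computed once with the
canonical implementation on a fixed 20 × 4 matrix.

## Numerical conventions

Coordinates 0-based half-open everywhere; BED native, printed 1-based
inclusive coordinates converted on ingestion. Strand ignored. Argmax ties →
lowest index; MAD ties → input order; hierarchical clustering uses scipy's
deterministic linkage. All stochastic stages take explicit seeds; derived
seeds come from `SeedSequence` spawning and stay below 2³¹. Epsilons: 1e-12
in multiplicative-update denominators; degenerate guards (zero-variance
genes, all-zero factor columns, never-co-sampled pairs, zero 3′ depth)
warn and report missing rather than fabricate values.
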