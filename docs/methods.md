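# Methods

This note documents the statistical procedures implemented by `methmirnet`,
the generative model behind the synthetic cohorts, the tunable parameters
and their defaults, and the design decisions taken where the workflow is
conventionally underspecified.

## 1. Differential meta-analysis

Each molecular layer (mRNA, miRNA, gene-level methylation score) is a
features × samples matrix with per-sample condition (tumor/normal) and
dataset labels. Meta-analysis proceeds by:

- **Z-score normalization per dataset**: for each feature within each
  dataset block, subtract the block mean and divide by the block sample
  standard deviation (ddof = 1), all samples of the block together.
  Zero-variance features map to an all-zero row (logged); features with
  fewer than two observations in a block are dropped with a warning.
  Z-scoring over all samples of a dataset (rather than tumor and normal
  separately) preserves the tumor−normal shift in the normalized data,
  which is what the downstream t-test consumes.
- **Pooling**: sample-wise concatenation over the intersection of feature
  ids; features absent from any dataset are dropped (count logged). An
  empty intersection is an error.
- **Differential test**: two-tailed two-sample Student (pooled-variance)
  t-test per feature. Welch's form is available via
  `scipy` directly but the pipeline deliberately uses the pooled-variance
  statistic, the field's default for this design. Bonferroni adjustment
  p_adj = min(1, m·p_raw), with m = number of features tested in the
  current layer/run. Significance: p_adj < `alpha_diff` (default 0.05).
  Degenerate features (both groups zero-variance) get t = 0, p = 1 when the
  means agree and p = 0 with a `degenerate` flag when they differ.
- **Top-k selection**: among significant features of a direction, the k
  (default 1000 per direction for the gene layer) with smallest p_adj;
  ties broken by larger |t|, then lexicographic feature id — a total order,
  so selection is deterministic.
- **Differential methylation** uses the same test with the *uncorrected*
  p < `alpha_meth` (default 0.05) cut, split by sign of the tumor−normal
  mean difference into hyper- and hypomethylated lists. At this cut a ~5%
  type-I background among non-differential genes is expected and intended;
  the downstream intersection with expression/survival-screened candidates
  absorbs it.

## 2. Survival screen

For each significant feature, tumor-sample expression is median-split:
patients strictly above the median are "high", ties go to "low" (a fixed,
documented rule; the convention is arbitrary but must be deterministic).
Patients lacking the endpoint's time or event are excluded per feature.
Overall survival drives candidate classification; relapse-free survival is
used only for signature validation.

- **Kaplan–Meier / log-rank**: product-limit estimation and the two-group
  Mantel–Cox test are delegated to `lifelines`; with no events anywhere the
  statistic is 0 and p = 1 by convention.
- **Hazard ratio**: exp of the maximum-partial-likelihood estimate for a
  single binary covariate with Breslow tie handling, Newton iteration on
  the scalar score with step clamping; Wald p from the observed
  information. Monotone likelihoods (all events in one group) are flagged
  with a warning and reported as a boundary HR (0 or ∞) with p = NaN; the
  classification skips such features since the hazard direction is
  untestable.
- **Joint rule**: TS = down-regulated ∧ log-rank p < `alpha_survival`
  (default 0.05) ∧ HR(high vs low) < 1; OG = up-regulated ∧ p < 0.05 ∧
  HR > 1. The same rule classifies TS/OG miRNAs on the miRNA layer.

## 3. Enrichment and GSEA

- **Over-representation**: one-sided hypergeometric tail p per gene set
  (sets intersected with the tested universe first), ranked ascending by p
  with ties broken by larger overlap then name. This is a plain
  hypergeometric test, not a reimplementation of any web service's modified
  score; for term *ranking* the plain test carries the same information.
  The annotation filter keeps the union of the members of the top
  `top_n_terms` (default 10) terms, intersected with the candidates.
- **Enrichment score**: classic weighted KS running sum over the ranked
  list; hits increment |w|^p normalized by the in-set total (p ∈ {0, 1},
  default 1), misses decrement 1/(N−|S|); ES = signed maximum deviation.
  The running sum is clamped to [−1, 1] against float round-off. A set
  covering none (or all) of the list is an error.
- **Permutation p**: the ranking metric is the per-feature pooled-variance
  t statistic between two phenotype classes; phenotype labels are permuted
  `n_perm` times (default 999) with a seeded generator; nominal p =
  (1 + #{sign-matched permuted ES at least as extreme})/(n_perm + 1). The
  +1 smoothing bounds p away from zero. Normalized enrichment scores and
  cross-set FDR are deliberately out of scope — the workflow's criterion is
  the nominal p only.

## 4. Pairing, pruning, network

Interaction edges (an opaque confidence in [0, 1], miRDIP-style) are kept
when they join a candidate miRNA to an opposite-role candidate gene at
confidence ≥ `min_confidence` (default 0 — no published score-class
threshold is assumed). The `top_n_mirnas` (default 5) miRNAs with most
candidate targets become hubs (ties by summed confidence, then id); per
gene at most `max_edges_per_gene` (default 2) highest-confidence incident
edges survive (ties prefer the lexicographically smaller miRNA id).
Methylation flags: TS ∩ hypermethylated, OG ∩ hypomethylated. Gene nodes
untargeted by the hubs are excluded from the network by default (they stay
in the exported candidate tables); `include_isolated_genes` restores them.
Node/edge attributes (node_type, direction, meth_flag, confidence) are
exported to GraphML, SIF and Cytoscape-importable TSV; styling is the
viewer's job.

## 5. Signatures and clinical statistics

A signature score is the per-patient **sum** of member Z-scores (missing
members dropped with a logged coverage count, no imputation; an empty
intersection is an error). Composites are exact differences:
mRNA-GS = TS-mRNA-GS − OG-mRNA-GS (annotation-filtered candidate lists by
default), miRNA-GS = TS-miRNA-GS − OG-miRNA-GS (full candidate miRNA
lists), meth-GS = hypermethylated-GS − hypomethylated-GS computed on *raw*
methylation scores — so a high meth-GS means the patient's TS genes are
relatively more methylated than their oncogenes. Cumulative
anabolic/catabolic scores: per enzyme role and condition, the sum over
annotated enzymes of the enzyme's mean Z-score within that condition.
Associations: Pearson r (two-sided t approximation, ≥ 3 complete pairs),
two-tailed Student t across clinical strata (vascular invasion yes/no,
stage I vs III, grade G1 vs G3, pathological T1 vs T3), and median-split
log-rank for overall and relapse-free survival.

## 6. Synthetic cohort model

The generator emulates the statistical structure of a multi-dataset
tumor/normal meta-analysis; it does not model platform/batch effects,
probe structure, CpG-level methylation or copy number, and its background
is independent Gaussian — so passing tests demonstrate the pipeline's
statistical correctness and recovery behavior, not robustness to
real-data artifacts such as batch confounding or heavy-tailed noise.

Per sample, all features are unit-variance Gaussians. Structure:

- **Planted differential features**: `n_planted_ts`/`n_planted_og` genes
  (default 100/100 of 2000) shifted ∓`effect_size` (default 1.5 SD — a
  convenience choice; real effect-size magnitudes are rarely reported) in
  tumors; likewise 5 + 5 planted miRNAs of 300.
- **Latent aggressiveness factor** A ~ N(0, 1) per patient. Planted genes
  load on A with loading `survival_loading` (default 0.85), sign matching
  their role (OG positive). The survival linear predictor is
  `hazard_log_ratio`·A (default log 2), realized as exponential event
  times with baseline hazard 0.1 (time unit ≈ months, median ~7) and
  independent exponential censoring whose rate is solved by bisection so
  the expected censored fraction equals `censor_rate` (default 0.3).
  The loading default comes from a power calculation: a median split of a
  gene with correlation ρ to A separates groups by ≈ 1.6ρ in A, giving a
  log-rank power ≈ 0.98 per gene at ρ = 0.85 with ~84 events — which is
  what makes the documented ≥ 0.85 classification sensitivity of the
  reference conditions achievable; at ρ = 0.7 the per-gene power drops to
  roughly two thirds.
- **miRNA–target coupling**: each planted miRNA is assigned a disjoint
  block of `targets_per_mirna` (default 20) opposite-role planted genes
  (so each planted gene has exactly one planted regulator and the pruning
  bound is exercised by decoys, not planted collisions). The miRNA
  residual is −w·(standardized mean residual of its targets) plus
  independent noise, with w calibrated analytically so each
  (miRNA, target) pair correlates at −`mirna_coupling` (default 0.6)
  within a condition. Through the targets' A component this also gives
  planted miRNAs the survival association their classification requires
  (|corr with A| ≈ 0.65 at the defaults; the miRNA screen is therefore
  intrinsically less powered than the gene screen — visible in hub
  recovery at small n).
- **Methylation**: a fraction `meth_fraction` (default 0.7) of planted TS
  genes are hypermethylation-coupled (+`effect_size` shift in tumors,
  correlation −`meth_coupling` (default 0.6) with their own expression
  residual), symmetrically for OG/hypomethylated; `n_background_meth`
  (default 50) extra background genes per direction are shifted without
  coupling, to exercise the candidate ∩ methylation intersection.
- **Interactions**: every planted edge with confidence U(0.5, 1) plus
  `n_decoy_edges` (default 400) random non-planted edges at U(0, 0.5), so
  confidence-based pruning is testable.
- **Clinical covariates**: vascular invasion, stage, grade and T category
  are thresholded noisy copies of A (5% "unknown"), so signatures built
  from planted features associate with them.
- **Gene sets**: one TS-enriched and one OG-enriched synthetic set (80% of
  the planted role list plus background mix-ins) and 20 random background
  sets, exercising the annotation filter and giving GSEA planted/null
  targets.
- **Pseudo-datasets**: samples are assigned round-robin to `n_datasets`
  (default 4) blocks, exercising per-dataset Z-scoring and pooling.

Everything derives from one `numpy` Generator seeded by `seed`; identical
configs produce byte-identical artifacts.

## 7. Problem sizes and numerical choices

The reference conditions are 120 tumors / 60 normals, 2000 genes, 300
miRNAs; the test suite and the acceptance script run the full pipeline at
these sizes (5–10 seeds) in a few minutes, with 999 permutations for the
single GSEA power check and 99 in the repeated calibration loops. Newton
iteration for the Cox score starts at β = 0, clamps steps to ±2 and
declares a boundary beyond |β| > 25. Text serialization uses TSV with `NA`
for missing values; readers validate strictly and raise typed errors
(configuration/parameter vs format/analysis), which the CLI maps to exit
codes 2 and 3.

## 8. Known limitations

- Survival modeling is univariate; no multivariate Cox, time-dependent
  covariates or competing risks.
- No probe-to-gene collapsing or GEO/TCGA ingestion: matrices are assumed
  gene-level and pre-harmonized (case-sensitive symbol matching, no
  aliasing).
- The hypergeometric annotation filter is a stand-in for interactive
  annotation tooling; GO graph structure and pathway topology are ignored.
- meth-GS operates on whatever scale the methylation matrix carries; no
  beta-value transform is applied.
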