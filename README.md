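# methmirnet

Integrative **meth-miRNA–mRNA regulatory-network analysis** for paired
tumor/normal multi-omics cohorts, with hepatocellular carcinoma (HCC)-style
study designs in mind. The package is aimed at computational biologists who
want a reusable, fully tested implementation of the classic
"differential meta-analysis → survival screen → inverse miRNA–target
pairing → methylation integration → network + gene-signature scoring"
workflow — together with a synthetic-cohort generator carrying a
planted-truth ledger, so every stage can be validated without access to
patient data.

## What it computes

Given mRNA expression, miRNA expression and gene-level methylation matrices
(tumor vs adjacent normal, possibly from several datasets), a clinical
table, a miRNA→gene interaction table with confidence scores and GMT gene
sets, the pipeline:

1. **Differential meta-analysis** — per-gene Z-scores within each dataset
   (x ↦ (x − μ)/σ, ddof = 1), pooled over shared features; two-tailed
   pooled-variance Student t-test tumor vs normal; Bonferroni adjustment
   p_adj = min(1, m·p); significance p_adj < 0.05; top 1000 up / 1000 down
   genes retained. Methylation uses the uncorrected p < 0.05 cut, split into
   hyper- and hypomethylated lists.
2. **Survival screen** — per significant feature, tumor-sample expression is
   median-split (ties → low) and overall survival compared by the log-rank
   (Mantel–Cox) test with a univariate Cox hazard ratio (Breslow ties).
   *Tumor suppressors (TS)*: down-regulated ∧ log-rank p < 0.05 ∧ HR(high) < 1.
   *Oncogenes (OG)*: up-regulated ∧ p < 0.05 ∧ HR > 1. Same rule classifies
   TS/OG miRNAs.
3. **Annotation filter** — hypergeometric over-representation of candidates
   against gene sets; candidates kept if they appear in the top-10 terms.
4. **Network assembly** — interaction edges joining candidate miRNAs to
   opposite-role candidate genes; top-5 miRNAs by target count become hubs;
   at most 2 highest-confidence edges per gene are kept; TS genes ∩
   hypermethylated and OG genes ∩ hypomethylated get methylation flags.
   Exported as GraphML / SIF / Cytoscape TSV.
5. **Gene signatures** — per-patient sums of member Z-scores:
   mRNA-GS = TS-mRNA-GS − OG-mRNA-GS, miRNA-GS = TS-miRNA-GS − OG-miRNA-GS,
   meth-GS = hypermethylated-GS − hypomethylated-GS (raw methylation scores);
   cumulative anabolic/catabolic enzyme scores; Pearson correlations,
   two-group t-tests across clinical strata, and median-split Kaplan–Meier /
   log-rank survival stratification.
6. **GSEA** — weighted running-sum enrichment score (signed maximum
   deviation; hit steps |w|^p normalized in-set, miss steps 1/(N−|S|)) with a
   phenotype-permutation nominal p, (1 + #{sign-matched ES* ≥ ES})/(n_perm+1).

## Worked example

Generate a reference synthetic cohort (120 tumors / 60 normals split over 4
pseudo-datasets, 2000 genes, 300 miRNAs, 100 planted TS + 100 planted OG
genes shifted by 1.5 SD, 5 planted hub miRNAs per role) and run the full
pipeline against its planted truth:

```bash
methmirnet simulate --out demo/cohort --seed 11
methmirnet report --in demo/cohort --out demo/run --seed 11
```

which prints (abridged):

```
                       n_found  n_truth     tp  sensitivity       ppv
ts_genes                  81.0    100.0   81.0     0.810000  1.000000
og_genes                  87.0    100.0   87.0     0.870000  1.000000
og_mirnas                  5.0      5.0    5.0     1.000000  1.000000
hyper                    165.0    120.0  120.0     1.000000  0.727273
flagged_ts                56.0     70.0   56.0     0.800000  1.000000
tumor_suppressor_hubs      5.0      5.0    5.0     1.000000  1.000000
planted_edges            114.0    113.0  113.0     1.000000  0.991228
```

Reading: of 100 planted TS genes, 81 were recovered by the joint
differential+survival rule and every reported candidate was a planted one
(PPV 1.0); the methylation screen found all 120 planted hyper genes plus
the expected ~5% type-I background (PPV 0.73 at the uncorrected p < 0.05
cut); all 5 planted oncogenic hub miRNAs were selected into the
tumor-suppressor network; and every planted edge eligible for the network
survived the top-2-per-gene pruning. `demo/run/` contains all per-stage
TSVs, the networks and `recovery_report.tsv`.

The same pipeline runs on real data by pointing `methmirnet run` at a
directory with the same file layout (see `methmirnet.synthetic.COHORT_FILES`).

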