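# kdapipe

Integrated transcriptomic–metabolomic analysis for exposure studies, with
network key-driver discovery and a planted-truth synthetic benchmark.

`kdapipe` is aimed at systems-biology studies of the kind where a small
cohort of animals is exposed to an environmental agent (diesel exhaust vs
filtered air, say), livers are profiled on both a microarray and a global
metabolomics platform, and the question is which genes *organize* the
molecular response. The pipeline covers:

- **Differential analysis** of both omics layers: rank-invariant
  normalization for array intensities, per-feature Welch (or Student)
  *t*-tests, Benjamini–Hochberg adjustment and Storey *q*-values, and
  directional signatures at an FDR cutoff.
- **Enrichment**: over-representation analysis with the fold-enrichment
  ratio `Enrichment = (k/K)/(n/N)` (k significant members of a pathway, K
  detected members, n significant features overall, N detected overall) and
  a hypergeometric tail p-value; plus weighted-running-sum GSEA with
  permutation NES, nominal p and sign-stratified FDR.
- **Key-driver analysis (KDA)** on a directed gene network: each gene's
  h-hop neighborhood is tested for signature enrichment with a one-sided
  Fisher exact test; genes passing Bonferroni-adjusted p < α are reported
  as key drivers. Seed-based subnetwork extraction and annotated GraphML
  export (Cytoscape-ready) are included.
- **Random-Forest classification** of exposure groups from metabolite
  profiles, with held-out accuracy and a ranked permutation-importance
  ("biochemical importance") table.
- **Integration**: a joint pathway table combining gene and metabolite
  enrichment on a shared pathway namespace, and reaction maps centered on a
  called key driver with nodes painted up/down/unmeasured.
- **Synthetic data with planted truth**: generators for expression
  matrices, metabolite tables, scale-free gene networks with planted key
  drivers, and pathway annotations — so every stage is benchmarked by how
  well it recovers what was planted, without any external download.

## Worked example

The `all` subcommand runs the whole synthetic study end to end — simulate
both omics and the network, call differential features, run GSEA/ORA, KDA,
the classifier, and the joint pathway table — and scores every stage
against the planted truth:

```sh
kdapipe all --seed 7 --outdir demo \
    --n-genes 2000 --n-metabolites 200 --n-permutations 200
```

which logs

```
pipeline complete: {"deg_observed_fdr": 0.0476, "deg_recall": 1.0,
                    "kd_precision": 1.0, "kd_recall": 0.8, "rf_accuracy": 1.0}
```

Reading `demo/run-report.json`: of 2,000 genes tested, 105 were called
differentially expressed at BH 0.05 — all 100 planted genes were recovered
(`deg_recall` 1.0) with 5 false calls (`deg_observed_fdr` 0.048, consistent
with the 5% FDR target). On the 1,000-node network, 8 key drivers were
called at Bonferroni α = 0.05; all 8 were planted drivers (`kd_precision`
1.0; 8 of the 10 planted found, `kd_recall` 0.8). The Random Forest
classified the n = 5/group metabolome with held-out accuracy 1.0. The top
of `demo/kda.tsv` shows the strongest driver:

```
gene    neighborhood_size  overlap  fisher_p   bonferroni_p  is_kd
G00001  113                72       3.86e-25   1.59e-22      True
```

a hub whose 113 network neighbors contain 72 signature genes — exactly the
topology-concentrated response the KDA is built to find.

Every stage is also available separately (`simulate-expression`,
`normalize`, `deg`, `metab-diff`, `gsea`, `ora`, `kda`, `subnet`,
`classify`, `integrate`), reading and writing plain TSV/GMT/SIF/GraphML,
and as library functions (`kdapipe.differential_table`,
`kdapipe.key_driver_analysis`, ...). A flat YAML config can set any stage
option; explicit flags win, and the effective configuration is written next
to the outputs.

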