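# Methods

This note records the statistical procedures `kdapipe` implements, the
defaults and why they were chosen, what the synthetic-data generators do and
do not emulate, and the numerical conventions that make runs reproducible.

## Differential analysis

**Normalization.** `rank_invariant_normalize` rescales each array sample
onto a reference profile (a named sample or the per-probe median
pseudo-sample) using probes whose rank is stable between sample and
reference. Candidate invariant probes satisfy |rank difference| ≤ 0.05 ·
n_probes; a second pass drops probes whose sample/reference log-ratio sits
more than twice the median absolute deviation from the set's median ratio,
and the sample is divided by the median ratio of the surviving probes.
Intensities must be strictly positive and on the original (not log) scale.
If the invariant set falls below min(50, ⌈5% of probes⌉) the function
refuses and suggests another reference — rescaling from a handful of probes
is worse than not rescaling. A sample exactly proportional to the reference
maps onto it exactly.

**Per-feature tests.** The default test is Welch's unequal-variance *t* on
log2 values, with the Welch–Satterthwaite degrees of freedom and a
two-sided p from the *t* distribution; a pooled-variance Student variant is
available. Features with fewer than two non-missing values in either group
get missing statistics and are excluded from the multiple-testing family
(the family size m is the number of features actually tested, logged when
features are dropped). Degenerate inputs are defined, not fatal: identical
groups give t = 0, p = 1; two zero-variance groups with different means
give p = 0 with a log note.

One calibration fact worth knowing: at n = 5 + 5 normal samples the
two-sided Welch test is conservative — its exact size at α = 0.05 is
0.0439, not 0.050 (measured by direct simulation with 10⁶ replicates).
Empirical type-I rates just under 0.045 on small-n metabolomics designs are
therefore the test behaving correctly, not an implementation artifact.

**Fold changes** are ratios of arithmetic group means on the original
scale (treated/control), the convention of targeted metabolomics reports;
tests run on the log2 scale. Metabolite tables are min-imputed per
metabolite (each missing cell replaced by that metabolite's smallest
observed value) before testing — the standard convention for
below-detection values in global metabolomics — while fold changes use the
same imputed original-scale values.

**Multiple testing.** `bh_adjust` is the Benjamini–Hochberg step-up,
written directly (sort, scale by m/rank, cumulative minimum from the top,
cap at 1) and checked in the tests against an independent step-up oracle
and against statsmodels. `q_values` adds Storey's estimate: π₀(λ) =
#{p > λ}/(m(1−λ)) on the λ-grid 0.05–0.95, smoothed with a cubic fit
evaluated at λ = 0.95 and clipped to (0, 1]; q = π₀ × BH. Storey
estimation needs ≥ 100 p-values; smaller families fall back to BH with a
warning. Signatures are called at an adjusted-p cutoff (default 0.05,
always a parameter, never hard-coded); a significant feature with fold
change exactly 1 joins neither direction and is logged.

## Enrichment

**ORA.** For each pathway intersected with the detected universe, the fold
enrichment is (k/K)/(n/N) and the p-value the upper hypergeometric tail
P(X ≥ k); enrichment is the default direction, depletion is behind a flag.
BH adjustment runs across pathways. The identity fold_enrichment = 1
whenever k/K = n/N, and invariance under common scaling of all four counts,
are asserted as properties.

**GSEA.** The enrichment score is the extremum of a running sum over the
ranked feature list: hits add |score|^w normalized to total 1 (w = 1 by
default — score-weighted; w = 0 recovers the classic Kolmogorov–Smirnov
form), misses subtract 1/(N − |S|). Rankings come from the differential
table by signed −log10 p (default), log2 fold change, or t; ties always
break by feature id so a ranking is a deterministic function of the table.
Significance uses permutations, default 1,000 of gene-set membership
(random same-size sets; the null ES is computed in O(|S| log |S|) from hit
positions, since the running sum is linear between hits). Phenotype
permutation — relabel samples, recompute the ranking — is implemented and
preferred when groups are large enough; with fewer than 3 samples per
group it falls back to gene-set permutation with a logged warning. NES is
ES divided by the mean |permuted ES| of the same sign, the nominal p is the
same-sign tail with +1 continuity, and the FDR q compares each NES with the
pooled same-sign permuted NES distribution against the observed same-sign
NES distribution, capped at 1. Set-size filters (default 15–500 after
intersection) apply before any statistic.

## Key-driver analysis

For every candidate gene (neighborhood size ≥ 5 by default — smaller
neighborhoods give uninformative 2×2 tables), the h-hop neighborhood
(default radius 1, edges treated as undirected; in/out variants available)
is tested for signature over-representation against the rest of the network
excluding the candidate, with a one-sided Fisher exact test (upper
hypergeometric tail). The background universe is the network's node set,
not all assayed genes: the hypothesis is about topology, so the signature
is intersected with the network first (discarded genes are counted in the
log). Bonferroni multiplies by the number of candidates actually tested;
genes with adjusted p < α (default 0.05) are key drivers. Ordering is by
adjusted p, ties by gene id. Subnetwork extraction takes the induced graph
on seeds plus their h-hop neighbors, ranks weakly connected components by
edge count (ties: node count, then lexicographically smallest member) and
returns the top component with the full ranking table.

## Random-Forest classification

Metabolite profiles are log2-transformed after min-imputation; the
classifier is an ensemble of CART trees with √p feature subsampling at
each split and balanced class weights.

Two validation schemes are offered, and the default (`scheme="auto"`)
picks by design size:

- **Out-of-bag** (groups of ≥ 6): classic bagging; each sample is scored
  by the trees whose bootstrap missed it.
- **Cross-validated** (any group ≤ 5 samples): trees are grown on the full
  training fold with feature subsampling as the only randomness (the
  random-subspace variant), and folds hold out *one sample per class*.

The small-n choices are deliberate, and both address failure modes that
are easy to reproduce: with 10 samples, a bootstrap keeps ~7 unique points,
and tens of pure-noise metabolites will separate 7 points perfectly by
chance — trees built on such spurious separators are systematically
*anti-*predictive out of bag (the held-out points are the ones that broke
the pattern), so OOB accuracy collapses regardless of how strong the
planted signal is. Growing each tree on the full fold makes chance
separation of all points far rarer (2/C(10,5) per noise feature vs
2/C(7,3)), so most trees split on real signal. Holding out one sample per
class keeps every training fold class-balanced; plain leave-one-out folds
(4 vs 5) let the majority vote amplify the slight majority tilt of
uninformative trees into systematically wrong predictions — on
label-permuted data that yields accuracies far *below* chance, whereas the
balanced scheme sits at 0.5 as a null should. The ensemble budget
(`n_trees`, default 500) is split across the folds holding a given sample
out, so each prediction still aggregates ~n_trees held-out tree votes.

Importance is Breiman-style out-of-bag permutation importance computed from
a bagged forest: per tree, the drop in out-of-bag accuracy when one
feature's values are shuffled (5 repeats), averaged over trees; only
features a tree actually splits on are evaluated (the rest contribute an
exact zero), which keeps the computation to one batched predict per tree.
Rankings break ties by metabolite id.

## Synthetic data

The generators emulate a two-group exposure design: transcriptomics at
n = 8/group, metabolomics at n = 5/group.

- **Expression**: per-gene log2 baselines ~ Normal(8, 1.5²) with
  Normal(0, 0.25²) residuals — plausible magnitudes for normalized
  bead-array intensities; no platform states a variance model, so these are
  exposed parameters, not claims. A chosen fraction of genes (default 5%)
  receives a signed uniform log2 shift (default 1–2) in the treated group.
- **Metabolome**: log-normal abundances (log2 baseline ~ Normal(10, 2²),
  residual SD 0.25); planted metabolites are multiplied by fold changes
  whose default palette spans 0.35× up to 104.13× — the range reported for
  TCA-cycle intermediates and glycogen-breakdown sugars in diesel-exposure
  liver metabolomics (citrate 0.35, glucose 3.26, fructose 9.6, maltose
  18.13, maltohexaose 104.13, among others). Values below a detection
  floor become missing.
- **Network**: a Barabási–Albert scale-free graph (3 attachments per node,
  a realistic edge density for tissue gene-regulatory networks) with each
  edge oriented by a fair coin. Planted drivers are sampled from the top
  5% of nodes by degree: a planted driver must be detectable *in
  principle*, and a power calculation shows that at ρ_in = 0.7 against a
  Bonferroni correction over several hundred candidates the median overlap
  0.7 × degree needs degree ≈ 14+, which the 5% pool guarantees (the decile
  boundary, degree ≈ 10, does not). The signature then includes each
  driver-neighbor with probability ρ_in (default 0.7) and every other node
  with probability ρ_bg (default 0.05); drivers adjacent to other drivers
  are themselves eligible.
- **Pathways**: a shared gene/metabolite pathway namespace; the first few
  pathways draw half their members from the planted features
  ("enriched by construction", flagged in the truth record).

What the generators do **not** emulate: probe-level array artifacts, batch
or chip effects, metabolite–metabolite correlation, heteroscedastic
per-feature variances, compositional effects, or mass-spectrometry peak
processing. Passing the recovery benchmarks therefore demonstrates that the
statistics and the pipeline plumbing are correct under their stated
assumptions — not that real data of this kind would yield these recovery
rates.

**Seeds.** One global seed expands into per-stage child seeds via
`SeedSequence(seed, spawn_key=(code,))` with a fixed documented code per
stage (expression 1, metabolome 2, network 3, pathways 4, GSEA 5,
classifier 6), so each stage is independently reproducible and adding a
stage never perturbs another. Same-seed end-to-end runs are byte-identical.

## Numerical and formatting conventions

Exact hypergeometric tails come from `scipy.stats.hypergeom.sf` and are
verified in the tests against exact rational enumeration for every 2×2
table with all margins ≤ 25 (82,251 tables, agreement to 1e-10). All
orderings define tie-breaks (feature/gene/metabolite id, lexicographic);
p-value floors (1e-300) guard the signed log-p ranking; GraphML booleans
are serialized as 0/1 for viewer portability; all text outputs are UTF-8
TSV with headers, missing values written as `NA` and read back from empty,
`NA` or `NaN` tokens. Identifier matching is case-sensitive exact string
comparison — silent case-folding across species conventions (Pck1 vs
PCK1) hides annotation bugs.

Benchmark problem sizes used by the test suite and the acceptance script —
10,000 genes × 8/group for DEG recovery, 1,000-node networks with 10
planted drivers for KDA (20 replicates), ~500 metabolites × 5/group for
the classifier (20 replicates), 1,000 permutations for GSEA — were chosen
to mirror the emulated study's scale while keeping a full run in the
minutes range on one CPU.

## Known limitations

- The KDA treats the network as fixed and error-free; edge uncertainty is
  not propagated.
- Storey's π₀ smoother is a cubic polynomial fit, adequate for the
  families tested here but less robust than spline-based estimators for
  very sparse alternatives.
- The classifier's importance is accuracy-based; with strongly correlated
  metabolites it splits credit across the correlated group.
- GSEA's phenotype permutation enumerates random relabelings, not the
  exact permutation distribution, and at n = 8 + 8 the tail resolution is
  limited by the number of distinct relabelings actually drawn.
- Probe-to-gene collapsing beyond first occurrence, batch correction and
  moderated (shrinkage) tests are out of scope.
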