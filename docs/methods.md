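# Methods

`lymtrace` re-implements, as one tested pipeline, the analysis chain used to
trace gypsy-moth (*Lymantria dispar*) invasions with a 60-locus amplicon
panel: haplotype-level genotype calling from multiplexed paired-end reads,
population diversity and differentiation statistics, discriminant analysis of
principal components (DAPC) for population structure, origin assignment with
an explicit decisiveness rule, and detection of F1/F2/backcross hybrids.
Every stage is exercisable on synthetic data produced by the package itself;
this note documents the models, the tunable parameters and their defaults,
and what the synthetic experiments do and do not demonstrate.

## Data model

A *locus* is a 350–425 bp amplicon identified by the first 40 bases of its
reference sequence (the anchor). An *allele* is a full haplotype sequence of
one amplified locus copy — loci carry a median of ~42 SNPs, so alleles are
multi-state, not biallelic. Allele identifiers are opaque strings compared by
exact match: haplotype sequences when calls come from reads, integer codes
when tables come from Genepop files. The panel mixes 55 diploid nuclear loci
with 5 haploid mitochondrial loci; the mitochondrial loci are treated as a
single linked block wherever that matters (simulation, inheritance) and are
excluded from heterozygosity-based statistics.

Genepop has no population names and no haploid dialect for mixed panels, so
the writer emits haploid loci as duplicated homozygous diploids and records
both the convention and the population labels as `key=value` tokens in the
free-text title line; the reader honours these tokens and falls back to
`pop1..popN` and an all-diploid reading for third-party files.

## Genotype calling

The caller follows the five-step amplicon workflow: (a) adapter and 3'
quality trimming, (b) merging of overlapping mates (seed-and-verify overlap
search, ≥ 10 bp overlap, ≤ 10 % mismatches, higher-quality base wins at
disagreements; merged reads shorter than 225 bp are discarded), (c) locus
assignment by anchor identity — a read is assigned to the unique locus whose
anchor matches ≥ 36 of the read's first 40 bases (90 %), both orientations
tried, ties unassigned and counted, (d) collapsing identical sequences, and
(e) calling the top two haplotypes as the diploid genotype.

Two thresholds in step (e) are not dictated by the workflow description and
are package choices, both config-exposed:

* `min_locus_depth = 6` — below this the locus call is missing;
* the runner-up haplotype becomes the second allele only when its count
  reaches `max(3, 0.2 × top count)`, otherwise the call is homozygous.

At the default simulated depth of 50X these suppress error haplotypes (which
are overwhelmingly singletons at per-base error ≲ 0.5 %) while accepting true
heterozygotes, whose minor-allele count is binomially concentrated near half
the depth. Count ties break lexicographically by sequence so calls are
deterministic. Specimen-level QC excludes individuals with mean per-locus
depth < 10X or more than 15 failed loci (strict inequality: exactly 15 is
retained). "Coverage across all loci" is read as the mean per-locus depth;
the alternative every-locus reading would make the failed-locus rule
redundant.

Marker-discovery contig filters (coverage within [20X, 10,000X], at least one
variant site) are provided as a standalone function.

## Population statistics

All diversity and differentiation statistics use nuclear loci with per-locus
complete-case handling of missing data (no imputation; imputation exists only
inside the DAPC encoding). Per-locus gene diversity is the unbiased
`n/(n−1) · (1 − Σp²)` with `n` counted in gene copies. In the summary table,
`D` averages gene diversity over *all* loci (monomorphic loci contribute 0)
while `H_O`/`H_E` average over the loci polymorphic within the population;
this makes the two columns non-redundant in the way field studies usually
report them. Private alleles are counted against all other populations in the
same table.

F_ST is the Weir–Cockerham (1984) variance-components estimator extended over
alleles, combined across loci as the ratio of summed components (the
convention of the standard F-statistics software); negative estimates are
reported as computed. The estimator is checked in the test suite against an
independently coded brute-force implementation of the same formulas (1e-12)
and against Balding–Nichols parameter recovery (below). Per-locus multi-group
estimates drive the "top half loci by F_ST" panel subsetting used in
cross-validation.

Linkage disequilibrium between locus pairs is screened with a permutation
G-test of independence on the two-locus genotype contingency table: one
locus's genotypes are permuted across co-typed individuals and
`p = (1 + #{perm ≥ obs}) / (n_perm + 1)`, which is exact under
exchangeability. This replaces the Markov-chain exact test used by Genepop:
the hypothesis is the same, the null is exact by construction, and the cost
is controllable. The multiple-testing correction is Bonferroni
(config-exposed); pairs with fewer than 5 co-typed individuals are skipped
and flagged.

## DAPC

Genotypes are encoded as an individuals × (locus, allele) matrix of within-
individual allele frequencies (diploid 0/0.5/1, haploid 0/1); missing calls
are imputed with column means, and query data are encoded on the training
dictionary (unseen alleles dropped, training means for imputation). PCA runs
on the centred (by default unscaled) matrix; linear discriminant axes are the
generalized eigenvectors of the between/within scatter on the retained PC
scores, normalized so the pooled within-group covariance in discriminant
space is the identity. Membership probabilities are Gaussian posteriors with
the pooled within-group covariance and uniform priors — the standard DAPC
predictive model. Because the whitened discriminant subspace spans all
between-mean directions, these posteriors equal full-PC-space Gaussian
posteriors with shared covariance; the test suite verifies this equivalence
against an independently coded density oracle (1e-8). Singular within-group
scatter (e.g. point-mass groups) receives a logged 1e-8 ridge.

Cluster search evaluates `BIC(K) = n·ln(WSS_K/n) + K·ln(n)` on the first
`n_pcs` PC scores, with K-means (restarted, seeded) or Ward agglomerative
labels — the same formula for both so the curves are comparable. `WSS = 0`
at `K = 1` (all rows identical) returns −inf so K = 1 is selected; at
`K > 1` the entry is dropped from the curve. Because the search reports the
full curve, flat-bottomed curves (the "equal support over a range of K"
situation) remain visible to the analyst rather than being collapsed to a
single K. PC retention can be chosen by stratified held-out assignment
accuracy starting from 300 PCs (capped at rank), ties resolved toward fewer
PCs.

Membership post-processing zeroes coefficients below 0.05 and redistributes
their mass proportionally over the surviving coefficients (rows re-sum to 1;
if everything but the maximum is sub-floor the row becomes an indicator).
The operation is idempotent. The hierarchical workflow repeats the cluster
search within each top-level group, leaving groups below 10 individuals
unsplit, and reports two-level labels.

## Assignment

The decisiveness criterion is the *relative probability*: the ratio of the
highest to the second-highest membership probability, +inf when the runner-up
is zero. A specimen is assigned only when the ratio reaches the threshold
(default 2); exact ties are inconclusive. Two engines feed this rule: the
DAPC posterior, and a support-vector classifier with Platt-calibrated
probabilities trained on the same retained PC scores as the DAPC. The SVM's
outputs are calibrated scores, not true posteriors, so the ratio rule can
behave differently between engines — both are reported. Queries typed at
fewer than half the panel loci are flagged unreliable but still scored.

Egg masses are summarized across sibling eggs: *identical* (all decisively
assigned to one group), *congruent* (decisive eggs agree and inconclusive
eggs point to the same group), otherwise *conflict*.

Panel diagnostic power is measured by stratified Monte-Carlo
cross-validation: per replicate, a fixed count (or fraction) per group is
held out and everything — including the F_ST locus ranking when the top-half
subset is used — is refit on the training split only, so no information leaks
from test individuals into locus selection or the classifier. Accuracy counts
an inconclusive held-out individual as incorrect by default (conservative);
the plain argmax convention is always reported alongside.

## Hybrid simulation and classification

Progenies are built from gametes. A parental pool contributes gametes drawn
independently per locus from the pool's allele frequencies (the behaviour of
the standard hybrid-simulation function in the reference R ecosystem); a
progeny pool used as a parent (F1 × F1, F1 × parent) instead draws one
individual and segregates one of its two alleles per locus, preserving the
inter-locus identity disequilibrium that makes F2 and backcross genomes
distinguishable from random-union genotypes. Mitochondria pass as one linked
block from the maternal pool; the maternal side is a fair coin per progeny by
default, mirroring reciprocal crosses. The five-class reference is
{pure AGM, pure EGM, F1 = AGM×EGM, F2 = F1×F1, BC = F1×EGM}, 100 individuals
per class by default; further generations are not simulated.

Classification applies, in order: (1) a decisive five-class relative
probability (≥ 2) names the class; (2) otherwise a specimen whose combined
purebred probability is below 0.05 while its combined hybrid probability
exceeds 0.95 is an *undetermined hybrid*; (3) otherwise *inconclusive*. The
ladder partitions the probability simplex (property-tested). Hybrid analyses
default to nuclear loci only, switchable to all 60.

The cross-validated benchmark reports per-class argmax accuracy (the
convention of the reference engine's cross-validation), decisive-rule
accuracy alongside, the mean confusion matrix, and the mutual F1↔F2
confusion rate.

## Synthetic data

The generator emulates the statistical structure the analyses assume, not
gypsy-moth biochemistry:

* **Cluster structure** is Balding–Nichols: ancestral allele frequencies from
  a symmetric Dirichlet (concentration configurable; values < 1 give the
  skewed many-rare-alleles spectra of haplotype panels), each cluster's
  frequencies a Dirichlet draw with concentration `p·(1−F)/F`. Two clusters
  with drifts F_j, F_k realize pairwise Weir–Cockerham F_ST ≈ (F_j+F_k)/2;
  the parameter-recovery suite verifies this within ±0.02 at F ∈
  {0.02, 0.10, 0.23}.
* **Genotypes**: each allele copy picks a source cluster (pure membership or
  per-individual admixture proportions) then an allele from that cluster;
  haploid loci share one source and one frequency quantile per individual
  (complete linkage); calls go missing independently at a configurable rate.
* **Panel sequences**: amplicons drawn in the 350–425 bp window; SNP counts
  per locus follow a rounded lognormal with median 42 and log-sd 0.47
  (quartiles ≈ 30/57); SNPs sit outside the 40 bp anchor by default so
  anchoring is genotype-independent (an option moves them into the anchor to
  stress-test the 90 % rule).
* **Reads**: per individual and locus, Poisson(mean depth, default 50 — the
  per-locus depth of the real experiment is not reported, so this is an
  engineering choice) read pairs of 2 × 300 bp geometry, fair-coin haplotype
  choice for heterozygotes, independent per-read substitution errors at the
  configured rate (errors are applied after slicing the template, as
  sequencing errors are), Phred characters encoding that rate, random strand
  orientation, and a configurable fraction of junk pairs built from random
  templates — junk merges like a real amplicon but fails anchoring, which is
  what makes the anchor-rejection rate testable.

What the generator does **not** model: PCR chimeras, index hopping, primer
artefacts, coalescent genealogies within clusters, linkage among nuclear
loci, and — importantly — mutual allele privacy beyond what Balding–Nichols
drift around a shared ancestral pool can produce (see below). Passing the
synthetic suites therefore shows the pipeline's operations are correct under
the stated statistical model, not that real moth data would reach the same
accuracies.

### Calibration of the hybrid-study pools

The hybrid emulation needs two parental pools standing in for the diverse
East-Asian pool and the founder-bottlenecked North-American pool. Defaults
(`HYBRID_STUDY`): 55 nuclear loci, 24 ancestral alleles per locus,
ancestral Dirichlet concentration 0.3, drifts F = (0.05, 0.41). These were
chosen to jointly reproduce the published summaries of those two pools — a
realized pairwise F_ST of ≈ 0.23 together with the strong gene-diversity
contrast (realized H_E ≈ 0.78 vs ≈ 0.50) and allele-richness asymmetry —
rather than to optimize downstream classifier scores.

Under this emulation the cross-validated five-class benchmark typically
yields parent-class accuracies of 0.96–1.00, backcross accuracy of about
0.90–0.97, and F1/F2 mutual confusion near one half. The backcross figure
sits at or slightly below the 96 % the field study reports, and the reason
is informative: multi-allelic Weir–Cockerham F_ST is compressed at high gene
diversity, so a real panel whose alleles are largely population-private can
print a moderate F_ST of 0.23 while carrying far more class information than
a Balding–Nichols draw matched to the same F_ST, in which the two pools
necessarily share their common ancestral alleles. Within the Balding–Nichols
family no parameterization reproduces both the printed F_ST and the printed
privacy level, and the package keeps the model rather than inflating
differentiation to flatter the benchmark.

## Numerical choices and degenerate inputs

Frequency vectors are validated to sum to 1 (1e-12); membership rows to 1
(1e-9). Dirichlet concentrations are floored at 1e-12 to avoid zero-parameter
draws. PCA retention is capped at matrix rank and n−1; discriminant axes at
groups−1. Singular covariances receive a logged 1e-8 ridge. Count ties in
calling and ranking break lexicographically; BIC ties resolve to the smaller
K via the minimum; PC-retention ties to fewer PCs. Empty query sets yield
empty outputs; individuals missing at every locus are rejected at encoding.

## Known limitations

* Genepop dialect support covers the common 2- and 3-digit forms with
  whitespace-separated genotypes; exotic variants (single-line pops,
  haploid-only files) are out of scope.
* The BIC cluster search inherits K-means/Ward instabilities on data with
  few informative dimensions; the full curve is reported so flat optima are
  visible.
* The SVM engine's calibrated probabilities make the ratio-2 rule stricter
  than for DAPC posteriors near certainty; congruence between engines is the
  intended use, as in the original analysis.
* Hybrid classes beyond the first backcross generation (F3, BC2) are not
  simulated, and sex-linked inheritance or hybrid-fitness effects are not
  modelled.
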