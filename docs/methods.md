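# Methods

## The model

`toascore` treats a fine-mapped GWAS signal — a 99% credible set of SNPs
with posterior probabilities of association (PPAs) summing to ≈ 1 — as a
probability mass to be divided among candidate tissues of action. The
division is driven entirely by annotation overlap:

1. **Chromatin states.** Each tissue contributes a genome segmentation
   (e.g. a 13-state ChromHMM map). For a SNP overlapping state *a*, the
   state's enrichment weight `w_{a,t} = 2^log2FE(a,t)` is split evenly over
   the tissues in which the state covers that position (the
   sum-of-indicators denominator). Enrichment values are consumed as
   input (typically fgwas output); estimating them is out of scope.
2. **Coding sequence.** CDS is a single genome-wide annotation with one
   weight. Its tissue profile comes not from chromatin but from the
   overlapped gene's expression specificity scores (ESS): median TPM per
   tissue normalised to sum to 1. A coding SNP on a liver-specific gene
   therefore pushes its PPA toward liver. When isoforms of several genes
   overlap a position, the mean of their ESS vectors is used (symmetric and
   order-independent), renormalised by its sum.
3. **Partition.** Each SNP's combined vector `s_j` is normalised by its own
   total before being scaled by the SNP's PPA, so the per-signal tissue
   scores τ plus the unclassified residual *U* reproduce the cumulative PPA
   exactly (to 1e-9 in all conservation checks). The self-normalisation
   also makes every profile invariant to rescaling all weights by a common
   factor — only *relative* enrichments matter.

Key assumptions: one base per variant (indels are treated as their start
position); chromatin states are strandless; credible sets whose PPAs sum
to less than 1 are scored as printed (τ + U equals the printed sum — no
renormalisation); a SNP overlapping no included annotation in any tissue
contributes wholly to *U*.

## Interval partitioning

Per-tissue segmentations are decomposed, independently per state label,
into maximal cross-tissue disjoint segments carrying exact
tissue-membership sets (tissue-specific / all-tissue / sub-combination).
The implementation is a numpy boundary sweep with adjacent-segment merging,
verified in the tests against a per-base brute-force labelling oracle and a
base-coverage conservation check (partitioned length per (state, tissue)
equals input length). SNP lookup is bisection per (chromosome, state);
CDS lookup, where isoform records may overlap, goes through an interval
tree. Different state labels may legitimately overlap across tissues (a
position can be enhancer in islet and transcribed in liver); both hits are
emitted and both contribute to `s_j`.

By default, state labels containing `quies`, `repress` or `low_signal`
(case-insensitive) are excluded from scoring, routing their PPA to *U*;
the included-state list is configurable because weak-transcription states,
though near-baseline in enrichment, carry a large share of posterior mass
and are scored by default.

## Classifier

Arg-max with a threshold in {0.0, 0.2, 0.5, 0.8}. With shared designation
enabled, a top-two gap ≤ 0.10 (with the top score still above threshold)
yields "shared"; the gap is computed on raw τ, not τ renormalised by
(1 − U). A top score of exactly 0 is always unclassified. Exact arg-max
ties with sharing disabled break deterministically by a fixed tissue order
(islet, adipose, liver, muscle) with a warning. Shared signals are tiered
by fine-mapping resolution: single-SNP set → tier 1, max PPA ≥ 0.5 →
tier 2, else tier 3.

The SSD tissue-specificity summary is the sum over unordered tissue pairs
of squared score differences, computed on the tissue scores only. "Sum of
squared distances between TOA scores" admits no other reading in which a
distance *between* scores is defined per signal; this is recorded as a
design choice.

The per-signal coding score (used to exclude coding-driven signals from
the nearest-gene analyses at cutoff 0.1) defaults to the share-weighted
form Σ_j P_j · (CDS share of s_j); a simpler Σ P_j over CDS-overlapping
SNPs is available via `simple_coding_score=True`.

## Permutation statistics

All enrichment analyses share one scheme: observed overlap vs N
size-matched null sets, fold = observed / null mean, and the add-one
empirical p value (n_{null ≥ obs} + 1)/(N + 1), whose floor 1/(N+1) keeps
p > 0 and makes the statistic super-uniform under the null (asserted by a
one-sided KS test over 500 null-drawn queries). Defaults: N = 1,000 for
eQTL enrichment and expression similarity, N = 10,000 for
physiology-cluster and GWAS-catalog tests. Sampling is without replacement
within a permutation, and every result records its seed.

* *Tissue-specific eQTLs*: specific(t) = S_t \ ∪_{u≠t} S_u; pairwise
  disjoint by construction. Significance filtering (FDR ≤ 0.05 q-values)
  is consumed as a pre-filtered input; a Benjamini–Hochberg helper is
  provided for users holding only nominal p values, documented as an
  approximation of a q-value procedure.
* *Matched nulls*: the matching covariates for eQTL nulls are an
  injectable strategy — uniform draws from a SNP universe by default, or
  stratified draws matching user-supplied covariate bins (e.g. MAF
  deciles) — because no single matching definition is canonical.
* *GWAS catalog*: index + LD-proxy SNPs of one signal overlapping a trait
  set count as a single overlap (collapsing local LD); null signal sets are
  resampled from the universe with each null signal carrying its own proxy
  expansion.
* *Expression similarity*: genes ranked by mean expression across tissues
  (mean of per-tissue means, balancing unequal sample sizes); nulls are
  drawn per query gene from genes within ±100 ranks, inside a ±150-rank
  background pool, applied per gene (the stricter reading; a pooled
  background is the documented alternative). The statistic is the
  within-tissue rank sum, lower tail; the enrichment factor is null mean /
  observed. The low-expression filter (TPM < 0.1 in > 50% of a tissue's
  samples) removes a gene only when it is low in *every* tissue by
  default — removing genes low in *any* tissue would discard precisely the
  tissue-specific genes of interest — with the strict variant behind
  `low_in_all=False`.
* *Co-expression*: mean squared pairwise Spearman ρ within a tissue, upper
  tail, against draws from the pool of signal-proximal genes.
  Zero-variance genes are dropped with a warning. "Nearest" is measured
  from index SNP to gene TSS (the conventional anchor), ties broken by
  gene id.

## Synthetic data generator

The generator emulates the *structure* of the real study inputs on one
linear chromosome (default 1 Mb): regulatory elements with exponential
gaps (mean 1,500 bp) and enhancer-scale lengths (mean 600 bp), each
carrying one functional state and a membership set that is a random
multi-tissue combination with probability `fraction_shared_elements`
(default 0.3) and a single tissue otherwise; per-tissue maps are valid
segmentations over a quiescent background. Credible-set sizes are
geometric (default mean 10; the standard test conditions use mean 20,
capped at 100), PPAs are a sorted Dirichlet(0.5) vector, and SNPs are
placed in planted-tissue elements, in descending-PPA order, until 80% of
the posterior mass is planted; the remainder falls uniformly. Planted
placements avoid coding intervals so that the chromatin signal of the
planted tissue is unconfounded — the fully specific single-SNP
configuration then provably yields τ = 1 in the planted tissue, which the
tests assert. Expression is Poisson with a 6-fold skew toward a primary
tissue for half the genes; enrichment defaults are log2FE 2.8 for strong
enhancers, 2.6 for active TSS, 1.5/0.8 for weak enhancer/transcription,
and 2.59 for CDS. Validation tables (eQTLs, clusters, proxies, trait
catalogs) are derived from the planted assignments plus decoys.

What the fixtures do **not** emulate: linkage disequilibrium (credible-set
SNPs are placed independently rather than in LD blocks), realistic
chromatin-state length distributions and autocorrelation, multi-chromosome
genomes, count overdispersion, and any population-genetic process. Passing
recovery tests therefore demonstrates the correctness and calibration of
the scoring machinery under its own model, not classifier accuracy on real
GWAS data, where fine-mapping error and annotation quality dominate.

Problem sizes in the test suite and acceptance script (200 three-signal
fixtures for conservation/oracle sweeps, 60-signal standard fixtures,
permutation counts of 99–4,000 against enumerable universes) are chosen so
the full suite completes in well under a minute while every oracle remains
exactly enumerable.

## Numerical choices

* Conservation tolerance 1e-9 absolute; weight-scale invariance asserted
  at 1e-12 relative.
* Midpoint median for even sample counts (the standard definition).
* Genes present in CDS annotations but absent from the expression matrix
  get a zero ESS vector and a logged warning; their coding SNPs contribute
  nothing through CDS (conservative).
* 99% credible-set construction keeps the minimal descending-PPA prefix
  reaching 0.99, ties broken lexicographically by SNP id; totals below
  0.99 retain all SNPs with a warning.
* Credible-set positions are 1-based; intervals are 0-based half-open; the
  overlap test is `start ≤ pos − 1 < end`. Chromosome-name styles are
  normalised once and mixing is an error, never a silent non-overlap.
* Duplicated (signal, SNP) rows are rejected at read time.

## Known limitations

* Tissue scores are relative to the evaluated panel: adding or removing a
  tissue changes every profile, and "unclassified" conflates inactive
  regions with activity in unmodelled tissues or cell types.
* The eQTL "matched SNP" nulls default to uniform draws; users with MAF or
  LD-score annotations should supply stratified bins.
* Enrichment weights are point estimates; their uncertainty is not
  propagated into τ.
* The co-expression msr test requires ≥ 2 genes and a proximal-gene pool
  at least as large as the query set.
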