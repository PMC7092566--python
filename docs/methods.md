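# Methods

`caniuc` re-implements, as a reusable and fully tested pipeline, a
bulk-RNA-seq tumor-expression analysis for canine invasive urothelial
carcinoma (iUC): differential expression against normal tissue, consensus
clustering of tumors into two mutation-associated groups (carrying or
lacking the activating BRAF V595E mutation, abstracted here as `mut` /
`wt`), per-tumor z-score significance and Jaccard cluster coherence, a
discriminating-gene classification rule, a sliding-window hypergeometric
scan for chromosomal hotspots of dysregulation, and gene-set
over-representation. A synthetic-data generator plants every structure
the analysis is designed to detect, so each stage can be scored for
recovery against known truth.

## Differential expression

The DE stage is a deliberately compact negative-binomial Wald test that
preserves the two quantities the downstream logic consumes — the log2
fold change and the BH-adjusted q-value — without the surrounding
machinery of a full DE framework (no Cook's-distance outlier handling,
no independent filtering, no fold-change shrinkage).

* **Size factors** are median-of-ratios: for genes with non-zero counts
  in every sample, a sample's factor is the median of
  count / geometric-mean-across-samples. The median is taken on the
  ratio scale itself (for an even number of reference genes this differs
  in the ~3rd decimal from the exp-median-log variant some frameworks
  use).
* **Counts model**: NB with Var = μ + αμ². Per-gene dispersion is a
  pooled within-group method-of-moments estimate (shot-noise corrected
  for size factors), shrunk 50/50 toward a trend α(μ) = a₀ + a₁/μ fitted
  by least squares across genes, floored at 10⁻⁸. The 50/50 shrinkage
  stabilises dispersion at the n = 8 vs 5 scale without replicating
  empirical-Bayes machinery.
* **Effect**: log2fc = log2((μ̂_case + ε)/(μ̂_ctrl + ε)) with pseudocount
  ε = 0.5 normalized counts, bounding fold changes for zero-count
  groups. The pseudocount makes fold changes of very weakly expressed
  genes (mean ≲ 5 normalized counts) shrink slightly toward zero; it
  also means a global library-depth change of one sample perturbs
  low-count fold changes by more than the spec-level < 0.01 seen for
  expressed genes.
* **Inference**: the delta-method standard error of log2fc under the NB
  variance is compared to a t reference with n₁ + n₂ − 2 degrees of
  freedom. The t reference (rather than a normal) compensates for the
  noise of the plug-in variance at small n; under the null at
  n = 8 vs 5 this yields a raw p < 0.05 rate of ≈ 0.035 and an empirical
  FDR at q < 0.01 well below 0.05.
* **Calls**: `up` iff log2fc ≥ 1 and q < 0.01; `down` mirrored; the
  |log2fc| = 1 boundary is inclusive, the q threshold strict. Genes with
  zero counts across all tested samples are removed before testing.

A note on the zero-effect noise floor: with effect 0 the fold-change
estimator is unbiased, but its magnitude cannot fall below the sampling
floor E|log2fc| ≈ √(2α/n)·√(2/π)/ln 2 for well-expressed genes (≈ 0.16
at α = 0.1, n = 10); tests of the "fold changes concentrate at zero"
property therefore assert unbiasedness at study-scale dispersion and the
< 0.1 magnitude bound at a dispersion (0.02) where the floor permits it.

## Transforms

* **VST**: log2(count/size_factor + 1) — monotone, variance-flattening
  (the sd-vs-mean regression slope drops > 5× on NB data), used for
  clustering, embeddings, and z-scores. The regularized-log alternative
  is not implemented; all transformed-scale analyses standardise on this
  one transform.
* **TPM**: (count/length) scaled per sample to sum to 10⁶; an all-zero
  sample yields TPM 0 by convention.

## Consensus clustering

Samples are subsampled (default fraction 0.8, without replacement) 1000
times; each subsample is cut into k groups by average-linkage
agglomerative clustering on Euclidean distances over the 2000 most
variable transformed genes (distances are computed once and subset per
resample — feature rows are fixed, so this is exact, not an
approximation). The consensus matrix records co-clustering frequency
among co-sampled pairs; final assignments cut an average-linkage tree of
(1 − consensus) at k, and a sample's item consensus is its mean
consensus with the other members of its cluster (1.0 for singletons).
Subsample fraction, linkage and feature count are configurable because
the original analysis does not state them; the defaults above are this
package's choices. k is a parameter (default 2); automatic k selection
is out of scope. PCA (SVD on gene-centered data) and classical Torgerson
MDS are provided for visual verification of tumor/normal separation;
both fix signs deterministically (largest-magnitude coordinate positive).

## Per-tumor z-scores and Jaccard coherence

Each tumor is standardized gene-by-gene against the mean and sample
standard deviation (n − 1) of the normal samples on the VST scale;
|z| ≥ 2.5 (boundary inclusive) flags a gene, with the sign splitting
up/down sets. With only ~5 normals, raw per-gene sds are unstable, so
the sd is floored at the 5th percentile of the positive per-gene sds;
without the floor, near-constant genes produce unbounded z-scores. Under
the null the per-gene flag rate is inflated above the Gaussian 1.24%
(small-n sd noise); tests bound it to [0.005, 0.10].

Group coherence: Jaccard similarity |∩|/|∪| (0 when both sets are empty)
over all tumor pairs, partitioned within-mut / within-wt / between. The
test statistic per group is mean(within) − mean(between); the default
p-value comes from permuting group labels over tumors (10,000 draws,
add-one correction), because pairwise Jaccard scores share samples and
are not independent — a Mann–Whitney U option exists but is expected to
be anti-conservative under that dependence. Null calibration over 200
replicates keeps the 5% rejection rate within [0.01, 0.12].

## Discriminating-gene rule

DE is run once per tumor group against the same normals on a shared gene
universe; every gene then falls in exactly one category:

* `shared` — significant in both groups, same direction;
* `opposite` — significant in both, opposite directions;
* `discriminating` — significant in exactly one group while the other
  group's fold change is reverse-signed or inside the open unchanged
  band (−0.5, 0.5);
* `other` — everything else (including a non-significant partner sitting
  exactly at |log2fc| = 0.5 with the same sign).

A gene significant in both groups with opposite signs is `opposite`,
never `discriminating` — the two categories are counted separately.

## Replication clustering and Fisher exact test

A replication cohort is clustered (average linkage, Euclidean) on a
user-supplied gene signature, cut at k = 2, and the genotype × cluster
2×2 table is tested with a two-sided Fisher exact test using the
point-probability rule (sum of hypergeometric probabilities of tables no
more probable than observed, margins fixed). The test is computed in
exact integer arithmetic, so probability ties are handled without
floating-point guards; the worked 8/8-vs-3/4 split gives p = 9/495 ≈
0.0182.

## Positional scan

Each gene's position is the mean over its transcripts of the midpoint
between first and last base (genes spanning multiple chromosomes are an
error; strand is ignored throughout). Chromosomes are tiled with 1 Mb
windows stepping by 250 kb (i.e. 750 kb overlap), anchored at 0, last
windows truncated, so every interior base lies in exactly 4 windows.
With population N = genes having both a position and a DE record and
K = those called in the scanned direction, each window's p is the
hypergeometric upper tail at its (n, k); significance applies Bonferroni
over all windows of that one (direction, group) scan. Window membership
is half-open [start, end). Overlapping-or-adjacent significant windows
merge into regions; the region p is recomputed from gene counts tallied
over the union interval with the same N and K. (The alternative reading
— combining the constituent windows' statistics — is not used; the
recount-over-union interpretation is this package's concrete choice.)
The background population is the positioned ∩ tested universe, not all
annotated genes, keeping K consistent with the DE table.

## Gene-set over-representation

Queries (e.g. all called genes) are tested against GMT collections with
the same hypergeometric upper tail, set members restricted to the
universe, BH control across sets, rows sorted by (q, p, name), top-k
reporting (default 10). The universe defaults to the tested gene
universe — the standard correction for expression-detectability bias —
and is configurable. Identifiers match case-sensitively; an `uppercase`
option supports human-ortholog GMTs.

## Synthetic data

The generator emulates the target study design and doubles as the test
bed:

* **Cohort**: 8 `mut` + 7 `wt` tumors and 5 normals by default (the
  study analysed 15 tumors vs 5 normals).
* **Counts**: NB(mean = baseline × size_factor × 2^(signed log2FC when
  the sample's group carries the effect), dispersion α = 0.1). Baseline
  means are log-normal on log2 (mean 6, sd 2), spanning low-count to
  saturated genes; library size factors are log-normal (sd 0.2 in log2),
  normalized to geometric mean 1. Normals never carry tumor effects.
* **Planted DE**: 6% shared, 5% mut-only, 5% wt-only genes at
  |log2FC| = 2 with random sign, plus a 0.04% opposite-direction
  fraction (sign flipped between groups) to exercise that classification
  branch — at the default 20,000 genes this yields 8 opposite genes, the
  scale the study reported. Mut-only/wt-only genes are the planted
  discriminating genes.
* **Genome**: 10 pseudo-chromosomes of 60 Mb (one per 2000 genes,
  ~33 genes/Mb — a 2.5 Mb interval then holds ~83 genes, matching the
  gene density at the study's strongest locus). Genes are uniform per
  chromosome with 1–3 transcripts each; a gene's mean transcript
  midpoint equals its drawn position exactly. The default hotspot packs
  45 wt-up genes into a 2.5 Mb interval, mirroring the strongest
  reported locus.
* **Gene sets**: one set with 60% planted-DE members plus random
  background sets.

What the generator does **not** emulate: GC/length bias, batch effects,
correlated gene programs beyond the planted group structure, read-level
artefacts, or annotation errors. Recovery results on synthetic data
therefore demonstrate the machinery's correctness and calibration under
the stated model, not performance on real cohorts, where dispersion is
gene-dependent and effects are heterogeneous.

## Determinism and numerics

Every stochastic step takes an explicit seed (`numpy.random.default_rng`);
the pipeline fans a single global seed out to stages by fixed offsets,
and identical config + seed reproduces byte-identical output checksums.
Agglomerative merges use scipy's deterministic linkage; embedding signs
are fixed by convention; enrichment ties break by set name; all tabular
output is written with 17-significant-digit floats so read-back is
exact. Degenerate inputs (all-zero tables, empty queries, groups below
minimum size, zero-variance baselines) raise errors rather than
propagate NaNs.

## Problem sizes used in the test suite

The statistical suites run at study-scale sample sizes (8 + 7 tumors,
5 normals) with gene counts chosen per question: 20,000-gene genomes for
positional recovery and null family-wise error (10 + 20 replicates),
5,000 genes for DE calibration/recovery, 3,000 for consensus recovery
(10 seeds × 1000 resamples) and Jaccard power, 2,000 for the 200-replicate
Jaccard null calibration. Oracle equivalence for the combinatorial
primitives is exhaustive for populations up to 60 and sampled (1000
cases) above.
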