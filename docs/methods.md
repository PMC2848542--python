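# Methods

## Reporter-metabolite scoring

The analysis treats a genome-scale metabolic reconstruction as a bipartite
metabolite–reaction graph and asks, per metabolite, whether the enzymes around
it change expression more coherently than a random set of enzymes of the same
size. Only topology enters: stoichiometric coefficients, reversibility and
compartment semantics are ignored (compartment suffixes can optionally be
collapsed, pattern-configurable, default off).

**Enzyme scores.** Every reaction's gene association is collapsed to a single
p-value by taking the minimum over its genes, regardless of whether the
boolean rule is an isozyme OR or a complex AND; the rule string is retained
for provenance only. The rationale for treating AND like OR is that the most
significant transcript is taken to speak for the enzyme in both cases; the
cost is that one strongly differential subunit can mark a whole complex.
Enzymes are identified by their gene set: identical gene sets attached to one
metabolite through several reactions count once (`dedup=True`), so one
transcript signal is not double-counted; `--no-dedup` restores per-reaction
counting for sensitivity analysis. Enzymes none of whose genes are scored are
excluded from k rather than imputed.

**Aggregation and background.** Enzyme p-values map to Z-scores through the
inverse normal CDF (p clamped to `[1e-15, 1 − 1e-15]`, implemented as
`−ndtri(p)` so the round trip `p → Z → p` is exact to ~1e-16). The metabolite
aggregate is `(Σ Z_i)/√k`. The choice of the 1/√k normalization is
immaterial: the background mean μ_k and SD σ_k are computed under the same
aggregation, so any fixed per-k factor cancels in the corrected score (this
is covered by a unit test). The background population is every scored enzyme
unit of the network after GPR collapse; sets are drawn without replacement
within a draw. When `C(n, k) ≤ 200,000` all subsets are enumerated exactly;
otherwise 10,000 Monte-Carlo draws are used (both defaults configurable).
Each k uses an independent child generator derived from the single configured
seed (`default_rng([seed, k])`), which makes results independent of the order
in which sizes are requested and byte-reproducible across runs. A degenerate
background (σ_k = 0, all enzyme Z identical) yields a corrected score of 0
with a warning rather than an error. Reporter calls use `p ≤ α` inclusive
(α = 0.05 default).

The corrected score is a *competitive* statistic: it measures coherence
relative to the network-wide distribution of enzyme scores under the same
contrast, not an absolute significance. When a large fraction of the network
is differential, μ_k rises and individual neighborhoods are judged against
that elevated baseline — the intended behaviour, but worth remembering when
interpreting small dense networks.

## Differential expression

The default per-probe test is the empirical-Bayes moderated t: per-probe
pooled variances (d = n1+n2−2 df) are shrunk toward a prior estimated by
matching the mean and variance of log sample variances to the theoretical
moments of a log scaled-F variate (digamma/trigamma identities; the trigamma
inverse is solved by Newton iteration to 1e-8). The moderated statistic uses
d + d0 degrees of freedom; d0 → ∞ (observed spread no larger than chi-square
noise) falls back to a common variance with a normal reference. A test
verifies agreement with the Bioconductor reference implementation of the same
construction to ~1e-4 relative on a small dataset, plus the two analytic
limits (d0 → 0 equals the ordinary pooled t; d0 → ∞ equals the common-variance
z). An unequal-variance Welch t is available; probes with zero variance in
both groups get p = 1 with a warning. P-values are two-sided; direction is
carried separately as the sign of logfc = mean(group1) − mean(group2).

Probe-sets collapse to genes by the top-rank-tier rule: restrict to probes of
the minimal tier (all probes default to tier 1 when no ranking is supplied,
in which case the rule degenerates to a plain median), copy a single probe's
values, otherwise take the median p and median logfc. A gene logfc of exactly
0 is assigned direction "down" deterministically, with a warning.
Precomputed gene-level scores can be supplied directly as a TSV, bypassing
this module.

## Motif enrichment

Promoters are the −800..+200 window around the TSS, strand-oriented, with
soft-masked (lowercase) bases turned into N. PFMs are read from TRANSFAC
flat files (column order taken from the P0 header and remapped to A,C,G,T).
Scanning uses log-odds scores `Σ_j log(f_j(b) / P_bg(b | context))` with
column frequencies from counts + 0.25 pseudocount per cell and an order-2
Markov background (add-one pseudocounts, N-containing contexts skipped,
marginal fallback where the context is unavailable); windows containing N
score −∞; both strands are scanned. A sequence counts as having the motif
when its best window reaches 70% of the matrix's maximal achievable score
against the background's stationary base distribution; when that maximum is
non-positive the fraction is taken on the (min, max) score range instead. An
`observed-best` mode thresholds at 70% of the best score seen in the dataset,
the other common reading of per-matrix thresholds.

For each reporter gene set (up and down tested separately, minimum 5 genes
with promoters), the negatives are all other network genes with promoters;
the background model is trained on the negative sequences of that set. The
2×2 per-sequence presence table is tested with a one-tailed Fisher's exact
test implemented as an exact hypergeometric tail sum in rational arithmetic
(tests verify it against full enumeration and an independent implementation
to 1e-12). Multiple testing uses Storey q-values computed within each gene
set across motifs (pooled mode available): π0(λ) on the grid 0.05..0.95 is
extrapolated to λ = 1 with a cubic least-squares fit, falling back to the
single-point estimate at λ = 0.5 below 100 p-values; with π0 fixed at 1 the
q-values reduce exactly to the rank-based FDR formula.

## Cross-contrast comparison and phenotype correlation

Reporter sets of different contrasts are compared by Jaccard distance
(fraction of non-overlapping reporters; two empty sets are distance 0 by
convention) and clustered agglomeratively (average linkage by default,
complete/single available; the distance matrix is computed on id-sorted
contrasts so input order cannot change the dendrogram, serialized as Newick
with merge heights as branch lengths). "Centroid expression" of a metabolite
is the per-sample mean of per-gene z-scored expression over its neighbor
genes (zero-variance genes dropped; a raw-mean mode exists); Pearson r with a
phenotype is reported per clinical group and pooled, with the exact t-based
two-sided p, and marked not-computable below 3 paired observations or at zero
variance.

## Synthetic data generator

The generator produces study-shaped inputs for every stage; its defaults are
the benchmark conditions used by the tests and the acceptance script.

*Network.* 50 metabolites, 140 reactions, a 280-gene pool. Metabolite
"popularity" weights follow a truncated Pareto (density ∝ w^−2.2, capped at
100× the minimum) so a few hub metabolites touch many reactions, as cofactors
do in real reconstructions; each reaction draws 2–4 distinct metabolites by
weight, random substrate/product roles, and a gene association that is a
single gene (70%), a 2–3 gene complex (15%) or a 2–3 gene isozyme group
(15%). Planted reporters are drawn among metabolites with ≥ 5 neighbor
reactions and a *localized* neighborhood of 5–15 distinct genes. Hubs are
deliberately excluded from planting: a coordinated transcriptional program
perturbs a pathway-sized neighborhood, and planting on a 50-node network's
hub would shift most of the network's genes — a regime in which the
competitive background correction is designed to suppress everything, and
which does not correspond to the genome-scale setting where any reporter's
neighbor genes are a small share of all enzymes. For the same reason the
gene pool is sized so the five planted neighborhoods cover only ~15% of
scored enzyme units.

*Expression.* Per-gene baseline ~ Normal(8, 1) on log2 scale, observation
noise SD 0.4, 1–3 probes per gene (60/30/10%), all rank tier 1, 10 samples
per group. The simulated chip carries the whole gene pool, not only genes
the network uses, as with real arrays. Planted metabolites shift
80% of their neighbor genes by ±effect_size × 1 log2 unit with one coherent
sign per metabolite (a gene claimed by two planted metabolites keeps its
first assignment). The default effect of 1.5 log2 units (~2.8-fold) makes a
planted gene strongly differential (p ~ 1e-7..1e-4 at these sample sizes) —
the regime the recovery benchmark is meant to probe; sensitivity at weaker
effects can be explored by lowering `effect_size`.

*Promoters.* An order-2 Markov background is trained on a 30 kb seeded
random genome and sampled per promoter (1000 bp). Planted genes receive one
instance of the motif consensus at a uniform offset on a random strand with
probability 0.9; planting the consensus (not a column-sampled realisation)
makes the generator's guarantee exact — a planted promoter always contains a
scanner hit at the 70% threshold, so the plant rate equals the hit rate.
About 5% of bases are masked to N in 8 bp runs that never overlap a planted
instance. Ten decoys are column permutations of the true matrix (identical
information content); permutations whose consensus stays within Hamming
distance 3 of the original or its reverse complement are rejected, since such
a shuffle would still recognise the planted sites and be no negative control.
The generated motif itself caps any base at half the columns so that
non-trivial permutations exist. A genome + TSS table is emitted alongside
the promoter FASTA and reproduces the promoters exactly through the
extraction code path.

*Phenotype.* value = slope × centroid + Normal(0, noise_sd) per sample,
against the first planted metabolite's centroid by default.

What passing these benchmarks does *not* show: the generator has Gaussian
noise, tier-free probe maps, independent promoters and an exactly planted
truth — real arrays have correlated probes, annotation error, repeat-driven
promoter structure and no ground truth. Recovery here demonstrates
correctness of the machinery, not field performance.

## Problem sizes and numerical choices

The default test and benchmark sizes — 50-metabolite recovery networks
(200 for null calibration, ~2000 probes), 10,000 background draws, 220
promoters of 1 kb, 20-run motif replicates — were chosen so the full suite
documents the method's behaviour at desk scale while each individual check
stays under a minute. Background Monte-Carlo at 10,000 draws gives μ_k to
~1% and σ_k to ~1.5% relative on a 12-enzyme pool (measured against exact
enumeration). Ties in sorting are broken by metabolite id; all stochastic
steps take explicit seeds and child generators are derived per purpose, so
every pipeline output is byte-reproducible for a fixed configuration.

## Known limitations

- The min-p GPR collapse ignores AND/OR structure; complexes are as easy to
  trigger as isozymes.
- The background pool includes differential enzymes by construction
  (competitive test); no "self-exclusion" variant is implemented.
- Reporter p-values are not corrected across metabolites, by design; users
  comparing many contrasts should treat the α = 0.05 calls accordingly.
- The scanner's per-sequence hit definition discards multiplicity ("n_hits"
  is reported but unused by the Fisher table).
- Storey's estimator below 100 p-values falls back to a single-λ estimate,
  which is noisy for the ~11-motif sets typical here.
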