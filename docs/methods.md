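# Methods

This note documents the statistical model behind pol3dyn, the synthetic
data it is validated on, and the numerical and design choices a maintainer
would want to know about. Every number quoted here is computed by the test
suite or by `scripts/acceptance.py`; nothing is asserted that the code does
not measure.

## Fragment processing

Paired-end tag pairs resolve to genomic fragments. Unique fragments carry
weight 1; a multi-mapped pair's candidates split one unit of weight
proportionally to the empirical size probability of each candidate's
implied insert length, `w_i = P(len_i)/Σ_j P(len_j)`. The size histogram is
estimated at 1-bp resolution from the unique fragments of the same sample,
floored at 1e-6 and renormalized, so a candidate with an unseen length is
never assigned exactly zero. Pairs with more than 500 candidate positions
are discarded, mirroring the cap applied at alignment time. Redundancy
(identical `(chrom, start, end)`; strand is not recorded) is collapsed to a
single fragment before any counting; the processing order is: deduplicate
unique pairs, estimate the size distribution from them, weight multi-mapped
pairs, then drop any candidate duplicating a unique fragment's coordinates.
Total fragment mass after processing equals unique pairs plus retained
multi-pairs, one unit each.

## Occupancy scores and the empirical null

Counts are fractional: a fragment contributes `weight × overlap/length` to
a window, so a fully contained fragment is worth its whole weight and the
expected count in a window of width `w` under uniform background is exactly
`depth × w / genome`, independent of fragment length. Counting is exact via
per-base prefix sums of the `weight/length` density (`CoverageIndex`);
direct interval evaluation and a per-base brute-force oracle agree to
1e-9 in the tests.

Scores are `log2((n_c f_c + 16)/(n_i f_i + 16))` with normalization factors
`f_s = median(totals)/total_s` applied before the pseudocount. The
pseudocount is added to both channels so equal normalized counts give score
0. Note one consequence: because the pseudocount is fixed while normalized
counts scale with sequencing depth, scores are only asymptotically
invariant under a joint rescaling of all depths; the normalization factors
themselves are exactly invariant.

The peak threshold for a ChIP/Input pair is the linear-interpolation
empirical quantile, at level `1 − α/n_loci` (α = 0.05), of the same score
computed in non-overlapping genome bins (400 bp for Pol III, 2 kb for
H3K4me3/RPB2, matching the narrower footprint of Pol III loci). Bins with
no fragments are retained at score 0. Two departures from a naive
whole-genome null are deliberate:

- **Annotated-locus masking.** On a compact simulated genome, bins
  overlapping annotated loci are a non-negligible fraction of all bins
  relative to the Bonferroni tail level `α/n_loci`, so an unmasked
  empirical quantile would land inside the true-signal distribution and
  the threshold would track the strongest loci rather than the background.
  The pipeline therefore excludes locus-overlapping bins from the null by
  default (`mask_null_bins`). On a full-size genome (millions of bins,
  hundreds of loci) the mask changes nothing measurable.
- **Feasibility check.** The quantile needs at least `n_loci/α` bins to be
  resolvable; fewer raise an error suggesting a larger genome or α.

On all-silent data the fraction of loci above threshold is 0 with the
default configuration (expected: `α/n_loci` per locus), well within the
binomial envelope the acceptance suite checks.

## Classification

Isolation (≥1.5 kb edge-to-edge to any other locus, boundary inclusive),
Pol II proximity (≤2.65 kb from locus body to a TSS or poly-A point,
boundary inclusive) and CpG association (island overlapping TSS ±1 kb) are
pure functions of coordinates. Distances are measured from the unextended
locus body; the choice of edge rather than TSS for Pol II distance is a
convention, fixed here once. The eight peak-presence groups are per
replicate combination; which H3K4me3 replicate accompanies which RPC4/RPB2
replicate is a configuration mapping, defaulting to H3K4me3 replicate 2
alongside replicate 1 of the polymerases (replicate pairing of the original
experiment design). Group comparisons use a permutation test with the
Welch (unequal-variance) t as statistic and the add-one estimator
`p = (1 + #{|t*| ≥ |t|})/(n_perm + 1)`; an exhaustive enumeration mode
serves as the oracle for small samples. Zero-variance degenerate input
returns p = 1 with a warning.

## Differential occupancy

The per-locus model is a saturated one-way layout over the four time
points (cell-means coding, OLS); with two replicates per level the
coefficients are level means and `s²_g` is the pooled within-level variance
on `d_g = n − 4` df. The empirical-Bayes prior follows the limma
hierarchical model: marginally `s²_g / s₀² ~ F(d_g, d₀)`, and `(s₀², d₀)`
are recovered by method of moments on `z = log s²` via the identities
`E[z] = log s₀² + ψ(d_g/2) − ψ(d₀/2) + log(d₀/d_g)` and
`Var[z] = ψ′(d_g/2) + ψ′(d₀/2)`, with a Newton trigamma inverse. The
implementation reproduces `limma::fitFDist`/`eBayes` (including the
degenerate branch `d₀ = ∞, s₀² = mean(s²)` when the observed spread of
`log s²` does not exceed the sampling floor, the `1e-5 × median` variance
floor, and the cap of the total df at the pooled residual df); the test
suite verifies agreement with Bioconductor limma to ~1e-8 on both branches.
Parameter recovery on hierarchical draws (d₀ = 4, s₀² = 1, m = 10⁴) is
within 20% and 10% respectively.

By default the prior is fitted on the *eligible* family (loci above cutoff
at either contrasted time point) rather than on all loci: below-cutoff loci
have pseudocount-compressed scores whose replicate variance is
systematically smaller, and letting them into the prior deflates the
shrunken standard errors of exactly the loci under test. `prior_from='all'`
restores pooling over everything. All loci still enter the per-locus model
fit, and ineligible loci are reported with q = NaN, mirroring the grey
"below cutoff at both time points" stratum of the original analysis;
significant loci are additionally stratified by whether they were above
cutoff at baseline.

q-values follow Storey: `π̂0(λ) = #{p>λ}/(m(1−λ))` on λ = 0, 0.05, …, 0.95,
smoothed by a natural cubic smoothing spline whose penalty is tuned by
bisection to 3 effective df (trace of the smoother matrix), evaluated at
λ = 0.95 and clamped into (0, 1]; then `q_i = π0 · min_{p_j ≥ p_i}
(m p_j / rank_j)`, monotone by construction. Two stabilizations protect the
estimator when the p-value family is small (tens of loci, where the tail
counts behind `π̂0` at large λ are single digits): grid points are weighted
by their binomial precision (∝ 1−λ), and the result is floored at half the
low-variance `π̂0(0.5)` point estimate. Both are numerically inert at
m = 10⁴, where the estimator recovers π0 ∈ {0.7, 0.9, 1.0} within ±0.05
(measured as the mean over independent mixtures, i.e. estimator accuracy
rather than single-draw noise). Null simulations (10⁴ loci, 4×2 design)
give uniform p-values (KS p ≈ 0.36) and a realized FDR of ~4.6% at
q < 0.05 on a 30%-effect mixture.

## Spatial statistics and profiles

Cluster chaining measures gaps edge-to-edge, strictly < 5 kb, by a single
linear scan per chromosome; maximal chains of ≥3 tRNA genes become
clusters. The scan handles nested/overlapping annotations by carrying the
running maximum end. KS tests (two-sided, asymptotic) compare in-cluster vs
same-chromosome out-of-cluster fold changes, where fold change is the
replicate-averaged score difference of the contrast (log2 units). The
chi-square independence test uses no continuity correction; Pearson
residuals `(O−E)/√E` are returned for mosaic-style reporting. 'Changing'
is q < 0.05, 'stable' is eligible with q ≥ 0.05, and below-cutoff loci are
excluded from the table. Overlap enrichment reports `a·b/N`, the fold, and
the exact hypergeometric upper tail; the universe is an explicit parameter
since the appropriate census (all annotated vs all active genes) depends on
the question.

Profiles are raw ChIP per-base weighted coverage (no input subtraction),
strand-oriented around the locus TSS, averaged across loci, normalized to
fragments per million, and binned by averaging; window ±2 kb and 10-bp bins
are presentation choices.

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes, not
sequence-level reality. A genome of 5 × 1.9 Mb chromosomes carries 200
loci (110 tRNA, 55 SINE, 15 Rn5s, 6 Rn4.5s, 14 other) in three classes:
`stable_high` (40%; log2 enrichment 4 at all time points), `dynamic_low`
(30%; enrichment 1 at TP0, +2 log2 at TP36 and after — the induction is
identical at TP36/48/60, so contrasts among the later time points are null
by construction), and `silent` (30%). Per-locus static offsets (sd 0.6 for
stable, 0.3 for dynamic) produce the broad occupancy spectrum real data
show; they cancel in all contrasts. 80% of stable loci get a Pol II TSS
200–800 bp upstream (divergent orientation) carrying H3K4me3 and RPB2
signal (log2 enrichment 3 with the same per-locus spread); stable loci away
from Pol II get an H3K4me3 flank peak only, and 70% of Pol II TSSs carry a
CpG island. Six tRNA clusters (3 genes, gaps 0.5–4 kb) are planted;
remaining loci are placed uniformly with a 200-bp minimum gap, and 30
background Pol II genes are kept ≥3.15 kb from any locus.

Fragments: Input is Poisson-uniform at 950 000 expected fragments per
sample; ChIP adds locus-centered signal fragments so the expected
window-count ratio is `2^enrichment`, with multiplicative lognormal
replicate noise of CV 0.1 on each locus's signal rate (chosen to yield the
>0.9 replicate score correlations the real data show; measured 0.91–0.98).
Fragment sizes are truncated normal (mean 200 bp, sd 40 bp); 5% of pairs
are emitted as 3-candidate multi-mapped records whose decoys sit at uniform
positions with a 3× broader size distribution, so size-probability
weighting is informative (the true origin receives ~2× the uniform 1/k
weight on average). All randomness flows from one seed through per-sample
substreams keyed by CRC32 of the sample id; a fixed seed reproduces every
output byte-identically.

Scale was set as the smallest configuration that keeps every component of
the method in its working regime: per-window background counts of ~40
(so the pseudocount attenuates but does not dominate), enough 2-kb genome
bins to resolve the Bonferroni quantile after locus masking, and a
200-locus census large enough for stable empirical-Bayes and π0
estimation — the original analysis had 646 loci, and the q-value machinery
degrades visibly below ~100 tested loci.

What passing tests do **not** show about real data: the generator has no
mappability or GC structure, no fragment-size dependence of signal, no
correlated biological replicate effects, no mean-variance trend, and its
classes are cleanly separated rather than a continuum; recovery rates here
are therefore upper bounds on what identical settings achieve on tissue
ChIP-seq.

## Known limitations

- The empirical null contains true signal on small genomes unless masked;
  the mask requires a locus annotation and is only as good as it is.
- With a fixed pseudocount, scores depend (weakly) on absolute depth;
  comparisons across experiments with very different depths should
  renormalize to a common target first.
- The moderated t assumes exchangeable variances; strong mean-variance
  trends (not simulated here) would call for an intensity-dependent prior.
- π0 estimation below ~100 tested hypotheses is noisy even with the
  stabilizations; for very small families a fixed π0 = 1 (Benjamini–
  Hochberg) is the safer choice.
- The permutation t-test enumerates nothing beyond `n_perm` draws; its
  resolution is bounded below by `1/(n_perm+1)`.
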