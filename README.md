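# pol3dyn

Analysis pipeline for RNA polymerase III occupancy dynamics measured by
paired-end ChIP-seq, modeled on the regenerating mouse liver: hepatocytes
leave G0 synchronously after partial hepatectomy, and Pol III occupancy
(via its RPC4 subunit), Pol II occupancy (RPB2) and H3K4me3 are profiled at
0, 36, 48 and 60 hours with two replicates per time point. The package is
aimed at genomicists who want the full statistical route from weighted
fragment alignments to differential-occupancy calls as reusable, tested
code, exercised end to end on a synthetic-data generator with known ground
truth.

## What it computes

**Occupancy scores.** Each Pol III locus gets, per ChIP/Input sample pair,

```
score = log2( (n_ChIP * f_ChIP + c) / (n_Input * f_Input + c) ),   c = 16
```

where `n` are fractional weighted fragment counts in an extended locus
window (body ±150 bp for RPC4; TSS ±1 kb for H3K4me3/RPB2), `f` are
median-depth normalization factors, and multi-mapped tag pairs carry
weights `P(len_i) / Σ_j P(len_j)` from the empirical size distribution of
uniquely mapped fragments (pairs with >500 candidates are discarded,
duplicate coordinates collapsed). A locus *has a peak* when its score
exceeds the empirical quantile at level `1 − α/n_loci` (Bonferroni,
α = 0.05) of the same score computed in non-overlapping genome bins
(400 bp for RPC4, 2 kb for H3K4me3/RPB2).

**Classification.** Loci are annotated as isolated (≥1.5 kb from any other
locus), near a Pol II gene (≤2.65 kb from a TSS or poly-A site), and
CpG-associated (island within 1 kb of the TSS), then assigned to one of
eight peak-presence groups per replicate combination. Group score
distributions are compared with a permutation Welch t-test (10 000
permutations).

**Differential occupancy.** Per locus, a one-way linear model over the four
time points is fit by least squares; residual variances `s²_g` (d_g df) are
shrunk toward an empirical-Bayes prior `(s²_0, d_0)` fitted by method of
moments on `log s²` (the limma hierarchical model; verified against
Bioconductor limma to ~1e-8). Contrasts such as TP36−TP0 are tested with
the moderated t

```
t = c'μ̂ / (s̃_g √(c'(X'X)⁻¹c)),    s̃²_g = (d₀s₀² + d_g s²_g)/(d₀ + d_g)
```

on `d₀ + d_g` df; q-values use Storey's π0 estimated by a cubic smoothing
spline (3 effective df) over the λ grid 0–0.95. Loci below cutoff at both
contrasted time points are excluded from the tested family; significance is
q < 0.05, with calls stratified by whether the locus was already above
cutoff at baseline.

**Spatial statistics.** tRNA clusters are maximal runs of ≥3 tRNA genes
spaced <5 kb; per-chromosome two-sample KS tests compare fold changes in vs
out of clusters; a chi-square independence test relates changing/stable
status to chromosome; overlap of changing-gene sets is tested with an
upper-tail hypergeometric. Metagene tag-density profiles (±2 kb, 10-bp
bins, per-million normalized) summarize factor geometry around Pol III
TSSs.

## Worked example

```python
import dataclasses
from pol3dyn import PipelineConfig, SimConfig, run_pipeline

cfg = PipelineConfig(sim=dataclasses.replace(SimConfig(), seed=1),
                     out_dir="report")
res = run_pipeline(cfg)
```

With the default study conditions (200 loci on a 5×1.9 Mb genome, 950 000
fragments per sample, induced loci gaining 2 log2 units at TP36) this
prints, via the summary fields:

```
loci scored: 200
RPC4 TP0 rep1 cutoff: 0.68
isolated loci: 188
significant TP36-TP0: 65 of 140 eligible loci
true classes of the calls: {'dynamic_low': 60, 'stable_high': 5}
called loci below cutoff at TP0: 18
tRNA clusters: 6 | chi2 chromosome p: 0.673
min replicate r: 0.912
```

All 60 induced (`dynamic_low`) loci are recovered with positive direction;
5 of 80 stable loci are false calls (within the q < 0.05 budget given 65
discoveries); 18 of the significant loci were below the occupancy cutoff at
TP0, the signature of genes switched on from silence. The `report/`
directory holds the score table, the eight-group classification summary,
the differential table, cluster/KS/chi-square results, profiles, replicate
concordance and a run manifest; identical config and seed reproduce the
files byte for byte.

The same pipeline runs from the shell:

```
pol3dyn simulate -o simdata --seed 1     # write annotation + fragment BEDs
pol3dyn run-all -o report --seed 1       # full analysis and report bundle
pol3dyn run-all -c my.yaml -d simdata -o report   # from files on disk
```

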