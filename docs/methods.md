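# Methods

## Statistical model

`zdosage` treats dosage compensation as a property of two observable ratio
distributions computed from a gene × sample expression matrix and a
gene → chromosome assignment.

**Within-sample Z:A.** For one sample, let `A` and `Z` be the FPKM values
of autosomal and Z-linked genes with nonzero expression in that sample (the
"true expression" universe). The mean-based ratio is
`mean(Z)/mean(A)` and the median-based ratio `median(Z)/median(A)`.
Means and medians are taken on the linear FPKM scale; the published
per-sample tables report linear medians, and for even-length vectors a
log-scale median (geometric mean of the central pair) would differ. Log2
values are used only as rank-sum test inputs and plot coordinates — for a
rank test the monotone transform is immaterial, but the convention is kept
explicit. The A-vs-Z comparison is a two-sided Mann–Whitney test of the two
log2-FPKM distributions.

**Between-sex M:F.** For one stage with a male and a female (replicate-
averaged) sample, the per-gene ratio `M(g)/F(g)` is computed over genes
with FPKM > 0 in *both* sexes. The class medians `median(M:F | Z)` and
`median(M:F | A)` summarise sex bias, and their quotient — the Z:A ratio of
medians — is ≈ 1 when the Z chromosome is no more sex-biased than the
autosomal background. Three two-sided rank-sum tests accompany each stage:
male vs female log2 FPKM within the Z class, the same within the A class
(both *unpaired* distribution-level comparisons, not paired gene-wise
tests), and Z vs A log2(M:F) ratio distributions.

p-values are reported raw. The analysis applies no multiple-testing
correction (a Benjamini–Hochberg pass can be bolted on by the caller; the
pipeline reports so few tests that control at the table level is a reader's
judgement call).

## Rank-sum test

`mwu_test` defines `U = #{(i,j): x_i > y_j} + ½·#ties` (computed via
mid-ranks). When `min(|x|,|y|) ≤ 8` and the pooled data are tie-free, the
exact null distribution of U is built by a subset-sum dynamic program over
the pooled ranks and the two-sided p-value is `min(1, 2·min(P(U≤u),
P(U≥u)))` — the doubling convention of the R default. Otherwise a normal
approximation is used with tie-corrected variance
`n1·n2/12·((n+1) − Σ(t³−t)/(n(n−1)))` and a 0.5 continuity correction
toward the mean; when every observation is identical the variance is zero
and p is defined as 1. Tests verify the exact path against full enumeration
of all rank assignments for every size pair up to 6×6, and the asymptotic
path against an independent library implementation.

## FPKM and library sizes

`FPKM(g,s) = 10⁹ · count(g,s) / (length(g) · N(s))` with `length` the
per-gene transcript length in bp and `N(s)` the library size. `N` may be
the column sum (default) or fixed, externally known depths. The distinction
matters for one subtle reason: any genome-wide multiplicative expression
difference between samples — such as a global male bias — cancels exactly
under column-sum normalization (and under TMM), and is only observable
against fixed depths. Parameter-recovery runs on synthetic data therefore
use the simulator's nominal depth; analyses of real data, where true depths
are unknowable, use column sums, accepting that only *relative* (gene-level
and class-level) contrasts are identified. Technical replicates are
averaged arithmetically per gene after FPKM, and singleton groups pass
through unchanged.

## TMM normalization

Between-library scaling factors follow the weighted trimmed mean of
M-values. For library k against reference r, over genes positive in both:

    M_g = log2((x_gk/N_k) / (x_gr/N_r))
    A_g = ½·log2((x_gk/N_k) · (x_gr/N_r))
    w_g = 1 / ((N_k−x_gk)/(N_k·x_gk) + (N_r−x_gr)/(N_r·x_gr))

Genes are doubly trimmed by mid-rank: the most extreme 30% at each end by
M and 5% at each end by A (rank window `[⌊n·t⌋+1, n−⌊n·t⌋]`, intersection
of the two windows), and `factor_k = 2^(Σw·M / Σw)` over the survivors,
finally rescaled so all factors have geometric mean 1 (hence product 1).
The automatic reference is the sample whose 75th-percentile count fraction
is closest to the mean of those fractions. Trim fractions are the
method's canonical defaults; the source analysis names the method without
parameters.

Degenerate cases: if a library shares no positive gene with the reference
the computation is a hard error; if no gene survives the double trim the
factor falls back to 1.0 with a warning. The latter can genuinely occur
with massive M ties — e.g. a library that is an exact genewise copy of
another collapses all non-DE M values into a handful of tie blocks whose
shared mid-rank may fall outside the trim window. Real libraries carry
sampling noise and do not hit this; the simulated validation pair is drawn
with Poisson noise accordingly. Note the factors are *not* exactly
invariant to rescaling a whole library: M values and the trimmed set are,
but the precision weights depend on absolute library size, moving the
weighted mean by ~1–2% (the reference implementation of the method behaves
identically); the invariance is tested at 5% tolerance.

The TMM-normalized expression used for M:F analysis is counts per million
of TMM-adjusted effective library size. Before TMM, genes with fewer than
`min_count = 4` raw reads in *any* of the four libraries of a stage's
male/female replicate quartet are removed (a gene with exactly 4 in all
four is kept).

## Bootstrap confidence intervals

`bootstrap_za_median` resamples the A vector (size |A|, with replacement)
and the Z vector (size |Z|) independently — the only resampling unit
consistent with a ratio of two group medians — and recomputes
`median(Z*)/median(A*)` for each of `n_boot = 10 000` replicates. The CI is
the empirical 2.5/97.5 percentile interval (linear interpolation) and the
reported point estimate is the *median of the bootstrap distribution*, a
deliberate choice: the published bootstrap tables report a
distribution summary that differs in the sixth decimal from the plug-in
ratio, and the bootstrap-median convention reproduces that behaviour class.
Resampling is done on the linear scale; for odd resample sizes any monotone
transform gives identical resample medians, so the choice only matters
through even-size central-pair averaging. BCa intervals are deliberately
out of scope (percentile matches the basic web-tool behaviour of the
original analysis). Everything is reproducible from an integer seed;
replicates are generated in fixed-size chunks so results do not depend on
memory layout.

Validation: with both classes lognormal (n = 200 each) and true median
ratio 0.5, the 95% interval covered the truth in ≈ 95–97% of 500
simulations (the band asserted is [92%, 98%]). Coverage here depends only
on ranks, not on the lognormal's scale or shape parameters.

## Quartile stratification

Two binning modes, both: stable descending sort (ties broken by gene id
ascending, for reproducibility), split into four contiguous bins as equal
as possible with earlier — higher-expression — bins taking the remainder;
Q4 is the top quartile, Q1 the bottom.

* *independent*: each sex's Z-linked true-expression values are ranked on
  their own, so a quartile's male and female gene sets may differ (used
  with the within-sample Z:A universe);
* *paired max*: per-gene (male, female) pairs are ranked by
  `max(male, female)` and never separated (used with the both-sexes M:F
  universe).

Within each quartile, male vs female log2 values are compared by two-sided
rank-sum test. Membership is invariant to any order-preserving transform
of the values; binning on FPKM or log2 FPKM is the same partition.

## Profile export and clustering

The heatmap export keeps *every* Z-linked gene, including silent ones
(zero FPKM is floored at 2⁻¹⁰, i.e. −10 on the log2 scale — a display
floor that never feeds the statistics). Optional row clustering is
deterministic, seedless hierarchical agglomeration (correlation distance,
average linkage) cut into k clusters; zero-variance rows get distance 0 to
other flat rows and 1 otherwise, and labels are canonicalised by each
cluster's lexicographically smallest gene id so permuting the input rows
permutes labels identically (exact distance ties in the dendrogram remain
order-dependent, as in any agglomerative scheme). The cluster count k is a
user parameter; no attempt is made to reproduce any particular published
clustering whose algorithm is unspecified.

## Gene → chromosome assignment

Annotations place genes on scaffolds; a two-column scaffold → chromosome
table lifts them to chromosomes (1–28, with 1 ≡ Z for *B. mori*; the Z
chromosome number is a config key for other ZW species). `gene` features
are the per-locus unit — annotations here merge transcript isoforms per
locus, and keying on `mRNA` would double-count multi-isoform loci. Genes on
scaffolds absent from the table become `unplaced` and are dropped from all
statistics rather than erroring (partially anchored assemblies are the
norm). No W chromosome exists in the annotation; a W-linked gene would
surface as `unplaced` and be dropped. GFF coordinates are validated as
1-based inclusive but otherwise unused.

## Synthetic data generator

The simulator emulates the *statistical shape* of a silkworm-like
transcriptome, not any real gene:

| parameter | default | meaning |
|---|---|---|
| genes | 450 Z + 9600 autosomal (chr 2–28) | study-scale gene counts |
| baseline | log2-mean 3, log2-SD 2 per gene | lognormal FPKM-like levels |
| dispersion | 10 (NB size) | overdispersed counts |
| library_size | 10⁷ | expected fragments per library |
| silent_fraction | 0.05 | P(gene off in one sex) |
| replicates | 2 | independent technical draws |
| gene length | LogNormal(ln 1500, 0.5) bp | for FPKM length correction |
| unmapped_fraction | 0.02 | scaffolds withheld from the map |

Counts are `NB(mean, size)` with
`mean = library_size · share(g) · dose(g, sex, stage)`, where `share` is
the gene's baseline fragment weight (baseline × length, normalized) and the
dose factor combines three per-stage multipliers: `z_dose_male` /
`z_dose_female` on Z genes (equal values < 1 = compensated-but-reduced Z;
a male excess = uncompensated) and a genome-wide `male_global_bias`. The
implied truth is `Z M:F = z_dose_male·bias/z_dose_female`,
`A M:F = bias`, and within-sample Z:A factors `z_dose_male` /
`z_dose_female` (the global bias cancels within a sample).

Three presets encode the study conditions: `uncompensated_early`
(Z M:F 1.5 on a 1.35 global male bias, Z dose 0.50/0.45 — early-embryo
like), `compensated_head` (Z M:F 1.0, Z:A 0.6 both sexes), and
`bombyx_like_timecourse` (78 h → 96 h → 120 h → head with Z M:F truth
1.6 → 1.5 → 1.05 → 1.0). A null configuration (all factors 1, no
silencing) supports test-level calibration.

What the simulator does *not* model: gene–gene correlation, length biases
beyond the FPKM formula, batch effects, mapping artifacts, biological
replicate variance (replicates are technical only) or any real locus.
Passing parameter-recovery tests therefore demonstrates that the
estimators are consistent for the model's dosage structure at realistic
scale and noise — not that real-data values would be reproduced.

## Validation problem sizes

Parameter recovery and the null calibration run at 450 Z + 5000 autosomal
genes; the null type-I rate uses 200 seeded replicates of the A-vs-Z
distribution test (asserted within [2%, 10%] at the 5% level); bootstrap
coverage uses 500 simulations of n = 200 per class with 1000 replicates
each. Recovery tolerances are ±0.1 for Z M:F = 1.5 and Z:A = 0.6, and
±0.05 for the null Z M:F = 1.0 — roughly 2–3 gene-sampling standard
errors of the class medians at these sizes.

## Known limitations

* Mean-based Z:A is dominated by the heavy upper tail of expression and is
  far noisier than the median-based ratio at a few hundred Z genes; the
  median is the headline estimate.
* The exact rank-sum path requires tie-free data; FPKM ties are rare but
  integer-count comparisons at small n fall back to the tie-corrected
  normal approximation.
* TMM factors assume most genes are not differentially expressed between
  libraries; gross violations (> 30–40% DE in one direction) defeat the
  trim.
* The within-class male-vs-female tests are unpaired distribution
  comparisons; they ignore gene pairing and are conservative for
  gene-level shifts with heterogeneous baselines.
* Global expression differences between samples are unidentifiable under
  depth normalization (column-sum FPKM or TMM); they are recoverable only
  against known library depths, as in simulation.
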