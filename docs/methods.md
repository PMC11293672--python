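# Methods

This note documents the statistical procedures, the simulators, the defaults
and the numerical conventions implemented in `hrscan`, and what the test
suite does and does not establish.

## Study design and data model

The design throughout is 8 closed replicate lines — 4 selected ("HR") and 4
non-selected control ("C") — each maintained as 10 breeding pairs.  The unit
of analysis is the per-line allele frequency at a biallelic SNP; tables are
loci × lines matrices with 1-based, inclusive genomic coordinates, sorted by
(chromosome, position).  Missing frequencies are NaN in memory and `.` in
the canonical tab-separated interchange format; all statistics skip missing
values locus-wise.  The minor allele frequency of a line group at a locus is
`min(af, 1 − af)` of the group mean: no polarization of alleles against an
ancestral state is attempted.

## Differentiation tests

All tests operate on the angular transform x = arcsin(√af), the classical
variance-stabilising transform for proportions, mapping [0, 1] to [0, π/2].

**Welch.** The ordinary unequal-variance T statistic on 4-vs-4 line values
with Welch–Satterthwaite degrees of freedom.  A locus where both groups have
zero variance and equal means has no defined statistic: it is flagged
*failed* (NaN) and excluded from every downstream count, numerator and
denominator alike.  Zero variance with unequal means yields t = ±∞, p = 0
(the locus is maximally differentiated, e.g. fixed for opposite alleles).

**Regularized (RegT).** With only 4 lines per group, per-locus variance
estimates are extremely noisy and small-variance loci generate spurious
extreme statistics.  Each group's variance is therefore shrunk toward a
background v̄ with ν₀ pseudo-observations,

    s*²_g = (ν₀·v̄ + (n_g − 1)·s²_g) / (ν₀ + n_g − 1),

where v̄ is the genome-wide mean of the pooled per-locus variances, and the
group degrees of freedom entering Satterthwaite become n_g + ν₀ − 1.  As
ν₀ → 0 the test reduces exactly to Welch — this reduction, together with the
window → genome reduction below, anchors the implementation's correctness
(the shrinkage constants themselves are configuration, not hard-coded).

**Windowed-regularized (WRT).** Identical, except v̄ at each locus is the
mean pooled variance over a centered sliding window of `window_size` loci
(default 1001, odd) on the same chromosome, truncated at chromosome ends; a
chromosome shorter than the window falls back to its chromosome-wide mean
with a warning.  On variance-homogeneous data WRT ≡ RegT ≡ Welch's fixed
point; their p-values are nearly perfectly correlated on drifted null data.

Defaults ν₀ = 4 and window 1001 are configuration knobs
(`RegularizationContext`); both reductions are property-tested.

## Exhaustive permutation FDR

With 8 lines split 4-vs-4 there are exactly C(8,4)/2 = 35 distinct unordered
partitions of the line labels, one of which is the observed HR/C split, so
the permutation null is enumerated exhaustively rather than sampled.  For
each partition the full test is recomputed — including the background
variance, which depends on the grouping.

The false discovery rate at an observed p-value p₀ is estimated directly:

    FDR(p₀) = [#{permuted p ≤ p₀} / n_perm] / #{observed p ≤ p₀},

evaluated for every candidate locus (observed p < 0.05), and the
significance threshold is the largest candidate p with FDR at or below the
target (default 0.01), with ties included.  Two conventions matter:

* **Null ensemble.**  The numerator averages over the 34 *non-observed*
  relabelings.  Counting the observed partition among the "permuted"
  discoveries would bound the FDR below by 1/35 ≈ 0.029 for any data,
  making a 1% target unattainable; the divergence null (below), which is a
  distributional pool rather than a discovery ratio, legitimately pools all
  35.
* **Candidate set.**  p < 0.05 is the candidate superset; restricting
  candidates further cannot admit additional thresholds at FDR ≤ 0.01, so
  the choice is conservative-neutral.

## Regions, strict culling, divergence over time

Significant loci are clustered per chromosome by single linkage with a gap
rule: consecutive loci more than `gap_bp` (default 1 Mbp) apart start a new
region.  Clustering is idempotent and order-independent; regions never span
chromosomes.  *Strict culling* then discards single-locus regions and keeps
a region iff it contains ≥ 20 significant loci or its minimum p is below
10⁻⁴ (regularized tests) / 10⁻⁶ (plain Welch, whose p-values run naturally
lower).  The rationale is robustness to sampling error: a cluster of many
linked significant SNPs is unlikely to arise from simultaneous
under-estimation of among-line variance.

The divergence-over-time statistic asks whether a locus's HR trajectory
between two sampled generations differs from its C trajectory.  Per locus, a
paired T across the 4 lines of each linetype is computed on the per-line AF
change (later − earlier), and D = |T_HR − T_C|.  Conventions:

* Changes are computed on **raw** per-line mean allele frequencies (a
  `transform` flag enables the angular scale); the paired difference of line
  means does not require variance stabilisation, and |·| makes the
  subtraction order immaterial.
* A locus where either paired T fails (zero variance of changes) is
  excluded.
* The null pools D over all loci × all 35 partitions into one genome-wide
  distribution; the threshold is the value exceeded by 5% of the null mass
  (the upper tail).  The *exceedance* — the share of observed D above the
  threshold — is the headline number: ~5% under exchangeable drift, more
  when real between-generation churn exists.  Excess over 5% estimates the
  nominally significant fraction.

Divergence regions cluster the top-N most divergent loci (default 1400) with
the same gap rule and keep clusters of ≥ 20 of those loci.

## Sampling-error models

Two measurement models mirror pooled sequencing and individual genotyping:

* **Pooled** (default 20 mice): 40 allele copies ~ Bernoulli(p); a read
  depth d drawn from the depth distribution; d reads resampled with
  replacement from the pool; estimate = alt reads / d.
* **Individual** (default 10 mice): genotypes ~ Binomial(2, p); each
  heterozygote collapses, with its per-call error probability, to a
  homozygote of its first allele (direction-symmetric on average); estimate
  = alt alleles / 20.

Both are unbiased; the pooled model's extra resampling layer makes its
variance strictly larger, which is the mechanism behind its lower test
power.  The original depth and genotype-quality data are unpublished, so the
defaults reproduce their printed summaries and filters: depth ~ Poisson(24)
truncated at ≥ 10 (24X mean, DP ≥ 10 filter), and per-call error
10^(−GQ/10) with GQ ~ Normal(25, 8) clipped at ≥ 6 (GQ > 5 filter; mean
error ≈ 1.6%).  Both distributions are pluggable callables, so empirical
tables can replace them; power at 0.4-vs-0.6 is insensitive to the error
distribution's exact shape (heterozygote errors shift the estimate by only
1/20 with ~1% probability) but mildly sensitive to depth overdispersion,
which is why the power tolerance is the widest of the acceptance bands.

Noise injection rounds each true AF to the nearest 0.05 grid point in
[0.05, 0.95] (fixed loci clamp to the endpoints unless `preserve_fixed`) and
replaces it with a draw from that point's empirical estimated-AF
distribution (default 100,000 samples per point).

## Forward simulator

**Phenotype.**  y = S·(μ + β₁X₁ + β₂X₂), clamped to [100, 50,000]
revolutions/day, with μ = 4,570, β₁ = 1.3, β₂ = 2,100.  X₁ is the summed
signed allelic effect over 2,096 unlinked biallelic loci; X₂ ~ N(0, 1) fresh
per individual.  The effect-size distribution is leptokurtic: classes
±0.4·2^k, k = 0..9, with counts (720, 480, 360, 240, 120, 80, 48, 24, 16,
8).  Only the two smallest counts, the largest, and the 2,096 total are
fixed by the published description; the intermediate counts are the monotone
sequence honouring those endpoints, chosen because it reproduces both stated
calibration anchors in closed form — founder narrow-sense heritability
h² = β₁²·2Σnᵢeᵢ² / (β₁²·2Σnᵢeᵢ² + β₂²) = 0.322 and phenotypic CV = 0.558 —
and they are config-overridable.

**Season.**  S cycles with period 4 as (0.769, 1.0, 1.3, 1.0), generation 0
= summer; the phase is a knob since the experiment's starting season is not
determined.  The cycle mean is 1.017, so season inflates or deflates
phenotypes by up to ±30% but cancels from any within-generation comparison;
the constraint is scaled by the same S, so constraint binding is
season-invariant.

**Constraint.**  An evolvable ceiling C = S·(10,000 + 1.0·X_C1 +
1,750·X_C2) over 100 additional loci (48×±1, 24×±4, 12×±11, 8×±36, 5×±101,
3×±306; analytic h² ≈ 0.2); realized running is min(y, C).  Because
high-ceiling alleles are favoured in selected lines, the ceiling itself
rises until the trait plateaus — at ~13,000 at S = 1, i.e. about 17,000 in
winter generations, matching the intended plateau.  X_C2 is independent of
X₂ (an open modelling choice; shared environmental draws would make
constraint binding more sharply genetic).  C is not floored: under the
stated parameters a negative C is a > 5σ event (mean 10,000, SD ≈ 1,937).

**Breeding.**  HR lines: each of 10 pairs produces 5 males + 5 females; the
top realized runner of each sex within each family breeds.  Control lines: 2
+ 2 offspring; the first of each sex breeds (random with respect to
running).  Pairing among the 20 breeders is uniform-random with sibling
pairs rejected and redrawn (bounded retries); founders carry distinct family
ids so the bar never binds at generation 1.  Transmission is Mendelian with
free recombination, no mutation, no dominance, no linkage.  Each line is
simulated for 61 generations; breeder allele counts (out of 40 copies) are
saved at generations 0, 5, …, 60, 22 and 61.

**Analytics.**  Per saved generation, per-locus Welch tests on
angular-transformed breeder AF give the power (share of computable loci with
p ≤ 0.05; failed loci excluded from both counts).  Cross-generation
consistency is the share of generation-22 significant loci still significant
at generation 61, and the Pearson correlation of the two p-value vectors.
Standardized within-family selection differentials are
(breeder − family-sex mean) / family-sex SD, undefined (and excluded) when
the within-family SD is zero; the sign convention makes HR differentials
positive.

**Heritability.**  The offspring-midparent regression pools (midparent
running, family-mean offspring running) pairs from control-line families at
the founder → first-generation transition and reports the *standardized*
regression coefficient (both variables z-scored).  The raw-scale slope is
multiplied by S(1)/S(0) whenever the two measurement occasions fall in
different seasons — a 30% artifact for adjacent cycle steps — so the
estimator removes scale by standardizing, the same reasoning that leads
selection analyses of the real experiment to adjust for generation effects.
Standardization makes the estimate phase-invariant; with the floor censoring
~4% of phenotypes it lands near 0.36, slightly above the analytic 0.322
because family-mean averaging shrinks the offspring-side residual variance.

## Synthetic data generator

The generator emulates what the scans assume about real data: 8 exchangeable
lines founded from a common pool (founder AF ~ Uniform(0.1, 0.9), the
post-filter spectrum of segregating loci), drifting independently by
binomial resampling of 2Ne = 40 allele copies per generation (Ne = 20
matches 10 breeding pairs), so among-line variance grows as
p(1−p)(1 − (1 − 1/2Ne)^g).  Planted differentiated regions shift the HR
lines' mean AF by δ, with all linked SNPs in a block sharing one latent
per-line shift plus N(0, 0.02) jitter — a haplotype block without a
recombination map.  Two-generation mode drifts the background onward and
activates each block per generation, creating churn; the two tables share
their locus sets.

What passing tests show — and what they do not.  The generator reproduces
exchangeability, drift scaling, and block-structured differentiation, so it
validates the scan's calibration (type-I control of the direct FDR) and
detection mechanics (recovery, strict culling, churn detection).  It does
not emulate read-level noise (that is `samplesim`'s role), realistic linkage
decay, selection acting on standing variation, or the much weaker real-world
drift of equalized-family-size breeding (effective size ≈ twice the census);
with the deliberately strong default drift, the regularized tests — which
shrink a planted block's small variance toward the large drift background —
are conservative, and the recovery properties are carried by the Welch scan.

## Problem sizes and tolerances

The acceptance computations use 10,000 Monte-Carlo replicates for the
sampling-error power, 20 replicate forward experiments per model (each 4 HR
+ 4 C lines × 61 generations; one experiment ≈ 1.5 s), 8,000 control-line
families for the heritability fit, and 100,000 samples per grid point for
noise injection — replication chosen so every reported quantity's
Monte-Carlo standard error is comfortably inside its comparison band.

## Known limitations

No sex effects on running, no litter-size variation, no dominance/epistasis,
no linkage or recombination map, no mutation, no relaxed-selection episodes;
the constraint's environmental component is independent of the trait's.
The constrained model's suppression of large-effect differentiation at
generation 22 is weaker here than the published largest-effect-class figure
suggests, while every aggregate anchor (total power by generation,
consistency, correlations, selection differentials) is reproduced; the
per-class discrepancy is documented where it is asserted.
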