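# Methods

## The statistic

Differentiation at a biallelic SNP between two groups is measured by
Wright's fixation index in the frequency form

    F_ST = (H_T − H_S) / H_T,
    H_T = 2 p̄ q̄,  H_S = p1 q1 + p2 q2,  p̄ = (p1 + p2)/2,

algebraically identical to `(p1 − p2)² / (4 p̄ q̄)`.  Group frequencies
enter unweighted by sample size, so the statistic is symmetric, bounded
in [0, 1], 0 iff the frequencies are equal, and 1 iff the groups are
fixed for opposite alleles.  A SNP monomorphic for the same allele in
both groups has H_T = 0 and no defined differentiation; it propagates
NaN and is excluded from averages.  This estimator was chosen as the
default because the scan averages SNP-wise values and interprets them on
the absolute [0, 1] scale; it ignores sampling noise in the frequencies,
which inflates small values at small sample sizes (visible in the
simulations: two populations at drift F = 0.1 each give a genome-wide
mean near 0.051 with 50 diploids per group rather than the
infinite-sample ≈ F/(2 − F) ≈ 0.053 plus nothing — the binomial sampling
adds a small positive bias that the Monte-Carlo oracle reproduces).

The optional two-population Weir–Cockerham θ corrects for unequal and
finite sample sizes using the observed heterozygote proportions (the
a/(a+b+c) variance-components form).  It can be negative around zero
differentiation; values are deliberately not clipped.  It is validated
against an independent hierarchical-ANOVA sums-of-squares computation.

**Multi-pair comparisons.**  A comparison is a list of group pairs
(e.g. out-group vs each of five commercial groups).  Pairwise F_ST is
averaged *within each SNP first* (NaN pairs excluded), then SNP values
are averaged within windows.  With no missing data this equals the joint
SNP×pair average; under missingness the per-SNP-first order is the
defined behaviour.

## Windows

Windows hold a fixed number of consecutive SNPs (default 40) and advance
by a fixed step (default 20), so consecutive windows share 20 members.
This follows array designs that space markers evenly in genetic distance:
a fixed SNP count gives roughly constant information per window while bp
spans vary over orders of magnitude (bp spans are reported for QC only).
Windows never cross chromosome or linkage-group boundaries.  Window
starts are at SNP ranks 1, 1+step, 2·step+1, …; each start takes
min(size, remaining) SNPs, and a sub-size window is kept when it has at
least two SNPs (`drop_partial=True` drops them instead).  Keeping
trailing partials avoids discarding telomeric signal; the rule also
implies that near a chromosome end a partial window can be contained in
the last full window — harmless for tail detection, where both then carry
the same signal.  Chromosomes with fewer than two SNPs yield no windows.

## Tail thresholds

Outlier calling is an empirical-quantile rule, not a parametric test.
Within each chromosome partition with n non-NaN windows and tail
fraction α (default 0.01), k = ⌈α·n⌉; the upper threshold is the k-th
largest window mean, the lower the k-th smallest, and comparison is
inclusive so the threshold value itself is flagged.  The rank rule is
exactly reproducible across platforms, unlike interpolated quantile
algorithms.  Ties may flag more than k windows (logged); a degenerate
all-equal distribution flags everything in both tails with a warning.

Chromosome Z forms its own partition because the sex chromosome's smaller
effective population size elevates its baseline F_ST; pooling it with the
autosomes would let Z windows dominate the upper tail.  The linkage
groups (labels "40" and "41", recoded from LGE22C19W28_E50C23 and LGE64)
are pooled with the autosomes.  A partition with fewer than ⌈1/α⌉ usable
windows is skipped with a warning.

## Permutation reference

For each of 100 replicates (default), individuals are drawn without
replacement into two groups whose sizes match the observed comparison
(label permutation — the standard exchangeable null, keeping estimator
variance comparable), per-SNP Wright/Nei F_ST is recomputed, averaged
over the *same* window geometry, and the genome-wide max and min window
means stored.  For multi-pair comparisons the involved samples are pooled
and permuted into two groups of the pooled side sizes, an approximation
of the two-group procedure.  Replicate r seeds its generator from the
pair (root seed, r), so results are independent of execution order and
replicate count.  The permuted envelope is a diagnostic of what label
shuffling can produce; detection always uses the empirical tails, since
the permuted extremes sit far below an observed distribution with real
structure and would make a uselessly liberal threshold.

## Region joining

Same-tail flagged windows on one chromosome are merged when the gap
between nearest bp edges is ≤ 500 kb (inclusive at exactly 500,000;
overlapping windows always merge).  Upper and lower tails never merge —
elevated and depressed differentiation are biologically distinct signals.
Joining is order-independent (canonical sort first) and idempotent.
BED export converts the internal 1-based closed coordinates to 0-based
half-open and scores regions by 1000 × peak window mean, clamped to
[0, 1000].

## QC and I/O conventions

* Missing genotype sentinel −1; positions 1-based; chicken chromosome
  universe 1–28, Z, 40, 41 (unknown labels sort after it).
* Duplicate "overlapping" SNPs are identified by (chrom, pos) — arrays
  share loci but not id strings; the first sorted occurrence is kept and
  genotype conflicts are logged, since array-merging conventions vary.
* Filter order: missingness first (default: any missing call removes the
  SNP — avoiding imputation on a dense panel is cheaper than modelling
  missingness), then MAF strictly below 5% removed (exactly 5% kept),
  computed over non-missing calls of all remaining samples.  The
  FilterReport enforces input = removed_missing + removed_maf + remaining.
* PED/MAP cannot say which allele is "alternate" at monomorphic sites, so
  the writer emits a `.ref` sidecar (snp_id, ref, alt) that the reader
  honours; without it alleles are taken in sorted observed order.  VCF
  I/O reads through cyvcf2 (multi-allelic sites skipped and counted) and
  writes minimal GT-only VCF 4.2.
* Z genotypes are taken as the diploid calls arrays deliver; there is no
  hemizygosity model.

## The synthetic panel generator

The generator exists so every pipeline stage can be exercised and
calibrated without external data.  It follows the Balding–Nichols model:
ancestral frequency p0 per SNP from a uniform or U-shaped (Beta(a, b),
default a = b = 0.3) spectrum truncated to [0.05, 0.95] (so a 5% MAF
filter does not annihilate the panel); population frequency from
Beta(p0(1−F)/F, (1−p0)(1−F)/F), whose dispersion parameter F is the
expected divergence from the ancestor; genotypes Binomial(2, p_pop).
Lines nested within breeds are produced by two-level drift (ancestor →
breed with F_breed, breed → line with F_line).  Positions have log-normal
bp gaps, emulating arrays even in genetic but not physical distance.

The default study-shaped panel (`study_panel_config`) mirrors the
six-group, 96-bird layer design: WL1 (10), WL2&3 (20), RIR1 (10),
RIR2 (10), WR (20), OG (26); breed drift 0.20/0.15/0.15 with line drift
0.05, out-group drift 0.03 on a uniform spectrum.  These drift values are
fixed design choices that place between-group mean F_ST in the 0.1–0.3
range typical of commercial layer comparisons and reproduce the
qualitative spectrum contrast (U-shaped in drifted commercial lines,
near-flat in the out-group).

Planted sweeps override the drawn frequencies of a block of
`width_snps` consecutive SNPs (default 40 = one window) around the target
position.  A single-SNP fixed difference would shift a 40-SNP window mean
by only ≈ 0.9/40 ≈ 0.02 — within noise — whereas a one-window block
makes recovery of a fixed difference essentially certain; the width is
therefore part of the planted effect size, not a free dial.

**What the generator does not emulate:** linkage disequilibrium and
recombination (SNPs are exchangeable given frequencies; real sweeps decay
with distance), selection dynamics over generations, genotyping error,
ascertainment bias of array SNPs, and admixture between groups.  Passing
tests therefore demonstrate the correctness of the scan machinery and its
behaviour under drift and planted differentiation — not calibrated power
on real, LD-structured genomes.

## Problem sizes and numerical choices

Simulation-backed tests use panels of 2,000–50,000 SNPs with 40–96
samples: large enough that window counts (≈100–2,500) support 1% tails
and Monte-Carlo comparisons, small enough to keep the whole suite in a
few tens of seconds.  Parameter recovery compares a 20,000-SNP panel
(50 diploids per population, F = 0.1) against a 300,000-draw Monte-Carlo
oracle of the identical generative model, at 3 combined standard errors.
All randomness flows from numpy `SeedSequence`; child streams are derived
from (root, index) pairs so every component is reproducible in isolation.
Floating-point policy: frequency-domain checks are strict ([0, 1] or
error), 0/0 situations propagate NaN rather than raising, and NaN is
uniformly read as "undefined, exclude from averages and counts".

## Known limitations

* The Wright/Nei form has no sampling correction; with very small groups
  (2-bird fancy breeds) SNP-wise values are strongly inflated — use
  `weir_cockerham` or interpret only relative ranks.
* The permutation null assumes exchangeable individuals; family structure
  or cryptic relatedness breaks this.
* Empirical tails always flag ≈ 2α of windows, structure or not; flags on
  an undifferentiated panel are rank-forced, not evidence of selection.
* Genotypes are treated as autosomal diploid everywhere, including Z.
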