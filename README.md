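# fstscan

F_ST-based selection-signature scanning for dense SNP genotype panels in
structured livestock (and other) populations.

Intensive artificial selection leaves footprints in the genome: regions
where allele frequencies have diverged sharply between populations bred
for different goals, and regions kept uniform by selection for shared
goals. `fstscan` detects both by scanning dense biallelic SNP panels —
for example commercial egg-layer chicken lines genotyped on 600K arrays
against non-commercial fancy breeds — for windows of extreme genetic
differentiation.

## Method

For each SNP, differentiation between two groups with alternate-allele
frequencies `p1`, `p2` is measured by Wright's fixation index in the
classic frequency (Nei) form

    F_ST = (H_T − H_S) / H_T = (p1 − p2)² / (4 p̄ q̄),      p̄ = (p1 + p2)/2,

which is 0 at identical frequencies, 1 at a fixed difference, and NaN
where both groups are monomorphic for the same allele.  A two-population
Weir–Cockerham θ with sample-size and heterozygosity corrections is
available as an option (`estimator: weir_cockerham`); unlike the
frequency form it can go negative, and negative values are retained.

The pipeline:

1. **QC** — duplicate positions (overlapping SNPs between arrays) are
   removed, then SNPs with any missing call, then SNPs with minor allele
   frequency below 5% (both configurable).
2. **Multi-group comparisons** — a comparison names a set of group pairs
   (e.g. out-group vs each of five commercial groups); per-SNP F_ST is
   averaged over pairs, NaN pairs excluded.
3. **Overlapping windows** — per-SNP values are averaged in 40-SNP
   windows advancing 20 SNPs at a time along each chromosome.
4. **Empirical tails** — windows in the upper or lower 1% of the window
   mean distribution are flagged; thresholds for chromosome Z are
   computed separately from the autosomes because Z carries higher
   baseline differentiation.
5. **Permutation reference** — individuals are repeatedly reassigned at
   random to two groups (100 replicates) and the genome-wide extreme
   window means recorded, as a randomisation yardstick for the observed
   distribution (not as the detection threshold).
6. **Region joining** — same-tail flagged windows within 500 kb are
   merged into candidate sweep regions and exported as BED/TSV for
   annotation.

A Balding–Nichols synthetic-panel generator (`fstscan.simulate`) with
plantable sweep loci makes the whole pipeline testable with no external
data; see `docs/methods.md` for the model and its limits.

## Worked example

Simulate a two-population panel (25 diploids each, drift F = 0.1 per
population, 20,000 SNPs) and scan it:

```bash
fstscan simulate --preset two_pop --n-snps 20000 --fst 0.1 \
    --n-diploids 25 --seed 11 --out panel
fstscan scan --genotypes panel --groups panel.groups.tsv \
    --comparison "A_vs_B:A-B" --permute 100 --seed 11 --outdir results
```

prints

```
wrote 50 samples x 20000 SNPs (2 groups) to panel
A_vs_B: 933 windows, 10/10 flagged (upper/lower), 8/10 regions
  permutation envelope over 100 reps: [0.001245, 0.03353]
```

Reading the numbers: the 20,000 SNPs give 933 overlapping windows; with
a 1% tail on 790 autosomal and 143 Z windows, 8 + 2 = 10 windows are
flagged per tail (upper-tail autosome threshold 0.089 here), joining into
8 upper and 10 lower candidate regions.  The permuted window means never
exceed 0.034 — far below the flagged upper windows, as expected when the
observed groups are genuinely differentiated.  `results/` contains
per-SNP F_ST, the window track, flagged outliers, joined regions
(TSV + BED) and a JSON manifest of every count.

The same scan runs on real data: PED/MAP or VCF genotypes plus a
two-column TSV mapping samples to groups, with comparison templates
`commercial_vs_outgroup` (five pairs vs the out-group) and
`white_vs_brown` (six white-by-brown pairs) built in for the six-group
layer design.

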