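# Methods

`ldtrace` estimates linkage disequilibrium (LD) from unphased diploid SNP
genotypes, summarises its decay with physical distance, measures how well
LD transfers between populations, and back-calculates a historical
effective-population-size (Ne) trajectory.  This note documents the models
and conventions the package commits to, the knobs that matter, and what
the bundled Wright–Fisher generator does and does not emulate.

## Data model and allele coding

A panel is an individuals × markers matrix of allele-B dosages (0/1/2,
−1 = missing) with a physical marker map.  The "B" allele of every marker
is fixed once: on PLINK binary input it is BIM allele 2; on text input it
defaults to the lexicographically larger allele (PED files carry no
orientation).  When panels from several populations are intersected on
their common SNPs (`merge_common_snps`), allele labels are reconciled
against the first panel — swapped labels flip dosages 0↔2 — so that the
*sign* of the LD correlation r means the same haplotype orientation in
every population.  All cross-population statistics assume this frozen
coding; without it, phase persistence is undefined.

Chromosome labels are opaque text and no chromosome is treated specially.
Positions are 1-based base pairs; all distances are position differences
within a chromosome.

## Quality control

Four filters run in a fixed order, each on the matrix the previous one
left: (1) samples with missing-genotype fraction above
`individual_missing_max` (default 0.05); (2) SNPs with call rate below
`snp_call_rate_min` (default 0.95); (3) SNPs with minor allele frequency
*strictly* below `maf_min` (default 0.05 — a SNP at exactly 0.05 is kept);
(4) SNPs with a Hardy–Weinberg exact-test p-value below `hwe_p_min`
(default 1e-6).  The HWE test is the exact conditional test on genotype
counts given allele counts (the PLINK convention: the two-sided p sums the
probabilities of all heterozygote counts no more probable than the
observed one, with a 1+1e-12 tie guard).  An exact test is used because
the intended panels include populations of only a few dozen diploids,
where the chi-square approximation misbehaves.  Each population is
filtered separately and panels are merged on common SNPs afterwards, so a
marker's frequencies are always judged within one population.

## Two-locus haplotype frequencies (EM)

LD statistics need two-locus haplotype frequencies, which unphased
genotypes do not give directly: only the double heterozygote is
phase-ambiguous.  Frequencies are maximum-likelihood estimates under
random mating via the standard two-locus EM — the double-heterozygote
count is split between AB/ab and Ab/aB in proportion to
`p_AB·p_ab / (p_AB·p_ab + p_Ab·p_aB)` and the haplotype counts re-estimated
until the largest frequency change falls below 1e-10 (cap 1000
iterations), starting from linkage equilibrium.  The equilibrium start is
deterministic and, in the rare bimodal-likelihood cases (all individuals
double-heterozygous), settles on the symmetric stationary point rather
than picking a mode arbitrarily.  Missing data are handled
pairwise-complete; each pair records `n_haplotypes` = 2 × complete cases.
Pairs with a monomorphic locus among complete cases are flagged degenerate
and never enter any average.

From fitted frequencies: `D = p_AB − p_A p_B`;
`r = D / sqrt(p_A p_a p_B p_b)` (signed, tied to the frozen allele
coding); `r² = r·r`; `|D'| = |D| / D_max` with
`D_max = min(p_A p_b, p_a p_B)` for `D > 0` and `min(p_A p_B, p_a p_b)`
for `D < 0` (Lewontin), and `D' = 0` when `D = 0`.  These satisfy
`0 ≤ r² ≤ |D'| ≤ 1` identically (AM–GM), which the test suite checks over
10,000 random frequency configurations.

The pairwise computation is vectorised: per chromosome, 3×3 genotype count
tables for all requested pairs are built from one-hot indicator columns
and the EM update runs on whole pair arrays.  The windowed enumerator
streams blocks of pairs so memory scales with the window, not the total
pair count.  One consequence: EM stops on the block-wide maximum change,
so regrouping pairs into different blocks can move individual estimates by
about the 1e-10 tolerance (never more).

## Decay binning and summaries

Pairs up to 15 Mb apart are grouped into 100 Kb bins, half-open
`(lower, upper]` and labelled by the upper edge, so the first bin is "LD
at 100 Kb".  Empty bins carry NaN means, never zeros.  Adjacent-pair
summaries (per chromosome and genome-wide) report mean ± SD of r² and
|D'| plus marker-spacing statistics; the SD uses the n−1 divisor.

## Phase persistence and LD consistency

For two populations on the shared coding, matched by marker-pair identity:

* persistence of LD phase — per distance bin, the sample Pearson
  correlation of the matched *signed* r values;
* adjacent-pair LD consistency — per chromosome, the Pearson correlation
  of √r² (unsigned) of matched adjacent pairs.

Both use the standard n−1 Pearson normalisation and are reported only
where at least three matched non-degenerate pairs exist and both sides
have positive variance.  The two statistics are deliberately separate
operations: the signed version carries the phase information that
multi-breed genomic evaluation depends on; the unsigned version measures
agreement of LD *strength* only.

## Historical Ne

Sved's drift–recombination relation `E[r²] ≈ 1/(1 + 4 Ne c)` is inverted
per distance bin: a bin labelled `d` bp maps to genetic distance
`c = d × (cM/Mb) × 1e-8` Morgans (default 1 cM/Mb) and probes ancestry
`t = 1/(2c)` generations back, so the 150-bin grid spans ~3.3 to 500
generations.  The bin's *label* (upper edge), not its mean pair distance,
is the representative distance — this is what makes the 100 Kb bin probe
exactly t = 500.  Before inversion the bin-mean r² receives the
finite-sample correction `(r² − 1/n)/(1 − 1/n)` with n the number of
sample haplotypes (2 × diploids), removing the ~1/n chance correlation.
The correction is applied to the bin mean (not per pair), and bins whose
corrected mean leaves the open interval (0.01, 0.99) are excluded — the
inversion degenerates toward infinite or zero Ne there.

Feeding the pipeline the idealised expectation `1/(1+4Nc) + 1/n`
reproduces N exactly in the large-n limit; at finite n the ratio-form
correction leaves a closed-form residual `Ne_est = N(1−1/n) − 1/(4cn)`,
below 1% for the sample sizes this package targets except at the very
smallest c.  No mutation-drift, chromosome-length (β) or map-aware
refinements (as in SNeP) are applied: the estimator is the plain Sved
inversion.

## Wright–Fisher generator

The simulator exists so every stage can be tested against known
demography.  It is a forward-in-time diploid Wright–Fisher model:
non-overlapping generations; two uniformly drawn parents per offspring
(selfing allowed); one recombinant gamete per parent with
Poisson(genetic length) crossovers placed uniformly (uniform map,
`cm_per_mb`, default 1 — the same constant the estimator assumes);
the same parent draw across chromosomes.  Variation is standing: sites
start as independent biallelic loci at frequencies uniform on
[0.05, 0.95] and drift through a burn-in of 4 × max(Ne) generations
(overridable) toward the drift–recombination equilibrium the estimator
assumes; there is no mutation, because the estimator uses LD only.
Monomorphic sites and sites under `maf_floor_for_output` (default 0.05,
mirroring a post-QC MAF spectrum) are dropped at output; for a split
simulation, a site must clear the floor in both samples so the two panels
share one map.  All randomness flows through one seeded generator: a
config reproduces byte-identical panels.

Defaults emulate a livestock diversity panel at desk scale: a handful of
10 Mb chromosomes, tens of sampled diploids (the study populations the
package targets run 25–253), Ne of order 10²–10³, ~1 cM/Mb.  Initial site
density is a free knob because drift prunes standing variation heavily —
after 4Ne generations roughly 85–90% of sites fall below a 0.05 MAF floor
at Ne = 100, and losses cluster: a whole small chromosome can coalesce.
Recovery experiments therefore seed 400 sites/Mb to retain ≥2000 SNPs at
the 5 × 10 Mb / Ne = 100 scale.

What the generator does **not** emulate: mutation, selection, migration
beyond a single clean split, overlapping generations, genotyping error,
array ascertainment bias, and non-uniform recombination maps.  Passing
tests therefore demonstrate internal consistency of the estimators under
the model's own assumptions, not robustness to the artefacts of real
array data.

Two quantitative caveats observed in simulation and worth keeping in mind
when reading recovery tests: (i) conditioning on sites that survive drift
above a MAF floor selects old, correlated genealogies and inflates mean
r² relative to the Sved expectation, biasing Ne estimates downward by a
modest factor (well within 2×); (ii) the single most distant bins of a
trajectory hold only the few pairs spanning almost a whole chromosome, so
recovery checks aggregate the recent end (geometric mean over bins with
t ≤ 10) rather than reading one bin.

## Numerical conventions

* EM: tolerance 1e-10 on frequencies, 1000-iteration cap, equilibrium
  start, pairwise-complete cases, degenerate pairs flagged not dropped.
* HWE: log-space enumeration (lgamma), ties included via a 1+1e-12
  factor; degenerate tables return p = 1.
* Binning: `(lower, upper]`, upper-edge labels; NaN for empty bins.
* Pearson statistics: n−1 divisors throughout; undefined below 3 matched
  pairs or at zero variance.
* Ne inclusion band: open interval (0.01, 0.99) on the corrected bin
  mean.
* Sample-size guardrails: `correct_r2` requires n ≥ 2; `ne_from_r2` and
  `generations_from_c` require c > 0.

## Problem sizes used in the shipped experiments

The recovery and persistence experiments in the test suite and the worked
examples use 5 × 10 Mb chromosomes, 50 sampled diploids, Ne = 100 over 3
seeds (recovery), and 3 × 5 Mb chromosomes, 50 + 50 diploids, splits of 2
and 20 generations over 5 seeds (persistence).  These sizes were chosen as
the smallest at which the quantities under test are stable across seeds;
the estimators themselves are vectorised and run comfortably on panels
two orders of magnitude larger.
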