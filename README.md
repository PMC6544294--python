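# ldtrace

Linkage-disequilibrium (LD) analysis for diploid SNP panels: pairwise LD
from unphased genotypes, distance-binned LD decay, cross-population
persistence of LD phase, and LD-based reconstruction of historical
effective population size (Ne).

The package is aimed at population-genetic studies of livestock and other
diversity panels genotyped on SNP arrays — the setting where one asks
whether marker density supports GWAS and genomic selection (LD decay),
whether marker–QTL phase transfers between breeds (phase persistence),
and how large the breeding population has been over time (Ne history).
A forward-in-time Wright–Fisher simulator with recombination and
population splits is included so every stage can be validated against
known demography without any external data.

## The statistics

For a SNP pair with haplotype frequency `p_AB` and allele frequencies
`p_A`, `p_B` (alleles oriented by a coding frozen across populations):

    D   = p_AB − p_A p_B
    r   = D / √(p_A p_a p_B p_b)          r² = r·r
    |D'| = |D| / D_max,   D_max = min(p_A p_b, p_a p_B)  if D > 0
                          D_max = min(p_A p_B, p_a p_b)  if D < 0

Haplotype frequencies come from the two-locus EM algorithm on unphased
genotypes (only double heterozygotes are phase-ambiguous).  Pairs up to
15 Mb apart are averaged in 100 Kb distance bins; a bin at distance d
probes ancestry `t = 1/(2c)` generations back, with `c = d` in Morgans at
1 cM ≈ 1 Mb.  After the finite-sample correction
`r²_c = (r² − 1/n)/(1 − 1/n)` (n = haplotypes sampled), Sved's relation
is inverted per bin:

    Ne = (1 / 4c) · (1 / r²_c − 1)

yielding a 150-point Ne trajectory from ~3 to 500 generations ago.
Persistence of LD phase between two populations is the per-bin Pearson
correlation of the *signed* r of matched SNP pairs; adjacent-pair LD
consistency is the per-chromosome correlation of √r².
See `docs/methods.md` for conventions and assumptions.

## Worked example

Simulate a constant-size population (diploid Ne = 100, five 10 Mb
chromosomes at 1 cM/Mb, 50 sampled diploids), then fit the LD decay and
Ne history:

```python
import ldtrace as lt

cfg = lt.SimConfig(ne_schedule=((0, 100),), n_chromosomes=5,
                   chromosome_length_bp=10_000_000, snp_density_per_mb=400,
                   sample_sizes=(50,), seed=1)
panel = lt.simulate_population(cfg)

fit = lt.NeHistoryModel(panel.dataset).fit()
print(fit.summary())
```

```
LD decay and historical Ne
============================================================
population:            pop1
samples x markers:     50 x 2468
haplotypes (n):        100
map scaling:           1.0 cM/Mb
decay grid:            100 Kb bins to 15 Mb (150 bins)
QC attrition:          samples 50 -> 50, markers 2468 -> 2468
adjacent pairs:        2463 (mean r2 0.937, mean |D'| 0.998)
adjacent r2 > t:       0.2: 0.954, 0.3: 0.949
Ne trajectory:         92 of 150 bins included
  oldest point:        t = 500 gen, Ne = 42
  most recent point:   t = 5.1 gen, Ne = 12
```

The trajectory itself is `fit.trajectory` (one row per bin: distance,
Morgans, generations, raw and corrected mean r², Ne, inclusion flag):

```
 bin_bp  c_morgans  t_generations  mean_r2_raw  mean_r2_corrected        Ne  included
 100000      0.001     500.000000     0.856502           0.855053 42.379553      True
 200000      0.002     250.000000     0.693996           0.690905 55.922040      True
 300000      0.003     166.666667     0.582915           0.578702 60.667202      True
```

At this tiny scale adjacent markers sit in near-complete LD (mean
adjacent r² 0.94) and the recent-generation estimates recover the true
order of magnitude (tens, against a truth of 100; single extreme bins are
noisy, which is why recovery checks aggregate the recent end of the
trajectory).  On an array-scale panel the same call produces the decay
curve, per-chromosome Table-style summaries (`fit.chromosome_summary`)
and the Ne trajectory in one pass.

For two populations on a common marker set:

```python
merged = lt.merge_common_snps([panel_a, panel_b])
fit = lt.PhasePersistenceModel.from_merged(merged, "A", "B").fit()
print(fit.summary())          # per-bin persistence of phase
fit.persistence               # DataFrame: bin_bp, correlation, n_common_pairs
```

The same pipeline is scriptable from the shell:

```sh
ldtrace simulate --seed 1 --ne 100 --samples 50 --out-prefix scratch/pop
ldtrace all scratch/pop --out-dir scratch/run     # QC -> LD -> decay -> Ne
```

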