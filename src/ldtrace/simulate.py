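"""Forward-in-time Wright–Fisher diploid simulator with recombination.

Generates genotype panels with known demography so every pipeline stage —
QC, pairwise LD, decay binning, phase persistence, Ne recovery — can be
exercised against ground truth.  The model is deliberately the same one the
LD-based Ne estimator assumes:

* discrete non-overlapping generations; each offspring draws two parents
  uniformly at random from the previous generation;
* each transmitted gamete recombines with a Poisson number of crossovers
  (mean = chromosome genetic length in Morgans at ``cm_per_mb``) placed
  uniformly along the chromosome;
* biallelic sites initialised as standing variation at frequencies drawn
  uniformly on [0.05, 0.95], then drifted through a burn-in of at least
  4 x max(Ne) generations so pairwise LD approaches its drift–recombination
  equilibrium; no mutation (the estimator uses LD only);
* monomorphic sites and sites below ``maf_floor_for_output`` are dropped at
  output, mimicking a post-QC MAF spectrum.

A population split (for phase-persistence experiments) duplicates the
ancestral population at the split point and evolves the two copies
independently, sharing one marker map.

All randomness flows through a single seeded ``numpy`` Generator, so a
given :class:`SimConfig` reproduces byte-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import GenotypeDataset, dataset_from_arrays

__all__ = ["SimConfig", "SimResult", "simulate_population", "simulate_split",
           "wright_fisher_step", "make_toy_fixture"]


@dataclass(frozen=True)
class SimConfig:
    """Wright–Fisher simulation parameters.

    ne_schedule : epochs as ``(generations, diploid_size)`` tuples, oldest
        first, run after the burn-in; the burn-in uses the first epoch's
        size.  A single-epoch schedule gives constant Ne.
    snp_density_per_mb : candidate biallelic sites seeded per Mb at
        initialisation (drift prunes a large share before output).
    sample_sizes : diploid individuals sampled per output population.
    split_generation : for :func:`simulate_split`, generations before
        sampling at which the two populations diverge.
    burn_in_generations : overrides the default 4 x max(Ne) burn-in.
    """

    ne_schedule: tuple[tuple[int, int], ...] = ((400, 100),)
    n_chromosomes: int = 5
    chromosome_length_bp: int = 10_000_000
    snp_density_per_mb: float = 100.0
    cm_per_mb: float = 1.0
    sample_sizes: tuple[int, ...] = (50,)
    split_generation: int | None = None
    maf_floor_for_output: float = 0.05
    seed: int = 0
    burn_in_generations: int | None = None

    def __post_init__(self) -> None:
        if not self.ne_schedule:
            raise ValueError("ne_schedule must contain at least one epoch")
        for span, size in self.ne_schedule:
            if span < 0 or size < 1:
                raise ValueError("epoch spans must be >= 0, sizes >= 1")
        if min(self.sample_sizes) < 1:
            raise ValueError("sample sizes must be positive")
        if max(self.sample_sizes) > self._final_size():
            raise ValueError(
                f"cannot sample {max(self.sample_sizes)} diploids without "
                f"replacement from a population of {self._final_size()}")
        if self.n_chromosomes < 1 or self.chromosome_length_bp < 2:
            raise ValueError("need >= 1 chromosome of >= 2 bp")
        if self.snp_density_per_mb <= 0 or self.cm_per_mb < 0:
            raise ValueError("snp density must be > 0, cm_per_mb >= 0")
        if not 0.0 <= self.maf_floor_for_output < 0.5:
            raise ValueError("maf_floor_for_output must be in [0, 0.5)")
        total = self.burn_in() + sum(s for s, _ in self.ne_schedule)
        if self.split_generation is not None and not (
                0 <= self.split_generation < total):
            raise ValueError("split_generation must fall inside the "
                             "simulated span")

    def _final_size(self) -> int:
        return self.ne_schedule[-1][1]

    def burn_in(self) -> int:
        if self.burn_in_generations is not None:
            return self.burn_in_generations
        return 4 * max(size for _, size in self.ne_schedule)


@dataclass
class SimResult:
    """A simulated panel plus its generating truth.

    ``haplotypes`` holds the phased truth per chromosome as
    ``(2*n_sampled, n_sites)`` 0/1 arrays aligned with the dataset's marker
    columns; ``dataset.genotypes`` is exactly the per-site sum of each
    individual's two haplotype rows.
    """

    dataset: GenotypeDataset
    haplotypes: list[np.ndarray]
    config: SimConfig
    population: str

    def truth_sidecar(self) -> str:
        """JSON text recording the generating parameters."""
        return json.dumps({
            "population": self.population,
            "ne_schedule": list(map(list, self.config.ne_schedule)),
            "burn_in_generations": self.config.burn_in(),
            "split_generation": self.config.split_generation,
            "n_chromosomes": self.config.n_chromosomes,
            "chromosome_length_bp": self.config.chromosome_length_bp,
            "cm_per_mb": self.config.cm_per_mb,
            "seed": self.config.seed,
        }, indent=2)


# ---------------------------------------------------------------------------
# core generation step
# ---------------------------------------------------------------------------

def _gametes(haps: np.ndarray, parents: np.ndarray, positions: np.ndarray,
             morgans: float, rng: np.random.Generator) -> np.ndarray:
    """One recombinant gamete per parent index.

    ``haps`` is the (2N, m) haplotype pool; ``parents`` indexes diploid
    parents.  Crossover counts are Poisson(morgans); crossover points are
    uniform on the physical chromosome (uniform genetic map).
    """
    k = parents.size
    start = rng.integers(0, 2, size=k)
    n_x = rng.poisson(morgans, size=k) if morgans > 0 else np.zeros(k, int)
    out = haps[2 * parents + start].copy()
    length = positions[-1] if positions.size else 0
    for g in np.flatnonzero(n_x):
        xpos = np.sort(rng.uniform(0, length, size=n_x[g]))
        segment = (start[g] + np.searchsorted(xpos, positions,
                                              side="right")) % 2
        h = haps[2 * parents[g]:2 * parents[g] + 2]
        out[g] = np.where(segment == 0, h[0], h[1])
    return out


def wright_fisher_step(haplotype_pools: list[np.ndarray],
                       positions: list[np.ndarray], n_offspring: int,
                       cm_per_mb: float, rng: np.random.Generator
                       ) -> list[np.ndarray]:
    """Advance one generation: random union of one maternal and one paternal
    recombinant gamete per offspring, parents drawn uniformly.

    ``haplotype_pools`` holds one (2N, m_c) array per chromosome; the same
    parent draw is used across chromosomes (individuals are whole
    organisms).  Returns the next generation's pools (2*n_offspring rows).
    """
    n_parents = haplotype_pools[0].shape[0] // 2
    mothers = rng.integers(0, n_parents, size=n_offspring)
    fathers = rng.integers(0, n_parents, size=n_offspring)
    new_pools = []
    for haps, pos in zip(haplotype_pools, positions):
        morgans = (pos[-1] if pos.size else 0) * cm_per_mb * 1e-8
        maternal = _gametes(haps, mothers, pos, morgans, rng)
        paternal = _gametes(haps, fathers, pos, morgans, rng)
        nxt = np.empty((2 * n_offspring, haps.shape[1]), dtype=haps.dtype)
        nxt[0::2] = maternal
        nxt[1::2] = paternal
        new_pools.append(nxt)
    return new_pools


def _init_population(config: SimConfig, rng: np.random.Generator
                     ) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Standing variation: independent sites at U[0.05, 0.95] frequencies."""
    n0 = config.ne_schedule[0][1]
    pools, positions = [], []
    per_chrom = max(2, int(round(config.snp_density_per_mb
                                 * config.chromosome_length_bp / 1e6)))
    for _ in range(config.n_chromosomes):
        pos = np.unique(rng.integers(
            1, config.chromosome_length_bp + 1, size=per_chrom))
        while pos.size < per_chrom:  # rare collision top-up
            extra = rng.integers(1, config.chromosome_length_bp + 1,
                                 size=per_chrom - pos.size)
            pos = np.unique(np.concatenate([pos, extra]))
        pos = pos.astype(np.int64)
        p = rng.uniform(0.05, 0.95, size=per_chrom)
        haps = (rng.random((2 * n0, per_chrom)) < p).astype(np.uint8)
        pools.append(haps)
        positions.append(pos)
    return pools, positions


def _run_epochs(pools, positions, config: SimConfig,
                rng: np.random.Generator, generations: int,
                sizes: list[int]) -> list[np.ndarray]:
    for gen in range(generations):
        pools = wright_fisher_step(pools, positions, sizes[gen],
                                   config.cm_per_mb, rng)
    return pools


def _size_sequence(config: SimConfig) -> list[int]:
    """Offspring count for every post-burn-in generation, oldest first."""
    seq: list[int] = []
    for span, size in config.ne_schedule:
        seq.extend([size] * span)
    return seq


def _sample(pools, positions, config: SimConfig, n_diploid: int,
            rng: np.random.Generator, population: str) -> SimResult:
    n_pool = pools[0].shape[0] // 2
    if n_diploid > n_pool:
        raise ValueError(f"cannot sample {n_diploid} diploids from a "
                         f"population of {n_pool}")
    chosen = np.sort(rng.choice(n_pool, size=n_diploid, replace=False))
    hap_rows = np.column_stack([2 * chosen, 2 * chosen + 1]).ravel()
    sampled = [h[hap_rows] for h in pools]
    return _build_result(sampled, positions, config, population)


def _build_result(sampled_pools, positions, config: SimConfig,
                  population: str,
                  keep_masks: list[np.ndarray] | None = None) -> SimResult:
    genos, ids, chroms, pos_all, haps_out = [], [], [], [], []
    for c, (haps, pos) in enumerate(zip(sampled_pools, positions)):
        if keep_masks is not None:
            keep = keep_masks[c]
        else:
            freq = haps.mean(axis=0)
            maf = np.minimum(freq, 1 - freq)
            keep = maf >= max(config.maf_floor_for_output,
                              np.finfo(float).tiny)
        haps = haps[:, keep]
        pos = pos[keep]
        genos.append(haps[0::2] + haps[1::2])
        haps_out.append(haps)
        chrom = str(c + 1)
        ids.extend(f"snp_{chrom}_{p}" for p in pos)
        chroms.extend([chrom] * pos.size)
        pos_all.extend(pos.tolist())
    genotypes = np.concatenate(genos, axis=1).astype(np.int8)
    n = genotypes.shape[0]
    m = genotypes.shape[1]
    dataset = dataset_from_arrays(
        ids, chroms, pos_all, ["A"] * m, ["B"] * m,
        [f"{population}_{i:04d}" for i in range(n)],
        [population] * n, genotypes)
    return SimResult(dataset=dataset, haplotypes=haps_out, config=config,
                     population=population)


def simulate_population(config: SimConfig) -> SimResult:
    """Simulate one population and sample ``config.sample_sizes[0]`` diploids."""
    rng = np.random.default_rng(config.seed)
    pools, positions = _init_population(config, rng)
    burn = config.burn_in()
    first_size = config.ne_schedule[0][1]
    pools = _run_epochs(pools, positions, config, rng, burn,
                        [first_size] * burn)
    sizes = _size_sequence(config)
    pools = _run_epochs(pools, positions, config, rng, len(sizes), sizes)
    return _sample(pools, positions, config, config.sample_sizes[0], rng,
                   population="pop1")


def simulate_split(config: SimConfig) -> tuple[SimResult, SimResult]:
    """Two populations diverged ``config.split_generation`` generations ago.

    The ancestral population evolves to the split point; two independent
    copies then evolve the remaining generations and are each sampled
    (``sample_sizes[0]`` and ``sample_sizes[1]``, the second defaulting to
    the first).  Both results share one marker map: a site is kept when it
    clears the MAF floor in *both* samples.
    """
    if config.split_generation is None:
        raise ValueError("config.split_generation must be set")
    rng = np.random.default_rng(config.seed)
    pools, positions = _init_population(config, rng)
    burn = config.burn_in()
    first_size = config.ne_schedule[0][1]
    sizes = [first_size] * burn + _size_sequence(config)
    pre_split = len(sizes) - config.split_generation
    pools = _run_epochs(pools, positions, config, rng, pre_split,
                        sizes[:pre_split])
    post_sizes = sizes[pre_split:]
    pools_a = [h.copy() for h in pools]
    pools_b = [h.copy() for h in pools]
    pools_a = _run_epochs(pools_a, positions, config, rng,
                          len(post_sizes), post_sizes)
    pools_b = _run_epochs(pools_b, positions, config, rng,
                          len(post_sizes), post_sizes)

    n_a = config.sample_sizes[0]
    n_b = (config.sample_sizes[1] if len(config.sample_sizes) > 1 else n_a)

    def _draw(pools_x, n_diploid):
        n_pool = pools_x[0].shape[0] // 2
        chosen = np.sort(rng.choice(n_pool, size=n_diploid, replace=False))
        rows = np.column_stack([2 * chosen, 2 * chosen + 1]).ravel()
        return [h[rows] for h in pools_x]

    sampled_a = _draw(pools_a, n_a)
    sampled_b = _draw(pools_b, n_b)
    keep_masks = []
    for ha, hb in zip(sampled_a, sampled_b):
        fa = ha.mean(axis=0)
        fb = hb.mean(axis=0)
        floor = max(config.maf_floor_for_output, np.finfo(float).tiny)
        keep_masks.append(
            (np.minimum(fa, 1 - fa) >= floor)
            & (np.minimum(fb, 1 - fb) >= floor))
    res_a = _build_result(sampled_a, positions, config, "popA", keep_masks)
    res_b = _build_result(sampled_b, positions, config, "popB", keep_masks)
    return res_a, res_b


# ---------------------------------------------------------------------------
# deterministic toy fixture
# ---------------------------------------------------------------------------

def make_toy_fixture() -> tuple[GenotypeDataset, dict]:
    """A hand-built 6-sample x 5-marker panel with worked-out expectations.

    The panel exercises every QC filter and an LD pair whose phase is
    unambiguous (no double heterozygotes), so EM must equal direct gamete
    counting.  Returns ``(dataset, expected)`` where ``expected`` freezes
    the hand-computed values, including the QCConfig under which they hold
    (individual_missing_max is 0.4 here: with only five markers a 5% rule
    would equate "any missing call" with removal and leave nothing to test
    at the SNP level).

    Layout (columns m1..m5, rows S1..S6, '.' = missing)::

        S1: 2 1 0 2 0
        S2: 2 1 0 1 1
        S3: 1 1 0 0 2
        S4: 0 1 0 . 2
        S5: 1 1 0 . 0
        S6: . . . 2 2   <- 3/5 = 60% missing, removed by sample filter

    After removing S6: m1 freq_b = 0.6 (MAF 0.4, keeps); m2 all-het (MAF
    0.5, HWE p stays above 1e-6 at n = 5, keeps); m3 monomorphic (MAF 0,
    removed by the MAF filter); m4 call rate 3/5 = 0.6 < 0.95 (removed);
    m5 freq_b = 0.5 (keeps).  Final panel: 5 samples x 3 markers.

    The (m1, m5) pair has no double heterozygote; direct gamete counting
    gives freq(B,B) = 0.2, D = −0.1, r = −0.40825, r² = 1/6, |D'| = 0.5.
    """
    M = -1
    genotypes = np.array([
        [2, 1, 0, 2, 0],
        [2, 1, 0, 1, 1],
        [1, 1, 0, 0, 2],
        [0, 1, 0, M, 2],
        [1, 1, 0, M, 0],
        [M, M, M, 2, 2],
    ], dtype=np.int8)
    positions = [1_000, 48_000, 95_000, 141_000, 188_000]
    dataset = dataset_from_arrays(
        [f"m{i}" for i in range(1, 6)], ["1"] * 5, positions,
        ["A"] * 5, ["B"] * 5,
        [f"S{i}" for i in range(1, 7)], ["toy"] * 6, genotypes)
    expected = {
        "qc_config": {"maf_min": 0.05, "snp_call_rate_min": 0.95,
                      "hwe_p_min": 1e-6, "individual_missing_max": 0.4},
        "samples_removed_missingness": 1,
        "markers_removed_call_rate": 1,       # m4
        "markers_removed_maf": 1,             # m3
        "markers_removed_hwe": 0,
        "surviving_markers": ["m1", "m2", "m5"],
        "surviving_samples": ["S1", "S2", "S3", "S4", "S5"],
        "m1_freq_b": 0.6,
        "m1_maf": 0.4,
        "m1_freq_b_before_sample_filter": 0.6,   # S6 missing at m1
        "m1_hwe_counts": (1, 2, 2),
        "ld_pair": ("m1", "m5"),
        "ld_freq_BB": 0.2,
        "ld_D": -0.1,
        "ld_r": -0.1 / np.sqrt(0.6 * 0.4 * 0.5 * 0.5),
        "ld_r2": 1.0 / 6.0,
        "ld_abs_dprime": 0.5,
    }
    return dataset, expected
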