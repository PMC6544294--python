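"""Pairwise linkage disequilibrium from unphased diploid genotypes.

Haplotype frequencies for a SNP pair are maximum-likelihood estimates under
random mating, obtained with the classic two-locus EM algorithm: every
genotype combination except the double heterozygote resolves into gametes
unambiguously, and the double heterozygote's AB/ab vs Ab/aB split is
iterated to convergence from a linkage-equilibrium start.  From the fitted
haplotype frequencies the module computes

    D   = freq_AB − freq_A · freq_B
    r   = D / sqrt(freq_A · freq_a · freq_B · freq_b)      (signed)
    r²  = r·r
    D'  = |D| / D_max   with  D_max = min(freq_A·freq_b, freq_a·freq_B)
          when D > 0 and min(freq_A·freq_B, freq_a·freq_b) when D < 0,

where allele "A"/"B" here denotes the dataset's counted allele (allele_b of
each marker), so the sign of r is tied to the allele coding frozen at merge
time and is comparable across populations.

Missing data are handled pairwise-complete: each pair uses the individuals
called at both loci, and ``n_haplotypes`` records 2x that count.  Pairs
where either locus is monomorphic among complete cases are flagged
degenerate and carry NaN statistics; downstream averages skip them.

The heavy lifting is vectorised: per chromosome, all 3x3 genotype count
tables for the requested pairs are formed with matrix products over one-hot
indicator matrices, and the EM update runs on whole pair arrays at once.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np
import pandas as pd

from .datamodel import MISSING, GenotypeDataset

__all__ = ["HaplotypeFreqs", "em_haplotype_freqs", "ld_from_freqs",
           "adjacent_pair_ld", "windowed_pair_ld", "collect_windowed_pair_ld",
           "LD_COLUMNS"]

EM_TOL = 1e-10
EM_MAX_ITER = 1000

#: Column layout of every LD pair table produced by this module.
LD_COLUMNS = ["chromosome", "id_i", "id_j", "pos_i", "pos_j", "distance_bp",
              "D", "Dprime", "r", "r2", "n_haplotypes", "degenerate"]


@dataclass(frozen=True)
class HaplotypeFreqs:
    """Two-locus haplotype frequencies (AB = counted allele at both loci)."""

    freq_AB: float
    freq_Ab: float
    freq_aB: float
    freq_ab: float
    n_haplotypes: int
    degenerate: bool = False

    @property
    def freq_A(self) -> float:
        return self.freq_AB + self.freq_Ab

    @property
    def freq_B(self) -> float:
        return self.freq_AB + self.freq_aB


# ---------------------------------------------------------------------------
# vectorised EM on 3x3 genotype count tables
# ---------------------------------------------------------------------------

def _em_from_counts(tables: np.ndarray
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """EM haplotype frequencies for a stack of genotype count tables.

    Parameters
    ----------
    tables : (..., 3, 3) array
        ``tables[..., gi, gj]`` counts individuals with dosage ``gi`` at the
        first locus and ``gj`` at the second (complete cases only).

    Returns
    -------
    freqs : (..., 4) array  — [AB, Ab, aB, ab] haplotype frequencies
    n_hap : (...) int array — haplotypes used (2 x complete cases)
    degenerate : (...) bool array — monomorphic locus among complete cases
    """
    t = np.asarray(tables, dtype=np.float64)
    n_ind = t.sum(axis=(-2, -1))
    n_hap = 2.0 * n_ind
    # unambiguous gamete counts; cell (1,1) is the phase-ambiguous double het
    x_AB = 2 * t[..., 2, 2] + t[..., 2, 1] + t[..., 1, 2]
    x_Ab = 2 * t[..., 2, 0] + t[..., 2, 1] + t[..., 1, 0]
    x_aB = 2 * t[..., 0, 2] + t[..., 0, 1] + t[..., 1, 2]
    x_ab = 2 * t[..., 0, 0] + t[..., 0, 1] + t[..., 1, 0]
    dh = t[..., 1, 1]

    with np.errstate(invalid="ignore", divide="ignore"):
        p_i = (x_AB + x_Ab + dh) / n_hap     # counted-allele freq, locus i
        p_j = (x_AB + x_aB + dh) / n_hap
    degenerate = (~np.isfinite(p_i) | ~np.isfinite(p_j)
                  | (p_i <= 0) | (p_i >= 1) | (p_j <= 0) | (p_j >= 1))

    # linkage-equilibrium initialisation
    pAB = p_i * p_j
    pAb = p_i * (1 - p_j)
    paB = (1 - p_i) * p_j
    pab = (1 - p_i) * (1 - p_j)
    safe_n = np.where(n_hap > 0, n_hap, 1.0)
    for _ in range(EM_MAX_ITER):
        num = pAB * pab
        den = num + pAb * paB
        with np.errstate(invalid="ignore", divide="ignore"):
            f = np.where(den > 0, num / den, 0.5)
        nAB = (x_AB + f * dh) / safe_n
        nab = (x_ab + f * dh) / safe_n
        nAb = (x_Ab + (1 - f) * dh) / safe_n
        naB = (x_aB + (1 - f) * dh) / safe_n
        delta = np.max(np.stack([np.abs(nAB - pAB), np.abs(nAb - pAb),
                                 np.abs(naB - paB), np.abs(nab - pab)]))
        pAB, pAb, paB, pab = nAB, nAb, naB, nab
        if delta < EM_TOL:
            break
    freqs = np.stack([pAB, pAb, paB, pab], axis=-1)
    return freqs, n_hap.astype(np.int64), degenerate


def em_haplotype_freqs(genotypes_i: np.ndarray, genotypes_j: np.ndarray
                       ) -> HaplotypeFreqs:
    """ML haplotype frequencies for one SNP pair from unphased dosages.

    Uses pairwise-complete individuals; requires at least two of them.
    """
    gi = np.asarray(genotypes_i, dtype=np.int64)
    gj = np.asarray(genotypes_j, dtype=np.int64)
    if gi.shape != gj.shape or gi.ndim != 1:
        raise ValueError("genotype vectors must be equal-length 1-D arrays")
    complete = (gi != MISSING) & (gj != MISSING)
    if complete.sum() < 2:
        raise ValueError("need at least 2 pairwise-complete individuals")
    table = np.zeros((3, 3))
    np.add.at(table, (gi[complete], gj[complete]), 1.0)
    freqs, n_hap, degen = _em_from_counts(table)
    return HaplotypeFreqs(float(freqs[0]), float(freqs[1]),
                          float(freqs[2]), float(freqs[3]),
                          int(n_hap), bool(degen))


# ---------------------------------------------------------------------------
# LD statistics
# ---------------------------------------------------------------------------

def _ld_stats(freqs: np.ndarray, degenerate: np.ndarray
              ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """(D, D', r, r2) arrays from stacked haplotype frequencies (..., 4)."""
    pAB = freqs[..., 0]
    pA = freqs[..., 0] + freqs[..., 1]
    pB = freqs[..., 0] + freqs[..., 2]
    pa = 1.0 - pA
    pb = 1.0 - pB
    D = pAB - pA * pB
    with np.errstate(invalid="ignore", divide="ignore"):
        r = D / np.sqrt(pA * pa * pB * pb)
        d_max = np.where(D > 0, np.minimum(pA * pb, pa * pB),
                         np.minimum(pA * pB, pa * pb))
        dprime = np.where(D == 0, 0.0, np.abs(D) / d_max)
    r2 = r * r
    bad = np.asarray(degenerate, dtype=bool)
    D = np.where(bad, np.nan, D)
    # clip tiny numerical overshoots; NaN propagates through clip
    r = np.clip(np.where(bad, np.nan, r), -1.0, 1.0)
    r2 = np.clip(np.where(bad, np.nan, r2), 0.0, 1.0)
    dprime = np.clip(np.where(bad, np.nan, dprime), 0.0, 1.0)
    return D, dprime, r, r2


def ld_from_freqs(h: HaplotypeFreqs) -> dict[str, float]:
    """D, D', signed r and r2 from one pair's haplotype frequencies."""
    if h.degenerate:
        raise ValueError("LD undefined: a locus is monomorphic among "
                         "complete cases")
    freqs = np.array([h.freq_AB, h.freq_Ab, h.freq_aB, h.freq_ab])
    D, dprime, r, r2 = _ld_stats(freqs, np.array(False))
    return {"D": float(D), "Dprime": float(dprime),
            "r": float(r), "r2": float(r2)}


# ---------------------------------------------------------------------------
# pair enumeration over a dataset
# ---------------------------------------------------------------------------

def _count_tables(G: np.ndarray, rows: np.ndarray, cols: np.ndarray
                  ) -> np.ndarray:
    """3x3 complete-case genotype tables for pairs (rows[k], cols[k]).

    ``G`` is the (n_samples, m) dosage matrix of one chromosome.  Builds the
    tables from one-hot indicator columns with vectorised contractions, so
    the cost is nine sample-axis reductions rather than a per-pair loop.
    """
    onehot = [(G == k).astype(np.float32) for k in (0, 1, 2)]
    tables = np.empty((len(rows), 3, 3), dtype=np.float64)
    R = [onehot[a][:, rows] for a in range(3)]
    C = [onehot[b][:, cols] for b in range(3)]
    for a in range(3):
        for b in range(3):
            tables[:, a, b] = np.einsum("np,np->p", R[a], C[b],
                                        optimize=True)
    return tables


def _pairs_to_frame(dataset: GenotypeDataset, sl: slice, rows: np.ndarray,
                    cols: np.ndarray) -> pd.DataFrame:
    G = dataset.genotypes[:, sl]
    tables = _count_tables(G, rows, cols)
    freqs, n_hap, degen = _em_from_counts(tables)
    # pairs with <2 complete cases are degenerate too
    degen = degen | (n_hap < 4)
    D, dprime, r, r2 = _ld_stats(freqs, degen)
    mk = dataset.markers.iloc[sl]
    pos = mk["position_bp"].to_numpy()
    ids = mk["id"].to_numpy()
    return pd.DataFrame({
        "chromosome": mk["chromosome"].to_numpy()[rows],
        "id_i": ids[rows], "id_j": ids[cols],
        "pos_i": pos[rows], "pos_j": pos[cols],
        "distance_bp": pos[cols] - pos[rows],
        "D": D, "Dprime": dprime, "r": r, "r2": r2,
        "n_haplotypes": n_hap, "degenerate": degen,
    })


def adjacent_pair_ld(dataset: GenotypeDataset) -> pd.DataFrame:
    """LD for every consecutive marker pair within each chromosome.

    Returns one row per adjacent pair (m−1 rows for a chromosome with m
    markers; no cross-chromosome pairs).  Degenerate pairs are flagged, not
    dropped, so callers control whether they enter averages.
    """
    frames = []
    for chrom in dataset.chromosomes:
        sl = dataset.chromosome_slice(chrom)
        m = sl.stop - sl.start
        if m < 2:
            continue
        rows = np.arange(m - 1)
        cols = rows + 1
        frames.append(_pairs_to_frame(dataset, sl, rows, cols))
    if not frames:
        return pd.DataFrame(columns=LD_COLUMNS)
    return pd.concat(frames, ignore_index=True)


def windowed_pair_ld(dataset: GenotypeDataset,
                     max_distance_bp: int = 15_000_000,
                     block_size: int = 256) -> Iterator[pd.DataFrame]:
    """Stream LD for all within-chromosome pairs up to ``max_distance_bp``.

    Yields per-block DataFrames (same columns as :func:`adjacent_pair_ld`)
    so memory scales with the widest window, not the total pair count.
    """
    for chrom in dataset.chromosomes:
        sl = dataset.chromosome_slice(chrom)
        m = sl.stop - sl.start
        if m < 2:
            continue
        pos = dataset.markers["position_bp"].to_numpy()[sl]
        for start in range(0, m - 1, block_size):
            stop = min(start + block_size, m - 1)
            rows_list, cols_list = [], []
            for i in range(start, stop):
                j_hi = np.searchsorted(pos, pos[i] + max_distance_bp,
                                       side="right")
                if j_hi > i + 1:
                    js = np.arange(i + 1, j_hi)
                    rows_list.append(np.full(js.size, i))
                    cols_list.append(js)
            if not rows_list:
                continue
            rows = np.concatenate(rows_list)
            cols = np.concatenate(cols_list)
            yield _pairs_to_frame(dataset, sl, rows, cols)


def collect_windowed_pair_ld(dataset: GenotypeDataset,
                             max_distance_bp: int = 15_000_000
                             ) -> pd.DataFrame:
    """Materialise :func:`windowed_pair_ld` into one DataFrame."""
    frames = list(windowed_pair_ld(dataset, max_distance_bp))
    if not frames:
        return pd.DataFrame(columns=LD_COLUMNS)
    return pd.concat(frames, ignore_index=True)
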