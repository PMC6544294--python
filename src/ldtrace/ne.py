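"""Historical effective population size from distance-binned LD.

The estimator rests on Sved's drift–recombination relation

    E[r²] ≈ 1 / (1 + 4·Ne·c),

inverted to  Ne = (1/(4c)) · (1/r² − 1),  where c is the genetic distance
in Morgans between the SNPs of a pair (physical distance converted at a
constant cM-per-Mb rate, 1 by default).  LD over distance c reflects
ancestry roughly t = 1/(2c) generations back, so each 100 Kb distance bin
of the decay curve yields one (t, Ne) point of a trajectory: the 150 bins
of a (0, 15 Mb] grid cover ~3 to 500 generations ago.

Finite sampling inflates r²; the chance correlation between unlinked loci
in a sample of n haplotypes is ~1/n, removed before inversion with

    r²_corrected = (r² − 1/n) / (1 − 1/n),

where n is the number of haplotypes (2 x sampled diploids).  Bins whose
corrected mean r² falls outside (0.01, 0.99) are excluded: the inversion
degenerates towards infinite (r²→0) or zero (r²→1) Ne there.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["NeConfig", "correct_r2", "ne_from_r2", "generations_from_c",
           "ne_trajectory"]


@dataclass(frozen=True)
class NeConfig:
    """Parameters of the LD -> Ne back-calculation.

    cm_per_mb : physical-to-genetic conversion (cM per Mb); 1.0 assumes the
        genome-wide average recombination rate.
    r2_low, r2_high : inclusion band for the corrected bin-mean r².
    n_haplotypes : sample haplotype count (2 x diploid individuals) used in
        the finite-sample correction.
    """

    n_haplotypes: int
    cm_per_mb: float = 1.0
    r2_low: float = 0.01
    r2_high: float = 0.99

    def __post_init__(self) -> None:
        if self.n_haplotypes < 2:
            raise ValueError("n_haplotypes must be >= 2")
        if self.cm_per_mb <= 0:
            raise ValueError("cm_per_mb must be positive")
        if not 0.0 <= self.r2_low < self.r2_high <= 1.0:
            raise ValueError("need 0 <= r2_low < r2_high <= 1")


def correct_r2(r2, n_haplotypes: int):
    """Finite-sample correction (r² − 1/n) / (1 − 1/n).

    May return a negative value when r² < 1/n; such bins are excluded from
    the Ne inversion downstream rather than clipped.
    """
    if n_haplotypes < 2:
        raise ValueError("n_haplotypes must be >= 2")
    inv_n = 1.0 / n_haplotypes
    return (np.asarray(r2, dtype=np.float64) - inv_n) / (1.0 - inv_n)


def ne_from_r2(r2_corrected: float, c: float) -> float:
    """Invert Sved's relation: Ne = (1/(4c)) (1/r² − 1).

    ``c`` is genetic distance in Morgans.  Raises for non-positive c; the
    caller applies the (r2_low, r2_high) inclusion band.
    """
    if c <= 0:
        raise ValueError("genetic distance c must be positive")
    return (1.0 / (4.0 * c)) * (1.0 / r2_corrected - 1.0)


def generations_from_c(c: float) -> float:
    """Generations in the past probed by LD at genetic distance c: t = 1/(2c)."""
    if c <= 0:
        raise ValueError("genetic distance c must be positive")
    return 1.0 / (2.0 * c)


def ne_trajectory(binned: pd.DataFrame, config: NeConfig) -> pd.DataFrame:
    """Historical Ne trajectory from a binned LD decay table.

    Parameters
    ----------
    binned : DataFrame
        Output of :func:`ldtrace.decay.bin_pairs` (columns ``bin_bp``,
        ``mean_r2``, ``n_pairs``).
    config : NeConfig

    Returns
    -------
    DataFrame with one row per bin: ``bin_bp, c_morgans, t_generations,
    mean_r2_raw, mean_r2_corrected, Ne, included``.  A bin's representative
    genetic distance is its upper-edge label converted to Morgans, so the
    100 Kb bin maps to t = 500 at 1 cM/Mb.  Empty bins and bins whose
    corrected r² leaves the inclusion band are flagged ``included=False``
    with NaN Ne.
    """
    bin_bp = binned["bin_bp"].to_numpy(dtype=np.float64)
    c = bin_bp * config.cm_per_mb * 1e-8          # bp -> Morgans
    t = 1.0 / (2.0 * c)
    raw = binned["mean_r2"].to_numpy(dtype=np.float64)
    n_pairs = binned["n_pairs"].to_numpy()
    corrected = correct_r2(raw, config.n_haplotypes)
    included = ((n_pairs > 0) & np.isfinite(corrected)
                & (corrected > config.r2_low) & (corrected < config.r2_high))
    with np.errstate(invalid="ignore", divide="ignore"):
        ne = np.where(included,
                      (1.0 / (4.0 * c)) * (1.0 / corrected - 1.0), np.nan)
    return pd.DataFrame({
        "bin_bp": bin_bp.astype(np.int64),
        "c_morgans": c,
        "t_generations": t,
        "mean_r2_raw": raw,
        "mean_r2_corrected": corrected,
        "Ne": ne,
        "included": included,
    })
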