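"""Distance-binned LD decay and per-chromosome adjacent-pair summaries.

Pairs are grouped on a 100 Kb grid over (0, 15 Mb] by default, using
half-open bins ``(lower, upper]`` labelled by their upper edge, so the
first bin is "LD at 100 Kb".  That labelling is what ties a bin to the
generation ``t = 1/(2c)`` it probes in the Ne back-calculation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["bin_pairs", "chromosome_summary", "threshold_proportions"]


def _clean(pairs: pd.DataFrame) -> pd.DataFrame:
    """Drop degenerate pairs (monomorphic locus, undefined statistics)."""
    if "degenerate" in pairs.columns:
        return pairs.loc[~pairs["degenerate"].astype(bool)]
    return pairs.loc[~pairs["r2"].isna()]


def bin_pairs(pairs, bin_width_bp: int = 100_000,
              max_bp: int = 15_000_000) -> pd.DataFrame:
    """Aggregate an LD pair table (or stream of tables) into distance bins.

    A pair at distance d lands in bin k with (k−1)·width < d ≤ k·width.
    Returns one row per bin with columns ``bin_bp`` (upper edge),
    ``mean_r2``, ``mean_abs_dprime``, ``n_pairs``, ``mean_distance_bp``.
    Empty bins carry NaN means (never zeros) and ``n_pairs = 0``; the
    returned grid always spans the full (0, max_bp] range.
    """
    n_bins = int(np.ceil(max_bp / bin_width_bp))
    sum_r2 = np.zeros(n_bins)
    sum_dp = np.zeros(n_bins)
    sum_d = np.zeros(n_bins)
    n = np.zeros(n_bins, dtype=np.int64)
    if isinstance(pairs, pd.DataFrame):
        pairs = [pairs]
    for frame in pairs:
        frame = _clean(frame)
        d = frame["distance_bp"].to_numpy(dtype=np.float64)
        keep = (d > 0) & (d <= max_bp)
        d = d[keep]
        if d.size == 0:
            continue
        k = np.ceil(d / bin_width_bp).astype(np.int64) - 1
        np.add.at(sum_r2, k, frame["r2"].to_numpy()[keep])
        np.add.at(sum_dp, k, np.abs(frame["Dprime"].to_numpy()[keep]))
        np.add.at(sum_d, k, d)
        np.add.at(n, k, 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_r2 = np.where(n > 0, sum_r2 / n, np.nan)
        mean_dp = np.where(n > 0, sum_dp / n, np.nan)
        mean_d = np.where(n > 0, sum_d / n, np.nan)
    return pd.DataFrame({
        "bin_bp": (np.arange(1, n_bins + 1) * bin_width_bp).astype(np.int64),
        "mean_r2": mean_r2,
        "mean_abs_dprime": mean_dp,
        "n_pairs": n,
        "mean_distance_bp": mean_d,
    })


def chromosome_summary(dataset, adjacent_pairs: pd.DataFrame) -> pd.DataFrame:
    """Per-chromosome (plus genome-wide) adjacent-pair LD and spacing table.

    One row per chromosome with SNP count, chromosome span, mean/min/max
    adjacent gap, and mean ± SD (sample SD, n−1 divisor) of adjacent r² and
    |D'| over non-degenerate pairs; a final ``ALL`` row pools the genome.
    """
    rows = []
    clean_frames = []
    for chrom in dataset.chromosomes:
        sl = dataset.chromosome_slice(chrom)
        pos = dataset.markers["position_bp"].to_numpy()[sl]
        n_snps = pos.size
        sub = adjacent_pairs.loc[adjacent_pairs["chromosome"] == chrom]
        clean = _clean(sub)
        clean_frames.append(clean)
        gaps = np.diff(pos) if n_snps >= 2 else np.array([])
        row = {
            "chromosome": chrom,
            "n_snps": n_snps,
            "length_bp": int(pos.max() - pos.min()) if n_snps >= 2 else 0,
            "mean_gap_bp": float(gaps.mean()) if gaps.size else np.nan,
            "min_gap_bp": float(gaps.min()) if gaps.size else np.nan,
            "max_gap_bp": float(gaps.max()) if gaps.size else np.nan,
            "n_pairs": len(clean),
            "mean_r2": clean["r2"].mean() if len(clean) else np.nan,
            "sd_r2": clean["r2"].std(ddof=1) if len(clean) > 1 else np.nan,
            "mean_abs_dprime": (clean["Dprime"].abs().mean()
                                if len(clean) else np.nan),
            "sd_abs_dprime": (clean["Dprime"].abs().std(ddof=1)
                              if len(clean) > 1 else np.nan),
        }
        rows.append(row)
    all_clean = (pd.concat(clean_frames, ignore_index=True)
                 if clean_frames else _clean(adjacent_pairs))
    gaps_all = []
    for chrom in dataset.chromosomes:
        sl = dataset.chromosome_slice(chrom)
        pos = dataset.markers["position_bp"].to_numpy()[sl]
        if pos.size >= 2:
            gaps_all.append(np.diff(pos))
    gaps_all = np.concatenate(gaps_all) if gaps_all else np.array([])
    rows.append({
        "chromosome": "ALL",
        "n_snps": dataset.n_markers,
        "length_bp": int(sum(r["length_bp"] for r in rows)),
        "mean_gap_bp": float(gaps_all.mean()) if gaps_all.size else np.nan,
        "min_gap_bp": float(gaps_all.min()) if gaps_all.size else np.nan,
        "max_gap_bp": float(gaps_all.max()) if gaps_all.size else np.nan,
        "n_pairs": len(all_clean),
        "mean_r2": all_clean["r2"].mean() if len(all_clean) else np.nan,
        "sd_r2": all_clean["r2"].std(ddof=1) if len(all_clean) > 1 else np.nan,
        "mean_abs_dprime": (all_clean["Dprime"].abs().mean()
                            if len(all_clean) else np.nan),
        "sd_abs_dprime": (all_clean["Dprime"].abs().std(ddof=1)
                          if len(all_clean) > 1 else np.nan),
    })
    return pd.DataFrame(rows)


def threshold_proportions(pairs: pd.DataFrame,
                          thresholds=(0.2, 0.3)) -> dict[float, float]:
    """Fraction of non-degenerate pairs with r² above each threshold."""
    clean = _clean(pairs)
    if len(clean) == 0:
        return {float(t): np.nan for t in thresholds}
    r2 = clean["r2"].to_numpy()
    return {float(t): float((r2 > t).mean()) for t in thresholds}
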