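"""Cross-population LD consistency and persistence of LD phase.

Two related statistics for a pair of populations genotyped on a common
marker set:

* **Persistence of LD phase** — the Pearson correlation, within a distance
  bin, of the *signed* LD correlation r of matched SNP pairs in the two
  populations.  High values at a distance mean marker–QTL phase carries
  over between populations at that scale, the condition for multi-breed
  genomic evaluation to work.  Signs are only comparable because the allele
  coding is frozen once when the panels are merged.

* **Adjacent-pair LD consistency** — the per-chromosome Pearson correlation
  of sqrt(r²) (unsigned) of matched adjacent marker pairs.

Both use the standard sample Pearson correlation (n−1 normalisation); a
correlation is reported only where at least three matched pairs exist and
both populations show positive variance.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["phase_correlation", "adjacent_consistency", "match_pairs"]

_MIN_PAIRS = 3


def match_pairs(pairs_a: pd.DataFrame, pairs_b: pd.DataFrame
                ) -> pd.DataFrame:
    """Inner-join two LD pair tables on (id_i, id_j), dropping degenerates.

    Returns a frame with suffixed statistic columns (``r_a``/``r_b`` etc.)
    and the shared distance/chromosome columns.
    """
    keep = ["chromosome", "id_i", "id_j", "distance_bp", "r", "r2",
            "degenerate"]
    a = pairs_a[keep]
    b = pairs_b[keep]
    merged = a.merge(b, on=["id_i", "id_j"], suffixes=("_a", "_b"))
    merged = merged.loc[~(merged["degenerate_a"].astype(bool)
                          | merged["degenerate_b"].astype(bool))]
    merged = merged.rename(columns={"chromosome_a": "chromosome",
                                    "distance_bp_a": "distance_bp"})
    return merged.reset_index(drop=True)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if x.size < _MIN_PAIRS:
        return np.nan
    sx = x.std(ddof=1)
    sy = y.std(ddof=1)
    if sx <= 0 or sy <= 0:
        return np.nan
    return float(((x - x.mean()) * (y - y.mean())).sum()
                 / ((x.size - 1) * sx * sy))


def phase_correlation(pairs_a: pd.DataFrame, pairs_b: pd.DataFrame,
                      bin_width_bp: int = 100_000,
                      max_bp: int = 15_000_000) -> pd.DataFrame:
    """Per-distance-bin correlation of signed r between two populations.

    Pairs are matched by marker-pair identity; each bin ``(k−1)w < d ≤ kw``
    reports the Pearson correlation of the matched signed-r values and the
    number of matched pairs.  Bins with fewer than three matched pairs or
    zero variance carry NaN.
    """
    matched = match_pairs(pairs_a, pairs_b)
    n_bins = int(np.ceil(max_bp / bin_width_bp))
    d = matched["distance_bp"].to_numpy(dtype=np.float64)
    inside = (d > 0) & (d <= max_bp)
    matched = matched.loc[inside]
    d = d[inside]
    k = np.ceil(d / bin_width_bp).astype(np.int64) - 1
    ra = matched["r_a"].to_numpy()
    rb = matched["r_b"].to_numpy()
    corr = np.full(n_bins, np.nan)
    n_common = np.zeros(n_bins, dtype=np.int64)
    for b in range(n_bins):
        sel = k == b
        n_common[b] = int(sel.sum())
        if n_common[b] >= _MIN_PAIRS:
            corr[b] = _pearson(ra[sel], rb[sel])
    return pd.DataFrame({
        "bin_bp": (np.arange(1, n_bins + 1) * bin_width_bp).astype(np.int64),
        "correlation": corr,
        "n_common_pairs": n_common,
    })


def adjacent_consistency(pairs_a: pd.DataFrame, pairs_b: pd.DataFrame
                         ) -> pd.DataFrame:
    """Per-chromosome correlation of sqrt(r²) of matched adjacent pairs.

    Returns one row per chromosome plus a pooled ``ALL`` row.
    """
    matched = match_pairs(pairs_a, pairs_b)
    xa = np.sqrt(matched["r2_a"].to_numpy())
    xb = np.sqrt(matched["r2_b"].to_numpy())
    chroms = matched["chromosome"].to_numpy()
    rows = []
    seen: dict[str, None] = {}
    for c in chroms:
        seen.setdefault(c, None)
    for chrom in seen:
        sel = chroms == chrom
        rows.append({"chromosome": chrom,
                     "correlation": _pearson(xa[sel], xb[sel]),
                     "n_common_pairs": int(sel.sum())})
    rows.append({"chromosome": "ALL",
                 "correlation": _pearson(xa, xb),
                 "n_common_pairs": int(len(matched))})
    return pd.DataFrame(rows)
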