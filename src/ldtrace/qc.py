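"""Per-population genotype quality control.

Filters are applied in a fixed order — samples by missingness, then SNPs by
call rate, minor allele frequency and Hardy–Weinberg exact test — and every
step's attrition is recorded in a :class:`QCReport`.  Each population panel
is filtered separately before the panels are intersected on common SNPs
(:func:`ldtrace.plink.merge_common_snps`), so a marker's frequencies are
judged within the population where they matter.

The HWE test is the exact conditional test on genotype counts given allele
counts, which stays valid at the small sample sizes (a few dozen diploids)
typical of livestock diversity panels where a chi-square approximation does
not.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import MISSING, GenotypeDataset

__all__ = ["QCConfig", "QCReport", "allele_frequency", "allele_frequencies",
           "hwe_exact_test", "run_qc"]


@dataclass(frozen=True)
class QCConfig:
    """Thresholds for the four QC filters.

    maf_min : drop SNPs with minor allele frequency strictly below this
        (a SNP at exactly the threshold is kept).
    snp_call_rate_min : drop SNPs whose fraction of called genotypes falls
        below this.
    hwe_p_min : drop SNPs whose HWE exact p-value is strictly below this.
    individual_missing_max : drop samples whose missing-genotype fraction
        exceeds this.
    """

    maf_min: float = 0.05
    snp_call_rate_min: float = 0.95
    hwe_p_min: float = 1e-6
    individual_missing_max: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 <= self.maf_min <= 0.5:
            raise ValueError("maf_min must be in [0, 0.5]")
        for name in ("snp_call_rate_min", "hwe_p_min",
                     "individual_missing_max"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class QCReport:
    """Attrition bookkeeping for one QC run."""

    population: str
    n_samples_initial: int = 0
    n_markers_initial: int = 0
    samples_removed_missingness: int = 0
    markers_removed_call_rate: int = 0
    markers_removed_maf: int = 0
    markers_removed_hwe: int = 0
    n_samples_final: int = 0
    n_markers_final: int = 0
    warnings: list[str] = field(default_factory=list)

    def check_conservation(self) -> bool:
        """initial − Σ removed == final, for samples and markers alike."""
        ok_s = (self.n_samples_initial - self.samples_removed_missingness
                == self.n_samples_final)
        ok_m = (self.n_markers_initial - self.markers_removed_call_rate
                - self.markers_removed_maf - self.markers_removed_hwe
                == self.n_markers_final)
        return ok_s and ok_m

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("samples_initial", self.n_samples_initial),
            ("samples_removed_missingness", self.samples_removed_missingness),
            ("samples_final", self.n_samples_final),
            ("markers_initial", self.n_markers_initial),
            ("markers_removed_call_rate", self.markers_removed_call_rate),
            ("markers_removed_maf", self.markers_removed_maf),
            ("markers_removed_hwe", self.markers_removed_hwe),
            ("markers_final", self.n_markers_final),
        ]
        return pd.DataFrame(rows, columns=["step", "count"]).assign(
            population=self.population)


def allele_frequencies(dataset: GenotypeDataset
                       ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Allele-B frequency, MAF and called-genotype count for every marker.

    Returns ``(freq_b, maf, n_called)`` arrays over markers; a marker with
    zero called genotypes gets ``freq_b = maf = nan`` (flagged, not fatal).
    """
    g = dataset.genotypes
    called = g != MISSING
    n_called = called.sum(axis=0)
    dose = np.where(called, g, 0).sum(axis=0, dtype=np.int64)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq_b = np.where(n_called > 0, dose / (2.0 * n_called), np.nan)
    maf = np.minimum(freq_b, 1.0 - freq_b)
    return freq_b, maf, n_called.astype(np.int64)


def allele_frequency(dataset: GenotypeDataset, marker_id: str
                     ) -> tuple[float, float, int]:
    """``(freq_b, maf, n_called)`` for one marker, by id."""
    idx = np.flatnonzero((dataset.markers["id"] == marker_id).to_numpy())
    if idx.size == 0:
        raise KeyError(f"marker {marker_id!r} not in dataset")
    freq_b, maf, n_called = allele_frequencies(dataset)
    j = int(idx[0])
    return float(freq_b[j]), float(maf[j]), int(n_called[j])


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided exact test of Hardy–Weinberg proportions.

    Conditions on the observed allele counts and sums the probabilities of
    all heterozygote counts whose conditional probability does not exceed
    that of the observed count (the mid-free two-sided convention used by
    PLINK).  Degenerate tables (monomorphic, or n = 0 handled by caller)
    return 1.0.  Symmetric in ``n_AA`` and ``n_aa``.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("at least one genotype required")
    n_a1 = 2 * n_AA + n_Aa
    n_a2 = 2 * n_aa + n_Aa
    rare = min(n_a1, n_a2)
    if rare == 0:
        return 1.0
    hets = np.arange(rare % 2, rare + 1, 2)
    # log P(het = h | allele counts) up to a constant:
    #   P(h) propto 2^h / ( ((n_a1-h)/2)! * h! * ((n_a2-h)/2)! )
    lg = math.lgamma
    logp = np.array([
        h * math.log(2.0) - lg((n_a1 - h) // 2 + 1) - lg(h + 1)
        - lg((n_a2 - h) // 2 + 1)
        for h in hets])
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    obs = probs[np.searchsorted(hets, n_Aa)]
    p = probs[probs <= obs * (1.0 + 1e-12)].sum()
    return float(min(1.0, p))


def _hwe_pvalues(dataset: GenotypeDataset) -> np.ndarray:
    g = dataset.genotypes
    p = np.ones(dataset.n_markers)
    n0 = (g == 0).sum(axis=0)
    n1 = (g == 1).sum(axis=0)
    n2 = (g == 2).sum(axis=0)
    for j in range(dataset.n_markers):
        if n0[j] + n1[j] + n2[j] >= 1:
            p[j] = hwe_exact_test(int(n0[j]), int(n1[j]), int(n2[j]))
    return p


def run_qc(dataset: GenotypeDataset, config: QCConfig | None = None
           ) -> tuple[GenotypeDataset, QCReport]:
    """Apply the sample and SNP filters in order and report attrition.

    Order: (1) samples by missing fraction, (2) SNPs by call rate, (3) SNPs
    by MAF, (4) SNPs by HWE exact p — each step computed on the matrix left
    by the previous one.
    """
    config = config or QCConfig()
    pop = ",".join(dataset.populations) or "<empty>"
    report = QCReport(population=pop,
                      n_samples_initial=dataset.n_samples,
                      n_markers_initial=dataset.n_markers)

    # 1. samples by missingness
    if dataset.n_markers > 0:
        miss_frac = (dataset.genotypes == MISSING).mean(axis=1)
    else:
        miss_frac = np.zeros(dataset.n_samples)
    keep_s = miss_frac <= config.individual_missing_max
    report.samples_removed_missingness = int((~keep_s).sum())
    ds = dataset.select_samples(keep_s)
    if ds.n_samples == 0:
        # call rate is 0 everywhere with no samples: all markers fall at step 2
        report.warnings.append("no samples survive the missingness filter")
        report.markers_removed_call_rate = ds.n_markers
        report.n_samples_final = 0
        report.n_markers_final = 0
        return ds.select_markers(np.zeros(ds.n_markers, dtype=bool)), report

    # 2. SNP call rate
    called_frac = (ds.genotypes != MISSING).mean(axis=0)
    keep_cr = called_frac >= config.snp_call_rate_min
    report.markers_removed_call_rate = int((~keep_cr).sum())
    ds = ds.select_markers(keep_cr)

    # 3. MAF (strictly-below rule; nan MAF from zero calls is also dropped)
    _, maf, _ = allele_frequencies(ds)
    keep_maf = ~(np.isnan(maf) | (maf < config.maf_min))
    report.markers_removed_maf = int((~keep_maf).sum())
    ds = ds.select_markers(keep_maf)

    # 4. HWE exact test
    pvals = _hwe_pvalues(ds)
    keep_hwe = pvals >= config.hwe_p_min
    report.markers_removed_hwe = int((~keep_hwe).sum())
    ds = ds.select_markers(keep_hwe)

    report.n_samples_final = ds.n_samples
    report.n_markers_final = ds.n_markers
    if ds.n_markers == 0:
        report.warnings.append("no markers survive QC")
    return ds, report
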