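"""Model/Results front end for the LD analyses.

Two modelling objects tie the pipeline stages together in the style of
statsmodels: a model is constructed from data plus configuration, ``fit()``
does the work, and the returned results object carries the estimates,
diagnostics, a ``summary()`` table and plotting helpers.

* :class:`NeHistoryModel` — one population panel -> QC, pairwise LD to
  15 Mb, 100 Kb decay bins, adjacent-pair chromosome summaries and the
  Sved-inversion Ne trajectory.
* :class:`PhasePersistenceModel` — two population panels on a shared
  marker coding -> per-bin persistence of LD phase (correlation of signed
  r) and per-chromosome adjacent-pair LD consistency (correlation of
  sqrt(r²)).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import decay, ld, ne, phase, plink, qc
from .datamodel import GenotypeDataset

__all__ = ["NeHistoryModel", "NeHistoryResults",
           "PhasePersistenceModel", "PhasePersistenceResults"]


class NeHistoryModel:
    """LD decay and historical Ne for one population panel.

    Parameters
    ----------
    dataset : GenotypeDataset
        Genotypes of a single population (other populations present in the
        dataset are dropped with a note in the results).
    qc_config : QCConfig, optional
        Filters applied before analysis; pass ``apply_qc=False`` to analyse
        the panel as-is (e.g. when it was already filtered upstream).
    ne_config : NeConfig, optional
        Defaults to 1 cM/Mb and the (0.01, 0.99) inclusion band, with
        ``n_haplotypes`` taken from the post-QC sample count.
    bin_width_bp, max_distance_bp : the decay grid; the defaults give the
        150-bin (0, 15 Mb] grid probing ~3 to 500 generations.
    """

    def __init__(self, dataset: GenotypeDataset,
                 qc_config: qc.QCConfig | None = None,
                 ne_config: ne.NeConfig | None = None,
                 bin_width_bp: int = 100_000,
                 max_distance_bp: int = 15_000_000,
                 apply_qc: bool = True):
        if len(dataset.populations) > 1:
            dataset = dataset.subset_population(dataset.populations[0])
        self.dataset = dataset
        self.qc_config = qc_config or qc.QCConfig()
        self.ne_config = ne_config
        self.bin_width_bp = int(bin_width_bp)
        self.max_distance_bp = int(max_distance_bp)
        self.apply_qc = apply_qc

    @classmethod
    def from_plink(cls, prefix: str, population_label: str = "pop",
                   binary: bool = False, **kwargs) -> "NeHistoryModel":
        """Build from ``prefix.ped/.map`` (or ``.bed/.bim/.fam``)."""
        if binary:
            ds = plink.read_plink_binary(prefix + ".bed", prefix + ".bim",
                                         prefix + ".fam", population_label)
        else:
            ds = plink.read_plink_text(prefix + ".ped", prefix + ".map",
                                       population_label)
        return cls(ds, **kwargs)

    def fit(self) -> "NeHistoryResults":
        if self.apply_qc:
            filtered, report = qc.run_qc(self.dataset, self.qc_config)
        else:
            filtered, report = self.dataset, None
        ne_config = self.ne_config or ne.NeConfig(
            n_haplotypes=max(2, 2 * filtered.n_samples))
        adjacent = ld.adjacent_pair_ld(filtered)
        binned = decay.bin_pairs(
            ld.windowed_pair_ld(filtered, self.max_distance_bp),
            bin_width_bp=self.bin_width_bp, max_bp=self.max_distance_bp)
        trajectory = ne.ne_trajectory(binned, ne_config)
        chrom_summary = decay.chromosome_summary(filtered, adjacent)
        proportions = decay.threshold_proportions(adjacent)
        return NeHistoryResults(
            model=self, dataset=filtered, qc_report=report,
            ne_config=ne_config, adjacent_pairs=adjacent, binned=binned,
            trajectory=trajectory, chromosome_summary=chrom_summary,
            adjacent_r2_proportions=proportions)


@dataclass
class NeHistoryResults:
    """Fitted LD decay curve and Ne trajectory for one population."""

    model: NeHistoryModel
    dataset: GenotypeDataset
    qc_report: qc.QCReport | None
    ne_config: ne.NeConfig
    adjacent_pairs: pd.DataFrame
    binned: pd.DataFrame
    trajectory: pd.DataFrame
    chromosome_summary: pd.DataFrame
    adjacent_r2_proportions: dict[float, float]

    @property
    def population(self) -> str:
        pops = self.dataset.populations
        return pops[0] if pops else "<empty>"

    def ne_at(self, generations: float) -> float:
        """Ne at the included trajectory point nearest to ``generations``."""
        inc = self.trajectory.loc[self.trajectory["included"]]
        if inc.empty:
            return float("nan")
        idx = (inc["t_generations"] - generations).abs().idxmin()
        return float(inc.loc[idx, "Ne"])

    def recent_ne(self) -> float:
        """Ne at the most recent included point (largest bin distance)."""
        inc = self.trajectory.loc[self.trajectory["included"]]
        if inc.empty:
            return float("nan")
        return float(inc.loc[inc["t_generations"].idxmin(), "Ne"])

    def mean_adjacent_r2(self) -> float:
        clean = self.adjacent_pairs.loc[
            ~self.adjacent_pairs["degenerate"].astype(bool)]
        return float(clean["r2"].mean()) if len(clean) else float("nan")

    def summary(self) -> str:
        """Human-readable run summary."""
        lines = [
            "LD decay and historical Ne",
            "=" * 60,
            f"population:            {self.population}",
            f"samples x markers:     {self.dataset.n_samples} x "
            f"{self.dataset.n_markers}",
            f"haplotypes (n):        {self.ne_config.n_haplotypes}",
            f"map scaling:           {self.ne_config.cm_per_mb} cM/Mb",
            f"decay grid:            {self.model.bin_width_bp / 1e3:.0f} Kb "
            f"bins to {self.model.max_distance_bp / 1e6:.0f} Mb "
            f"({len(self.binned)} bins)",
        ]
        if self.qc_report is not None:
            r = self.qc_report
            lines += [
                f"QC attrition:          samples {r.n_samples_initial} -> "
                f"{r.n_samples_final}, markers {r.n_markers_initial} -> "
                f"{r.n_markers_final}",
            ]
        clean = self.adjacent_pairs.loc[
            ~self.adjacent_pairs["degenerate"].astype(bool)]
        if len(clean):
            lines += [
                f"adjacent pairs:        {len(clean)} "
                f"(mean r2 {clean['r2'].mean():.3f}, "
                f"mean |D'| {clean['Dprime'].abs().mean():.3f})",
                "adjacent r2 > t:       " + ", ".join(
                    f"{t:g}: {p:.3f}"
                    for t, p in self.adjacent_r2_proportions.items()),
            ]
        inc = self.trajectory.loc[self.trajectory["included"]]
        if len(inc):
            oldest = inc.loc[inc["t_generations"].idxmax()]
            newest = inc.loc[inc["t_generations"].idxmin()]
            lines += [
                f"Ne trajectory:         {len(inc)} of "
                f"{len(self.trajectory)} bins included",
                f"  oldest point:        t = {oldest['t_generations']:.0f} "
                f"gen, Ne = {oldest['Ne']:.0f}",
                f"  most recent point:   t = {newest['t_generations']:.1f} "
                f"gen, Ne = {newest['Ne']:.0f}",
            ]
        else:
            lines.append("Ne trajectory:         no bins included")
        return "\n".join(lines)

    def plot_decay(self, ax=None):
        """Mean r² against bin distance (basic decay curve)."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        b = self.binned.dropna(subset=["mean_r2"])
        ax.plot(b["bin_bp"] / 1e6, b["mean_r2"], marker=".", lw=1)
        ax.set_xlabel("distance (Mb)")
        ax.set_ylabel("mean $r^2$")
        ax.set_title(f"LD decay — {self.population}")
        return ax

    def plot_trajectory(self, ax=None):
        """Ne against generations in the past (log-log)."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        inc = self.trajectory.loc[self.trajectory["included"]]
        ax.plot(inc["t_generations"], inc["Ne"], marker=".", lw=1)
        ax.set_xscale("log")
        ax.set_xlabel("generations ago")
        ax.set_ylabel("$N_e$")
        ax.set_title(f"historical Ne — {self.population}")
        return ax


class PhasePersistenceModel:
    """Cross-population LD consistency and persistence of LD phase.

    The two datasets must share marker ids and allele coding — either both
    drawn from one merged dataset (see :meth:`from_merged`) or produced by
    the simulator's split with a shared map.  QC, when enabled, runs per
    population first and the panels are then intersected on common SNPs,
    mirroring the per-population-filter-then-merge workflow.
    """

    def __init__(self, dataset_a: GenotypeDataset, dataset_b: GenotypeDataset,
                 qc_config: qc.QCConfig | None = None,
                 bin_width_bp: int = 100_000,
                 max_distance_bp: int = 15_000_000,
                 apply_qc: bool = True):
        self.dataset_a = dataset_a
        self.dataset_b = dataset_b
        self.qc_config = qc_config or qc.QCConfig()
        self.bin_width_bp = int(bin_width_bp)
        self.max_distance_bp = int(max_distance_bp)
        self.apply_qc = apply_qc

    @classmethod
    def from_merged(cls, merged: GenotypeDataset, population_a: str,
                    population_b: str, **kwargs) -> "PhasePersistenceModel":
        return cls(merged.subset_population(population_a),
                   merged.subset_population(population_b),
                   apply_qc=kwargs.pop("apply_qc", False), **kwargs)

    def fit(self) -> "PhasePersistenceResults":
        a, b = self.dataset_a, self.dataset_b
        reports = []
        if self.apply_qc:
            a, rep_a = qc.run_qc(a, self.qc_config)
            b, rep_b = qc.run_qc(b, self.qc_config)
            reports = [rep_a, rep_b]
            merged = plink.merge_common_snps([a, b])
            a = merged.subset_population(a.populations[0])
            b = merged.subset_population(b.populations[0])
        pairs_a = ld.collect_windowed_pair_ld(a, self.max_distance_bp)
        pairs_b = ld.collect_windowed_pair_ld(b, self.max_distance_bp)
        adj_a = ld.adjacent_pair_ld(a)
        adj_b = ld.adjacent_pair_ld(b)
        persistence = phase.phase_correlation(
            pairs_a, pairs_b, self.bin_width_bp, self.max_distance_bp)
        consistency = phase.adjacent_consistency(adj_a, adj_b)
        return PhasePersistenceResults(
            model=self, population_pair=(a.populations[0], b.populations[0]),
            qc_reports=reports, persistence=persistence,
            adjacent_consistency=consistency)


@dataclass
class PhasePersistenceResults:
    """Per-bin phase persistence and per-chromosome LD consistency."""

    model: PhasePersistenceModel
    population_pair: tuple[str, str]
    qc_reports: list
    persistence: pd.DataFrame
    adjacent_consistency: pd.DataFrame

    def mean_persistence(self, max_bp: int | None = None) -> float:
        p = self.persistence.dropna(subset=["correlation"])
        if max_bp is not None:
            p = p.loc[p["bin_bp"] <= max_bp]
        return float(p["correlation"].mean()) if len(p) else float("nan")

    def summary(self) -> str:
        a, b = self.population_pair
        defined = self.persistence.dropna(subset=["correlation"])
        lines = [
            "Persistence of LD phase",
            "=" * 60,
            f"populations:           {a} vs {b}",
            f"bins defined:          {len(defined)} of "
            f"{len(self.persistence)}",
        ]
        if len(defined):
            first = defined.iloc[0]
            lines += [
                f"persistence at {first['bin_bp'] / 1e3:.0f} Kb: "
                f"{first['correlation']:.3f} "
                f"({first['n_common_pairs']} pairs)",
                f"mean persistence:      {defined['correlation'].mean():.3f}",
            ]
        overall = self.adjacent_consistency.loc[
            self.adjacent_consistency["chromosome"] == "ALL", "correlation"]
        if len(overall) and np.isfinite(overall.iloc[0]):
            lines.append(
                f"adjacent consistency:  {overall.iloc[0]:.3f} (genome-wide "
                f"correlation of sqrt(r2))")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Persistence of phase against bin distance."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        p = self.persistence.dropna(subset=["correlation"])
        ax.plot(p["bin_bp"] / 1e6, p["correlation"], marker=".", lw=1)
        ax.set_xlabel("distance (Mb)")
        ax.set_ylabel("correlation of signed r")
        ax.set_title(f"phase persistence — {self.population_pair[0]} vs "
                     f"{self.population_pair[1]}")
        return ax
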