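"""In-memory model for diploid SNP genotype panels.

A :class:`GenotypeDataset` holds an individuals x markers matrix of allele-B
dosage codes together with a marker map and per-sample population labels.
It is the substrate every analysis stage (QC, pairwise LD, decay binning,
phase persistence, Ne history) operates on.

Coding convention
-----------------
Genotypes count copies of ``allele_b`` (0, 1, 2); :data:`MISSING` (-1) marks
a no-call.  A single fixed convention keeps allele frequencies and the sign
of the LD correlation ``r`` unambiguous across modules and across
populations once their panels are merged on a common marker set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Genotype code for a missing call.
MISSING: int = -1

_MARKER_COLUMNS = ["id", "chromosome", "position_bp", "allele_a", "allele_b"]
_SAMPLE_COLUMNS = ["sample_id", "population"]


@dataclass(frozen=True)
class Marker:
    """A biallelic SNP with a physical map position (1-based, bp)."""

    id: str
    chromosome: str
    position_bp: int
    allele_a: str
    allele_b: str

    def __post_init__(self) -> None:
        if self.position_bp < 1:
            raise ValueError(f"marker {self.id}: position_bp must be >= 1")
        if self.allele_a == self.allele_b:
            raise ValueError(f"marker {self.id}: alleles must differ")


class GenotypeDataset:
    """Diploid SNP genotypes with marker map and population labels.

    Parameters
    ----------
    markers : pandas.DataFrame
        Columns ``id, chromosome, position_bp, allele_a, allele_b``.
    samples : pandas.DataFrame
        Columns ``sample_id, population``.
    genotypes : numpy.ndarray
        ``(n_samples, n_markers)`` int8 matrix of allele-B counts with
        :data:`MISSING` for no-calls.

    Markers are stored sorted by ``(chromosome, position_bp)``; the
    constructor sorts and reorders the matrix columns if needed.
    """

    def __init__(self, markers: pd.DataFrame, samples: pd.DataFrame,
                 genotypes: np.ndarray):
        markers = markers.reset_index(drop=True)
        samples = samples.reset_index(drop=True)
        genotypes = np.asarray(genotypes, dtype=np.int8)
        if list(markers.columns) != _MARKER_COLUMNS:
            markers = markers[_MARKER_COLUMNS]
        if list(samples.columns) != _SAMPLE_COLUMNS:
            samples = samples[_SAMPLE_COLUMNS]
        if genotypes.ndim != 2 or genotypes.shape != (len(samples), len(markers)):
            raise ValueError(
                f"genotype matrix shape {genotypes.shape} does not match "
                f"{len(samples)} samples x {len(markers)} markers")
        bad = ~np.isin(genotypes, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("genotype codes must be 0, 1, 2 or MISSING (-1)")
        if markers["id"].duplicated().any():
            dup = markers.loc[markers["id"].duplicated(), "id"].iloc[0]
            raise ValueError(f"duplicate marker id {dup!r}")
        order = np.lexsort((markers["position_bp"].to_numpy(),
                            markers["chromosome"].to_numpy()))
        if not np.array_equal(order, np.arange(len(markers))):
            markers = markers.iloc[order].reset_index(drop=True)
            genotypes = genotypes[:, order]
        self.markers = markers
        self.samples = samples
        self.genotypes = genotypes

    # -- basic views ------------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def chromosomes(self) -> list[str]:
        """Chromosome labels in map order (labels are opaque text)."""
        seen: dict[str, None] = {}
        for c in self.markers["chromosome"]:
            seen.setdefault(c, None)
        return list(seen)

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.samples["population"]:
            seen.setdefault(p, None)
        return list(seen)

    def marker(self, index: int) -> Marker:
        row = self.markers.iloc[index]
        return Marker(str(row["id"]), str(row["chromosome"]),
                      int(row["position_bp"]), str(row["allele_a"]),
                      str(row["allele_b"]))

    def chromosome_slice(self, chromosome: str) -> slice:
        """Column slice covering one chromosome (markers are map-sorted)."""
        mask = (self.markers["chromosome"] == chromosome).to_numpy()
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            return slice(0, 0)
        return slice(int(idx[0]), int(idx[-1]) + 1)

    def select_markers(self, index: np.ndarray) -> "GenotypeDataset":
        """New dataset restricted to the given marker positions (boolean or int index)."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeDataset(self.markers.iloc[index],
                               self.samples, self.genotypes[:, index])

    def select_samples(self, index: np.ndarray) -> "GenotypeDataset":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeDataset(self.markers, self.samples.iloc[index],
                               self.genotypes[index, :])

    def subset_population(self, population: str) -> "GenotypeDataset":
        mask = (self.samples["population"] == population).to_numpy()
        if not mask.any():
            raise KeyError(f"no samples with population label {population!r}")
        return self.select_samples(mask)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"<GenotypeDataset {self.n_samples} samples x "
                f"{self.n_markers} markers, populations={self.populations}>")


def dataset_from_arrays(marker_ids, chromosomes, positions, allele_a, allele_b,
                        sample_ids, populations, genotypes) -> GenotypeDataset:
    """Convenience constructor from plain sequences/arrays."""
    markers = pd.DataFrame({
        "id": list(marker_ids),
        "chromosome": [str(c) for c in chromosomes],
        "position_bp": np.asarray(positions, dtype=np.int64),
        "allele_a": list(allele_a),
        "allele_b": list(allele_b),
    })
    samples = pd.DataFrame({
        "sample_id": list(sample_ids),
        "population": list(populations),
    })
    return GenotypeDataset(markers, samples, genotypes)
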