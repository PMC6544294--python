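"""PLINK text (PED/MAP) and PLINK 1 binary (BED/BIM/FAM) readers and writers.

Both dialects round-trip through :class:`~ldtrace.datamodel.GenotypeDataset`.
The binary codec follows the PLINK 1 specification: magic bytes ``6C 1B``,
mode byte ``01`` (SNP-major), two bits per genotype packed little-endian
within each byte, one padded byte row per marker.

Also provides :func:`merge_common_snps`, which intersects marker sets across
population panels and reconciles allele coding so that allele-B dosages (and
hence the sign of the LD correlation r) are comparable across populations.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .datamodel import MISSING, GenotypeDataset

__all__ = [
    "read_plink_text", "write_plink_text",
    "read_plink_binary", "write_plink_binary",
    "merge_common_snps",
    "PlinkParseError", "BiallelicViolationError", "MergeError",
]

_BED_MAGIC = b"\x6c\x1b"
_BED_SNP_MAJOR = b"\x01"

# 2-bit PLINK codes -> allele-B dosage (A1 = allele_a, A2 = allele_b):
# 00 hom A1 -> 0, 01 missing, 10 het -> 1, 11 hom A2 -> 2
_BED_DECODE = np.array([0, MISSING, 1, 2], dtype=np.int8)
_BED_ENCODE = {0: 0b00, MISSING: 0b01, 1: 0b10, 2: 0b11}


class PlinkParseError(ValueError):
    """Malformed PLINK file content."""


class BiallelicViolationError(PlinkParseError):
    """More than two distinct non-missing alleles observed at one marker."""


class MergeError(ValueError):
    """Inconsistent marker definitions across datasets being merged."""


# ---------------------------------------------------------------------------
# text dialect
# ---------------------------------------------------------------------------

def _read_map(map_path: str | os.PathLike) -> pd.DataFrame:
    rows = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 4:
                raise PlinkParseError(
                    f"{map_path}: line {lineno}: expected 4 columns, "
                    f"got {len(fields)}")
            chrom, snp_id, _cm, bp = fields
            rows.append((chrom, snp_id, int(bp)))
    return pd.DataFrame(rows, columns=["chromosome", "id", "position_bp"])


def read_plink_text(ped_path: str | os.PathLike, map_path: str | os.PathLike,
                    population_label: str,
                    alleles: Mapping[str, tuple[str, str]] | None = None,
                    ) -> GenotypeDataset:
    """Read a PED/MAP pair into a :class:`GenotypeDataset`.

    Allele "0" denotes a missing call; a half-missing genotype (one allele
    "0") is treated as fully missing.  Because PED files carry no allele
    ordering, ``allele_b`` defaults to the lexicographically larger of the
    two observed alleles at each marker; pass ``alleles`` (marker id ->
    ``(allele_a, allele_b)``) to fix a different orientation.  At a marker
    where only one allele is observed, that allele becomes ``allele_a`` and
    ``allele_b`` is the placeholder ``"0"``.

    Raises
    ------
    PlinkParseError
        On a malformed row (names the line number).
    BiallelicViolationError
        If a marker shows more than two distinct non-missing alleles.
    """
    marker_map = _read_map(map_path)
    m = len(marker_map)
    sample_ids: list[str] = []
    allele1_rows: list[np.ndarray] = []
    allele2_rows: list[np.ndarray] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6 + 2 * m:
                raise PlinkParseError(
                    f"{ped_path}: line {lineno}: expected {6 + 2 * m} "
                    f"columns for {m} markers, got {len(fields)}")
            sample_ids.append(fields[1])
            geno = np.array(fields[6:], dtype=object)
            allele1_rows.append(geno[0::2])
            allele2_rows.append(geno[1::2])
    n = len(sample_ids)
    a1 = (np.vstack(allele1_rows) if n else np.empty((0, m), dtype=object))
    a2 = (np.vstack(allele2_rows) if n else np.empty((0, m), dtype=object))

    genotypes = np.full((n, m), MISSING, dtype=np.int8)
    allele_a_col: list[str] = []
    allele_b_col: list[str] = []
    for j in range(m):
        seen = (set(a1[:, j]) | set(a2[:, j])) if n else set()
        observed = sorted(seen - {"0"})
        if len(observed) > 2:
            raise BiallelicViolationError(
                f"marker {marker_map['id'][j]!r}: more than two alleles "
                f"observed: {observed}")
        if alleles is not None and marker_map["id"][j] in alleles:
            aa, ab = alleles[marker_map["id"][j]]
            extra = set(observed) - {aa, ab}
            if extra:
                raise BiallelicViolationError(
                    f"marker {marker_map['id'][j]!r}: observed alleles "
                    f"{sorted(extra)} outside declared pair ({aa}, {ab})")
        elif len(observed) == 2:
            aa, ab = observed[0], observed[1]
        elif len(observed) == 1:
            aa, ab = observed[0], "0"
        else:
            aa, ab = "0", "0"  # fully missing column
        allele_a_col.append(aa)
        allele_b_col.append(ab)
        if n:
            called = (a1[:, j] != "0") & (a2[:, j] != "0")
            dose = (a1[:, j] == ab).astype(np.int8) + (a2[:, j] == ab).astype(np.int8)
            genotypes[called, j] = dose[called]

    markers = pd.DataFrame({
        "id": marker_map["id"], "chromosome": marker_map["chromosome"],
        "position_bp": marker_map["position_bp"].astype(np.int64),
        "allele_a": allele_a_col, "allele_b": allele_b_col,
    })
    samples = pd.DataFrame({"sample_id": sample_ids,
                            "population": [population_label] * n})
    return GenotypeDataset(markers, samples, genotypes)


def write_plink_text(dataset: GenotypeDataset, ped_path: str | os.PathLike,
                     map_path: str | os.PathLike) -> None:
    """Write PED/MAP files re-readable by :func:`read_plink_text`."""
    with open(map_path, "w") as fh:
        for row in dataset.markers.itertuples(index=False):
            fh.write(f"{row.chromosome}\t{row.id}\t0\t{row.position_bp}\n")
    aa = dataset.markers["allele_a"].to_numpy()
    ab = dataset.markers["allele_b"].to_numpy()
    with open(ped_path, "w") as fh:
        for i, srow in enumerate(dataset.samples.itertuples(index=False)):
            fields = [str(srow.population), str(srow.sample_id),
                      "0", "0", "0", "-9"]
            for j in range(dataset.n_markers):
                g = dataset.genotypes[i, j]
                if g == MISSING:
                    fields += ["0", "0"]
                elif g == 0:
                    fields += [aa[j], aa[j]]
                elif g == 1:
                    fields += [aa[j], ab[j]]
                else:
                    fields += [ab[j], ab[j]]
            fh.write(" ".join(fields) + "\n")


# ---------------------------------------------------------------------------
# binary dialect
# ---------------------------------------------------------------------------

def read_plink_binary(bed_path: str | os.PathLike, bim_path: str | os.PathLike,
                      fam_path: str | os.PathLike,
                      population_label: str) -> GenotypeDataset:
    """Read a PLINK 1 binary fileset (SNP-major) into a dataset.

    BIM allele 1 maps to ``allele_a`` and allele 2 to ``allele_b``, so the
    stored codes count copies of allele 2.
    """
    bim = pd.read_csv(bim_path, sep=r"\s+", header=None,
                      names=["chromosome", "id", "cm", "position_bp",
                             "allele_a", "allele_b"],
                      dtype={"chromosome": str, "id": str,
                             "allele_a": str, "allele_b": str})
    fam = pd.read_csv(fam_path, sep=r"\s+", header=None,
                      names=["fid", "iid", "pat", "mat", "sex", "pheno"],
                      dtype=str)
    n, m = len(fam), len(bim)
    with open(bed_path, "rb") as fh:
        header = fh.read(3)
        payload = fh.read()
    if len(header) < 3 or header[:2] != _BED_MAGIC:
        raise PlinkParseError(f"{bed_path}: bad BED magic bytes")
    if header[2:3] != _BED_SNP_MAJOR:
        raise PlinkParseError(f"{bed_path}: not in SNP-major mode")
    bytes_per_marker = (n + 3) // 4
    if len(payload) != bytes_per_marker * m:
        raise PlinkParseError(
            f"{bed_path}: expected {bytes_per_marker * m} data bytes for "
            f"{n} samples x {m} markers, found {len(payload)}")
    raw = np.frombuffer(payload, dtype=np.uint8).reshape(m, bytes_per_marker)
    # unpack 2-bit fields, little-endian within each byte
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    codes2 = (raw[:, :, None] >> shifts) & 0b11          # (m, bpm, 4)
    codes2 = codes2.reshape(m, bytes_per_marker * 4)[:, :n]
    genotypes = _BED_DECODE[codes2].T                    # (n, m)

    markers = bim[["id", "chromosome", "position_bp", "allele_a", "allele_b"]]
    samples = pd.DataFrame({"sample_id": fam["iid"],
                            "population": [population_label] * n})
    return GenotypeDataset(markers, samples,
                           np.ascontiguousarray(genotypes))


def write_plink_binary(dataset: GenotypeDataset, bed_path: str | os.PathLike,
                       bim_path: str | os.PathLike,
                       fam_path: str | os.PathLike) -> None:
    """Write a PLINK 1 binary fileset (SNP-major)."""
    with open(bim_path, "w") as fh:
        for row in dataset.markers.itertuples(index=False):
            fh.write(f"{row.chromosome}\t{row.id}\t0\t{row.position_bp}\t"
                     f"{row.allele_a}\t{row.allele_b}\n")
    with open(fam_path, "w") as fh:
        for row in dataset.samples.itertuples(index=False):
            fh.write(f"{row.population}\t{row.sample_id}\t0\t0\t0\t-9\n")
    n, m = dataset.n_samples, dataset.n_markers
    bytes_per_marker = (n + 3) // 4
    code_lut = np.zeros(4, dtype=np.uint8)
    for dose, bits in _BED_ENCODE.items():
        code_lut[dose % 4] = bits                        # MISSING=-1 -> idx 3
    codes2 = code_lut[dataset.genotypes.T % 4]           # (m, n)
    padded = np.zeros((m, bytes_per_marker * 4), dtype=np.uint8)
    padded[:, :n] = codes2
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    packed = (padded.reshape(m, bytes_per_marker, 4) << shifts).sum(
        axis=2).astype(np.uint8)
    with open(bed_path, "wb") as fh:
        fh.write(_BED_MAGIC + _BED_SNP_MAJOR)
        fh.write(packed.tobytes())


# ---------------------------------------------------------------------------
# merging
# ---------------------------------------------------------------------------

def merge_common_snps(datasets: Sequence[GenotypeDataset]) -> GenotypeDataset:
    """Intersect marker sets across panels and concatenate their samples.

    Markers are matched by (id, chromosome, position); only markers present
    in every input survive.  Allele coding is reconciled against the first
    dataset: where a later dataset labels the alleles in the opposite order,
    its codes are flipped 0<->2 so allele-B dosage means the same haplotype
    orientation everywhere.  This frozen shared coding is what makes signed
    r comparable across populations in the phase-persistence analysis.

    Raises
    ------
    MergeError
        If the same marker id occurs with conflicting positions, or allele
        labels neither match nor swap.
    """
    if len(datasets) < 2:
        raise ValueError("merge_common_snps needs at least two datasets")
    ref = datasets[0]
    keys = [set(zip(d.markers["id"], d.markers["chromosome"],
                    d.markers["position_bp"])) for d in datasets]
    # detect id reuse with conflicting map coordinates
    for d in datasets[1:]:
        lookup = dict(zip(ref.markers["id"],
                          zip(ref.markers["chromosome"],
                              ref.markers["position_bp"])))
        for mid, chrom, pos in zip(d.markers["id"], d.markers["chromosome"],
                                   d.markers["position_bp"]):
            if mid in lookup and lookup[mid] != (chrom, pos):
                raise MergeError(
                    f"marker {mid!r}: conflicting map position "
                    f"{lookup[mid]} vs {(chrom, pos)}")
    common = set.intersection(*keys)
    keep_mask = [
        (mid, chrom, pos) in common
        for mid, chrom, pos in zip(ref.markers["id"],
                                   ref.markers["chromosome"],
                                   ref.markers["position_bp"])]
    kept = ref.select_markers(np.asarray(keep_mask, dtype=bool))
    ref_alleles = {mid: (aa, ab) for mid, aa, ab in zip(
        kept.markers["id"], kept.markers["allele_a"], kept.markers["allele_b"])}
    order_ids = list(kept.markers["id"])

    geno_blocks = [kept.genotypes]
    sample_frames = [kept.samples]
    for d in datasets[1:]:
        col_of = {mid: j for j, mid in enumerate(d.markers["id"])}
        cols = [col_of[mid] for mid in order_ids]
        block = d.genotypes[:, cols].copy()
        for out_j, (mid, src_j) in enumerate(zip(order_ids, cols)):
            aa, ab = (d.markers["allele_a"].iloc[src_j],
                      d.markers["allele_b"].iloc[src_j])
            raa, rab = ref_alleles[mid]
            if (aa, ab) == (raa, rab):
                continue
            if (aa, ab) == (rab, raa):
                col = block[:, out_j]
                flip = col != MISSING
                block[flip, out_j] = 2 - col[flip]
            else:
                raise MergeError(
                    f"marker {mid!r}: allele labels ({aa},{ab}) neither "
                    f"match nor swap reference ({raa},{rab})")
        geno_blocks.append(block)
        sample_frames.append(d.samples)

    samples = pd.concat(sample_frames, ignore_index=True)
    genotypes = np.vstack(geno_blocks)
    return GenotypeDataset(kept.markers, samples, genotypes)
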