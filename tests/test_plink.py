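import numpy as np
import pytest

import ldtrace as lt
from ldtrace import plink
from ldtrace.plink import (BiallelicViolationError, MergeError,
                           PlinkParseError)

from conftest import random_dataset


def test_text_round_trip_random_panel(tmp_path, rng):
    ds = random_dataset(rng, n_samples=20, n_markers=50)
    plink.write_plink_text(ds, tmp_path / "x.ped", tmp_path / "x.map")
    back = plink.read_plink_text(tmp_path / "x.ped", tmp_path / "x.map", "p1")
    assert np.array_equal(back.genotypes, ds.genotypes)
    assert list(back.markers["id"]) == list(ds.markers["id"])
    assert list(back.markers["position_bp"]) == list(ds.markers["position_bp"])


def test_binary_round_trip_random_panel(tmp_path, rng):
    ds = random_dataset(rng, n_samples=21, n_markers=37)  # n not divisible by 4
    plink.write_plink_binary(ds, tmp_path / "x.bed", tmp_path / "x.bim",
                             tmp_path / "x.fam")
    back = plink.read_plink_binary(tmp_path / "x.bed", tmp_path / "x.bim",
                                   tmp_path / "x.fam", "p1")
    assert np.array_equal(back.genotypes, ds.genotypes)
    assert list(back.markers["allele_a"]) == list(ds.markers["allele_a"])


def test_ped_genotype_recoding_conventions(tmp_path):
    # one sample, three markers: hom-B, half-missing, fully missing
    (tmp_path / "t.map").write_text("1 m1 0 100\n1 m2 0 200\n1 m3 0 300\n")
    (tmp_path / "t.ped").write_text("f s1 0 0 0 -9 A A A 0 0 0\n")
    ds = plink.read_plink_text(tmp_path / "t.ped", tmp_path / "t.map", "p",
                               alleles={"m1": ("C", "A")})
    g = ds.genotypes[0]
    assert g[0] == 2          # homozygote for the counted allele
    assert g[1] == lt.MISSING  # half-call treated as missing
    assert g[2] == lt.MISSING


def test_missing_written_as_zero_alleles(tmp_path):
    ds = lt.dataset_from_arrays(["m1"], ["1"], [100], ["A"], ["B"],
                                ["s1"], ["p"], np.array([[lt.MISSING]]))
    plink.write_plink_text(ds, tmp_path / "m.ped", tmp_path / "m.map")
    assert tmp_path.joinpath("m.ped").read_text().split()[6:8] == ["0", "0"]
    plink.write_plink_binary(ds, tmp_path / "m.bed", tmp_path / "m.bim",
                             tmp_path / "m.fam")
    payload = tmp_path.joinpath("m.bed").read_bytes()
    assert payload[:3] == b"\x6c\x1b\x01"
    assert payload[3] & 0b11 == 0b01  # PLINK 1 missing code


def test_single_het_bed_byte(tmp_path):
    ds = lt.dataset_from_arrays(["m1"], ["1"], [100], ["A"], ["B"],
                                ["s1"], ["p"], np.array([[1]], dtype=np.int8))
    plink.write_plink_binary(ds, tmp_path / "h.bed", tmp_path / "h.bim",
                             tmp_path / "h.fam")
    assert tmp_path.joinpath("h.bed").read_bytes()[3] & 0b11 == 0b10
    back = plink.read_plink_binary(tmp_path / "h.bed", tmp_path / "h.bim",
                                   tmp_path / "h.fam", "p")
    assert back.genotypes[0, 0] == 1


def test_empty_marker_dataset_round_trips(tmp_path):
    ds = lt.dataset_from_arrays([], [], [], [], [], ["s1"], ["p"],
                                np.zeros((1, 0), dtype=np.int8))
    plink.write_plink_text(ds, tmp_path / "e.ped", tmp_path / "e.map")
    back = plink.read_plink_text(tmp_path / "e.ped", tmp_path / "e.map", "p")
    assert back.n_markers == 0 and back.n_samples == 1


def test_malformed_ped_row_names_line(tmp_path):
    (tmp_path / "b.map").write_text("1 m1 0 100\n")
    (tmp_path / "b.ped").write_text("f s1 0 0 0 -9 A A\nf s2 0 0 0 -9 A\n")
    with pytest.raises(PlinkParseError, match="line 2"):
        plink.read_plink_text(tmp_path / "b.ped", tmp_path / "b.map", "p")


def test_triallelic_marker_rejected(tmp_path):
    (tmp_path / "t.map").write_text("1 m1 0 100\n")
    (tmp_path / "t.ped").write_text("f s1 0 0 0 -9 A C\nf s2 0 0 0 -9 G G\n")
    with pytest.raises(BiallelicViolationError, match="m1"):
        plink.read_plink_text(tmp_path / "t.ped", tmp_path / "t.map", "p")


def test_truncated_bed_raises_dimension_error(tmp_path, rng):
    ds = random_dataset(rng, n_samples=8, n_markers=10)
    plink.write_plink_binary(ds, tmp_path / "x.bed", tmp_path / "x.bim",
                             tmp_path / "x.fam")
    raw = tmp_path.joinpath("x.bed").read_bytes()
    tmp_path.joinpath("x.bed").write_bytes(raw[:-1])
    with pytest.raises(PlinkParseError, match="bytes"):
        plink.read_plink_binary(tmp_path / "x.bed", tmp_path / "x.bim",
                                tmp_path / "x.fam", "p")
    tmp_path.joinpath("x.bed").write_bytes(b"\x00\x00\x01" + raw[3:])
    with pytest.raises(PlinkParseError, match="magic"):
        plink.read_plink_binary(tmp_path / "x.bed", tmp_path / "x.bim",
                                tmp_path / "x.fam", "p")


def _panel(ids, positions, genotypes, pop, alleles=None):
    m = len(ids)
    aa = [a for a, _ in alleles] if alleles else ["A"] * m
    ab = [b for _, b in alleles] if alleles else ["B"] * m
    n = genotypes.shape[0]
    return lt.dataset_from_arrays(ids, ["1"] * m, positions, aa, ab,
                                  [f"{pop}_{i}" for i in range(n)],
                                  [pop] * n, genotypes)


def test_merge_keeps_exact_intersection():
    g = np.zeros((2, 3), dtype=np.int8)
    d1 = _panel(["a", "b", "c"], [10, 20, 30], g, "p1")
    d2 = _panel(["b", "c", "d"], [20, 30, 40], g, "p2")
    d3 = _panel(["b", "c"], [20, 30], g[:, :2], "p3")
    merged = plink.merge_common_snps([d1, d2, d3])
    assert list(merged.markers["id"]) == ["b", "c"]
    assert merged.n_samples == 6
    assert merged.populations == ["p1", "p2", "p3"]


def test_merge_with_itself_doubles_samples(rng):
    ds = random_dataset(rng, n_samples=5, n_markers=8)
    other = lt.GenotypeDataset(ds.markers,
                               ds.samples.assign(population="p2"),
                               ds.genotypes)
    merged = plink.merge_common_snps([ds, other])
    assert merged.n_markers == ds.n_markers
    assert merged.n_samples == 2 * ds.n_samples


def test_merge_reconciles_swapped_alleles():
    g1 = np.array([[0, 2], [1, 1], [2, 0]], dtype=np.int8)
    d1 = _panel(["a", "b"], [10, 20], g1, "p1")
    # second panel labels marker b's alleles in the opposite order
    g2 = np.array([[0, 0], [1, 2], [2, lt.MISSING]], dtype=np.int8)
    d2 = _panel(["a", "b"], [10, 20], g2, "p2",
                alleles=[("A", "B"), ("B", "A")])
    merged = plink.merge_common_snps([d1, d2])
    col_b = list(merged.markers["id"]).index("b")
    block2 = merged.genotypes[3:, col_b]
    assert list(block2) == [2, 0, lt.MISSING]  # codes flipped, missing kept
    # allele-B frequency now agrees with what p2 carried under its own labels
    from ldtrace.qc import allele_frequencies
    freq, _, _ = allele_frequencies(merged.select_samples(np.arange(3, 6)))
    assert freq[col_b] == pytest.approx(0.5)


def test_merge_conflicting_position_and_alleles_rejected():
    g = np.zeros((2, 1), dtype=np.int8)
    d1 = _panel(["a"], [10], g, "p1")
    d2 = _panel(["a"], [99], g, "p2")
    with pytest.raises(MergeError, match="position"):
        plink.merge_common_snps([d1, d2])
    d3 = _panel(["a"], [10], g, "p2", alleles=[("C", "T")])
    with pytest.raises(MergeError, match="allele"):
        plink.merge_common_snps([d1, d3])


def test_merge_conserves_called_genotypes(rng):
    d1 = random_dataset(rng, n_samples=6, n_markers=12)
    d2 = random_dataset(rng, n_samples=4, n_markers=12)
    d2 = lt.GenotypeDataset(d1.markers, d2.samples.assign(population="p2"),
                            d2.genotypes)
    merged = plink.merge_common_snps([d1, d2])
    called = (merged.genotypes != lt.MISSING).sum()
    assert called == ((d1.genotypes != lt.MISSING).sum()
                      + (d2.genotypes != lt.MISSING).sum())
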