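import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from trioassoc.genotypes_io import (
    MISSING,
    Cohort,
    GenotypeCounts,
    Individual,
    Marker,
    PedMapParseError,
    TriAllelicError,
    genotype_counts,
    read_pedmap,
    write_pedmap,
)

from helpers import cohort_from_dosages


def write_files(tmp_path, ped_lines, map_lines):
    ped = tmp_path / "x.ped"
    mp = tmp_path / "x.map"
    ped.write_text("\n".join(ped_lines) + "\n")
    mp.write_text("\n".join(map_lines) + "\n")
    return ped, mp


MAP2 = ["11 rs1 0 100", "11 rs2 0 200"]


class TestReadPedmap:
    def test_dosage_coding_missing_and_minor_orientation(self, tmp_path):
        # T is the minor allele of rs1 (2 copies vs 4 G); "0 0" is missing
        ped, mp = write_files(
            tmp_path,
            [
                "f1 i1 0 0 1 2 G G A A",
                "f2 i2 0 0 2 1 T G A C",
                "f3 i3 0 0 1 2 T G 0 0",
            ],
            MAP2,
        )
        cohort, trios = read_pedmap(ped, mp)
        rs1 = cohort.marker_index("rs1")
        assert cohort.markers[rs1].allele_minor == "T"
        assert cohort.genotypes[:, rs1].tolist() == [0, 1, 1]
        rs2 = cohort.marker_index("rs2")
        # C rarer than A at rs2; third individual untyped
        assert cohort.markers[rs2].allele_minor == "C"
        assert cohort.genotypes[:, rs2].tolist() == [0, 1, MISSING]
        assert len(trios) == 0
        assert [i.group for i in cohort.individuals] == ["CASE", "CONTROL", "CASE"]

    def test_minor_allele_tie_broken_lexicographically(self, tmp_path):
        ped, mp = write_files(
            tmp_path, ["f1 i1 0 0 1 1 G T", "f2 i2 0 0 1 1 T G"], ["11 rs1 0 100"]
        )
        cohort, _ = read_pedmap(ped, mp)
        assert cohort.markers[0].allele_minor == "G"

    def test_trio_links_resolved_from_parent_columns(self, tmp_path):
        ped, mp = write_files(
            tmp_path,
            [
                "fam1 dad 0 0 1 1 T G A A",
                "fam1 mum 0 0 2 1 G G A C",
                "fam1 kid dad mum 1 2 T G A C",
            ],
            MAP2,
        )
        cohort, trios = read_pedmap(ped, mp)
        assert trios.trios == ((0, 1, 2),)

    def test_malformed_column_count_names_line(self, tmp_path):
        ped, mp = write_files(tmp_path, ["f1 i1 0 0 1 2 G G A"], MAP2)
        with pytest.raises(PedMapParseError, match="line 1"):
            read_pedmap(ped, mp)

    def test_triallelic_marker_named_in_error(self, tmp_path):
        ped, mp = write_files(
            tmp_path,
            ["f1 i1 0 0 1 2 G G A A", "f2 i2 0 0 1 1 T C A A"],
            MAP2,
        )
        with pytest.raises(TriAllelicError, match="rs1"):
            read_pedmap(ped, mp)


class TestWritePedmap:
    def test_empty_cohort_gives_empty_ped_valid_map(self, tmp_path):
        cohort = cohort_from_dosages(np.empty((0, 2), dtype=np.int8))
        ped, mp = tmp_path / "o.ped", tmp_path / "o.map"
        write_pedmap(cohort, ped, mp)
        assert ped.read_text() == ""
        assert len(mp.read_text().splitlines()) == 2

    def test_missing_genotype_written_as_zero_pair(self, tmp_path):
        cohort = cohort_from_dosages([[MISSING]])
        ped, mp = tmp_path / "o.ped", tmp_path / "o.map"
        write_pedmap(cohort, ped, mp)
        assert ped.read_text().split()[-2:] == ["0", "0"]

    def test_round_trip_random_cohort(self, tmp_path, rng):
        dosages = rng.choice([MISSING, 0, 0, 0, 1, 1, 2], size=(50, 10)).astype(np.int8)
        groups = rng.choice(["CASE", "CONTROL", "ADHD"], size=50).tolist()
        cohort = cohort_from_dosages(dosages, groups)
        ped, mp = tmp_path / "o.ped", tmp_path / "o.map"
        write_pedmap(cohort, ped, mp)
        first, _ = read_pedmap(ped, mp)
        write_pedmap(first, ped, mp)
        again, _ = read_pedmap(ped, mp)
        assert again == first

    def test_round_trip_preserves_trios(self, tmp_path):
        from trioassoc.genotypes_io import TrioSet

        import dataclasses

        cohort = cohort_from_dosages([[0], [1], [1]], ["CONTROL", "CONTROL", "CASE"])
        # trio links resolve within a family: give all three the same fid
        cohort.individuals = [
            dataclasses.replace(ind, fid="fam1") for ind in cohort.individuals
        ]
        trios = TrioSet(trios=((0, 1, 2),))
        ped, mp = tmp_path / "o.ped", tmp_path / "o.map"
        write_pedmap(cohort, ped, mp, trioset=trios)
        _, back = read_pedmap(ped, mp)
        assert back.trios == trios.trios


@given(
    dosages=st.lists(
        st.lists(st.sampled_from([MISSING, 0, 1, 2]), min_size=3, max_size=3),
        min_size=1,
        max_size=12,
    )
)
def test_write_read_is_identity_on_canonical_cohorts(tmp_path_factory, dosages):
    """read(write(c)) == c once the minor-allele orientation is canonical."""
    tmp = tmp_path_factory.mktemp("rt")
    cohort = cohort_from_dosages(np.array(dosages, dtype=np.int8))
    ped, mp = tmp / "a.ped", tmp / "a.map"
    write_pedmap(cohort, ped, mp)
    canonical, _ = read_pedmap(ped, mp)
    write_pedmap(canonical, ped, mp)
    back, _ = read_pedmap(ped, mp)
    assert back == canonical


class TestGenotypeCounts:
    def test_symmetric_counts(self):
        cohort = cohort_from_dosages([[2], [1], [0]])
        c = genotype_counts(cohort, "m1")
        assert (c.n_hom_minor, c.n_het, c.n_hom_major, c.n_missing) == (1, 1, 1, 0)
        assert c.maf == 0.5

    def test_all_missing_gives_undefined_maf(self):
        cohort = cohort_from_dosages([[MISSING], [MISSING]])
        c = genotype_counts(cohort, "m1")
        assert c.maf is None
        assert c.missing_rate == 1.0

    def test_published_control_genotype_row_reproduces_printed_maf(self):
        # hom-minor 47, het 118, hom-major 67 -> 212 vs 252 alleles, MAF 0.457
        c = GenotypeCounts(n_hom_minor=47, n_het=118, n_hom_major=67)
        assert (c.allele_count_minor, c.allele_count_major) == (212, 252)
        assert round(c.maf, 3) == 0.457

    def test_unknown_marker_and_group_raise(self):
        cohort = cohort_from_dosages([[0]])
        with pytest.raises(KeyError):
            genotype_counts(cohort, "nope")
        with pytest.raises(KeyError):
            genotype_counts(cohort, "m1", ("NOT_A_GROUP",))

    @given(
        dosages=st.lists(st.sampled_from([MISSING, 0, 1, 2]), min_size=1, max_size=40)
    )
    def test_allele_count_identity_and_dosage_involution(self, dosages):
        d = np.array(dosages, dtype=np.int8)
        c = GenotypeCounts.from_dosages(d)
        n_nonmiss = int((d != MISSING).sum())
        assert c.allele_count_minor + c.allele_count_major == 2 * n_nonmiss
        flipped = GenotypeCounts.from_dosages(np.where(d == MISSING, MISSING, 2 - d))
        assert flipped.allele_count_minor == c.allele_count_major
        if c.maf is not None:
            assert flipped.maf == pytest.approx(1 - c.maf)
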