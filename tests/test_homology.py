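"""Painting-map algebra: inversion, composition, census, association detection."""

import pytest

from karyopaint import (
    check_matrix_consistency,
    compose_maps,
    count_homologous_segments,
    detect_syntenic_associations,
    invert_map,
    painting_map_between,
    read_ancestral_matrix,
    read_painting_table,
    write_ancestral_matrix,
)
from karyopaint.painting import PaintingError, PaintingMap
from karyopaint.segments import SegmentRef


def identity_map(species, labels):
    return PaintingMap(species, species, tuple((l, (SegmentRef(l),)) for l in labels))


class TestInvert:
    def test_split_probe_inverts_to_two_entries(self, tml_tin_map):
        inv = invert_map(tml_tin_map)
        assert inv.probe_species == "TIN" and inv.target_species == "TML"
        assert inv.target_chromosomes_of("16") == ("4",)
        assert inv.target_chromosomes_of("26") == ("4",)

    def test_involution(self, tml_tin_map):
        assert invert_map(invert_map(tml_tin_map)) == tml_tin_map

    def test_identity_fixed_point(self):
        m = identity_map("TIN", ["1", "2", "X"])
        assert invert_map(m) == m

    def test_arm_annotations_change_sides_losslessly(self):
        arm_map = read_painting_table(
            "# probe_species: TML\n# target_species: LAF\nprobe\ttargets\n8p\t17q-dist\n"
        )
        inv = invert_map(arm_map)
        assert inv.probe_units == ("17q-dist",)
        assert inv.entries[0][1] == (SegmentRef("8", "p"),)
        assert invert_map(inv) == arm_map


class TestCompose:
    def test_compose_with_identity(self, tml_tin_map):
        ident = identity_map("TIN", sorted({t.chromosome for _, ts in tml_tin_map.entries for t in ts}))
        composed = compose_maps(tml_tin_map, ident)
        assert composed.as_dict() == {
            u: tuple(SegmentRef(t.chromosome) for t in ts) for u, ts in tml_tin_map.entries
        }

    def test_species_mismatch_rejected(self, tml_tin_map):
        with pytest.raises(PaintingError, match="cannot compose"):
            compose_maps(tml_tin_map, tml_tin_map)

    def test_two_step_homology(self, apk_matrix, tml_tin_map):
        # HSA 6 lies on TML 3, which paints TIN 5
        hsa_tml = painting_map_between(apk_matrix, "HSA", "TML")
        composed = compose_maps(hsa_tml, tml_tin_map)
        assert composed.target_chromosomes_of("6") == ("5",)

    def test_associative_on_fixtures(self, apk_matrix, tml_tin_map):
        hsa_tml = painting_map_between(apk_matrix, "HSA", "TML")
        tin_ident = identity_map("TIN", [str(i) for i in range(1, 28)])
        left = compose_maps(compose_maps(hsa_tml, tml_tin_map), tin_ident)
        right = compose_maps(hsa_tml, compose_maps(tml_tin_map, tin_ident))
        assert left.as_dict() == right.as_dict()

    def test_paths_carry_evidence_chains(self, apk_matrix, tml_tin_map):
        hsa_tml = painting_map_between(apk_matrix, "HSA", "TML")
        composed = compose_maps(hsa_tml, tml_tin_map)
        chains = composed.paths[("5", "1")]  # HSA 5 → TML 1 → TIN 1
        assert chains[0][0].chromosome == "1"


class TestCensus:
    def test_identity_census_equals_chromosome_count(self):
        census = count_homologous_segments(identity_map("TIN", [str(i) for i in range(1, 11)]))
        assert census.total == 10
        assert census.multi_signal_probes == ()

    def test_permutation_invariance(self, tml_tin_map):
        reversed_map = PaintingMap(
            tml_tin_map.probe_species, tml_tin_map.target_species, tuple(reversed(tml_tin_map.entries))
        )
        assert count_homologous_segments(reversed_map).total == count_homologous_segments(tml_tin_map).total

    def test_autosomal_convention_drops_sex_probes(self, tml_tin_map):
        assert count_homologous_segments(tml_tin_map, "autosomal").total == 27

    def test_unknown_convention_rejected(self, tml_tin_map):
        with pytest.raises(ValueError):
            count_homologous_segments(tml_tin_map, "arms")


class TestAssociations:
    @pytest.fixture()
    def toy_composed(self):
        hsa_b = read_painting_table(
            "# probe_species: HSA\n# target_species: TML\nprobe\ttargets\n"
            "1\t1\n2\t1;2\n3\t2\n4\t3\n"
        )
        b_c = read_painting_table(
            "# probe_species: TML\n# target_species: TIN\nprobe\ttargets\n1\t1\n2\t2\n3\t3\n"
        )
        return compose_maps(hsa_b, b_c)

    def test_cooccurrence_hit(self, toy_composed):
        report = detect_syntenic_associations(toy_composed, [("1", "2")])
        assert [h.target_chromosome for h in report.hits] == ["1"]
        assert report.is_present(("1", "2"))

    def test_absent_pair_reported_explicitly(self, toy_composed):
        report = detect_syntenic_associations(toy_composed, [("1", "4")])
        assert report.hits == ()
        assert report.absent == (frozenset({"1", "4"}),)

    def test_unknown_chromosome_rejected(self, toy_composed):
        with pytest.raises(PaintingError, match="unknown chromosome"):
            detect_syntenic_associations(toy_composed, [("1", "99")])

    def test_evidence_chains_name_both_members(self, toy_composed):
        (hit,) = detect_syntenic_associations(toy_composed, [("1", "2")]).hits
        members = {chain[0].chromosome for chain in hit.evidence}
        assert members == {"1", "2"}


class TestMatrixConsistency:
    def test_full_fixture_is_consistent(self, apk_matrix, tml_tin_map):
        """Every ancestral row's TML/TIN cell pair agrees with the painting map."""
        assert check_matrix_consistency(apk_matrix, tml_tin_map) == []

    def test_injected_contradiction_is_found(self, apk_matrix, tml_tin_map):
        text = write_ancestral_matrix(apk_matrix)
        # row 2 pairs TML 2 with TIN 3; forge the TIN cell to 5
        corrupted = read_ancestral_matrix(text.replace("2\t3qcd\t2\t2\t2\t3\t1/19", "2\t3qcd\t2\t2\t2\t5\t1/19"))
        findings = check_matrix_consistency(corrupted, tml_tin_map)
        assert len(findings) == 1
        assert findings[0].subject == "APK 2"

    def test_species_not_in_matrix_rejected(self, apk_matrix):
        foreign = identity_map("TIN", ["1"])
        m = PaintingMap("APK", "APK", foreign.entries)
        with pytest.raises(PaintingError):
            check_matrix_consistency(apk_matrix, m)
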