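"""Painting-table and ancestral-matrix readers, writers, deconvolution, fixtures."""

import pytest

from karyopaint import (
    deconvolve_probe_peaks,
    load_fixture,
    read_ancestral_matrix,
    read_painting_table,
    write_ancestral_matrix,
    write_painting_table,
)
from karyopaint.ancestral import AncestralMatrixError
from karyopaint.fixtures import FixtureError, fixture_text
from karyopaint.painting import PaintingError
from karyopaint.segments import SegmentRef

SIMPLE = """# probe_species: TML
# target_species: TIN
probe\ttargets
8\t19;22
Y\tY
"""


class TestReadPaintingTable:
    def test_multi_target_row(self):
        m = read_painting_table(SIMPLE)
        assert m.as_dict()["8"] == (SegmentRef("19"), SegmentRef("22"))

    def test_sex_chromosome_row(self):
        assert read_painting_table(SIMPLE).as_dict()["Y"] == (SegmentRef("Y"),)

    def test_empty_target_field_rejected(self):
        with pytest.raises(PaintingError):
            read_painting_table(SIMPLE + "5\t\n")

    def test_unknown_species_rejected(self):
        with pytest.raises(PaintingError, match="unknown species"):
            read_painting_table(SIMPLE.replace("TML", "ZZZ"))

    def test_conflicting_duplicate_rows_rejected(self):
        with pytest.raises(PaintingError, match="conflicting"):
            read_painting_table(SIMPLE + "8\t19\n")

    def test_identical_duplicate_rows_collapsed(self, caplog):
        # the TML 20 probe occupies two flow peaks (NOR heteromorphism):
        # the printed table repeats the row, the reader keeps one copy
        import logging

        with caplog.at_level(logging.INFO, logger="karyopaint.painting"):
            m = read_painting_table(SIMPLE + "8\t19;22\n")
        assert m.probe_units.count("8") == 1
        assert any("duplicate" in r.message for r in caplog.records)


@pytest.mark.parametrize(
    "name", ["tml_laf_arms.tsv", "tml_pca_arms.tsv", "tml_tin_arms.tsv"]
)
def test_painting_table_round_trips_byte_identically(name):
    text = fixture_text(name)
    body = "\n".join(l for l in text.splitlines() if not l.startswith("# provenance")) + "\n"
    assert write_painting_table(read_painting_table(text)) == body


class TestDeconvolution:
    def test_composite_peak_resolved(self):
        peaks = load_fixture("table1_peaks")
        assignments = load_fixture("tml_tin_assignments")
        m = deconvolve_probe_peaks(peaks, assignments)
        assert m.is_deconvolved
        assert m.target_chromosomes_of("6") == ("15", "27")
        assert m.target_chromosomes_of("X") == ("X",)
        assert m.target_chromosomes_of("2") == ("3",)
        assert m.target_chromosomes_of("4") == ("16", "26")

    def test_map_without_composites_unchanged(self):
        m = read_painting_table(SIMPLE)
        assert deconvolve_probe_peaks(m, {}) == m

    def test_missing_assignment_rejected(self):
        peaks = load_fixture("table1_peaks")
        with pytest.raises(PaintingError, match="no deconvolution assignment"):
            deconvolve_probe_peaks(peaks, {})

    def test_unattributed_target_rejected(self):
        text = SIMPLE + "2+4\t3;16;26\n"
        peaks = read_painting_table(text)
        partial = {"2+4": {"2": (SegmentRef("3"),), "4": (SegmentRef("16"),)}}
        with pytest.raises(PaintingError, match="26"):
            deconvolve_probe_peaks(peaks, partial)


class TestAncestralMatrix:
    def test_shape(self, apk_matrix):
        assert apk_matrix.n_rows == 28
        assert apk_matrix.derived_2n() == 58
        assert apk_matrix.taxa == ("OAF", "LAF", "TML", "PCA", "TIN", "HSA")

    def test_structural_flags_attach_to_cells(self, apk_matrix):
        assert apk_matrix.cell("1", "TIN").flag == "inv"
        assert apk_matrix.cell("1", "LAF").flag == "inv/cr"
        assert apk_matrix.cell("1", "TML").flag is None

    def test_synteny_cell_parses_to_two_refs(self, apk_matrix):
        assert apk_matrix.cell("1", "HSA").chromosomes == ("5", "21")

    def test_unresolved_cell(self, apk_matrix):
        assert apk_matrix.cell("22", "PCA").unresolved

    def test_round_trips_byte_identically(self, apk_matrix):
        text = fixture_text("apk_matrix.tsv")
        body = "\n".join(l for l in text.splitlines() if not l.startswith("# provenance")) + "\n"
        assert write_ancestral_matrix(read_ancestral_matrix(text)) == body

    def test_row_with_wrong_cell_count_rejected(self):
        with pytest.raises(AncestralMatrixError, match="cells for"):
            read_ancestral_matrix("APK\tTIN\tHSA\n1\t1\n")

    def test_missing_row_key_rejected(self):
        with pytest.raises(AncestralMatrixError, match="missing key"):
            read_ancestral_matrix("APK\tTIN\n\t5\n")


class TestFixtures:
    def test_deconvolved_map_has_full_probe_set(self, tml_tin_map):
        # 23 autosomal probes + X + Y
        assert len(tml_tin_map.probe_units) == 25
        assert set(tml_tin_map.probe_units) == {str(i) for i in range(1, 24)} | {"X", "Y"}

    def test_unknown_fixture_name(self):
        with pytest.raises(FixtureError, match="unknown fixture"):
            load_fixture("table9")

    def test_manifest_covers_every_data_file(self):
        import csv
        from importlib import resources

        listed = {
            row[0]
            for row in csv.reader(fixture_text("MANIFEST.tsv").splitlines(), delimiter="\t")
            if row and row[0].endswith(".tsv")
        }
        present = {
            p.name
            for p in resources.files("karyopaint.data").iterdir()
            if p.name.endswith(".tsv") and p.name != "MANIFEST.tsv"
        }
        assert listed == present

    def test_published_association_list(self, published_associations):
        by_label = {a.label: a for a in published_associations}
        assert by_label["14/15"].target_chromosomes == ("8",)
        assert by_label["4/8"].status == "absent"
        assert len(published_associations) == 10
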