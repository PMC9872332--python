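"""Rearrangement-event inference, lineage counting and change rates."""

import pytest

from karyopaint import (
    compute_change_rate,
    count_lineage_events,
    detect_syntenic_associations,
    find_shared_associations,
    infer_pairwise_events,
    invert_map,
    read_painting_table,
    summarize_events,
)
from karyopaint.events import EventRecord
from karyopaint.homology import AssociationHit, AssociationReport


class TestPairwise:
    def test_manatee_fissions_all_robertsonian(self, tml_tin_map, karyo_tml, karyo_tin):
        result = infer_pairwise_events(tml_tin_map, karyo_tml, karyo_tin)
        assert result.findings == ()
        fissions = [e for e in result.events if e.type == "fission"]
        assert len(fissions) == 4
        assert sorted(e.sources[0] for e in fissions) == ["4", "6", "8", "9"]
        assert all(e.robertsonian for e in fissions)
        products = sorted(p for e in fissions for p in e.products)
        assert products == ["15", "16", "19", "22", "24", "25", "26", "27"]

    def test_identity_map_yields_no_events(self, karyo_tin):
        ident = read_painting_table(
            "# probe_species: TIN\n# target_species: TIN\nprobe\ttargets\n1\t1\n2\t2\n"
        )
        assert infer_pairwise_events(ident).events == ()

    def test_duality_under_inversion(self, tml_tin_map, karyo_tml, karyo_tin):
        """Reading the map in the opposite polarity swaps fissions for fusions."""
        fwd = summarize_events(infer_pairwise_events(tml_tin_map, karyo_tml, karyo_tin).events)
        rev = summarize_events(
            infer_pairwise_events(invert_map(tml_tin_map), karyo_tin, karyo_tml).events
        )
        assert fwd.counts.get("fission", 0) == rev.counts.get("fusion", 0)
        assert fwd.counts.get("fusion", 0) == rev.counts.get("fission", 0)
        assert fwd.total == rev.total
        assert fwd.robertsonian_count == rev.robertsonian_count

    def test_missing_morphology_downgrades_with_finding(self, tml_tin_map):
        result = infer_pairwise_events(tml_tin_map, None, None)
        fissions = [e for e in result.events if e.type == "fission"]
        assert len(fissions) == 4
        assert not any(e.robertsonian for e in fissions)
        assert {f.code for f in result.findings} == {"morphology-missing"}

    def test_annotations_appended_verbatim(self, tml_tin_map, karyo_tml, karyo_tin):
        ann = EventRecord("pericentric_inversion", ("TML", "TIN"), ("1",), ("1",), evidence="annotation")
        result = infer_pairwise_events(tml_tin_map, karyo_tml, karyo_tin, (ann,))
        assert result.events[-1] == ann
        assert result.summary.total == 5


class TestLineageCounts:
    def test_tin_column(self, apk_matrix):
        lin = count_lineage_events(apk_matrix, "TIN")
        assert dict(lin.summary.counts) == {
            "fusion": 1,
            "pericentric_inversion": 1,
            "centromere_repositioning": 2,
        }
        assert lin.summary.total == 4
        (fusion,) = [e for e in lin.events if e.type == "fusion"]
        assert fusion.products == ("9",)  # two ancestral rows merged into TIN 9

    def test_tml_column(self, apk_matrix):
        lin = count_lineage_events(apk_matrix, "TML")
        assert dict(lin.summary.counts) == {"fusion": 5, "centromere_repositioning": 2}
        assert lin.summary.total == 7
        fused = sorted({e.products[0] for e in lin.events if e.type == "fusion"})
        assert fused == ["15", "4", "6", "8", "9"]

    def test_laf_column(self, apk_matrix):
        lin = count_lineage_events(apk_matrix, "LAF")
        assert lin.count("fusion") == 5
        # the encoded matrix carries three multi-chromosome LAF cells; the
        # parenthetical "27 (24)" is stored as an alternative label, not a split
        assert lin.count("fission") == 3
        assert lin.count("centromere_repositioning") == 1

    def test_pca_column_with_uncertainty(self, apk_matrix):
        lin = count_lineage_events(apk_matrix, "PCA")
        assert lin.count("fusion") == 3
        assert lin.count("fission") == 2
        assert len(lin.unresolved) == 2  # the "?" cell and the "16p?" token
        strict = count_lineage_events(apk_matrix, "PCA", include_uncertain=False)
        assert strict.count("fusion") == 2  # dropping 16p? removes the PCA 16 merge
        assert strict.count("fission") == 1

    def test_absent_taxon_rejected(self, apk_matrix):
        with pytest.raises(Exception, match="not a matrix column"):
            count_lineage_events(apk_matrix, "HSA2")


class TestChangeRate:
    def test_manatee_divergence_rate(self):
        assert compute_change_rate(5, 1.34) == pytest.approx(5 / 1.34)

    def test_zero_events(self):
        assert compute_change_rate(0, 7.5) == 0.0

    def test_deep_divergence_rate(self):
        assert compute_change_rate(4, 56.0) == pytest.approx(0.0714285, abs=1e-6)

    @pytest.mark.parametrize("bad_myr", [0.0, -1.0])
    def test_nonpositive_divergence_rejected(self, bad_myr):
        with pytest.raises(ValueError):
            compute_change_rate(3, bad_myr)


def report_with(present_pairs, absent_pairs=()):
    hits = tuple(AssociationHit(frozenset(p), "1") for p in present_pairs)
    return AssociationReport(hits=hits, absent=tuple(frozenset(p) for p in absent_pairs))


class TestSharedAssociations:
    def test_clade_shared_and_derived(self):
        pair = ("2", "3")
        per_taxon = {
            "TIN": report_with([pair]),
            "TML": report_with([pair]),
            "LAF": report_with([pair]),
            "OAF": report_with([], [pair]),
        }
        (assoc,) = find_shared_associations(per_taxon, outgroup="OAF")
        assert assoc.clade_shared and assoc.derived
        assert assoc.present_in == ("LAF", "TIN", "TML")

    def test_present_in_single_taxon_is_not_shared(self):
        pair = ("4", "8")
        per_taxon = {
            "TIN": report_with([pair]),
            "TML": report_with([], [pair]),
            "OAF": report_with([], [pair]),
        }
        (assoc,) = find_shared_associations(per_taxon, outgroup="OAF")
        assert not assoc.clade_shared and not assoc.derived

    def test_untested_taxon_counts_as_unresolved(self):
        pair = ("2", "3")
        per_taxon = {
            "TIN": report_with([pair]),
            "TML": report_with([]),
            "OAF": report_with([], [pair]),
        }
        (assoc,) = find_shared_associations(per_taxon, outgroup="OAF")
        assert assoc.unresolved_in == ("TML",)
        assert not assoc.clade_shared

    def test_missing_outgroup_rejected(self):
        with pytest.raises(ValueError, match="outgroup"):
            find_shared_associations({"TIN": report_with([]), "TML": report_with([])}, outgroup="OAF")


class TestEventRecordInvariants:
    def test_fusion_arity(self):
        with pytest.raises(ValueError):
            EventRecord("fusion", ("A", "B"), ("1",), ("2",))

    def test_inversion_requires_annotation_evidence(self):
        with pytest.raises(ValueError, match="annotation"):
            EventRecord("pericentric_inversion", ("A", "B"), ("1",), ("1",), evidence="painting")
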