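import dataclasses

import pytest

from conftest import candidate_from_protein

from cyclomine.anchoring import anchor_to_profile, decompose_loops
from cyclomine.classify import (
    Classification,
    ClassifyParams,
    SignatureProfile,
    assign_lineage,
    assign_names,
    assign_subfamily,
    classify_precursor,
    extract_signature,
    group_species_series,
    organism_code,
)
from cyclomine.synthetic import sample_precursor


def _sig(occ="+" * 19, marks=("-", "-", "-"), hyb=("-", "-"), dipep="HS", residues=None):
    if residues is None:
        residues = tuple(c if c != "+" else "A" for c in occ) + ("A",) * 18
    return SignatureProfile(
        ntpp_occupancy=tuple(occ),
        linear_bracelet_marks=tuple(marks),
        hybrid_mark=tuple(hyb),
        ntr_dipeptide=dipep,
        ntpp_residues=residues,
    )


def _moebius_occ():
    # gaps at [-56,-54] and [-50,-38]; residues at [-53,-51]
    return "---" + "+++" + "-" * 13


class TestExtractSignature:
    def test_archetypal_moebius_signature(self, bundle, template_map):
        truth, _ = sample_precursor(template_map["YS1"], 0)
        anc = anchor_to_profile(candidate_from_protein(truth.protein), bundle)
        sig = extract_signature(anc)
        assert "".join(sig.ntpp_occupancy) == _moebius_occ()
        assert sig.ntr_dipeptide == "YS"
        assert sig.hybrid_mark == ("-", "-")

    def test_linear_bracelet_signature(self, bundle, template_map):
        truth, _ = sample_precursor(template_map["PN1"], 0)
        anc = anchor_to_profile(candidate_from_protein(truth.protein), bundle)
        sig = extract_signature(anc)
        m49, m48, m39 = sig.linear_bracelet_marks
        assert m49 in "PAL" and m48 in "NA" and m39 in "DE"
        assert sig.ntr_dipeptide[0] in "QEPK" and sig.ntr_dipeptide[1] in "DN"

    def test_truncated_precursor_yields_question_marks(self, bundle, template_map):
        truth, _ = sample_precursor(template_map["HS1"], 0)
        cut = truth.cds[0].ntr_span[0] + 9  # keep from consensus -10 onward
        anc = anchor_to_profile(candidate_from_protein(truth.protein[cut:]), bundle)
        sig = extract_signature(anc)
        assert set(sig.ntpp_occupancy) == {"?"}
        assert sig.ntr_dipeptide == "HS"  # dipeptide still read


class TestAssignLineage:
    def test_fully_gapped_deletion_windows_moebius(self):
        lineage, _ = assign_lineage(_sig(occ=_moebius_occ()))
        assert lineage == "moebius"

    def test_fully_occupied_insertion_region_bracelet(self):
        lineage, _ = assign_lineage(_sig(occ="+" * 19))
        assert lineage == "bracelet"

    def test_half_occupied_window_unclassified(self):
        # [-50,-38] has 13 positions; 6 occupied is just under half
        occ = "+++" + "+++" + "+" * 6 + "-" * 7
        assert _sig(occ=occ).ntpp_occupancy.count("+") == 12
        lineage, _ = assign_lineage(_sig(occ=occ))
        assert lineage == "unclassified"

    def test_linear_bracelet_marks_rescue_lineage(self):
        # deletion flanked by the two diagnostic insertions
        occ = "++++++" + "-" + "++" + "-" * 8 + "++"
        lineage, rationale = assign_lineage(_sig(occ=occ, marks=("P", "N", "D")))
        assert lineage == "bracelet"
        assert any("flanking insertions" in r for r in rationale)

    def test_all_unknown_ntpp_unclassified_partial(self):
        lineage, rationale = assign_lineage(_sig(occ="?" * 19))
        assert lineage == "unclassified"
        assert "partial" in rationale[0]


class TestAssignSubfamily:
    def test_moebius_yy_linear(self):
        sub, _ = assign_subfamily("moebius", _sig(dipep="YY"))
        assert sub == "linear_moebius"

    def test_moebius_hybrid_needs_insertion_mark(self):
        sub, _ = assign_subfamily("moebius", _sig(dipep="YS", hyb=("+", "+")))
        assert sub == "hybrid"
        sub, _ = assign_subfamily("moebius", _sig(dipep="YS", hyb=("-", "-")))
        assert sub == "archetypal_moebius"

    def test_bracelet_linear_needs_marks(self):
        sub, _ = assign_subfamily("bracelet", _sig(dipep="QD", marks=("P", "N", "D")))
        assert sub == "linear_bracelet"
        sub, _ = assign_subfamily("bracelet", _sig(dipep="QD"))
        assert sub == "unassigned"  # QD fails the cyclic residue classes too

    def test_bracelet_cyclic_dipeptide(self):
        sub, _ = assign_subfamily("bracelet", _sig(dipep="HS"))
        assert sub == "cyclic_bracelet"

    def test_unknown_dipeptide_unassigned(self):
        sub, _ = assign_subfamily("moebius", _sig(dipep="?S"))
        assert sub == "unassigned"


class TestGroupSpeciesSeries:
    def _cls(self, lineage="bracelet"):
        return Classification(lineage=lineage, subfamily="cyclic_bracelet")

    def test_same_series_different_occupancy_two_species(self):
        occ_a = "+" * 19
        occ_b = "+" * 18 + "-"
        pairs = [
            (_sig(occ=occ_a, dipep="HS"), self._cls()),
            (_sig(occ=occ_b, dipep="HS"), self._cls()),
        ]
        group_species_series(pairs)
        assert pairs[0][1].series_key == pairs[1][1].series_key == "HS"
        assert {pairs[0][1].species_key, pairs[1][1].species_key} == {"HS1", "HS2"}

    def test_identical_signatures_one_species(self):
        pairs = [(_sig(dipep="HS"), self._cls()) for _ in range(3)]
        group_species_series(pairs)
        assert {c.species_key for _, c in pairs} == {"HS1"}

    def test_four_templates_give_four_species(self, bundle, template_map):
        names = ["HS1", "HS2", "NS1", "YS1"]
        pairs = []
        for k in range(10):
            truth, _ = sample_precursor(template_map[names[k % 4]], k)
            anc = anchor_to_profile(candidate_from_protein(truth.protein), bundle)
            pairs.append(classify_precursor(anc, decompose_loops(anc, 0)))
        group_species_series(pairs)
        assert len({(c.series_key, c.species_key) for _, c in pairs}) == 4

    def test_partial_gets_series_only(self):
        pairs = [
            (_sig(dipep="HS"), self._cls()),
            (_sig(occ="?" * 19, dipep="HS"), self._cls()),
        ]
        group_species_series(pairs)
        assert pairs[1][1].series_key == "HS"
        assert pairs[1][1].species_key is None

    def test_low_identity_splits_species(self):
        res_a = ("A",) * 37
        res_b = ("A",) * 7 + ("W",) * 30  # identity far below 0.8
        pairs = [
            (_sig(dipep="HS", residues=res_a), self._cls()),
            (_sig(dipep="HS", residues=res_b), self._cls()),
        ]
        group_species_series(pairs)
        assert pairs[0][1].species_key != pairs[1][1].species_key

    def test_numbering_follows_input_order(self):
        occ_b = "+" * 18 + "-"
        sig1, sig2 = _sig(dipep="NL"), _sig(occ=occ_b, dipep="NL")
        pairs = [(sig1, self._cls()), (sig2, self._cls())]
        group_species_series(pairs)
        first = pairs[0][1].species_key
        pairs_swapped = [(sig2, self._cls()), (sig1, self._cls())]
        group_species_series(pairs_swapped)
        assert first == "NL1" and pairs_swapped[0][1].species_key == "NL1"


class TestAssignNames:
    def test_published_example_shape(self):
        cls = Classification(lineage="bracelet", subfamily="cyclic_bracelet",
                             series_key="HS", species_key="HS4")
        rows = [
            ("c1", "Viola acuminata", cls),
            ("c2", "Viola acuminata", cls),
        ]
        names = assign_names(rows, entity="cyclotide")
        assert names[1].full_name == "vacum2-HS4"

    def test_precursor_prefix_and_existing_names(self):
        cls = Classification(lineage="moebius", subfamily="hybrid",
                             series_key="YS", species_key="YS1")
        names = assign_names(
            [("p1", "Viola uliginosa", cls), ("p2", "Viola uliginosa", cls)],
            entity="precursor",
            existing_names={"p1": "viul A"},
        )
        assert names[0].full_name == "prc-viul A"
        assert names[1].full_name.startswith("prc-vulig")

    def test_first_of_new_species_gets_rank_one(self):
        cls = Classification(lineage="moebius", subfamily="archetypal_moebius",
                             series_key="YA", species_key="YA2")
        (nm,) = assign_names([("c", "Viola canadensis", cls)])
        assert nm.rank == 1 and nm.full_name == "vcana1-YA2"

    def test_code_table_and_fallback(self):
        assert organism_code("Viola mandshurica") == "viman"
        assert organism_code("Viola tricolor") == "vtric"
        with pytest.raises(ValueError):
            organism_code("Viola")


class TestClosureProperty:
    def test_every_template_classifies_back(self, bundle, templates):
        """Sampled precursors recover their template's lineage/subfamily/series."""
        for t in templates:
            truth, _ = sample_precursor(t, 13)
            anc = anchor_to_profile(candidate_from_protein(truth.protein), bundle)
            sig, cls = classify_precursor(anc, decompose_loops(anc, 0))
            assert cls.lineage == t.lineage, t.name
            assert cls.subfamily == t.subfamily, t.name
            assert sig.ntr_dipeptide == t.series, t.name

    def test_linear_subfamily_consistent_with_nd(self, bundle, small_sim):
        """No precursor is linear_* while carrying an N/D site, unless flagged."""
        _, _, truth = small_sim
        for p in truth.precursors:
            anc = anchor_to_profile(candidate_from_protein(p.protein), bundle)
            loops = decompose_loops(anc, 0)
            _, cls = classify_precursor(anc, loops)
            if cls.subfamily.startswith("linear") and loops.nd_site is not None:
                assert cls.abnormality_flags
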