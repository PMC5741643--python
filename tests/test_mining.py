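import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import CYO2, KB1, candidate_from_protein
from oracles import motif_oracle, sw_score_oracle

from cyclomine.mining import (
    DEFAULT_LOOP_WINDOWS,
    MiningParams,
    mine_precursors,
    scan_cd_motif,
    similarity_score,
    six_frame_orfs,
)
from cyclomine.seqio import SequenceRecord
from cyclomine.synthetic import sample_precursor


def _nt(seq_id, seq):
    return SequenceRecord(id=seq_id, description="", alphabet="nucleotide", residues=seq)


class TestSixFrameOrfs:
    def test_simple_forward_orf(self):
        orfs = six_frame_orfs(_nt("t", "ATGGGTTGA"), min_orf_len=1, min_transcript_len=1)
        fw = [o for o in orfs if o.frame == 1]
        assert fw[0].protein == "MG"
        assert fw[0].nt_span == (0, 6)

    def test_reverse_complement_symmetry(self):
        from Bio.Seq import Seq

        cds = "ATGGGTCCTGTTTGCGGTGAAACTTGA"
        rc = str(Seq(cds).reverse_complement())
        fw = six_frame_orfs(_nt("f", cds), 1, 1)
        rv = six_frame_orfs(_nt("r", rc), 1, 1)
        fw_prots = {o.protein for o in fw if o.frame > 0}
        rv_prots = {o.protein for o in rv if o.frame < 0}
        assert "MGPVCGET" in fw_prots and "MGPVCGET" in rv_prots
        # coordinates map back to the same forward-strand interval
        o = next(o for o in rv if o.protein == "MGPVCGET")
        assert o.nt_span == (3, 27)  # excludes the (reverse-strand) stop codon

    def test_short_transcript_yields_nothing(self):
        assert six_frame_orfs(_nt("t", "ATG" * 50), min_orf_len=1) == []

    def test_n_codons_translate_to_x(self):
        orfs = six_frame_orfs(_nt("t", "ATGNNNGGT"), 1, 1)
        assert any(o.protein == "MXG" for o in orfs)

    def test_min_orf_len_filters(self):
        orfs = six_frame_orfs(_nt("t", "ATGGGTTGA"), min_orf_len=3, min_transcript_len=1)
        assert all(len(o.protein) >= 3 for o in orfs)


class TestScanCdMotif:
    def test_kalata_b1_loop_lengths(self):
        hits = scan_cd_motif(KB1)
        assert len(hits) == 1
        assert hits[0].loop_lengths == (3, 4, 4, 1, 4)

    def test_cyo2_loop_lengths(self):
        (hit,) = scan_cd_motif(CYO2)
        assert hit.loop_lengths == (3, 4, 6, 1, 4)

    def test_adjacent_cysteines_no_hit(self):
        assert scan_cd_motif("CCCCCC") == []

    def test_two_disjoint_domains_two_hits(self):
        protein = KB1 + "A" * 20 + KB1
        hits = scan_cd_motif(protein)
        assert len(hits) == 2
        assert hits == sorted(hits, key=lambda h: h.cys_positions[0])

    def test_malformed_window_errors(self):
        with pytest.raises(ValueError, match="malformed"):
            scan_cd_motif(KB1, [(5, 2), (3, 6), (2, 8), (1, 2), (3, 6)])

    def test_matches_oracle_exhaustively_short(self):
        # every string up to length 8 over {C,A,G}
        import itertools

        for n in range(1, 9):
            for tup in itertools.product("CAG", repeat=n):
                s = "".join(tup)
                got = [h.cys_positions for h in scan_cd_motif(s)]
                assert got == motif_oracle(s, DEFAULT_LOOP_WINDOWS), s

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(st.text(alphabet="CAG", min_size=6, max_size=30))
    def test_matches_oracle_random(self, s):
        got = [h.cys_positions for h in scan_cd_motif(s)]
        assert got == motif_oracle(s, DEFAULT_LOOP_WINDOWS)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.text(alphabet="CAGWSTNP", min_size=6, max_size=40))
    def test_hits_never_overlap_and_loops_in_windows(self, s):
        hits = scan_cd_motif(s)
        for h in hits:
            for (lo, hi), g in zip(DEFAULT_LOOP_WINDOWS, h.loop_lengths):
                assert lo <= g <= hi
        for a, b in zip(hits, hits[1:]):
            assert a.cys_positions[-1] < b.cys_positions[0]


class TestSimilarityScore:
    def test_self_alignment_is_diagonal_sum(self):
        from Bio.Align import substitution_matrices

        b62 = substitution_matrices.load("BLOSUM62")
        expected = sum(b62[c][c] for c in KB1)
        score, ref = similarity_score(KB1, [("kb1", KB1)])
        assert score == expected and ref == "kb1"

    def test_no_common_residues_scores_zero(self):
        score, _ = similarity_score("GGGGGG", [("w", "WWWWWW")])
        assert score == 0.0

    def test_kb1_vs_cyo2_equals_oracle(self):
        score, _ = similarity_score(KB1, [("cyO2", CYO2)])
        assert score == sw_score_oracle(KB1, CYO2)

    def test_empty_candidate_errors(self):
        with pytest.raises(ValueError):
            similarity_score("", [("x", "MK")])

    def test_matches_oracle_on_random_pairs(self):
        rng = np.random.default_rng(42)
        aas = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        for _ in range(200):
            a = "".join(rng.choice(aas, size=rng.integers(1, 41)))
            b = "".join(rng.choice(aas, size=rng.integers(1, 41)))
            score, _ = similarity_score(a, [("r", b)])
            assert score == sw_score_oracle(a, b), (a, b)

    def test_tie_breaks_lexicographically(self):
        score, ref = similarity_score(KB1, [("b", KB1), ("a", KB1)])
        assert ref == "a"


class TestMinePrecursors:
    def test_planted_precursor_found_once(self, bundle, template_map):
        truth, cds = sample_precursor(template_map["HS1"], 1)
        rec = _nt("t1", "A" * 60 + cds + "A" * 60)
        cands = mine_precursors([rec], bundle)
        assert len(cands) == 1
        assert len(cands[0].motif_hits) == 1
        assert truth.protein == cands[0].protein

    def test_duplicate_proteins_collapsed_with_provenance(self, bundle, template_map):
        truth, cds = sample_precursor(template_map["HS1"], 1)
        recs = [_nt("t1", "A" * 60 + cds + "A" * 60), _nt("t2", "G" * 70 + cds + "C" * 30)]
        cands = mine_precursors(recs, bundle)
        assert len(cands) == 1
        assert cands[0].provenance == ("t1", "t2")

    def test_decoys_rejected(self, bundle, small_sim):
        records, _, truth = small_sim
        decoys = [r for r in records if r.id.startswith("TRINITY_DECOY")]
        assert mine_precursors(decoys, bundle) == []

    def test_full_recall_on_noise_free_transcriptome(self, bundle, small_sim):
        records, _, truth = small_sim
        cands = mine_precursors(records, bundle)
        mined = {c.protein for c in cands}
        for p in truth.precursors:
            assert p.protein in mined

    def test_five_cysteine_precursor_rescued_by_similarity(self, bundle, template_map):
        truth, _ = sample_precursor(template_map["HS2"], 2)
        # drop one CD cysteine: no valid motif placement remains
        idx = truth.cds[0].cd_span[0]
        protein = truth.protein[:idx] + truth.protein[idx:].replace("C", "S", 1)
        from cyclomine.mining import scan_cd_motif as scan

        assert scan(protein) == []
        cds = "".join(
            {  # quick manual back-translation, one codon per residue
                aa: codon
                for aa, codon in zip(
                    "ACDEFGHIKLMNPQRSTVWY",
                    ["GCT", "TGT", "GAT", "GAA", "TTT", "GGT", "CAT", "ATT", "AAA", "CTT",
                     "ATG", "AAT", "CCT", "CAA", "CGT", "TCT", "ACT", "GTT", "TGG", "TAT"],
                )
            }[aa]
            for aa in protein
        )
        rec = _nt("t1", "A" * 30 + "TAA" + cds + "TAA" + "A" * 30)
        cands = mine_precursors([rec], bundle)
        assert len(cands) == 1
        assert "abnormal_cysteines" in cands[0].flags
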