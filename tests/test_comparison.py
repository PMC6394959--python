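"""Per-code comparison: score deltas, classification, residue tabulation."""

from collections import Counter

import pytest

import recodon as rc
from recodon.alignment import AlignmentResult
from recodon.comparison import (EQUAL, IMPROVED_BOTH, IMPROVED_UAR,
                                IMPROVED_UGA, NO_HIT, CodeHit, classify,
                                stop_aligned_residues)

# deterministic back-translation: one standard-code codon per amino acid
_CODON_FOR = {
    "A": "GCT", "R": "CGT", "N": "AAT", "D": "GAT", "C": "TGT", "Q": "CAA",
    "E": "GAA", "G": "GGT", "H": "CAT", "I": "ATT", "L": "CTT", "K": "AAA",
    "M": "ATG", "F": "TTT", "P": "CCT", "S": "TCT", "T": "ACT", "W": "TGG",
    "Y": "TAT", "V": "GTT",
}

PROTEIN = "MKVAWLEDGHIWRNPQSTYWKVAEDGHILRN"  # three Trp residues


def back_translate(protein: str, recode: dict[str, str] | None = None) -> str:
    recode = recode or {}
    return "".join(recode.get(aa, _CODON_FOR[aa]) for aa in protein)


@pytest.fixture(scope="module")
def single_ref_db():
    return rc.ReferenceDB({"refA": PROTEIN})


class TestCompareCodes:
    def test_no_stops_means_equal_scores(self, single_ref_db):
        transcript = back_translate(PROTEIN)
        rec = rc.compare_codes("t1", transcript, single_ref_db)
        assert rec.classification == EQUAL
        scores = {tid: hit.alignment.raw_score for tid, hit in rec.per_code.items()}
        assert len(set(scores.values())) == 1
        assert sum(rec.n_stops_in_query.values()) == 0

    def test_three_tga_at_trp_sites_adds_three_identities(self, single_ref_db):
        # all three Trp codons written as TGA; zero divergence elsewhere
        transcript = back_translate(PROTEIN, recode={"W": "TGA"})
        rec = rc.compare_codes("t2", transcript, single_ref_db)
        d_ident = rec.per_code[4].identities - rec.per_code[1].identities
        assert d_ident == 3
        assert rec.classification == IMPROVED_UGA
        assert rec.n_stops_in_query["TGA"] == 3

    def test_uar_codons_improve_table6_only(self, single_ref_db):
        transcript = back_translate(PROTEIN, recode={"Q": "TAA"})
        rec = rc.compare_codes("t3", transcript, single_ref_db)
        assert rec.classification == IMPROVED_UAR
        assert rec.per_code[6].identities > rec.per_code[1].identities

    def test_both_reassignments_improve_both(self, single_ref_db):
        transcript = back_translate(PROTEIN, recode={"W": "TGA", "Q": "TAG"})
        rec = rc.compare_codes("t4", transcript, single_ref_db)
        assert rec.classification == IMPROVED_BOTH

    def test_unmatchable_transcript_is_no_hit(self, single_ref_db):
        rec = rc.compare_codes("t5", "ACGT" * 30, single_ref_db)
        assert rec.classification == NO_HIT
        assert rec.best_hit is None

    def test_improved_fraction_matches_planted_reassignment(self, parasite_sim,
                                                            parasite_records):
        _, _, _, truth = parasite_sim
        _, records = parasite_records
        carriers = [r for r in records if truth[r.transcript_id].n_reassigned >= 1]
        improved = [r for r in carriers if r.classification.startswith("improved")]
        assert len(improved) / len(carriers) > 0.8


class TestClassify:
    def _hit(self, identities, positives):
        aln = AlignmentResult(100, identities, positives, 0, positives,
                              1, positives, 1, positives, [])
        return CodeHit(0, 0, "s", positives, aln, 1e-50)

    @pytest.mark.parametrize("d4,d6,expected", [
        ((0, 0), (0, 0), EQUAL),
        ((0, 1), (0, 0), IMPROVED_UGA),
        ((0, 0), (1, 0), IMPROVED_UAR),
        ((2, 2), (0, 1), IMPROVED_BOTH),
        ((-1, -1), (0, 0), EQUAL),  # strictly-greater rule
    ])
    def test_delta_cases(self, d4, d6, expected):
        base = self._hit(10, 12)
        per_code = {1: base,
                    4: self._hit(10 + d4[0], 12 + d4[1]),
                    6: self._hit(10 + d6[0], 12 + d6[1])}
        assert classify(per_code) == expected

    def test_missing_baseline_is_an_error(self):
        with pytest.raises(ValueError):
            classify({4: self._hit(1, 1)})


class TestResidueTabulation:
    def test_all_uga_aligned_to_trp(self, single_ref_db):
        transcript = back_translate(PROTEIN, recode={"W": "TGA"})
        rec = rc.compare_codes("t", transcript, single_ref_db)
        items = [("t", rec.best_hit, transcript)]
        profile = rc.tabulate_aligned_residues(items)
        assert profile.frequencies("TGA") == {"W": 1.0}
        assert profile.modal_residue("TGA") == "W"

    def test_gap_aligned_stops_counted_separately(self):
        # hand-built alignment: the 2nd query residue ('*') sits across a gap
        pairs = [("M", "M"), ("*", "-"), ("K", "K"), ("V", "V")]
        aln = AlignmentResult(10, 3, 3, 1, 4, 1, 4, 1, 3, pairs)
        hit = CodeHit(1, 0, "ref", 3, aln, 1e-30)
        transcript = "ATG" + "TGA" + "AAA" + "GTT"
        profile = rc.tabulate_aligned_residues([("t", hit, transcript)])
        assert profile.gap_counts["TGA"] == 1
        assert sum(profile.counts["TGA"].values()) == 0

    def test_simulated_modal_residues(self, parasite_sim, parasite_records):
        _, _, transcripts, _ = parasite_sim
        _, records = parasite_records
        improved = [r for r in records if r.classification.startswith("improved")]
        items = [(r.transcript_id, r.best_hit, transcripts[r.transcript_id])
                 for r in improved]
        profile = rc.tabulate_aligned_residues(items)
        assert profile.modal_residue("TAA") == "Q"
        assert profile.modal_residue("TAG") == "Q"
        assert profile.modal_residue("TGA") == "W"

    def test_empty_input_gives_empty_profile(self):
        profile = rc.tabulate_aligned_residues([])
        assert all(not c for c in profile.counts.values())


class TestStopAlignedResidues:
    def test_positions_are_codon_first_bases(self, single_ref_db):
        transcript = back_translate(PROTEIN, recode={"W": "TGA"})
        rec = rc.compare_codes("t", transcript, single_ref_db)
        found = stop_aligned_residues(transcript, rec.best_hit)
        # Trp at protein positions 5, 12, 20 -> codon first bases 13, 34, 58
        assert [(c, p) for c, p, _ in found] == \
            [("TGA", 13), ("TGA", 34), ("TGA", 58)]
        assert all(res == "W" for _, _, res in found)


class TestRankAllCodes:
    def test_standard_code_transcript_ties_to_table_1(self, single_ref_db):
        transcript = back_translate(PROTEIN)
        best, hist = rc.rank_all_codes({"t": transcript}, single_ref_db)
        assert best["t"] == 1
        assert hist[1] == 1

    def test_ciliate_set_modal_table_6(self, parasite_sim):
        cfg, proteome, transcripts, _ = parasite_sim
        db = rc.ReferenceDB(proteome)
        subset = dict(list(transcripts.items())[:30])
        best, hist = rc.rank_all_codes(subset, db)
        modal = max((t for t in hist if t != "no_hit"), key=lambda t: hist[t])
        assert modal == 6


class TestStringencySweep:
    def test_single_threshold_equals_plain_tabulation(self, parasite_sim,
                                                      parasite_records):
        _, _, transcripts, _ = parasite_sim
        _, records = parasite_records
        improved = [r for r in records if r.classification.startswith("improved")]
        items = [(r.transcript_id, r.best_hit, transcripts[r.transcript_id])
                 for r in improved]
        rows = rc.stringency_sweep(items, [1e-10])
        profile = rc.tabulate_aligned_residues(items)
        assert rows[0]["TGA"]["modal_residue"] == profile.modal_residue("TGA")
        assert rows[0]["TGA"]["n"] == sum(profile.counts["TGA"].values())

    def test_impossible_threshold_flagged_empty(self, parasite_sim,
                                                parasite_records):
        _, _, transcripts, _ = parasite_sim
        _, records = parasite_records
        items = [(r.transcript_id, r.best_hit, transcripts[r.transcript_id])
                 for r in records if r.best_hit is not None]
        rows = rc.stringency_sweep(items, [1e-10, 0.0])
        assert rows[1]["empty"] is True

    def test_trp_proportion_does_not_degrade_with_stringency(self, parasite_sim,
                                                             parasite_records):
        _, _, transcripts, _ = parasite_sim
        _, records = parasite_records
        improved = [r for r in records if r.classification.startswith("improved")]
        items = [(r.transcript_id, r.best_hit, transcripts[r.transcript_id])
                 for r in improved]
        rows = rc.stringency_sweep(items, [1e-10, 1e-60])
        loose = rows[0]["TGA"]["modal_fraction"]
        strict = rows[1]["TGA"]["modal_fraction"]
        assert not rows[1]["empty"]
        assert strict >= loose - 0.05  # sampling slack


def test_collapse_components_keeps_longest():
    def rec(tid):
        return rc.CodeComparisonRecord(tid, {}, Counter(), Counter(), EQUAL)
    records = [rec("a1"), rec("a2"), rec("b1")]
    component_of = {"a1": "compA", "a2": "compA", "b1": "compB"}
    lengths = {"a1": 500, "a2": 900, "b1": 300}
    kept = rc.comparison.collapse_components(records, component_of, lengths)
    assert sorted(r.transcript_id for r in kept) == ["a2", "b1"]
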