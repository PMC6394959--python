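"""Codon counts, RSCU, third-position stats and alignment-guided extraction."""

import numpy as np
import pytest

import recodon as rc
from recodon.codon_usage import CodonCountTable, contains_coding_uga


@pytest.fixture(scope="module")
def code6():
    return rc.load_tables((6,))[6]


class TestCountCodons:
    def test_simple_count(self):
        t = rc.count_codons(["ATGATG"])
        assert t.counts == {"ATG": 2}
        assert t.total == 2

    def test_empty_set(self):
        t = rc.count_codons([])
        assert t.total == 0 and t.n_sequences == 0

    def test_additive_over_concatenation(self):
        a = rc.count_codons(["ATGAAA", "TTTGGG"])
        b = rc.count_codons(["ATGCCC"])
        combined = rc.count_codons(["ATGAAA", "TTTGGG", "ATGCCC"])
        assert (a + b).counts == combined.counts

    def test_bad_length_names_the_sequence(self):
        with pytest.raises(ValueError, match="bad_seq"):
            rc.count_codons({"bad_seq": "ATGA"})


class TestRSCU:
    def test_uniform_usage_gives_ones(self, code6):
        counts = CodonCountTable()
        for codon in ("CAA", "CAG", "TAA", "TAG"):
            counts.counts[codon] = 7
        table = rc.rscu(counts, code6)
        assert all(table.value(c) == pytest.approx(1.0)
                   for c in ("CAA", "CAG", "TAA", "TAG"))

    def test_single_codon_dominance(self, code6):
        counts = CodonCountTable()
        counts.counts["CAA"] = 12
        table = rc.rscu(counts, code6)
        assert table.value("CAA") == pytest.approx(4.0)
        assert table.value("TAA") == pytest.approx(0.0)

    def test_family_sums_equal_family_sizes(self, code6):
        rng = np.random.default_rng(41)
        counts = CodonCountTable()
        for codon in rc.ALL_CODONS:
            if code6.codon_to_aa[codon] != "*":
                counts.counts[codon] = int(rng.integers(1, 50))
        table = rc.rscu(counts, code6)
        assert table.family_sum("Q") == pytest.approx(4.0)
        assert table.family_sum("F") == pytest.approx(2.0)
        assert table.family_sum("S") == pytest.approx(6.0)

    def test_zero_count_family_is_undefined_not_zero(self, code6):
        counts = CodonCountTable()
        counts.counts["ATG"] = 5
        table = rc.rscu(counts, code6)
        assert table.value("TGT") is None  # Cys family unseen
        assert table.family_sum("C") is None

    def test_invariant_to_duplicating_the_cds_set(self, code6):
        cds = ["ATGCAACAGTAATTT"[:12], "GGTGGCGGAGGG"]
        t1 = rc.rscu(rc.count_codons(cds), code6)
        t2 = rc.rscu(rc.count_codons(cds + cds), code6)
        for codon in rc.ALL_CODONS:
            v1, v2 = t1.value(codon), t2.value(codon)
            assert (v1 is None) == (v2 is None)
            if v1 is not None:
                assert v1 == pytest.approx(v2)


class TestThirdPositionStats:
    def test_all_gc_thirds(self, code6):
        stats = rc.third_position_stats(["TTCAAGGGC"], code6)  # F,K,G
        assert stats.GC3s == pytest.approx(1.0)
        assert stats.A3s == stats.T3s == 0.0

    def test_hand_computed_toy_excludes_single_codon_families(self, code6):
        # ATG (Met) and TGG (Trp) are single-codon families under the ciliate
        # code and must not enter the denominator; TTT, GAA, AAA remain.
        stats = rc.third_position_stats(["ATGTTTGAATGGAAA"], code6)
        assert stats.n_synonymous_third_positions == 3
        assert stats.T3s == pytest.approx(1 / 3)
        assert stats.A3s == pytest.approx(2 / 3)
        assert stats.GC3s == pytest.approx(0.0)

    def test_at3_parameter_recovery(self):
        cfg = rc.SimulationConfig(seed=42, code_truth=1, at3_bias=0.7,
                                  p_taa_q=0, p_tag_q=0, p_tga_w=0,
                                  n_transcripts=60)
        proteome = rc.simulate_reference_proteome(cfg)
        transcripts, truth = rc.simulate_transcriptome(cfg, proteome)
        code1 = rc.load_tables((1,))[1]
        cds = [transcripts[t][r.cds_start - 1: r.cds_start - 1 + r.cds_len_nt]
               for t, r in truth.transcripts.items()]
        stats = rc.third_position_stats(cds, code1)
        assert stats.A3s + stats.T3s == pytest.approx(0.7, abs=0.02)

    def test_denominator_independent_of_sequence_order(self, code6):
        cds = ["ATGTTTGAA", "AAATGGCAA", "TTCGAT"]
        s1 = rc.third_position_stats(cds, code6)
        s2 = rc.third_position_stats(list(reversed(cds)), code6)
        assert s1.n_synonymous_third_positions == s2.n_synonymous_third_positions
        assert s1.A3s == pytest.approx(s2.A3s)


class TestExtractAlignedCodons:
    def test_ungapped_alignment_recovers_in_frame_split(self):
        protein = "MKVAWLEDGH"
        transcript = "ATGAAAGTTGCTTGGCTTGAAGATGGTCAT"
        db = rc.ReferenceDB({"r": protein})
        rec = rc.compare_codes("t", transcript, db, evalue_cutoff=1.0)
        codons = rc.extract_aligned_codons(transcript, rec.best_hit)
        assert codons == [transcript[i:i + 3] for i in range(0, 30, 3)]

    def test_round_trip_reproduces_aligned_query_residues(self, parasite_sim,
                                                          parasite_records):
        _, _, transcripts, _ = parasite_sim
        _, records = parasite_records
        tables = rc.load_tables()
        checked = 0
        for rec in records[:15]:
            hit = rec.best_hit
            if hit is None:
                continue
            seq = transcripts[rec.transcript_id]
            codons = rc.extract_aligned_codons(seq, hit)
            code = tables[hit.table_id]
            translated = "".join(code.translate_codon(c) for c in codons)
            aligned_query = "".join(qc for qc, _ in hit.alignment.pairs if qc != "-")
            assert translated == aligned_query
            checked += 1
        assert checked >= 10

    def test_subject_gap_column_still_emits_codon(self):
        # query has one residue more than the subject
        protein_q = "MKVAWLEDGH"
        protein_s = "MKVWLEDGH"  # A deleted
        transcript = "ATGAAAGTTGCTTGGCTTGAAGATGGTCAT"
        db = rc.ReferenceDB({"r": protein_s})
        rec = rc.compare_codes("t", transcript, db,
                               evalue_cutoff=1.0)  # tiny example, permissive
        hit = rec.per_code[1]
        codons = rc.extract_aligned_codons(transcript, hit)
        n_query_residues = sum(1 for qc, _ in hit.alignment.pairs if qc != "-")
        assert len(codons) == n_query_residues


class TestFamilyReport:
    def test_all_tgg(self):
        report = rc.family_codon_report(["TGG"] * 5)
        assert report["W"]["codons"]["TGG"]["rscu"] == pytest.approx(2.0)
        assert report["W"]["codons"]["TGA"]["rscu"] == pytest.approx(0.0)

    def test_family_sums(self):
        codons = ["TGG", "TGA", "TGA", "CAA", "CAG", "TAA", "TAG", "TAA"]
        report = rc.family_codon_report(codons)
        w_sum = sum(d["rscu"] for d in report["W"]["codons"].values())
        q_sum = sum(d["rscu"] for d in report["Q"]["codons"].values())
        assert w_sum == pytest.approx(2.0)
        assert q_sum == pytest.approx(4.0)

    def test_planted_taa_weight_recovered_as_rscu(self):
        # dynein-heavy-chain-like genes: long, Gln-rich usage with
        # P(TAA|Q)=0.45 should give RSCU(TAA) ~ 1.8
        cfg = rc.SimulationConfig(seed=43, p_taa_q=0.45, p_tag_q=0.10,
                                  n_transcripts=5, n_proteins=5,
                                  protein_length_mean=800,
                                  protein_length_sd=50, divergence=0.05)
        proteome = rc.simulate_reference_proteome(cfg)
        transcripts, truth = rc.simulate_transcriptome(cfg, proteome)
        db = rc.ReferenceDB(proteome)
        all_codons = []
        for tid, seq in transcripts.items():
            rec = rc.compare_codes(tid, seq, db)
            if rec.best_hit is not None:
                all_codons.extend(rc.extract_aligned_codons(seq, rec.best_hit))
        report = rc.family_codon_report(all_codons)
        n_q = report["Q"]["total"]
        assert n_q > 100
        rscu_taa = report["Q"]["codons"]["TAA"]["rscu"]
        band = 3 * 4 * np.sqrt(0.45 * 0.55 / n_q)  # 3 sigma on the RSCU scale
        assert rscu_taa == pytest.approx(4 * 0.45, abs=band)


class TestLongestOrf:
    def test_longest_orf_properties(self, code6):
        # stop-to-stop segments: the result must be stop-free, long enough,
        # at least as long as the planted CDS body, and in-frame
        rng = np.random.default_rng(44)
        cds = "ATG" + "".join(rng.choice(["TCA", "GCT", "AAA", "CAA"], 120)) + "TGA"
        transcript = "TGATTTAG" + cds + "CCTGA"
        found = rc.find_longest_orf(transcript, code6, min_codons=50)
        assert found is not None
        orf, frame, start = found
        assert len(orf) % 3 == 0
        assert len(orf) >= len(cds) - 3
        strand_seq = transcript if frame < 3 else rc.reverse_complement(transcript)
        assert strand_seq[start - 1:start - 1 + len(orf)] == orf
        assert "*" not in rc.translate(orf, 0, code6)

    def test_none_below_min_length(self, code6):
        assert rc.find_longest_orf("TGAGCTGCTTGA", code6, min_codons=50) is None


def test_contains_coding_uga_detection():
    protein = "MKVAWLEDGH"
    with_uga = "ATGAAAGTTGCTTGACTTGAAGATGGTCAT"  # W codon written as TGA
    without = "ATGAAAGTTGCTTGGCTTGAAGATGGTCAT"
    db = rc.ReferenceDB({"r": protein})
    rec1 = rc.compare_codes("a", with_uga, db, evalue_cutoff=1.0)
    rec2 = rc.compare_codes("b", without, db, evalue_cutoff=1.0)
    assert contains_coding_uga(with_uga, rec1.best_hit) is True
    assert contains_coding_uga(without, rec2.best_hit) is False
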