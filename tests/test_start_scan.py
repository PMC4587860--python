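"""Start-codon anchoring, enumeration, translation and gene classification."""

import re

import numpy as np
import pytest
from hypothesis import given, strategies as st

import orchidmatk as om
from orchidmatk.seq_io import SequenceRecord
from orchidmatk.start_scan import EmptyOrfError, GeneStatusKind, StartCandidate

dna = st.text(alphabet="ACGT", min_size=1, max_size=300)


class TestAnchorCic:
    def test_identity_query_maps_to_itself(self, reference):
        pos, is_atg = om.anchor_cic(reference.record, reference.record,
                                    reference.cic_pos)
        assert pos == reference.cic_pos and is_atg

    def test_prefix_shifts_anchor_by_prefix_length(self, reference):
        query = SequenceRecord(id="q", residues="C" * 20 + reference.residues)
        pos, is_atg = om.anchor_cic(query, reference.record, reference.cic_pos)
        assert pos == reference.cic_pos + 20 and is_atg

    def test_upstream_insertion_shifts_cic_by_its_length(self, exemplar):
        # the 4-nt ATGT insertion lies 5' of the cic, so the cic moves +4
        pos, is_atg = om.anchor_cic(exemplar.orchid, exemplar.reference.record,
                                    exemplar.reference.cic_pos)
        assert pos == exemplar.reference.cic_pos + 4 == exemplar.cic_pos
        assert is_atg

    def test_unrelated_sequence_not_anchored(self, reference):
        rng = np.random.default_rng(0)
        junk = SequenceRecord(id="q", residues="".join(rng.choice(list("AC"), 400)))
        pos, _ = om.anchor_cic(junk, reference.record, reference.cic_pos)
        assert pos is None


class TestEnumerate:
    def test_exemplar_reports_minus10_minus6_and_cic(self, exemplar):
        scan = om.enumerate_start_candidates(exemplar.orchid, exemplar.cic_pos)
        offsets = {c.offset: c.frame_relation for c in scan.candidates}
        assert offsets == {-10: "out_of_frame", -6: "in_frame", 0: "in_frame"}
        assert not scan.truncated

    def test_no_upstream_atg_yields_cic_only(self, reference):
        scan = om.enumerate_start_candidates(reference.record, reference.cic_pos)
        assert [c.offset for c in scan.candidates] == [0]

    def test_matches_exhaustive_substring_oracle_on_random_sequences(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            seq = "".join(rng.choice(list("ACGT"), size=int(rng.integers(20, 400))))
            cic = int(rng.integers(1, len(seq) + 1))
            scan = om.enumerate_start_candidates(seq, cic)
            lo, hi = max(1, cic - 60), cic + 30
            oracle = [m.start() + 1 for m in re.finditer("(?=ATG)", seq)
                      if lo <= m.start() + 1 <= hi and m.start() + 3 <= len(seq)]
            assert [c.abs_pos for c in scan.candidates] == oracle
            assert scan.truncated == (cic - 60 < 1)

    def test_truncated_window_flagged_but_candidates_returned(self, exemplar):
        short = SequenceRecord(id="s", residues=exemplar.orchid.residues[exemplar.cic_pos - 21:])
        scan = om.enumerate_start_candidates(short, 21)
        assert scan.truncated
        assert {c.offset for c in scan.candidates} >= {-10, -6, 0}

    @given(dna)
    def test_candidate_triplets_are_atg(self, seq):
        scan = om.enumerate_start_candidates(seq, max(1, len(seq) // 2))
        for c in scan.candidates:
            assert seq[c.abs_pos - 1 : c.abs_pos + 2] == "ATG"
            assert c.in_frame == (c.offset % 3 == 0)


class TestEvaluateTranslation:
    def test_immediate_stop(self):
        cand = StartCandidate(abs_pos=1, offset=0)
        rep = om.evaluate_translation("ATGTAA", cand, ref_peptide_len=1)
        assert rep.peptide_len == 1 and rep.first_stop_codon == 2

    def test_injected_stop_is_located(self):
        ref = om.generate_reference_cds(len_codons=200, seed=9)
        c = ref.cic_pos
        p = c + 3 * 119  # first base of codon 120
        mutated = ref.residues[: p - 1] + "TAG" + ref.residues[p + 2 :]
        rep = om.evaluate_translation(mutated, StartCandidate(abs_pos=c, offset=0),
                                      ref_peptide_len=200)
        assert rep.first_stop_codon == 120 and rep.peptide_len == 119
        assert not rep.full_length

    def test_stop_free_reference_is_full_length(self, reference):
        rep = om.evaluate_translation(
            reference.record, StartCandidate(abs_pos=reference.cic_pos, offset=0),
            ref_peptide_len=reference.peptide_len)
        assert rep.full_length
        assert rep.peptide_len == reference.peptide_len
        assert rep.first_stop_codon == reference.peptide_len + 1

    def test_ambiguous_codons_translate_to_x_not_stop(self):
        seq = "ATG" + "TNA" + "TAA"  # N-containing codon must not terminate
        rep = om.evaluate_translation(seq, StartCandidate(abs_pos=1, offset=0),
                                      ref_peptide_len=2)
        assert rep.peptide == "MX" and rep.first_stop_codon == 3

    def test_empty_orf_is_an_error(self):
        with pytest.raises(EmptyOrfError):
            om.evaluate_translation("ATGTA", StartCandidate(abs_pos=1, offset=0),
                                    ref_peptide_len=1)


class TestClassify:
    def test_exemplar_is_aic_functional_at_minus10(self, exemplar):
        status = om.scan_record(exemplar.orchid, exemplar.reference.record,
                                exemplar.reference.cic_pos,
                                exemplar.reference.peptide_len)
        assert status.status == GeneStatusKind.AIC_FUNCTIONAL
        assert status.primary_start.offset == -10

    def test_all_candidates_premature_yields_no_full_orf(self, reference):
        variant, truth = om.apply_orchid_edit_model(reference, "pseudo", seed=2)
        status = om.scan_record(variant, reference.record, reference.cic_pos,
                                reference.peptide_len)
        assert status.status == GeneStatusKind.NO_FULL_ORF

    def test_five_prime_proximal_candidate_wins_when_both_full(self, reference):
        # an Anthosiphon-like case: an extra in-frame AUG 6 nt upstream of the
        # cic makes two full-length candidates; the upstream one is primary
        c = reference.cic_pos
        seq = reference.residues[: c - 1] + "ATGTTT" + reference.residues[c - 1 :]
        rec = SequenceRecord(id="double", residues=seq)
        scan = om.enumerate_start_candidates(rec, c + 6)
        status = om.classify_gene(rec, c + 6, scan, reference.peptide_len)
        full = [r.start.abs_pos for r in status.reports if r.full_length]
        assert len(full) >= 2
        assert status.primary_start.abs_pos == min(full)
        assert status.status == GeneStatusKind.ALT_INFRAME

    def test_invariant_to_prepending_utr_beyond_window(self, exemplar):
        base = om.scan_record(exemplar.orchid, exemplar.reference.record,
                              exemplar.reference.cic_pos,
                              exemplar.reference.peptide_len)
        padded = SequenceRecord(id="p", residues="C" * 80 + exemplar.orchid.residues)
        shifted = om.scan_record(padded, exemplar.reference.record,
                                 exemplar.reference.cic_pos,
                                 exemplar.reference.peptide_len)
        assert shifted.status == base.status
        assert shifted.primary_start.offset == base.primary_start.offset

    def test_truncated_record_is_undetermined(self, reference):
        variant, truth = om.apply_orchid_edit_model(reference, "truncated", seed=3)
        status = om.scan_record(variant, reference.record, reference.cic_pos,
                                reference.peptide_len)
        assert status.status == GeneStatusKind.UNDETERMINED_5PRIME_TRUNCATED

    def test_zero_noise_cohort_recovered_exactly(self):
        cohort = om.generate_cohort(om.CohortConfig(
            n_cic=3, n_aic=4, n_minus6=2, n_pseudo=2, n_truncated=2,
            ref_len_codons=200, seed=17))
        for rec, truth in zip(cohort.records, cohort.truths):
            status = om.scan_record(rec, cohort.reference.record,
                                    cohort.reference.cic_pos,
                                    cohort.reference.peptide_len)
            assert status.status == truth.true_status, rec.id
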