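"""Indel extraction, compensatory-set search and the distortion diff."""

import numpy as np
import pytest

import orchidmatk as om
from orchidmatk.frame_ledger import (CompensatorySet, FrameNotRestoredError,
                                     IndelEvent)
from orchidmatk.synth import Edit, replay_edits


class TestDetectIndels:
    def test_canonical_orchid_insertions(self, exemplar):
        events = om.detect_indels(exemplar.pair, exemplar.aic_pos)
        assert [(e.anchor_offset, e.length, e.kind) for e in events] == [
            (1, 4, "insertion"), (38, 4, "insertion"), (43, 1, "insertion")]

    def test_palmorchis_style_correction(self, reference):
        variant, truth = om.single_base_correction_pair(reference, reverse=False)
        pair = replay_edits(reference.residues, list(truth.edit_script))
        events = om.detect_indels(pair, reference.cic_pos)
        assert [(e.anchor_offset, e.length, e.kind) for e in events] == [
            (18, 1, "insertion"), (31, 1, "deletion")]

    def test_maxillaria_style_mirror(self, reference):
        variant, truth = om.single_base_correction_pair(reference, reverse=True)
        pair = replay_edits(reference.residues, list(truth.edit_script))
        events = om.detect_indels(pair, reference.cic_pos)
        assert [(e.anchor_offset, e.length, e.kind) for e in events] == [
            (18, 1, "deletion"), (31, 1, "insertion")]

    def test_identical_rows_have_no_events(self, reference):
        pair = replay_edits(reference.residues, [])
        assert om.detect_indels(pair, reference.cic_pos) == []

    def test_edit_script_replay_recovers_injected_indels(self, reference):
        rng = np.random.default_rng(23)
        c = reference.cic_pos
        for trial in range(20):
            # random non-overlapping indels downstream of the cic
            pos = sorted(rng.choice(np.arange(c + 5, c + 400, 10),
                                    size=3, replace=False))
            edits, expected = [], []
            for p in pos:
                length = int(rng.integers(1, 5))
                if rng.random() < 0.5:
                    ins = "".join(rng.choice(list("ACGT"), size=length))
                    edits.append(Edit(ref_pos=int(p), kind="insertion", seq=ins))
                else:
                    edits.append(Edit(ref_pos=int(p), kind="deletion", length=length))
            pair = replay_edits(reference.residues, edits)
            events = om.detect_indels(pair, c)
            assert [(e.length, e.kind) for e in events] == \
                [(e.length or len(e.seq), e.kind) for e in edits]


class TestNetFrameshift:
    def test_canonical_nine_base_triplet(self):
        events = [IndelEvent(1, 4, "insertion"), IndelEvent(38, 4, "insertion"),
                  IndelEvent(43, 1, "insertion")]
        assert om.net_frameshift(events) == (9, 0)

    def test_empty_event_list(self):
        assert om.net_frameshift([]) == (0, 0)

    def test_matches_direct_summation_on_random_lists(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            n = int(rng.integers(0, 8))
            offsets = np.cumsum(rng.integers(2, 30, size=n)) if n else []
            events = [IndelEvent(int(o), int(rng.integers(1, 6)),
                                 str(rng.choice(["insertion", "deletion"])))
                      for o in offsets]
            lo, hi = sorted(rng.integers(0, 250, size=2))
            net, mod = om.net_frameshift(events, (int(lo), int(hi)))
            oracle = sum(e.signed_length for e in events
                         if lo <= e.anchor_offset <= hi)
            assert (net, mod) == (oracle, oracle % 3)


def _oracle_partition(signed_lengths):
    """Independent earliest-closure oracle: prefix sums scanned 5'->3'."""
    groups, cur, total = [], [], 0
    for s in signed_lengths:
        cur.append(s)
        total += s
        if total % 3 == 0:
            groups.append((tuple(cur), True))
            cur, total = [], 0
    if cur:
        groups.append((tuple(cur), False))
    return groups


class TestCompensatorySets:
    def test_canonical_set_is_closed_nine_inserted(self, exemplar):
        events = om.detect_indels(exemplar.pair, exemplar.aic_pos)
        (cset,) = om.find_compensatory_sets(events)
        assert cset.closed and cset.total_inserted == 9
        assert cset.net_shift % 3 == 0
        assert cset.span == (1, 43)

    def test_deletion_insertion_pair_closes_at_net_zero(self):
        events = [IndelEvent(18, 1, "deletion"), IndelEvent(31, 1, "insertion")]
        (cset,) = om.find_compensatory_sets(events)
        assert cset.closed and cset.net_shift == 0

    def test_single_insertion_left_open(self):
        (cset,) = om.find_compensatory_sets([IndelEvent(10, 1, "insertion")])
        assert not cset.closed

    def test_exhaustive_oracle_over_all_small_event_lists(self):
        # every list of <= 5 events with lengths <= 4 and either kind
        options = [(l, k) for l in range(1, 5) for k in ("insertion", "deletion")]
        from itertools import product
        for n in range(0, 6):
            for combo in product(options, repeat=n):
                events = [IndelEvent(10 * (i + 1), l, k)
                          for i, (l, k) in enumerate(combo)]
                got = om.find_compensatory_sets(events)
                want = _oracle_partition([e.signed_length for e in events])
                assert [(tuple(e.signed_length for e in s.events), s.closed)
                        for s in got] == want


class TestDistortionDiff:
    def test_canonical_geometry_changes_eleven_residues(self, exemplar):
        events = om.detect_indels(exemplar.pair, exemplar.aic_pos)
        (cset,) = om.find_compensatory_sets(events)
        rep = om.distortion_diff(exemplar.pair, query_start=exemplar.aic_pos,
                                 ref_start=exemplar.reference.cic_pos, cset=cset)
        assert rep.n_changed == 11
        assert rep.span == (1, 43)

    def test_identical_sequences_change_nothing(self, reference):
        pair = replay_edits(reference.residues, [])
        cset = CompensatorySet(events=(IndelEvent(1, 3, "insertion"),), closed=True)
        # span of a dummy closed set over the start; no residue differs
        rep = om.distortion_diff(pair, reference.cic_pos, reference.cic_pos, cset)
        assert rep.n_changed == 0

    def test_in_frame_triplet_insertion_is_one_gap_no_change(self, reference):
        c = reference.cic_pos
        edits = [Edit(ref_pos=c + 30, kind="insertion", seq="GCA")]
        pair = replay_edits(reference.residues, edits)
        events = om.detect_indels(pair, c)
        (cset,) = om.find_compensatory_sets(events)
        assert cset.closed
        rep = om.distortion_diff(pair, c, c, cset)
        assert rep.n_changed == 0 and rep.n_gap_cols == 1

    def test_open_set_raises(self, reference):
        c = reference.cic_pos
        pair = replay_edits(reference.residues,
                            [Edit(ref_pos=c + 30, kind="insertion", seq="G")])
        (cset,) = om.find_compensatory_sets(om.detect_indels(pair, c))
        with pytest.raises(FrameNotRestoredError):
            om.distortion_diff(pair, c, c, cset)

    def test_invariant_to_synonymous_change_outside_span(self, exemplar):
        # recode a downstream leucine codon (CTT<->CTC etc.) far 3' of the span
        ref = exemplar.reference
        orchid = exemplar.orchid.residues
        c_ref = ref.cic_pos
        # find a downstream reference codon starting with CT (Leu, 4-fold box)
        for j in range(60, ref.peptide_len - 10):
            p = c_ref + 3 * (j - 1)
            if ref.residues[p - 1 : p + 1] == "CT":
                break
        else:
            pytest.skip("no CT-leading codon found")
        swapped = ref.residues[: p + 1] + ("C" if ref.residues[p + 1] != "C" else "T") \
            + ref.residues[p + 2 :]
        ref2 = om.Reference(record=om.SequenceRecord(id="ref2", residues=swapped),
                            cic_pos=ref.cic_pos, peptide_len=ref.peptide_len)
        pair2 = om.GappedPair(query_id="q", ref_id="r",
                              query_aln=exemplar.pair.query_aln,
                              ref_aln=_apply_point(exemplar.pair.ref_aln, ref.residues,
                                                   swapped))
        events = om.detect_indels(pair2, exemplar.aic_pos)
        (cset,) = om.find_compensatory_sets(events)
        rep = om.distortion_diff(pair2, exemplar.aic_pos, ref2.cic_pos, cset)
        assert rep.n_changed == 11

    def test_frame_restored_downstream_of_span(self, exemplar):
        # downstream of the compensatory span the two frames encode the same
        # residues (codon-column mapping coincides)
        from orchidmatk.start_scan import translate_from
        qpep, _ = translate_from(exemplar.orchid.residues, exemplar.aic_pos)
        rpep, _ = translate_from(exemplar.reference.residues,
                                 exemplar.reference.cic_pos)
        assert qpep[15:] == rpep[10:]


def _apply_point(ref_aln, old_seq, new_seq):
    """Rewrite the gapped reference row after a point change in the sequence."""
    out, i = [], 0
    for ch in ref_aln:
        if ch == "-":
            out.append(ch)
        else:
            out.append(new_seq[i])
            i += 1
    assert i == len(old_seq)
    return "".join(out)
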