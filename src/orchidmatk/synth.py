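"""Synthetic matK-like data with known truth labels.

Every pipeline stage is testable without downloads: this module generates a
monocot-like reference CDS (ATG start, stop-free frame, clean 5' window),
derives orchid-style variants from it by a replayable edit script, and
simulates initiation-codon character histories on random trees.

Variant modes mirror the structures seen in real orchid *matK*:

``cic``
    unchanged reading frame (consensus initiation codon functional).
``aic``
    a 4-nt ``ATGT`` insertion placing a new out-of-frame AUG 10 nt upstream
    of the cic, plus two downstream compensatory insertions (4 nt whose
    first base sits at +38 and 1 nt at +43 from the aic, anchor A = +1);
    9 nt inserted in total, a triplet, so the aic frame realigns with the
    reference frame downstream while the cic frame hits a premature stop.
``minus6``
    the cic ATG destroyed and an in-frame AUG planted 6 nt upstream
    (the rare orchid configuration lacking both cic and aic).
``pseudo``
    an uncompensated single-base insertion: premature stops in every
    candidate frame, a true pseudogene structure.
``truncated``
    the 5' region removed past the scan window, leaving the initiation
    codon undeterminable.

The generator *verifies* each variant's label-defining properties (and
resamples inserted bases, or substitutes distorted-region bases, within a
bounded retry budget) rather than assuming them; a variant is never silently
mislabelled.  Cohort substitutions are constrained so truth labels stay
valid: they avoid start/stop codons, indel neighbourhoods and the whole scan
window, and are rejected when they would create a stop codon in the
label-defining reading frame.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd

from .codon_phylo import STATES, TipStateMap, TransitionEvent, _node_label
from .frame_ledger import IndelEvent
from .seq_io import (Feature, FeatureTable, GappedPair, SequenceRecord,
                     revcomp, tree_from_string, write_fasta)
from .splice_check import (DEFAULT_FWD_PRIMER, DEFAULT_REV_PRIMER, PrimerPair,
                           find_primer_sites)
from .start_scan import (FULL_LENGTH_FRAC, GeneStatusKind, STOP_CODONS,
                         WINDOW_DOWN, WINDOW_UP, translate_from)

_BASES = np.array(list("ACGT"))
_SENSE_CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
                 if a + b + c not in STOP_CODONS]
_SENSE_NO_ATG = [c for c in _SENSE_CODONS if c != "ATG"]

UTR5_LEN = 80
UTR3_LEN = 30
REF_LEN_CODONS = 510  # ~62 kDa MatK scale


class SynthesisError(RuntimeError):
    """Retry budget exhausted while enforcing a variant's truth label."""


# ---------------------------------------------------------------------------
# Edit scripts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Edit:
    """One replayable edit in *reference* coordinates (1-based).

    ``insertion``: ``seq`` inserted immediately before ``ref_pos``;
    ``deletion``: ``length`` reference bases removed starting at ``ref_pos``;
    ``substitution``: reference bases starting at ``ref_pos`` replaced by
    ``seq`` (same length).
    """

    ref_pos: int
    kind: str  # insertion | deletion | substitution
    seq: str = ""
    length: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("insertion", "deletion", "substitution"):
            raise ValueError(f"bad edit kind {self.kind!r}")
        if self.kind == "deletion":
            if self.length < 1:
                raise ValueError("deletion needs length >= 1")
        elif not self.seq:
            raise ValueError(f"{self.kind} needs a sequence")


def replay_edits(ref_residues: str, edits: Sequence[Edit]) -> GappedPair:
    """Apply an edit script to the reference, producing the variant alignment.

    Edits must be non-overlapping; they are applied 5'->3' (insertions
    before a position sort ahead of substitutions/deletions at it).
    """
    ordered = sorted(enumerate(edits),
                     key=lambda t: (t[1].ref_pos, t[1].kind != "insertion", t[0]))
    q: list[str] = []
    r: list[str] = []
    p = 1  # next unconsumed reference position
    for _, e in ordered:
        if e.ref_pos < p:
            raise ValueError("overlapping edits in script")
        block = ref_residues[p - 1 : e.ref_pos - 1]
        q.append(block)
        r.append(block)
        if e.kind == "insertion":
            q.append(e.seq)
            r.append("-" * len(e.seq))
            p = e.ref_pos
        elif e.kind == "deletion":
            q.append("-" * e.length)
            r.append(ref_residues[e.ref_pos - 1 : e.ref_pos - 1 + e.length])
            p = e.ref_pos + e.length
        else:  # substitution
            q.append(e.seq)
            r.append(ref_residues[e.ref_pos - 1 : e.ref_pos - 1 + len(e.seq)])
            p = e.ref_pos + len(e.seq)
    tail = ref_residues[p - 1 :]
    q.append(tail)
    r.append(tail)
    return GappedPair(query_id="variant", ref_id="reference",
                      query_aln="".join(q), ref_aln="".join(r))


def _variant_ref_map(ref_residues: str, edits: Sequence[Edit]) -> list[int | None]:
    """Reference position of each variant base (None for inserted bases)."""
    pair = replay_edits(ref_residues, edits)
    v2r: list[int | None] = []
    rpos = 0
    for qc, rc in zip(pair.query_aln, pair.ref_aln):
        if rc != "-":
            rpos += 1
        if qc != "-":
            v2r.append(rpos if rc != "-" else None)
    return v2r


@dataclass(frozen=True)
class SynthTruth:
    """Ground truth for one synthetic variant."""

    record_id: str
    true_status: GeneStatusKind
    mode: str
    edit_script: tuple[Edit, ...]
    expected_indels: tuple[IndelEvent, ...]  # vs reference, anchored below
    indel_anchor: int | None  # 1-based anchor position on the variant
    injected_stops: tuple[int, ...]  # cic-frame codon indices, if any
    seed_used: int
    cic_pos: int  # 1-based cic-homologous position on the variant
    aic_pos: int | None  # 1-based aic position, aic mode only


@dataclass(frozen=True)
class Reference:
    """A monocot-like reference: UTR5 + ATG..stop CDS + UTR3."""

    record: SequenceRecord
    cic_pos: int
    peptide_len: int

    @property
    def residues(self) -> str:
        return self.record.residues


# ---------------------------------------------------------------------------
# Reference generation
# ---------------------------------------------------------------------------

def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_BASES, size=n))


def _window_atg_positions(residues: str, cic_pos: int,
                          window_up: int = WINDOW_UP,
                          window_down: int = WINDOW_DOWN) -> set[int]:
    lo = max(1, cic_pos - window_up)
    hi = min(cic_pos + window_down, len(residues) - 2)
    return {p for p in range(lo, hi + 1) if residues[p - 1 : p + 2] == "ATG"}


def generate_reference_cds(len_codons: int = REF_LEN_CODONS, seed: int = 0,
                           utr5: str | None = None,
                           utr3_len: int = UTR3_LEN,
                           max_retries: int = 500) -> Reference:
    """A reference CDS with clean start context, deterministic per seed.

    The CDS starts with ATG, contains no in-frame internal stop, ends in a
    single terminal stop, and the scan window around the cic holds no AUG
    other than the cic itself (the first ten post-start codons also avoid
    ATG, keeping windowed scans of derived variants interpretable).
    """
    if len_codons < 50:
        raise ValueError("len_codons must be >= 50")
    rng = np.random.default_rng(seed)
    for _ in range(max_retries):
        u5 = utr5 if utr5 is not None else _random_dna(rng, UTR5_LEN)
        body = ["ATG"]
        body += list(rng.choice(_SENSE_NO_ATG, size=10))
        body += list(rng.choice(_SENSE_CODONS, size=len_codons - 11))
        body.append("TAA")
        cds = "".join(body)
        u3 = _random_dna(rng, utr3_len)
        residues = u5 + cds + u3
        cic = len(u5) + 1
        if _window_atg_positions(residues, cic) == {cic}:
            rec = SequenceRecord(id=f"ref_seed{seed}", residues=residues,
                                 description="synthetic monocot-like matK reference")
            return Reference(record=rec, cic_pos=cic, peptide_len=len_codons)
    raise SynthesisError("could not generate a clean reference (retry budget)")


# ---------------------------------------------------------------------------
# Orchid edit model
# ---------------------------------------------------------------------------

def _first_stop(residues: str, start_pos: int) -> tuple[int, int | None]:
    pep, stop = translate_from(residues, start_pos)
    return len(pep), stop


def _is_premature(residues: str, start_pos: int, ref_len: int,
                  frac: float = FULL_LENGTH_FRAC) -> bool:
    pep_len, stop = _first_stop(residues, start_pos)
    return stop is not None and pep_len < frac * ref_len


def _destop(codon: str) -> str:
    """Minimal middle-base change making a stop codon a sense codon."""
    return codon[0] + "C" + codon[2]


def apply_orchid_edit_model(ref: Reference, mode: str, seed: int = 0,
                            with_minus6: bool = False,
                            max_retries: int = 60
                            ) -> tuple[SequenceRecord, SynthTruth]:
    """Derive one orchid-style variant from the reference, truth recorded.

    See the module docstring for the modes.  ``with_minus6`` additionally
    plants the in-frame -6 AUG seen in a subset of orchids (aic mode only).
    """
    if mode not in ("cic", "aic", "minus6", "pseudo", "truncated"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    c = ref.cic_pos
    L = ref.peptide_len
    res = ref.residues

    if mode == "cic":
        rec = SequenceRecord(id=f"cic_seed{seed}", residues=res)
        truth = SynthTruth(record_id=rec.id, true_status=GeneStatusKind.CIC_FUNCTIONAL,
                           mode=mode, edit_script=(), expected_indels=(),
                           indel_anchor=None, injected_stops=(), seed_used=seed,
                           cic_pos=c, aic_pos=None)
        return rec, truth

    if mode == "truncated":
        keep_from = c - 20  # leaves 20 nt of UTR; the 60-nt window overruns
        edits = [Edit(ref_pos=1, kind="deletion", length=keep_from - 1)]
        pair = replay_edits(res, edits)
        rec = SequenceRecord(id=f"truncated_seed{seed}", residues=pair.query_seq)
        truth = SynthTruth(record_id=rec.id,
                           true_status=GeneStatusKind.UNDETERMINED_5PRIME_TRUNCATED,
                           mode=mode, edit_script=tuple(edits), expected_indels=(),
                           indel_anchor=None, injected_stops=(), seed_used=seed,
                           cic_pos=21, aic_pos=None)
        return rec, truth

    if mode == "minus6":
        edits: list[Edit] = []
        if res[c - 7 : c - 4] != "ATG":  # plant the -6 in-frame AUG
            edits.append(Edit(ref_pos=c - 6, kind="substitution", seq="ATG"))
        mid = res[c - 4 : c - 1]  # codon between the -6 AUG and the cic
        if mid in STOP_CODONS:
            edits.append(Edit(ref_pos=c - 3, kind="substitution", seq=_destop(mid)))
        edits.append(Edit(ref_pos=c, kind="substitution", seq="C"))  # ATG -> CTG
        pair = replay_edits(res, edits)
        variant = pair.query_seq
        if _window_atg_positions(variant, c) != {c - 6}:
            raise SynthesisError("minus6 variant has unexpected window AUGs")
        pep_len, stop = _first_stop(variant, c - 6)
        if not (pep_len == L + 2 and stop == L + 3):
            raise SynthesisError("minus6 variant failed full-length verification")
        rec = SequenceRecord(id=f"minus6_seed{seed}", residues=variant)
        truth = SynthTruth(record_id=rec.id, true_status=GeneStatusKind.ALT_INFRAME,
                           mode=mode, edit_script=tuple(edits), expected_indels=(),
                           indel_anchor=None, injected_stops=(), seed_used=seed,
                           cic_pos=c, aic_pos=None)
        return rec, truth

    if mode == "pseudo":
        ins_at = c + 3 * 30  # first base of codon 31
        injected: tuple[int, ...] = ()
        for _ in range(max_retries):
            base = str(rng.choice(_BASES))
            edits = [Edit(ref_pos=ins_at, kind="insertion", seq=base)]
            variant = replay_edits(res, edits).query_seq
            if _window_atg_positions(variant, c) != {c}:
                continue
            if _is_premature(variant, c, L):
                break
        else:
            edits = [Edit(ref_pos=ins_at, kind="insertion", seq="A")]
            variant, edits, stop_idx = _inject_cic_stop(res, edits, c, L,
                                                        keep_open=[])
            injected = (stop_idx,)
        rec = SequenceRecord(id=f"pseudo_seed{seed}", residues=variant)
        truth = SynthTruth(record_id=rec.id, true_status=GeneStatusKind.NO_FULL_ORF,
                           mode=mode, edit_script=tuple(edits),
                           expected_indels=(IndelEvent(anchor_offset=3 * 30 + 1,
                                                       length=1, kind="insertion"),),
                           indel_anchor=c, injected_stops=injected, seed_used=seed,
                           cic_pos=c, aic_pos=None)
        return rec, truth

    # ---- mode == "aic" ----
    seg_edits: list[Edit] = []
    if with_minus6 and res[c - 7 : c - 4] != "ATG":
        seg_edits.append(Edit(ref_pos=c - 6, kind="substitution", seq="ATG"))
    aic_q, cic_q = c - 6, c + 4  # reference prefix untouched by the edits
    for _ in range(max_retries):
        i4 = _random_dna(rng, 4)
        i6 = _random_dna(rng, 1)
        edits = list(seg_edits) + [
            Edit(ref_pos=c - 6, kind="insertion", seq="ATGT"),
            Edit(ref_pos=c + 27, kind="insertion", seq=i4),
            Edit(ref_pos=c + 28, kind="insertion", seq=i6),
        ]
        variant = replay_edits(res, edits).query_seq
        v2r = _variant_ref_map(res, edits)
        repaired = _repair_aic_frame(variant, aic_q, v2r)
        if repaired is None:
            continue  # a distorted-region stop involves an inserted base
        variant, repair_edits = repaired
        edits += repair_edits
        expected_atg = {aic_q, cic_q} | ({cic_q - 6} if with_minus6 else set())
        if _window_atg_positions(variant, cic_q) != expected_atg:
            continue
        pep_len, stop = _first_stop(variant, aic_q)
        if not (pep_len == L + 5 and stop == L + 6):
            continue
        injected = ()
        if not _is_premature(variant, cic_q, L):
            variant, edits, stop_idx = _inject_cic_stop(res, edits, cic_q, L,
                                                        keep_open=[aic_q])
            injected = (stop_idx,)
        rec = SequenceRecord(id=f"aic_seed{seed}", residues=variant)
        truth = SynthTruth(
            record_id=rec.id, true_status=GeneStatusKind.AIC_FUNCTIONAL,
            mode=mode, edit_script=tuple(edits),
            expected_indels=(
                IndelEvent(anchor_offset=1, length=4, kind="insertion"),
                IndelEvent(anchor_offset=38, length=4, kind="insertion"),
                IndelEvent(anchor_offset=43, length=1, kind="insertion"),
            ),
            indel_anchor=aic_q, injected_stops=injected, seed_used=seed,
            cic_pos=cic_q, aic_pos=aic_q)
        return rec, truth
    raise SynthesisError("aic variant failed verification (retry budget)")


def _repair_aic_frame(variant: str, aic_q: int, v2r: list[int | None],
                      max_fix: int = 15) -> tuple[str, list[Edit]] | None:
    """Remove aic-frame stops in the distorted region (codons 2..15).

    Stops whose middle base is a reference base are fixed by substituting it
    with ``C`` (recorded as an edit); a stop whose middle base was inserted
    signals the caller to resample the insertions (returns None).
    """
    extra: list[Edit] = []
    v = variant
    for _ in range(max_fix):
        hit = None
        for qi in range(2, 16):
            p = aic_q + 3 * (qi - 1)
            if v[p - 1 : p + 2] in STOP_CODONS:
                hit = p
                break
        if hit is None:
            return v, extra
        mid_q = hit + 1  # variant position of the middle base
        ref_pos = v2r[mid_q - 1]
        if ref_pos is None:
            return None
        v = v[: mid_q - 1] + "C" + v[mid_q:]
        extra.append(Edit(ref_pos=ref_pos, kind="substitution", seq="C"))
    return None


def _inject_cic_stop(ref_res: str, edits: list[Edit], frame_start: int, L: int,
                     keep_open: list[int]) -> tuple[str, list[Edit], int]:
    """Force a premature stop in the frame starting at ``frame_start``.

    Searches downstream codons of that frame for a single-base substitution
    creating a stop without terminating any frame in ``keep_open``; only
    needed when a frame shift happens not to produce an early stop itself.
    """
    variant = replay_edits(ref_res, edits).query_seq
    v2r = _variant_ref_map(ref_res, edits)
    for j in range(40, L - 30):
        p = frame_start + 3 * (j - 1)
        codon = variant[p - 1 : p + 2]
        for stop in ("TAA", "TAG", "TGA"):
            diff = [k for k in range(3) if codon[k] != stop[k]]
            if len(diff) != 1:
                continue
            vpos = p + diff[0]
            ref_pos = v2r[vpos - 1]
            if ref_pos is None:
                continue
            trial = variant[: vpos - 1] + stop[diff[0]] + variant[vpos:]
            ok = all(
                (lambda pe_st: pe_st[1] is None or pe_st[0] >= L)
                (_first_stop(trial, other))
                for other in keep_open
            )
            if ok and _is_premature(trial, frame_start, L):
                new_edits = edits + [Edit(ref_pos=ref_pos, kind="substitution",
                                          seq=stop[diff[0]])]
                return trial, new_edits, j
    raise SynthesisError("could not inject a premature stop")


# ---------------------------------------------------------------------------
# The canonical aic fixture
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AicExemplar:
    """Reference + canonical aic orchid variant with verified headline counts.

    The orchid carries exactly the three insertions of the canonical
    geometry (4 nt at +1 creating the aic, 4 nt at +38, 1 nt at +43 from the
    aic), the -6 in-frame AUG, an SD-like 4/5 core at -31..-28 from the aic,
    a GAA -1 triplet at the aic, and a distorted region in which all eleven
    pairable codons encode different residues between the aic and cic
    frames.
    """

    reference: Reference
    orchid: SequenceRecord
    truth: SynthTruth
    pair: GappedPair

    @property
    def aic_pos(self) -> int:
        assert self.truth.aic_pos is not None
        return self.truth.aic_pos

    @property
    def cic_pos(self) -> int:
        return self.truth.cic_pos


def _exemplar_utr5(rng: np.random.Generator) -> str:
    u = list(_random_dna(rng, UTR5_LEN))
    u[43:47] = "GGAG"    # SD-like core, -31..-28 from the aic
    u[47] = "A"          # break the fifth consensus position
    u[71:74] = "GAA"     # -1 triplet of the aic (no uracil at -1)
    u[74:80] = "CTGCAA"  # segment preceding the cic; C->A creates the -6 AUG
    return "".join(u)


def _sd_placement_ok(orchid_residues: str, aic_q: int) -> bool:
    """Exactly one >= 4/5 SD placement, the one whose core is -31..-28."""
    from .regulatory_scan import SD_CONSENSUS
    good = 0
    for off in range(-44, -5):
        window = orchid_residues[aic_q + off - 1 : aic_q + off + 4]
        if len(window) < 5:
            continue
        matches = sum(a == b for a, b in zip(window, SD_CONSENSUS))
        if matches >= 4:
            if off != -31:
                return False
            good += 1
    return good == 1


def aic_exemplar(seed: int = 2015, len_codons: int = REF_LEN_CODONS,
                 max_attempts: int = 500) -> AicExemplar:
    """Deterministically construct the canonical orchid aic fixture.

    Construction searches seeded reference draws until the variant
    satisfies, by direct sequence checks: candidate AUGs exactly at
    -10/-6/0, a full-length aic frame with no repair substitutions inside
    the distorted region, a premature cic-frame stop, a unique SD placement,
    and residue mismatches at all eleven pairable codons of the distorted
    region.
    """
    for attempt in range(max_attempts):
        rng = np.random.default_rng([seed, attempt])
        u5 = _exemplar_utr5(rng)
        if "ATG" in u5 or "GGAGG" in u5:
            continue
        sub_seed = int(rng.integers(0, 2**31 - 1))
        try:
            ref = generate_reference_cds(len_codons, seed=sub_seed, utr5=u5)
            orchid, truth = apply_orchid_edit_model(ref, "aic", seed=sub_seed,
                                                    with_minus6=True)
        except SynthesisError:
            continue
        if any(e.kind == "substitution" and e.ref_pos > ref.cic_pos
               for e in truth.edit_script):
            continue  # repair inside the distorted region perturbs the counts
        if truth.injected_stops:
            continue
        assert truth.aic_pos is not None
        if not _sd_placement_ok(orchid.residues, truth.aic_pos):
            continue
        if not _distortion_is_eleven(orchid.residues, ref, truth.aic_pos):
            continue
        pair = replay_edits(ref.residues, list(truth.edit_script))
        return AicExemplar(reference=ref, orchid=orchid,
                           truth=replace(truth, record_id="orchid_exemplar"),
                           pair=pair)
    raise SynthesisError("exemplar construction failed (attempt budget)")


def _distortion_is_eleven(orchid: str, ref: Reference, aic_q: int) -> bool:
    """Direct check that all 11 pairable distorted-region codons mismatch.

    In the canonical geometry the aic-frame codons 4..14 pair with reference
    codons 1..9, 9 and 10 respectively (aic codons 1..3 have no reference
    counterpart); the headline count requires all eleven pairs to differ.
    """
    qpep, _ = translate_from(orchid, aic_q)
    rpep, _ = translate_from(ref.residues, ref.cic_pos)
    pairs = [(qi, qi - 3) for qi in range(4, 13)] + [(13, 9), (14, 10)]
    return all(qpep[qi - 1] != rpep[ri - 1] for qi, ri in pairs)


# ---------------------------------------------------------------------------
# Companion fixtures: cic-maintaining single-base indel pairs
# ---------------------------------------------------------------------------

def single_base_correction_pair(ref: Reference, reverse: bool = False,
                                seed: int = 0) -> tuple[SequenceRecord, SynthTruth]:
    """A variant with a frame-restoring 1-nt insertion/deletion pair.

    ``reverse=False`` inserts one base at +18 from the cic and deletes one
    so the deletion reports at +31 (the Palmorchis-style correction);
    ``reverse=True`` swaps the two event kinds (the Maxillaria-style
    mirror).  The net shift is 0, restoring the cic frame downstream.  The
    fixture realizes the ledger geometry; the short distorted region between
    the events may alter (or terminate) a few residues, so it carries no
    classification guarantee.
    """
    rng = np.random.default_rng(seed)
    c = ref.cic_pos
    if reverse:
        edits = [Edit(ref_pos=c + 17, kind="deletion", length=1),
                 Edit(ref_pos=c + 31, kind="insertion", seq=str(rng.choice(_BASES)))]
        expected = (IndelEvent(anchor_offset=18, length=1, kind="deletion"),
                    IndelEvent(anchor_offset=31, length=1, kind="insertion"))
    else:
        edits = [Edit(ref_pos=c + 17, kind="insertion", seq=str(rng.choice(_BASES))),
                 Edit(ref_pos=c + 29, kind="deletion", length=1)]
        expected = (IndelEvent(anchor_offset=18, length=1, kind="insertion"),
                    IndelEvent(anchor_offset=31, length=1, kind="deletion"))
    pair = replay_edits(ref.residues, edits)
    rec = SequenceRecord(id="maxillaria_like" if reverse else "palmorchis_like",
                         residues=pair.query_seq)
    truth = SynthTruth(record_id=rec.id, true_status=GeneStatusKind.CIC_FUNCTIONAL,
                       mode="cic_indel_pair", edit_script=tuple(edits),
                       expected_indels=expected, indel_anchor=c,
                       injected_stops=(), seed_used=seed, cic_pos=c, aic_pos=None)
    return rec, truth


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortConfig:
    n_cic: int = 2
    n_aic: int = 3
    n_minus6: int = 1
    n_pseudo: int = 1
    n_truncated: int = 1
    ref_len_codons: int = REF_LEN_CODONS
    sub_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_cic", "n_aic", "n_minus6", "n_pseudo", "n_truncated"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0 <= self.sub_rate < 0.5):
            raise ValueError("sub_rate must be in [0, 0.5)")

    @property
    def total(self) -> int:
        return (self.n_cic + self.n_aic + self.n_minus6 + self.n_pseudo
                + self.n_truncated)


@dataclass(frozen=True)
class Cohort:
    reference: Reference
    records: tuple[SequenceRecord, ...]
    truths: tuple[SynthTruth, ...]

    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"record_id": [t.record_id for t in self.truths],
             "true_status": [t.true_status.value for t in self.truths],
             "mode": [t.mode for t in self.truths],
             "n_edits": [len(t.edit_script) for t in self.truths],
             "seed_used": [t.seed_used for t in self.truths]}
        )

    def write(self, out_prefix: str | Path) -> None:
        out_prefix = Path(out_prefix)
        out_prefix.parent.mkdir(parents=True, exist_ok=True)
        write_fasta(self.records, f"{out_prefix}cohort.fasta")
        write_fasta([self.reference.record], f"{out_prefix}reference.fasta")
        self.truth_frame().to_csv(f"{out_prefix}truth.tsv", sep="\t", index=False)


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate a labelled cohort of variants from one shared reference."""
    ref = generate_reference_cds(config.ref_len_codons, seed=config.seed)
    modes = (["cic"] * config.n_cic + ["aic"] * config.n_aic
             + ["minus6"] * config.n_minus6 + ["pseudo"] * config.n_pseudo
             + ["truncated"] * config.n_truncated)
    records: list[SequenceRecord] = []
    truths: list[SynthTruth] = []
    for i, mode in enumerate(modes):
        rec_seed = config.seed + i + 1
        variant, truth = apply_orchid_edit_model(ref, mode, seed=rec_seed)
        if config.sub_rate > 0:
            variant, truth = _substitute(ref, variant, truth, config.sub_rate,
                                         np.random.default_rng([config.seed, i]))
        rid = f"{mode}_{i:03d}"
        records.append(SequenceRecord(id=rid, residues=variant.residues))
        truths.append(replace(truth, record_id=rid))
    return Cohort(reference=ref, records=tuple(records), truths=tuple(truths))


def _functional_start(truth: SynthTruth) -> int | None:
    if truth.mode == "cic":
        return truth.cic_pos
    if truth.mode == "aic":
        return truth.aic_pos
    if truth.mode == "minus6":
        return truth.cic_pos - 6
    return None


def _substitute(ref: Reference, variant: SequenceRecord, truth: SynthTruth,
                rate: float, rng: np.random.Generator,
                max_retries: int = 30) -> tuple[SequenceRecord, SynthTruth]:
    """Label-preserving substitutions at ``rate`` per eligible site.

    Protected: the whole scan window, inserted bases and +-2 nt around every
    edit, the functional frame's terminal stop, and the first cic-frame stop
    of aic/pseudo variants.  A proposed substitution that would create a
    stop in the label-defining frame is skipped; the label-defining
    properties are re-verified after sampling and the draw repeated on
    (rare) failure.
    """
    res = ref.residues
    n = len(variant.residues)
    v2r = _variant_ref_map(res, truth.edit_script)

    protected: set[int] = set()
    c = truth.cic_pos
    protected |= set(range(max(1, c - WINDOW_UP), min(n, c + WINDOW_DOWN + 2) + 1))
    protected |= {i + 1 for i, rp in enumerate(v2r) if rp is None}
    for e in truth.edit_script:
        width = e.length if e.kind == "deletion" else len(e.seq)
        lo, hi = e.ref_pos - 2, e.ref_pos + width + 2
        protected |= {i + 1 for i, rp in enumerate(v2r)
                      if rp is not None and lo <= rp <= hi}
    start = _functional_start(truth)
    if start is not None:
        _, stop = _first_stop(variant.residues, start)
        if stop is not None:
            p = start + 3 * (stop - 1)
            protected |= {p, p + 1, p + 2}
    if truth.mode in ("aic", "pseudo"):
        _, cstop = _first_stop(variant.residues, truth.cic_pos)
        if cstop is not None:
            p = truth.cic_pos + 3 * (cstop - 1)
            protected |= {p, p + 1, p + 2}

    for _ in range(max_retries):
        seq = list(variant.residues)
        new_edits: list[Edit] = []
        mask = rng.random(n) < rate
        alt_idx = rng.integers(0, 3, size=n)
        for i in np.flatnonzero(mask):
            pos = int(i) + 1
            if pos in protected or v2r[i] is None:
                continue
            old = seq[i]
            new = [b for b in "ACGT" if b != old][int(alt_idx[i])]
            seq[i] = new
            if start is not None and pos >= start:
                k = (pos - start) // 3
                codon = "".join(seq[start - 1 + 3 * k : start + 2 + 3 * k])
                if len(codon) == 3 and codon in STOP_CODONS:
                    seq[i] = old  # would terminate the functional frame
                    continue
            new_edits.append(Edit(ref_pos=v2r[i], kind="substitution", seq=new))
        mutated = "".join(seq)
        if _verify_label(mutated, truth, ref):
            rec = SequenceRecord(id=variant.id, residues=mutated)
            merged = tuple(list(truth.edit_script) + new_edits)
            return rec, replace(truth, edit_script=merged)
    raise SynthesisError("substitution sampling kept violating the truth label")


def _verify_label(residues: str, truth: SynthTruth, ref: Reference) -> bool:
    L = ref.peptide_len
    if truth.mode == "cic":
        pep, stop = _first_stop(residues, truth.cic_pos)
        return pep == L and stop == L + 1
    if truth.mode == "aic":
        assert truth.aic_pos is not None
        pep, stop = _first_stop(residues, truth.aic_pos)
        return (pep == L + 5 and stop == L + 6
                and _is_premature(residues, truth.cic_pos, L))
    if truth.mode == "minus6":
        pep, stop = _first_stop(residues, truth.cic_pos - 6)
        return pep == L + 2 and stop == L + 3
    if truth.mode == "pseudo":
        return _is_premature(residues, truth.cic_pos, L)
    return True  # truncated: undetermined whatever happens downstream


# ---------------------------------------------------------------------------
# trnK-like region for the splice check
# ---------------------------------------------------------------------------

def generate_trnk_region(seed: int = 0, unspliced_target: int = 2833,
                         max_retries: int = 50
                         ) -> tuple[SequenceRecord, FeatureTable, PrimerPair]:
    """A trnK-like exon/intron/exon model calibrated to the assay layout.

    Exon-anchored primers give a short spliced product (50-56 nt depending
    on the drawn 5' exon length) and an unspliced product of
    ``unspliced_target`` nt.
    """
    rng = np.random.default_rng(seed)
    primers = PrimerPair(fwd_name=DEFAULT_FWD_PRIMER[0], fwd_seq=DEFAULT_FWD_PRIMER[1],
                         rev_name=DEFAULT_REV_PRIMER[0], rev_seq=DEFAULT_REV_PRIMER[1])
    exon3_len = 26
    for _ in range(max_retries):
        exon5_len = int(rng.integers(30, 37))
        spliced = exon5_len + 3 + len(primers.rev_seq)  # fwd at exon5 start
        intron_len = unspliced_target - spliced
        exon5 = primers.fwd_seq + _random_dna(rng, exon5_len - len(primers.fwd_seq))
        exon3 = (_random_dna(rng, 3) + revcomp(primers.rev_seq)
                 + _random_dna(rng, exon3_len - 3 - len(primers.rev_seq)))
        pre = _random_dna(rng, 8)
        post = _random_dna(rng, 10)
        residues = pre + exon5 + _random_dna(rng, intron_len) + exon3 + post
        rec = SequenceRecord(id=f"trnk_seed{seed}", residues=residues)
        if (len([s for s in find_primer_sites(rec, primers.fwd_seq) if s[1] == "+"]) != 1
                or len([s for s in find_primer_sites(rec, primers.rev_seq) if s[1] == "-"]) != 1):
            continue
        e5 = Feature(record_id=rec.id, start=9, end=8 + exon5_len, label="exon5")
        intr = Feature(record_id=rec.id, start=9 + exon5_len,
                       end=8 + exon5_len + intron_len, label="intron")
        e3 = Feature(record_id=rec.id, start=9 + exon5_len + intron_len,
                     end=8 + exon5_len + intron_len + exon3_len, label="exon3")
        return rec, FeatureTable(features=(e5, intr, e3)), primers
    raise SynthesisError("trnK region generation failed (retry budget)")


# ---------------------------------------------------------------------------
# Trees and character histories
# ---------------------------------------------------------------------------

def random_tree(n_tips: int, seed: int = 0,
                tip_labels: Sequence[str] | None = None) -> dendropy.Tree:
    """A random rooted binary tree with labelled internal nodes."""
    if n_tips < 2:
        raise ValueError("need >= 2 tips")
    rng = np.random.default_rng(seed)
    labels = list(tip_labels) if tip_labels else [f"t{i}" for i in range(1, n_tips + 1)]
    if len(labels) != n_tips:
        raise ValueError("tip_labels length must equal n_tips")
    nodes = list(labels)
    counter = 0
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        counter += 1
        merged = f"({nodes[i]},{nodes[j]})n{counter}"
        nodes = [x for k, x in enumerate(nodes) if k not in (i, j)] + [merged]
    return tree_from_string(nodes[0] + ";")


def simulate_character_on_tree(tree: dendropy.Tree, root_state: str,
                               events: dict[str, str] | None = None,
                               rate: float | None = None, seed: int = 0
                               ) -> tuple[TipStateMap, list[TransitionEvent]]:
    """Evolve the initiation-codon state along a rooted tree, truth recorded.

    Either ``events`` (child-node label -> new state, applied on the branch
    leading to that node) or ``rate`` (expected state changes per branch,
    Poisson; each change moves to a uniformly drawn *different* state) must
    be given; ``events={}`` simulates a constant character.
    """
    if events is None and rate is None:
        raise ValueError("give either explicit events or a rate")
    rng = np.random.default_rng(seed)
    assigned: dict[dendropy.Node, str] = {tree.seed_node: root_state}
    true_events: list[TransitionEvent] = []
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        state = assigned[node.parent_node]
        label = _node_label(node)
        if events is not None:
            if label in events and events[label] != state:
                true_events.append(TransitionEvent(
                    parent_label=_node_label(node.parent_node),
                    child_label=label, from_state=state, to_state=events[label]))
                state = events[label]
        else:
            for _ in range(int(rng.poisson(rate))):
                new = str(rng.choice([s for s in STATES if s != state]))
                true_events.append(TransitionEvent(
                    parent_label=_node_label(node.parent_node),
                    child_label=label, from_state=state, to_state=new))
                state = new
        assigned[node] = state
    tips = {_node_label(leaf): assigned[leaf] for leaf in tree.leaf_node_iter()}
    return TipStateMap(mapping=tips), true_events
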