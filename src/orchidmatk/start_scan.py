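"""Candidate initiation codons, translation evaluation and gene classification.

The core of the pseudogene re-assessment: many orchid *matK* sequences carry
a 4-nt ``ATGT`` insertion that creates an AUG ten bases upstream of — and out
of frame with — the consensus initiation codon (cic) used by other monocots.
Translating from that alternative initiation codon (aic) restores a
full-length MatK reading frame in sequences that show premature stops when
read from the cic.  This module anchors the cic on a query via pairwise
alignment, enumerates every AUG in a 5' window, evaluates translation from
each (plastid genetic code, NCBI table 11), and assigns a per-gene status.

Only ATG is accepted as an initiator; GTG/TTG starts are out of scope, as is
RNA editing (sequences are evaluated as submitted).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import NamedTuple

from Bio import Align
from Bio.Data.CodonTable import unambiguous_dna_by_id

from .seq_io import SequenceRecord

_TABLE11 = unambiguous_dna_by_id[11]
STOP_CODONS = frozenset(_TABLE11.stop_codons)  # TAA, TAG, TGA
_FORWARD = dict(_TABLE11.forward_table)

#: Default scan window around the cic (nt upstream / downstream).
WINDOW_UP = 60
WINDOW_DOWN = 30

#: Full-length criterion defaults: peptide >= 95% of the reference length and
#: a stop codon within +-10 codons of the reference stop position.
FULL_LENGTH_FRAC = 0.95
STOP_TOLERANCE = 10

#: Minimum global-alignment identity (over aligned columns) for cic anchoring.
ANCHOR_IDENTITY_FLOOR = 0.40


class GeneStatusKind(str, Enum):
    CIC_FUNCTIONAL = "CIC_FUNCTIONAL"
    AIC_FUNCTIONAL = "AIC_FUNCTIONAL"
    ALT_INFRAME = "ALT_INFRAME"
    NO_FULL_ORF = "NO_FULL_ORF"
    UNDETERMINED_5PRIME_TRUNCATED = "UNDETERMINED_5PRIME_TRUNCATED"


@dataclass(frozen=True)
class StartCandidate:
    """A candidate initiation codon.

    ``offset`` is the plain signed difference ``abs_pos - cic_pos`` (0 for the
    cic itself, -10 for the canonical orchid aic); a candidate is in frame
    with the cic iff ``offset % 3 == 0``.
    """

    abs_pos: int  # 1-based position of the A of ATG
    offset: int

    @property
    def in_frame(self) -> bool:
        return self.offset % 3 == 0

    @property
    def frame_relation(self) -> str:
        return "in_frame" if self.in_frame else "out_of_frame"


class ScanWindow(NamedTuple):
    """Start candidates plus a flag set when the window ran past the 5' end."""

    candidates: tuple[StartCandidate, ...]
    truncated: bool


@dataclass(frozen=True)
class TranslationReport:
    start: StartCandidate
    peptide_len: int
    first_stop_codon: int | None  # start ATG = codon 1; None if no stop found
    fraction_of_ref: float
    full_length: bool
    peptide: str = field(repr=False, default="")


@dataclass(frozen=True)
class GeneStatus:
    record_id: str
    status: GeneStatusKind
    primary_start: StartCandidate | None
    reports: tuple[TranslationReport, ...]
    notes: str = ""


class EmptyOrfError(ValueError):
    """Fewer than one complete codon follows the start codon."""


# ---------------------------------------------------------------------------
# Translation
# ---------------------------------------------------------------------------

def translate_codon(codon: str) -> str:
    """One codon under NCBI table 11; ambiguity (incl. N) -> 'X', never a stop."""
    if codon in STOP_CODONS:
        return "*"
    return _FORWARD.get(codon, "X")


def translate_from(seq: str, start_pos: int) -> tuple[str, int | None]:
    """Translate ``seq`` from ``start_pos`` (1-based A of the start codon).

    Returns ``(peptide, first_stop_codon)`` with the start ATG as codon 1 and
    the stop excluded from the peptide.  Trailing incomplete codons are
    ignored; a codon containing ambiguity translates to ``X`` and never
    terminates.
    """
    peptide: list[str] = []
    idx = 0
    for i in range(start_pos - 1, len(seq) - 2, 3):
        idx += 1
        aa = translate_codon(seq[i : i + 3])
        if aa == "*":
            return "".join(peptide), idx
        peptide.append(aa)
    return "".join(peptide), None


# ---------------------------------------------------------------------------
# cic anchoring
# ---------------------------------------------------------------------------

def _make_aligner() -> Align.PairwiseAligner:
    # EDNAFULL-style affine scoring for global DNA alignment.
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 5
    aligner.mismatch_score = -4
    aligner.open_gap_score = -10
    aligner.extend_gap_score = -0.5
    return aligner


def anchor_cic(query: SequenceRecord, reference: SequenceRecord,
               ref_cic_pos: int,
               identity_floor: float = ANCHOR_IDENTITY_FLOOR) -> tuple[int | None, bool]:
    """Locate the cic-homologous position on ``query`` by global alignment.

    Returns ``(query_pos, codon_is_atg)``; ``(None, False)`` when the
    alignment identity falls below ``identity_floor`` or the cic column is a
    gap in the query (the gene then becomes UNDETERMINED).
    """
    if not (1 <= ref_cic_pos <= len(reference) - 2):
        raise ValueError("ref_cic_pos outside the reference sequence")
    aligner = _make_aligner()
    aln = aligner.align(reference.residues, query.residues)[0]
    ref_blocks, query_blocks = aln.aligned
    matches = 0
    qpos: int | None = None
    ref_cic0 = ref_cic_pos - 1
    for (rs, re_), (qs, qe) in zip(ref_blocks, query_blocks):
        for k in range(re_ - rs):
            if reference.residues[rs + k] == query.residues[qs + k]:
                matches += 1
        if rs <= ref_cic0 < re_:
            qpos = qs + (ref_cic0 - rs) + 1  # back to 1-based
    # identity over all alignment columns (gaps included), so an unrelated
    # query cannot look similar merely because few columns align
    total_cols = aln.shape[1]
    if total_cols == 0 or matches / total_cols < identity_floor:
        return None, False
    if qpos is None:
        return None, False
    is_atg = query.residues[qpos - 1 : qpos + 2] == "ATG"
    return qpos, is_atg


def alignment_identity(a: str, b: str) -> float:
    """Identity over aligned (both non-gap) columns of two gapped rows."""
    pairs = [(x, y) for x, y in zip(a, b) if x != "-" and y != "-"]
    if not pairs:
        return 0.0
    return sum(x == y for x, y in pairs) / len(pairs)


# ---------------------------------------------------------------------------
# Candidate enumeration and evaluation
# ---------------------------------------------------------------------------

def enumerate_start_candidates(seq: SequenceRecord | str, cic_pos: int,
                               window_up: int = WINDOW_UP,
                               window_down: int = WINDOW_DOWN) -> ScanWindow:
    """Every ATG whose A lies in ``[cic_pos - window_up, cic_pos + window_down]``.

    Candidates are sorted 5'->3'.  When the window extends past the record's
    5' end the (clipped) candidates are still returned together with a
    truncation flag.  An N inside the triplet disqualifies the candidate.
    """
    residues = seq.residues if isinstance(seq, SequenceRecord) else seq
    lo = cic_pos - window_up
    truncated = lo < 1
    lo = max(1, lo)
    hi = min(cic_pos + window_down, len(residues) - 2)
    found = []
    for pos in range(lo, hi + 1):
        if residues[pos - 1 : pos + 2] == "ATG":
            found.append(StartCandidate(abs_pos=pos, offset=pos - cic_pos))
    return ScanWindow(candidates=tuple(found), truncated=truncated)


def evaluate_translation(seq: SequenceRecord | str, start: StartCandidate,
                         ref_peptide_len: int,
                         full_length_frac: float = FULL_LENGTH_FRAC,
                         stop_tolerance: int = STOP_TOLERANCE) -> TranslationReport:
    """Translate from a candidate and score it against the reference length.

    ``full_length`` is true iff the peptide reaches ``full_length_frac`` of
    the reference peptide length *and* a stop codon occurs within
    ``stop_tolerance`` codons of the reference stop position (reference
    peptide length + 1, counting the start ATG as codon 1).  This tolerates
    the known length variability of the MatK N-terminus.
    """
    residues = seq.residues if isinstance(seq, SequenceRecord) else seq
    if residues[start.abs_pos - 1 : start.abs_pos + 2] != "ATG":
        raise ValueError(f"no ATG at position {start.abs_pos}")
    if len(residues) - (start.abs_pos + 2) < 3:
        raise EmptyOrfError(f"empty ORF: no complete codon after start at {start.abs_pos}")
    peptide, first_stop = translate_from(residues, start.abs_pos)
    peptide_len = len(peptide)
    fraction = peptide_len / ref_peptide_len if ref_peptide_len else 0.0
    ref_stop = ref_peptide_len + 1
    full = (
        first_stop is not None
        and peptide_len >= full_length_frac * ref_peptide_len
        and abs(first_stop - ref_stop) <= stop_tolerance
    )
    return TranslationReport(start=start, peptide_len=peptide_len,
                             first_stop_codon=first_stop,
                             fraction_of_ref=fraction, full_length=full,
                             peptide=peptide)


def classify_gene(seq: SequenceRecord, cic_pos: int, scan: ScanWindow,
                  ref_peptide_len: int,
                  full_length_frac: float = FULL_LENGTH_FRAC,
                  stop_tolerance: int = STOP_TOLERANCE) -> GeneStatus:
    """Assign a per-gene status from the candidate scan.

    The primary start is the 5'-most candidate whose translation is full
    length (translation initiates at the 5'-proximal AUG).  A 5'-truncated
    scan window always yields ``UNDETERMINED_5PRIME_TRUNCATED``: with
    upstream sequence missing, the 5'-proximal rule cannot be applied even
    when a visible candidate translates to full length.
    """
    reports = []
    for cand in scan.candidates:
        try:
            reports.append(
                evaluate_translation(seq, cand, ref_peptide_len,
                                     full_length_frac, stop_tolerance)
            )
        except EmptyOrfError:
            reports.append(
                TranslationReport(start=cand, peptide_len=0, first_stop_codon=None,
                                  fraction_of_ref=0.0, full_length=False)
            )
    reports_t = tuple(reports)
    if scan.truncated:
        return GeneStatus(record_id=seq.id,
                          status=GeneStatusKind.UNDETERMINED_5PRIME_TRUNCATED,
                          primary_start=None, reports=reports_t,
                          notes="scan window extends past the 5' end")
    primary = next((r.start for r in reports_t if r.full_length), None)
    if primary is None:
        status = GeneStatusKind.NO_FULL_ORF
    elif primary.offset == 0:
        status = GeneStatusKind.CIC_FUNCTIONAL
    elif not primary.in_frame:
        status = GeneStatusKind.AIC_FUNCTIONAL
    else:
        status = GeneStatusKind.ALT_INFRAME
    return GeneStatus(record_id=seq.id, status=status, primary_start=primary,
                      reports=reports_t)


def scan_record(query: SequenceRecord, reference: SequenceRecord,
                ref_cic_pos: int, ref_peptide_len: int,
                window_up: int = WINDOW_UP, window_down: int = WINDOW_DOWN,
                full_length_frac: float = FULL_LENGTH_FRAC,
                stop_tolerance: int = STOP_TOLERANCE,
                identity_floor: float = ANCHOR_IDENTITY_FLOOR) -> GeneStatus:
    """Anchor the cic on ``query`` and classify it (the per-record pipeline)."""
    cic_pos, _is_atg = anchor_cic(query, reference, ref_cic_pos, identity_floor)
    if cic_pos is None:
        return GeneStatus(record_id=query.id,
                          status=GeneStatusKind.UNDETERMINED_5PRIME_TRUNCATED,
                          primary_start=None, reports=(),
                          notes="cic could not be anchored (low identity)")
    scan = enumerate_start_candidates(query, cic_pos, window_up, window_down)
    return classify_gene(query, cic_pos, scan, ref_peptide_len,
                         full_length_frac, stop_tolerance)
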