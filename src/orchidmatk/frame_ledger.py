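"""Frame ledger: indels vs a reference, compensatory sets, distortion diff.

Orchid *matK* sequences that use the alternative initiation codon carry a
small set of nearby insertions (4 nt at the aic itself, 4 nt around +38 and
1 nt at +43, anchor A = +1) whose total length is a multiple of three.  Such
a *compensatory set* restores the ancestral reading frame downstream while
distorting it only between the first and last member indel; within that span
the two frames encode different residues (eleven, in the canonical orchid
geometry).  This module extracts indels from a pairwise alignment, groups
them into frame-restoring sets, and counts the residues changed inside the
distorted region.

Offset convention: an indel "at +k" has its first inserted/deleted base at
anchor offset k, with the A of the anchor ATG at +1 and -1 the base
immediately 5' of it (no offset 0).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .seq_io import GAP, GappedPair, offset_from_anchor
from .start_scan import translate_from


class FrameNotRestoredError(ValueError):
    """distortion_diff was asked to diff across an uncompensated frameshift."""


@dataclass(frozen=True)
class IndelEvent:
    """One maximal gap run of a pairwise alignment, in anchor offsets.

    ``anchor_offset`` locates the first affected base: for an insertion, the
    first query base absent from the reference; for a deletion, the query
    offset at which the deleted reference bases are missing.
    """

    anchor_offset: int
    length: int
    kind: str  # "insertion" | "deletion" (relative to the reference)

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("indel length must be >= 1")
        if self.kind not in ("insertion", "deletion"):
            raise ValueError(f"bad indel kind {self.kind!r}")

    @property
    def signed_length(self) -> int:
        return self.length if self.kind == "insertion" else -self.length

    @property
    def last_affected_offset(self) -> int:
        if self.kind == "deletion":
            return self.anchor_offset
        off = self.anchor_offset + self.length - 1
        # skip the nonexistent offset 0 when a span crosses the anchor
        if self.anchor_offset < 0 and off >= 0:
            off += 1
        return off


@dataclass(frozen=True)
class CompensatorySet:
    """A 5'->3' run of indels whose net length shift is ~0 (mod 3)."""

    events: tuple[IndelEvent, ...]
    closed: bool  # False: unbalanced tail, frame NOT restored

    @property
    def net_shift(self) -> int:
        return sum(e.signed_length for e in self.events)

    @property
    def total_inserted(self) -> int:
        return sum(e.length for e in self.events if e.kind == "insertion")

    @property
    def span(self) -> tuple[int, int]:
        return (self.events[0].anchor_offset,
                self.events[-1].last_affected_offset)


@dataclass(frozen=True)
class DistortionReport:
    """Residue-level effect of a compensatory set on the translation."""

    span: tuple[int, int]
    n_changed: int
    n_gap_cols: int


# ---------------------------------------------------------------------------
# Indel extraction
# ---------------------------------------------------------------------------

def detect_indels(pair: GappedPair, anchor_start_pos_on_query: int) -> list[IndelEvent]:
    """Maximal gap runs of ``pair``, reported in query anchor offsets.

    Gap runs in the reference row are insertions (bases present only in the
    query); runs in the query row are deletions.  Events come out sorted
    5'->3' and non-overlapping by construction.
    """
    anchor = anchor_start_pos_on_query
    if not (1 <= anchor <= len(pair.query_seq)):
        raise ValueError("anchor position outside the query sequence")
    events: list[IndelEvent] = []
    qpos = 0  # 1-based position of the last query base seen
    i = 0
    cols = len(pair.query_aln)
    while i < cols:
        q, r = pair.query_aln[i], pair.ref_aln[i]
        if r == GAP:  # insertion run
            start_qpos = qpos + 1
            length = 0
            while i < cols and pair.ref_aln[i] == GAP:
                qpos += 1
                length += 1
                i += 1
            events.append(IndelEvent(
                anchor_offset=offset_from_anchor(start_qpos, anchor),
                length=length, kind="insertion"))
        elif q == GAP:  # deletion run
            length = 0
            while i < cols and pair.query_aln[i] == GAP:
                length += 1
                i += 1
            events.append(IndelEvent(
                anchor_offset=offset_from_anchor(qpos + 1, anchor),
                length=length, kind="deletion"))
        else:
            qpos += 1
            i += 1
    return events


def net_frameshift(events: Sequence[IndelEvent],
                   region: tuple[int, int] | None = None) -> tuple[int, int]:
    """Signed net length shift of ``events`` within ``region`` and its mod 3.

    ``region`` is an inclusive interval of anchor offsets; ``None`` sums all
    events.  Insertions count positive, deletions negative.
    """
    if region is None:
        net = sum(e.signed_length for e in events)
    else:
        lo, hi = region
        net = sum(e.signed_length for e in events
                  if lo <= e.anchor_offset <= hi)
    return net, net % 3


def find_compensatory_sets(events: Sequence[IndelEvent]) -> list[CompensatorySet]:
    """Group sorted indels into earliest-closing frame-restoring sets.

    Scanning 5'->3', a set closes at the earliest event where the running net
    shift is ~0 (mod 3); an unbalanced tail is returned as an open set
    (frame not restored).
    """
    sets: list[CompensatorySet] = []
    current: list[IndelEvent] = []
    net = 0
    for ev in events:
        current.append(ev)
        net += ev.signed_length
        if net % 3 == 0:
            sets.append(CompensatorySet(events=tuple(current), closed=True))
            current, net = [], 0
    if current:
        sets.append(CompensatorySet(events=tuple(current), closed=False))
    return sets


# ---------------------------------------------------------------------------
# Distortion diff
# ---------------------------------------------------------------------------

def _codon_index_maps(pair: GappedPair, query_start: int, ref_start: int
                      ) -> tuple[list[int], list[int]]:
    """Per-alignment-column codon indices (1-based; 0 = not in a codon)."""
    qcols = pair.column_of_query()
    rcols = pair.column_of_ref()
    ncols = len(pair.query_aln)
    qmap = [0] * ncols
    rmap = [0] * ncols
    for pos0, col in enumerate(qcols):
        if pos0 >= query_start - 1:
            qmap[col] = (pos0 - (query_start - 1)) // 3 + 1
    for pos0, col in enumerate(rcols):
        if pos0 >= ref_start - 1:
            rmap[col] = (pos0 - (ref_start - 1)) // 3 + 1
    return qmap, rmap


def distortion_diff(pair: GappedPair, query_start: int, ref_start: int,
                    cset: CompensatorySet) -> DistortionReport:
    """Residues changed between query-frame and reference-frame translations.

    Both rows are translated from their own starts; peptides are aligned via
    the nucleotide alignment: each query codon is paired with the reference
    codon sharing the most alignment columns (ties to the 5'-most), and
    query codons with no reference overlap are peptide-alignment gaps.  Only
    codons inside ``cset.span`` are counted — a codon straddling the span
    boundary counts iff at least two of its bases lie inside.

    Raises :class:`FrameNotRestoredError` for an open (uncompensated) set.
    """
    if not cset.closed or cset.net_shift % 3 != 0:
        raise FrameNotRestoredError("frame not restored: open compensatory set")
    qpep, _ = translate_from(pair.query_seq, query_start)
    rpep, _ = translate_from(pair.ref_seq, ref_start)
    qmap, rmap = _codon_index_maps(pair, query_start, ref_start)
    qcols = pair.column_of_query()
    lo, hi = cset.span

    n_changed = 0
    n_gap = 0
    for qi in range(1, len(qpep) + 1):
        base_pos0 = (query_start - 1) + 3 * (qi - 1)
        offsets = [p - (query_start - 1) + 1 for p in range(base_pos0, base_pos0 + 3)]
        inside = sum(lo <= off <= hi for off in offsets)
        if inside < 2:
            continue
        # columns of this codon's three bases
        cols = qcols[base_pos0 : base_pos0 + 3]
        overlap: dict[int, int] = {}
        for c in cols:
            rj = rmap[c]
            if rj:
                overlap[rj] = overlap.get(rj, 0) + 1
        if not overlap:
            n_gap += 1
            continue
        best = max(overlap.items(), key=lambda kv: (kv[1], -kv[0]))[0]
        if best > len(rpep):
            n_gap += 1
            continue
        if qpep[qi - 1] != rpep[best - 1]:
            n_changed += 1
    return DistortionReport(span=(lo, hi), n_changed=n_changed, n_gap_cols=n_gap)
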