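"""Ribosome-binding context of candidate start codons.

Many chloroplast mRNAs retain a prokaryotic-type Shine-Dalgarno (SD) element
(consensus ``GGAGG``) upstream of the initiation codon; its spacing relative
to the start determines whether it can plausibly influence ribosome binding.
The nucleotide immediately 5' of the start (the -1 position of the "-1
triplet") also modulates initiation, U being the favoured base.

Offsets are anchor offsets: the A of the start ATG is +1 and -1 is the base
immediately 5' of it.
"""

from __future__ import annotations

from dataclasses import dataclass

from .seq_io import SequenceRecord

SD_CONSENSUS = "GGAGG"
#: Scan window for SD-like elements (both offsets inclusive, 5' of the start).
SD_WINDOW = (-44, -2)
#: "Moderate similarity": at least 4 of 5 consensus positions matched.
SD_MIN_MATCHES = 4
#: Spacer range (nt between the SD 3' end and the start A) within which an SD
#: element plausibly influences ribosome binding: neither "within a few
#: bases" nor "greater than -20 bases" upstream.
SD_INFLUENCE_SPACER = (4, 17)


@dataclass(frozen=True)
class SDHit:
    """The matched core of one consensus placement upstream of a start.

    ``offset_start``/``offset_end`` delimit the first..last position of the
    placement that matches the consensus (so a 4/5 placement whose mismatch
    is terminal reports a 4-nt core); ``matches`` counts matching positions
    of the full consensus-length placement.
    """

    offset_start: int
    offset_end: int
    matches: int
    matched_seq: str

    def __post_init__(self) -> None:
        if not (self.offset_start <= self.offset_end < 0):
            raise ValueError("SD hit offsets must be upstream (negative)")

    @property
    def spacer(self) -> int:
        """Bases between the hit's 3' end and the A of the start codon."""
        return -self.offset_end - 1


@dataclass(frozen=True)
class MinusOneContext:
    triplet: str  # bases at offsets -3..-1 (may be shorter near the 5' end)
    complete: bool

    @property
    def minus1_base(self) -> str:
        return self.triplet[-1] if self.triplet else ""

    @property
    def u_preferred(self) -> bool:
        return self.minus1_base == "T"


def _upstream_base(residues: str, start_pos: int, offset: int) -> str | None:
    """Base at a negative anchor offset, or None past the 5' end."""
    pos = start_pos + offset  # offset < 0; -1 -> base at start_pos - 1
    if pos < 1:
        return None
    return residues[pos - 1]


def scan_sd(seq: SequenceRecord | str, start_pos: int,
            window: tuple[int, int] = SD_WINDOW,
            consensus: str = SD_CONSENSUS,
            min_matches: int = SD_MIN_MATCHES) -> list[SDHit]:
    """Slide the SD consensus across the upstream window of a start codon.

    Every placement with at least ``min_matches`` matching positions is
    reported, best first (more matches, then smaller ``|offset_start|``).
    Windows running past the 5' end of the record are clipped.
    """
    residues = seq.residues if isinstance(seq, SequenceRecord) else seq
    k = len(consensus)
    lo, hi = window
    hits: list[SDHit] = []
    for off_start in range(lo, hi - k + 2):  # placement fully inside window
        bases = [_upstream_base(residues, start_pos, off_start + j) for j in range(k)]
        if any(b is None for b in bases):
            continue  # clipped at the 5' end
        matches = sum(b == c for b, c in zip(bases, consensus))
        if matches < max(min_matches, 1):
            continue  # a placement with no matching position has no core
        match_idx = [j for j, (b, c) in enumerate(zip(bases, consensus)) if b == c]
        core_lo = off_start + match_idx[0]
        core_hi = off_start + match_idx[-1]
        hits.append(SDHit(offset_start=core_lo, offset_end=core_hi,
                          matches=matches,
                          matched_seq="".join(bases[match_idx[0]: match_idx[-1] + 1])))
    hits.sort(key=lambda h: (-h.matches, abs(h.offset_start)))
    return hits


def classify_sd_influence(hit: SDHit,
                          spacer_range: tuple[int, int] = SD_INFLUENCE_SPACER) -> str:
    """``likely``/``unlikely`` influence on ribosome binding, by spacer only."""
    lo, hi = spacer_range
    return "likely" if lo <= hit.spacer <= hi else "unlikely"


def minus_one_context(seq: SequenceRecord | str, start_pos: int) -> MinusOneContext:
    """The -3..-1 triplet immediately 5' of a start codon."""
    residues = seq.residues if isinstance(seq, SequenceRecord) else seq
    bases = [_upstream_base(residues, start_pos, off) for off in (-3, -2, -1)]
    present = [b for b in bases if b is not None]
    return MinusOneContext(triplet="".join(present), complete=len(present) == 3)
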