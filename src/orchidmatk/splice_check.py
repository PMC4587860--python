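"""In-silico surrogate for the trnK splicing RT-PCR assay.

MatK maturase activity is read out by whether the group IIA intron of
trnK(UUU) is removed from the precursor transcript.  With exon-anchored
primers, the mature (spliced) product is a short amplicon (~50-61 bp in
orchids) while the precursor yields the full primer-to-primer genomic span
(~2.8 kb).  This module locates primer binding sites and computes both
expected amplicon sizes from an exon/intron annotation; the difference must
equal the intron length.

Thermodynamics, Tm and splice-site prediction are out of scope — annotations
are inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

from .seq_io import FeatureTable, SequenceRecord, revcomp

#: Exon-anchored primers used for the trnK splicing readout.
DEFAULT_FWD_PRIMER = ("NITtrnkRev", "GGTTGCTAACTCAACGGTAGAG")
DEFAULT_REV_PRIMER = ("trnK3end", "GGGACTCGAACCCGGAA")


class PrimerSiteError(ValueError):
    """Zero or multiple binding sites where exactly one is required."""


@dataclass(frozen=True)
class PrimerPair:
    fwd_name: str
    fwd_seq: str
    rev_name: str
    rev_seq: str

    def __post_init__(self) -> None:
        for name, seq in ((self.fwd_name, self.fwd_seq), (self.rev_name, self.rev_seq)):
            if len(seq) < 10:
                raise ValueError(f"primer {name!r} shorter than 10 nt")
        object.__setattr__(self, "fwd_seq", self.fwd_seq.upper().replace("U", "T"))
        object.__setattr__(self, "rev_seq", self.rev_seq.upper().replace("U", "T"))


@dataclass(frozen=True)
class AmpliconReport:
    spliced_len: int
    unspliced_len: int
    intron_len: int
    fwd_site: int  # 1-based genomic position of the fwd primer's 5'-most base
    rev_site: int  # 1-based genomic position of the rev site's 5'-most base (+ strand)


def _hamming_le(a: str, b: str, limit: int) -> bool:
    mism = 0
    for x, y in zip(a, b):
        if x != y:
            mism += 1
            if mism > limit:
                return False
    return True


def find_primer_sites(seq: SequenceRecord | str, primer: str,
                      max_mismatch: int = 0) -> list[tuple[int, str]]:
    """All (<= max_mismatch) primer matches on both strands.

    Positions are 1-based and refer to the 5'-most matched base on the
    forward strand; strand is '+' when the primer itself matches, '-' when
    its reverse complement does.
    """
    residues = (seq.residues if isinstance(seq, SequenceRecord) else seq).upper()
    primer = primer.upper().replace("U", "T")
    k = len(primer)
    rc = revcomp(primer)
    sites: list[tuple[int, str]] = []
    for i in range(len(residues) - k + 1):
        window = residues[i : i + k]
        if _hamming_le(window, primer, max_mismatch):
            sites.append((i + 1, "+"))
        if _hamming_le(window, rc, max_mismatch):
            sites.append((i + 1, "-"))
    return sites


def _unique_site(sites: list[tuple[int, str]], strand: str, what: str) -> int:
    on_strand = [pos for pos, s in sites if s == strand]
    if len(on_strand) != 1:
        raise PrimerSiteError(
            f"{what}: expected exactly one {strand!r}-strand site, found "
            f"{on_strand or 'none'}"
        )
    return on_strand[0]


def amplicon_sizes(record: SequenceRecord, features: FeatureTable,
                   primers: PrimerPair, max_mismatch: int = 0) -> AmpliconReport:
    """Expected spliced and unspliced amplicon lengths for one record.

    The unspliced length is measured on the genomic record (fwd primer 5'
    start to rev site 3' end, both footprints included); the spliced length
    on the exon-ligated sequence, so a reverse primer spanning the exon-exon
    junction is still found.  The invariant ``unspliced - spliced ==
    intron_len`` is enforced.
    """
    feats = features.for_record(record.id)
    for needed in ("exon5", "exon3"):
        if needed not in feats:
            raise ValueError(f"record {record.id!r}: missing {needed} feature")
    exon5, exon3 = feats["exon5"], feats["exon3"]
    if "intron" in feats:
        intron_len = len(feats["intron"])
    else:
        intron_len = exon3.start - exon5.end - 1  # adjacent exons -> 0

    fwd = _unique_site(find_primer_sites(record, primers.fwd_seq, max_mismatch),
                       "+", f"fwd primer {primers.fwd_name!r}")
    rev = _unique_site(find_primer_sites(record, primers.rev_seq, max_mismatch),
                       "-", f"rev primer {primers.rev_name!r}")
    unspliced = rev + len(primers.rev_seq) - 1 - fwd + 1

    ligated = (record.residues[exon5.start - 1 : exon5.end]
               + record.residues[exon3.start - 1 : exon3.end])
    fwd_l = _unique_site(find_primer_sites(ligated, primers.fwd_seq, max_mismatch),
                         "+", f"fwd primer {primers.fwd_name!r} on ligated exons")
    rev_l = _unique_site(find_primer_sites(ligated, primers.rev_seq, max_mismatch),
                         "-", f"rev primer {primers.rev_name!r} on ligated exons")
    spliced = rev_l + len(primers.rev_seq) - 1 - fwd_l + 1

    if unspliced - spliced != intron_len:
        raise ValueError(
            f"record {record.id!r}: unspliced - spliced = {unspliced - spliced} "
            f"!= intron length {intron_len}; primers must flank the intron "
            "from within (or 5'/3' of) the exons"
        )
    return AmpliconReport(spliced_len=spliced, unspliced_len=unspliced,
                          intron_len=intron_len, fwd_site=fwd, rev_site=rev)
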