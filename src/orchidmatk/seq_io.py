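"""Readers, writers and coordinate conventions shared by the whole pipeline.

Coordinate conventions
----------------------
All user-facing coordinates are 1-based inclusive.  Two offset conventions
coexist, mirroring how positions are quoted in the plastid-genetics
literature:

* **Start-candidate offsets** are plain signed differences against the
  consensus initiation codon (cic): ``offset = abs_pos - cic_pos``.  The cic
  itself is offset 0 and the alternative initiation codon (aic) created by the
  orchid ``ATGT`` insertion is at offset -10.

* **Anchor offsets** ("+37 from the aic" style, used for indels and
  ribosome-binding context) place the A of the anchor ATG at +1 and the base
  immediately 5' of it at -1; there is no offset 0.  See
  :func:`offset_from_anchor`.

``U`` is accepted on input and stored as ``T``; the only gap character is
``-`` (``.`` is rejected).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import pandas as pd
from Bio import SeqIO

# IUPAC DNA, no gap; U is transliterated before validation.
IUPAC_DNA = frozenset("ACGTNRYSWKMBDHV")
GAP = "-"

FEATURE_LABELS = ("exon5", "intron", "exon3", "cds")


class SeqIOError(ValueError):
    """Malformed input file or record."""


def offset_from_anchor(pos: int, anchor: int) -> int:
    """Signed offset of ``pos`` relative to an anchor start codon.

    The A of the anchor ATG is +1; the base immediately 5' of it is -1.
    """
    return pos - anchor + 1 if pos >= anchor else pos - anchor


def position_at_offset(offset: int, anchor: int) -> int:
    """Inverse of :func:`offset_from_anchor`."""
    if offset == 0:
        raise ValueError("anchor offsets have no 0 (A of the anchor ATG is +1)")
    return anchor + offset - 1 if offset > 0 else anchor + offset


@dataclass(frozen=True)
class SequenceRecord:
    """A named DNA sequence with optional provenance (e.g. an accession)."""

    id: str
    residues: str
    description: str = ""
    source: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise SeqIOError("record id must be non-empty")
        if not self.residues:
            raise SeqIOError(f"record {self.id!r}: empty sequence")
        clean = self.residues.upper().replace("U", "T")
        bad = next((i for i, c in enumerate(clean) if c not in IUPAC_DNA), None)
        if bad is not None:
            raise SeqIOError(
                f"record {self.id!r}: non-IUPAC character "
                f"{self.residues[bad]!r} at position {bad + 1}"
            )
        object.__setattr__(self, "residues", clean)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class GappedPair:
    """Two rows of a pairwise alignment (query vs reference)."""

    query_id: str
    ref_id: str
    query_aln: str
    ref_aln: str

    def __post_init__(self) -> None:
        if len(self.query_aln) != len(self.ref_aln):
            raise SeqIOError(
                f"alignment rows {self.query_id!r}/{self.ref_id!r} differ in "
                f"length ({len(self.query_aln)} vs {len(self.ref_aln)})"
            )
        for row_id, row in ((self.query_id, self.query_aln), (self.ref_id, self.ref_aln)):
            if "." in row:
                raise SeqIOError(f"row {row_id!r}: '.' gaps are not supported, use '-'")
            stripped = row.replace(GAP, "")
            if not stripped:
                raise SeqIOError(f"row {row_id!r} is all gaps")
            # validates the residue alphabet as a side effect
            SequenceRecord(id=row_id, residues=stripped)
        for col, (q, r) in enumerate(zip(self.query_aln, self.ref_aln)):
            if q == GAP and r == GAP:
                raise SeqIOError(f"column {col + 1} is a gap in both rows")
        norm = lambda s: s.upper().replace("U", "T")  # noqa: E731
        object.__setattr__(self, "query_aln", norm(self.query_aln))
        object.__setattr__(self, "ref_aln", norm(self.ref_aln))

    @property
    def query_seq(self) -> str:
        return self.query_aln.replace(GAP, "")

    @property
    def ref_seq(self) -> str:
        return self.ref_aln.replace(GAP, "")

    def column_of_query(self) -> list[int]:
        """0-based alignment column of each query base (index = 0-based pos)."""
        return [i for i, c in enumerate(self.query_aln) if c != GAP]

    def column_of_ref(self) -> list[int]:
        return [i for i, c in enumerate(self.ref_aln) if c != GAP]


@dataclass(frozen=True)
class Feature:
    record_id: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    label: str

    def __post_init__(self) -> None:
        if self.label not in FEATURE_LABELS:
            raise SeqIOError(
                f"feature label {self.label!r} not in {FEATURE_LABELS}"
            )
        if self.start > self.end:
            raise SeqIOError(
                f"reversed interval {self.start}..{self.end} on {self.record_id!r}"
            )
        if self.start < 1:
            raise SeqIOError("coordinates are 1-based; start < 1")

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class FeatureTable:
    """Exon/intron (or CDS) layout of one or more records, 1-based inclusive."""

    features: tuple[Feature, ...]

    def __post_init__(self) -> None:
        by_record: dict[str, list[Feature]] = {}
        for f in self.features:
            by_record.setdefault(f.record_id, []).append(f)
        for rid, feats in by_record.items():
            feats = sorted(feats, key=lambda f: f.start)
            for a, b in zip(feats, feats[1:]):
                if b.start <= a.end:
                    raise SeqIOError(f"overlapping features on {rid!r}")
            pos = {f.label: f.start for f in feats}
            if {"exon5", "intron", "exon3"} <= pos.keys():
                if not pos["exon5"] < pos["intron"] < pos["exon3"]:
                    raise SeqIOError(
                        f"features on {rid!r} violate exon5 < intron < exon3"
                    )

    def for_record(self, record_id: str) -> dict[str, Feature]:
        return {f.label: f for f in self.features if f.record_id == record_id}

    def __iter__(self):
        return iter(self.features)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read unaligned FASTA; uppercases, transliterates U->T, rejects gaps."""
    records = _parse_fasta(path, allow_gaps=False)
    if not records:
        raise SeqIOError(f"{path}: no records")
    return records


def _parse_fasta(path: str | Path, allow_gaps: bool) -> list[SequenceRecord]:
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise SeqIOError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        residues = str(rec.seq)
        if not allow_gaps and (GAP in residues or "." in residues):
            raise SeqIOError(
                f"{path}: record {rec.id!r} contains gap characters; "
                "use read_alignment for aligned FASTA"
            )
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append(SequenceRecord(id=rec.id, residues=residues, description=desc))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = f">{rec.id}"
            if rec.description:
                header += f" {rec.description}"
            fh.write(header + "\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Aligned FASTA
# ---------------------------------------------------------------------------

def read_alignment(path: str | Path) -> list[SequenceRecord]:
    """Read aligned FASTA (rows of equal length, '-' gaps retained).

    Returns records whose ``residues`` may contain ``-``; validation of the
    residue alphabet is applied to the degapped rows.
    """
    rows: list[tuple[str, str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise SeqIOError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        rows.append((rec.id, str(rec.seq), desc))
    if not rows:
        raise SeqIOError(f"{path}: no records")
    length = len(rows[0][1])
    out = []
    for rid, aln, desc in rows:
        if len(aln) != length:
            raise SeqIOError(
                f"{path}: ragged alignment, row {rid!r} has length "
                f"{len(aln)} != {length}"
            )
        if "." in aln:
            raise SeqIOError(f"{path}: row {rid!r}: '.' gaps not supported")
        SequenceRecord(id=rid, residues=aln.replace(GAP, ""))  # validate
        out.append(
            AlignedRow(id=rid, residues=aln.upper().replace("U", "T"), description=desc)
        )
    return out


@dataclass(frozen=True)
class AlignedRow:
    """One row of an alignment; like SequenceRecord but gaps allowed."""

    id: str
    residues: str
    description: str = ""

    def degapped(self) -> SequenceRecord:
        return SequenceRecord(id=self.id, residues=self.residues.replace(GAP, ""),
                              description=self.description)


def as_gapped_pair(rows: Sequence[AlignedRow], query_id: str | None = None,
                   ref_id: str | None = None) -> GappedPair:
    """Extract a query/reference pair from a 2-row alignment.

    With default ids, the first row is the query and the second the reference.
    Columns gapped in both rows (possible when slicing a larger alignment)
    are dropped before validation.
    """
    by_id = {r.id: r for r in rows}
    if query_id is None or ref_id is None:
        if len(rows) != 2:
            raise SeqIOError("query_id/ref_id required for alignments with > 2 rows")
        query, ref = rows[0], rows[1]
    else:
        query, ref = by_id[query_id], by_id[ref_id]
    q, r = [], []
    for cq, cr in zip(query.residues, ref.residues):
        if cq == GAP and cr == GAP:
            continue
        q.append(cq)
        r.append(cr)
    return GappedPair(query_id=query.id, ref_id=ref.id,
                      query_aln="".join(q), ref_aln="".join(r))


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------

def read_newick(path: str | Path) -> dendropy.Tree:
    """Read a single rooted Newick tree with unique tip labels.

    Branch lengths are retained but ignored by the parsimony machinery.
    """
    try:
        tree = dendropy.Tree.get(path=str(path), schema="newick",
                                 preserve_underscores=True)
    except Exception as exc:  # dendropy raises several parse error types
        raise SeqIOError(f"{path}: Newick parse error: {exc}") from exc
    return _check_tree(tree, str(path))


def tree_from_string(newick: str) -> dendropy.Tree:
    try:
        tree = dendropy.Tree.get(data=newick, schema="newick",
                                 preserve_underscores=True)
    except Exception as exc:
        raise SeqIOError(f"Newick parse error: {exc}") from exc
    return _check_tree(tree, "<string>")


def _check_tree(tree: dendropy.Tree, origin: str) -> dendropy.Tree:
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter() if leaf.taxon]
    dupes = {l for l in labels if labels.count(l) > 1}
    if dupes:
        raise SeqIOError(f"{origin}: duplicate tip label(s) {sorted(dupes)}")
    if not labels:
        raise SeqIOError(f"{origin}: tree has no labelled tips")
    tree.is_rooted = True
    return tree


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True,
               unquoted_underscores=True)


# ---------------------------------------------------------------------------
# Feature tables (BED / GFF3)
# ---------------------------------------------------------------------------

def read_feature_table(path: str | Path, dialect: str) -> FeatureTable:
    """Read BED (0-based half-open) or GFF3 (1-based inclusive) features.

    Both are normalized to 1-based inclusive internal coordinates.  The
    feature label is BED column 4 / the GFF3 ``type`` column and must be one
    of ``exon5``, ``intron``, ``exon3``, ``cds``.
    """
    dialect = dialect.upper()
    if dialect == "BED":
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
        if df.shape[1] < 4:
            raise SeqIOError(f"{path}: BED needs >= 4 columns (chrom,start,end,name)")
        feats = [
            Feature(record_id=row[0], start=int(row[1]) + 1, end=int(row[2]),
                    label=row[3])
            for row in df.itertuples(index=False)
        ]
    elif dialect == "GFF3":
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
        if df.shape[1] < 5:
            raise SeqIOError(f"{path}: GFF3 needs >= 5 columns")
        feats = [
            Feature(record_id=row[0], start=int(row[3]), end=int(row[4]),
                    label=row[2])
            for row in df.itertuples(index=False)
        ]
    else:
        raise SeqIOError(f"unknown feature dialect {dialect!r} (use BED or GFF3)")
    return FeatureTable(features=tuple(feats))


def write_feature_table(table: FeatureTable, path: str | Path, dialect: str = "GFF3") -> None:
    dialect = dialect.upper()
    with open(path, "w") as fh:
        for f in table:
            if dialect == "BED":
                fh.write(f"{f.record_id}\t{f.start - 1}\t{f.end}\t{f.label}\n")
            else:
                fh.write(
                    f"{f.record_id}\torchidmatk\t{f.label}\t{f.start}\t{f.end}"
                    f"\t.\t+\t.\tID={f.label}\n"
                )


def revcomp(seq: str) -> str:
    """Reverse complement over the IUPAC DNA alphabet."""
    comp = str.maketrans("ACGTNRYSWKMBDHV", "TGCANYRSWMKVHDB")
    return seq.upper().replace("U", "T").translate(comp)[::-1]
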