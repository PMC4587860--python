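"""Pipeline orchestration: scan -> ledger -> sd -> (splice) -> (phylo).

Merges per-gene results into one verdict table plus a JSON-able summary.
Stages after the start-codon scan are optional and configured explicitly;
reruns on identical inputs produce byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import codon_phylo, frame_ledger, regulatory_scan, splice_check
from .seq_io import FeatureTable, GappedPair, SequenceRecord, write_fasta
from .start_scan import (ANCHOR_IDENTITY_FLOOR, FULL_LENGTH_FRAC,
                         STOP_TOLERANCE, WINDOW_DOWN, WINDOW_UP,
                         GeneStatus, GeneStatusKind, _make_aligner, anchor_cic,
                         classify_gene, enumerate_start_candidates)

logger = logging.getLogger("orchidmatk")

#: Gene status -> initiation-codon character state for the phylogenetic stage.
STATUS_TO_STATE = {
    GeneStatusKind.CIC_FUNCTIONAL: "cic",
    GeneStatusKind.AIC_FUNCTIONAL: "aic",
    GeneStatusKind.ALT_INFRAME: "alt_inframe",
    GeneStatusKind.NO_FULL_ORF: "unknown",
    GeneStatusKind.UNDETERMINED_5PRIME_TRUNCATED: "unknown",
}


@dataclass(frozen=True)
class PipelineConfig:
    """Inputs and thresholds for one pipeline run."""

    records: tuple[SequenceRecord, ...]
    reference: SequenceRecord
    ref_cic_pos: int
    ref_peptide_len: int
    window_up: int = WINDOW_UP
    window_down: int = WINDOW_DOWN
    full_length_frac: float = FULL_LENGTH_FRAC
    stop_tolerance: int = STOP_TOLERANCE
    identity_floor: float = ANCHOR_IDENTITY_FLOOR
    run_ledger: bool = True
    run_sd: bool = True
    sd_min_matches: int = regulatory_scan.SD_MIN_MATCHES
    # optional splice stage
    splice_record: SequenceRecord | None = None
    splice_features: FeatureTable | None = None
    splice_primers: splice_check.PrimerPair | None = None
    # optional phylo stage
    tree: object | None = None  # dendropy.Tree
    root_state: str = "cic"


@dataclass(frozen=True)
class PipelineResult:
    verdicts: pd.DataFrame
    summary: dict

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.verdicts.to_csv(out / "verdicts.tsv", sep="\t", index=False)
        with open(out / "summary.json", "w") as fh:
            json.dump(self.summary, fh, indent=2, sort_keys=True)
            fh.write("\n")


def _align_pair(query: SequenceRecord, reference: SequenceRecord) -> GappedPair:
    aligner = _make_aligner()
    aln = aligner.align(reference.residues, query.residues)[0]
    # rows: [0] = reference, [1] = query
    return GappedPair(query_id=query.id, ref_id=reference.id,
                      query_aln=str(aln[1]), ref_aln=str(aln[0]))


def _scan_one(query: SequenceRecord, cfg: PipelineConfig
              ) -> tuple[GeneStatus, int | None]:
    cic_pos, _ = anchor_cic(query, cfg.reference, cfg.ref_cic_pos,
                            cfg.identity_floor)
    if cic_pos is None:
        status = GeneStatus(record_id=query.id,
                            status=GeneStatusKind.UNDETERMINED_5PRIME_TRUNCATED,
                            primary_start=None, reports=(),
                            notes="cic could not be anchored (low identity)")
        return status, None
    scan = enumerate_start_candidates(query, cic_pos, cfg.window_up,
                                      cfg.window_down)
    status = classify_gene(query, cic_pos, scan, cfg.ref_peptide_len,
                           cfg.full_length_frac, cfg.stop_tolerance)
    return status, cic_pos


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the configured stages over every record and merge the verdicts."""
    rows: list[dict] = []
    states: dict[str, str] = {}
    for query in config.records:
        logger.info("scan: %s", query.id)
        status, cic_pos = _scan_one(query, config)
        primary = status.primary_start
        row: dict = {
            "record_id": query.id,
            "status": status.status.value,
            "primary_offset": primary.offset if primary else None,
            "primary_abs_pos": primary.abs_pos if primary else None,
            "peptide_len": None,
            "first_stop_codon": None,
            "n_candidates": len(status.reports),
            "net_shift": None,
            "total_inserted": None,
            "n_changed": None,
            "sd_offset": None,
            "sd_matches": None,
            "sd_influence": None,
            "minus1_triplet": None,
            "notes": status.notes,
        }
        if primary is not None:
            report = next(r for r in status.reports if r.start == primary)
            row["peptide_len"] = report.peptide_len
            row["first_stop_codon"] = report.first_stop_codon
        states[query.id] = STATUS_TO_STATE[status.status]

        anchor = primary.abs_pos if primary else cic_pos
        if config.run_ledger and anchor is not None:
            try:
                pair = _align_pair(query, config.reference)
                events = frame_ledger.detect_indels(pair, anchor)
                sets = frame_ledger.find_compensatory_sets(events)
                row["net_shift"] = sum(e.signed_length for e in events)
                row["total_inserted"] = sum(s.total_inserted for s in sets)
                closed = [s for s in sets if s.closed and s.events]
                if closed and primary is not None and primary.offset != 0:
                    try:
                        rep = frame_ledger.distortion_diff(
                            pair, query_start=primary.abs_pos,
                            ref_start=config.ref_cic_pos, cset=closed[0])
                        row["n_changed"] = rep.n_changed
                    except frame_ledger.FrameNotRestoredError:
                        pass
            except Exception as exc:  # ledger failures degrade to a note
                logger.warning("ledger failed for %s: %s", query.id, exc)
                row["notes"] = (row["notes"] + "; " if row["notes"] else "") + \
                    f"ledger failed: {exc}"

        if config.run_sd and anchor is not None:
            start = primary.abs_pos if primary else cic_pos
            hits = regulatory_scan.scan_sd(query, start,
                                           min_matches=config.sd_min_matches)
            if hits:
                row["sd_offset"] = hits[0].offset_start
                row["sd_matches"] = hits[0].matches
                row["sd_influence"] = regulatory_scan.classify_sd_influence(hits[0])
            ctx = regulatory_scan.minus_one_context(query, start)
            row["minus1_triplet"] = ctx.triplet
        rows.append(row)

    verdicts = pd.DataFrame(rows)
    counts = verdicts["status"].value_counts().to_dict()
    summary: dict = {"n_records": len(rows), "status_counts": counts}

    if config.splice_record is not None:
        if config.splice_features is None or config.splice_primers is None:
            raise ValueError("splice stage requested without features/primers")
        rep = splice_check.amplicon_sizes(config.splice_record,
                                          config.splice_features,
                                          config.splice_primers)
        summary["splice"] = {"spliced_len": rep.spliced_len,
                             "unspliced_len": rep.unspliced_len,
                             "intron_len": rep.intron_len}

    if config.tree is not None:
        known = {tip: states.get(tip, "unknown")
                 for tip in (leaf.taxon.label for leaf in config.tree.leaf_node_iter())}
        tip_map = codon_phylo.TipStateMap(mapping=known)
        events = codon_phylo.map_states(config.tree, tip_map, config.root_state)
        summary["phylo"] = {
            "min_changes": events.min_changes,
            "n_reversals_to_cic": events.n_reversals_to_cic,
            "events": [
                {"branch": f"{e.parent_label}->{e.child_label}",
                 "from": e.from_state, "to": e.to_state}
                for e in events.events
            ],
        }
    return PipelineResult(verdicts=verdicts, summary=summary)
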