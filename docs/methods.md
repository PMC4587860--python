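# Methods

This note documents the models, conventions and design choices behind
`orchidmatk`, in the order the pipeline applies them.

## The problem being modelled

Plastid `matK` sits inside the trnK(UUU) group IIA intron and encodes the
only plastid-encoded maturase.  In most orchids a 4-nt `ATGT` insertion
places an AUG 10 nt upstream of, and out of frame with, the consensus
initiation codon (cic) used by other angiosperms.  Translating such
sequences from the cic produces premature stops (hence the widespread
"pseudogene" annotations); translating from the upstream alternative
initiation codon (aic) yields a full-length maturase once two further
insertions (4 nt and 1 nt) have brought the total inserted length to a
multiple of three.  The package operationalises each step of that argument.

## Coordinates and offsets

All positions are 1-based inclusive.  Two offset conventions coexist
because the literature uses both:

- candidate offsets are plain differences vs the cic (`offset =
  abs_pos − cic_pos`; the aic is at −10, an in-frame upstream variant at −6);
- anchor offsets ("+38 from the aic") place the A of the anchor ATG at +1
  and the base immediately 5′ at −1, with no offset 0.

`U` is transliterated to `T` on input; the only gap character is `-`.

## cic anchoring

The cic-homologous position on a query is found by global pairwise
alignment against a reference carrying a validated cic
(Bio.Align.PairwiseAligner; match 5, mismatch −4, gap open −10, extend
−0.5, an EDNAFULL-style scheme).  Identity is measured over *all* alignment
columns, gaps included, so an unrelated query cannot clear the floor merely
because its few aligned columns match; below the floor (default 40 %) or
when the cic column is gapped in the query, the gene is reported
undetermined.

## Start-candidate scan and classification

Every `ATG` whose A lies in `[cic − 60, cic + 30]` is a candidate (the
window covers the −10 and −6 starts with margin while excluding distant
spurious AUGs; both bounds are configurable).  Only ATG initiates — GTG/TTG
starts and RNA editing are out of scope; sequences are evaluated as
submitted.  Translation uses NCBI table 11; codons containing ambiguity
codes translate to `X` and never terminate, and an N inside a candidate's
ATG disqualifies it.

Full length is a two-part criterion, since the MatK N-terminus varies in
length across taxa: the peptide must reach 95 % of the reference peptide
length *and* a stop must fall within ±10 codons of the reference stop
position (start ATG = codon 1).  Both thresholds are configurable.

Classification follows the 5′-proximal rule: the primary start is the
5′-most full-length candidate.  Offset 0 → `CIC_FUNCTIONAL`; out-of-frame →
`AIC_FUNCTIONAL`; in-frame non-zero → `ALT_INFRAME`; no full-length
candidate → `NO_FULL_ORF`.  A record whose scan window runs past the 5′
end is always `UNDETERMINED_5PRIME_TRUNCATED`, even when a visible
candidate translates to full length: with upstream sequence missing the
5′-proximal rule cannot be applied, mirroring how partial accessions are
treated in practice.  Stop-codon counting uses "start ATG = codon 1"
throughout; where published per-accession counts imply a different
nucleotide-offset convention, the codon-index convention is authoritative
here.

## Frame ledger

Indels are maximal gap runs of a pairwise alignment: reference-row gaps are
insertions, query-row gaps deletions, each located by the anchor offset of
its first affected base.  An indel "at +k" means first inserted/deleted
base at offset k; published "+37"/"+42" phrasings are ambiguous by ±1, and
the packaged canonical geometry fixes first bases at +38 and +43 — the
headline quantities (9 nt total, a triplet; 11 changed residues) are
invariant to that choice.

Compensatory sets close at the earliest event where the running signed net
shift ≡ 0 (mod 3); an unbalanced tail is returned open and refuses a
distortion diff.  The published material exhibits only the resulting sets;
the earliest-closure rule is this package's reconstruction and is pinned to
an exhaustive oracle over all small event lists.

The distortion diff translates query and reference from their own starts
and aligns the peptides through the nucleotide alignment: each query codon
pairs with the reference codon sharing the most alignment columns (ties to
the 5′-most; no overlap → a peptide-alignment gap), and a codon counts as
inside the distorted span iff at least two of its bases are.  Under these
rules the canonical geometry yields exactly eleven pairable codons in the
distorted region (aic-frame codons 4–14 against reference codons 1–10),
and the fixture generator verifies that all eleven pairs differ — making
the 11-residue figure a deterministic property of the fixture rather than
an accident of one draw.

## Ribosome-binding context

The Shine–Dalgarno consensus `GGAGG` is slid across offsets −44..−2
upstream of a start; placements with ≥ 4/5 matches are reported ("moderate
similarity" is not quantified in the literature; 4/5 is this package's
operationalisation, configurable).  A hit reports its matched core — the
first..last consensus-matching position — so a 4/5 placement whose mismatch
is terminal spans four offsets (e.g. −31..−28).  Influence on ribosome
binding is a pure spacer rule: likely iff the gap between the hit's 3′ end
and the start A is 4–17 nt, reconstructing the two-sided observation that
elements within a few bases or beyond about −20 are non-influential.  The
−1 triplet is reported with a flag for the favoured U at −1.  Free-energy
duplex models and Kozak scoring are out of scope.

## Splice-product sizing

Amplicon lengths include both primer footprints (standard PCR product
definition).  The unspliced product is measured on the genomic record
between the unique forward-primer site and the unique reverse site (reverse
primers match the minus strand); the spliced product on the exon-ligated
sequence, so junction-spanning reverse primers are found.  The invariant
`unspliced − spliced = intron length` is enforced and doubles as an input
sanity check.  Primer matching is exact by default (`max_mismatch`
configurable); thermodynamics and splice-site prediction are out of scope —
annotations are inputs.

## Initiation-codon phylogenetics

Initiation-codon usage is an unordered three-state character
(`cic`/`aic`/`alt_inframe`; `alt_inframe` is deliberately not merged with
`cic`, since taxa exist that lack both the cic and the aic).  Unknown tips
carry the full state set and hence no cost.  A standard Fitch bottom-up
pass gives the minimum change count (polytomies are folded child-by-child;
all shipped trees are binary and the oracle tests use binary trees).  The
event history fixes the root state from the outgroup and resolves top-down
DELTRAN-style — a node keeps its parent's state whenever its Fitch set
allows, delaying changes toward the tips; forcing a root state outside the
root's Fitch set warns and counts one extra change.  Reversals are events
`aic → cic`.  No total reversal count is asserted anywhere: the method
reports whatever the supplied tree and states imply.  Tree inference,
branch-length-aware models and bootstrap support are out of scope.

## Synthetic data

The generator's defaults define the study conditions: a 510-codon reference
CDS (the ~62 kDa MatK scale) with an 80-nt 5′ UTR and 30-nt 3′ UTR, scan
window free of AUGs other than the cic, and the first ten post-start codons
additionally AUG-free so derived variants' windows stay interpretable.
Five variant modes reproduce the observed structures (see the module
docstring): the canonical aic geometry, the −6 in-frame start, an
uncompensated frameshift pseudogene, and a 5′ truncation.  Every variant is
built from a replayable edit script in reference coordinates; replay
reproduces both the variant and its alignment exactly, which is what the
indel-recovery tests consume.

The generator verifies rather than assumes: aic variants must translate to
exactly reference-length + 5 residues from the aic and hit a premature stop
in the cic frame; a frame shift does not logically force an early stop, so
inserted bases are resampled (and, if ever needed, a stop substituted in)
within a bounded budget, and failure raises instead of mislabelling.
Cohort substitutions preserve labels by construction: the scan window,
indel neighbourhoods and label-relevant stop codons are protected, a
substitution that would create a stop in the label-defining frame is
skipped, and each record's label-defining properties are re-verified after
sampling.  This slightly biases the realised substitution rate downward
and means noisy-cohort recovery measures the pipeline's robustness to
*label-neutral* noise — substitution noise that genuinely destroys an ORF
is a change of truth, not noise, and is outside what the truth table can
express.  What passing tests show, therefore, is correctness of the
machinery on structurally realistic inputs, not performance on real
sequencing error, alignment ambiguity, or biological length variation.

The trnK-like region draws its 5′ exon length so the spliced product falls
in the 50–61 nt assay range with an unspliced product of 2833 nt by
default; character histories on random trees evolve by explicit branch
events or per-branch Poisson changes, with the true event list recorded so
parsimony's lower-bound property is testable.

All randomness flows through `numpy.random.default_rng` seeds; identical
configurations are byte-identical, and the canonical fixture is found by a
seeded search over reference draws whose acceptance checks are exact
sequence properties, so it is deterministic as well.

## Numerical and degenerate-input choices

- SD hit ordering: more matches first, then smaller `|offset_start|`.
- Candidate ties: the 5′-most full-length candidate wins, always.
- Empty ORF (< 1 complete codon after the start) is an error, not a
  zero-length report, inside `evaluate_translation`; the classifier
  converts it to a non-full report.
- Feature tables normalise BED (0-based half-open) and GFF3 (1-based
  inclusive) to the internal 1-based inclusive convention; a missing intron
  feature between adjacent exons denotes a zero-length intron.
- Problem sizes in the shipped tests (cohorts of up to 200 records at 510
  codons, trees of ≤ 13 tips, exhaustive oracles over all indel lists of
  ≤ 5 events) were chosen as the smallest scales at which every property is
  informative.

## Known limitations

- The pairwise-alignment ledger stage depends on the aligner's gap
  placement; equal-scoring gap shifts can move an indel's reported offset
  by a few bases.  Replayed (known-edit) alignments are exact.
- The compensatory-set closure rule and the distortion-diff pairing rule
  are reconstructions of how the published counts arise; alternative
  conventions (e.g. latest closure, single-column pairing) would change
  per-codon bookkeeping but not the 9-nt/triplet arithmetic.
- Fitch mapping treats gains and reversals as equally costly; asymmetric
  costs would need a Sankoff variant, not provided.
- The generator does not model codon-usage bias, rate heterogeneity or RNA
  editing.
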