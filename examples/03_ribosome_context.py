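"""Inspect the ribosome-binding context of a candidate start codon.

Scans the 5' window of the alternative initiation codon for
Shine-Dalgarno-like elements (consensus GGAGG) and reports the -1 triplet.
"""

import orchidmatk as om

exemplar = om.aic_exemplar()

hits = om.scan_sd(exemplar.orchid, exemplar.aic_pos)
print("SD-like elements upstream of the aic (>= 4/5 consensus matches):")
for hit in hits:
    verdict = om.classify_sd_influence(hit)
    print(f"  {hit.matched_seq} at {hit.offset_start}..{hit.offset_end} "
          f"({hit.matches}/5 matches, spacer {hit.spacer} nt) -> {verdict}")

ctx = om.minus_one_context(exemplar.orchid, exemplar.aic_pos)
print(f"\n-1 triplet at the aic: {ctx.triplet} "
      f"(uracil at -1: {ctx.u_preferred})")
print("\nReading: the SD-like core sits ~28 nt upstream - too far to drive")
print("ribosome binding - and the -1 base is not a U, so neither feature")
print("singles out one initiation codon; other signals must decide.")
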