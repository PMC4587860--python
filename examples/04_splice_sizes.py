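"""Predict RT-PCR product sizes for the trnK splicing readout.

MatK splices the group IIA intron of trnK(UUU); with exon-anchored primers
the mature transcript gives a short amplicon and the unspliced precursor the
full genomic span.  This computes both expected sizes from a synthetic
trnK-like region.
"""

import orchidmatk as om

record, features, primers = om.generate_trnk_region(seed=0)
report = om.amplicon_sizes(record, features, primers)

print(f"forward primer {primers.fwd_name} binds at {report.fwd_site}")
print(f"reverse primer {primers.rev_name} site starts at {report.rev_site}")
print(f"spliced (mature trnK) product : {report.spliced_len} bp")
print(f"unspliced precursor product   : {report.unspliced_len} bp")
print(f"annotated intron length       : {report.intron_len} bp")
print("\nReading: a short band near 50-60 bp on a gel means the intron was")
print("removed - i.e. the maturase is active - while a ~2.8 kb band means the")
print("precursor is still intact; the size difference equals the intron.")
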