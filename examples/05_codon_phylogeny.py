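"""Map initiation-codon usage onto a phylogeny and find reversals.

A small orchid-like tree: the outgroup and a basal lineage keep the
consensus initiation codon (cic); most of the ingroup uses the alternative
one (aic); one nested tip reverted to the cic.
"""

import orchidmatk as om
from orchidmatk.seq_io import tree_from_string

tree = tree_from_string("((outgroup),(basal,((v1,v2),(reverted,(e1,e2)))));")
states = om.TipStateMap(mapping={
    "outgroup": "cic", "basal": "cic",
    "v1": "aic", "v2": "aic",
    "reverted": "cic", "e1": "aic", "e2": "aic",
})

min_changes, node_sets = om.fitch_reconstruct(tree, states)
summary = om.summarize_transitions(tree, (min_changes, node_sets),
                                   root_state="cic")

print(f"minimum state changes: {summary.min_changes}")
for ev in summary.events:
    print(f"  {ev.from_state} -> {ev.to_state} on branch "
          f"{ev.parent_label} -> {ev.child_label}")
print(f"reversals to the cic: {summary.n_reversals_to_cic}")
print("\nReading: parsimony needs one gain of the alternative codon at the base")
print("of the ingroup and one later reversal back to the consensus codon -")
print("the pattern of loss and regain seen within the orchid family.")
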