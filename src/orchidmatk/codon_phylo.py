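"""Parsimony mapping of initiation-codon usage on a rooted phylogeny.

Initiation-codon usage (consensus ``cic``, alternative out-of-frame ``aic``,
or an in-frame alternative ``alt_inframe``) is treated as an unordered
three-state character.  A standard Fitch bottom-up pass gives the minimum
number of state changes; a DELTRAN-style top-down resolution (changes
delayed toward the tips, root fixed from the outgroup) yields one concrete
event history from which gains of the aic and reversals back to the cic are
enumerated.  Tree inference is out of scope: the module consumes any
user-supplied rooted tree.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import dendropy

STATES = ("cic", "aic", "alt_inframe")
UNKNOWN = "unknown"


@dataclass(frozen=True)
class TipStateMap:
    """Initiation-codon state of every tree tip; unknown tips carry no cost."""

    mapping: Mapping[str, str]

    def __post_init__(self) -> None:
        for tip, state in self.mapping.items():
            if state not in STATES and state != UNKNOWN:
                raise ValueError(f"tip {tip!r}: unknown state {state!r}")

    def state_set(self, tip_label: str) -> frozenset[str]:
        state = self.mapping[tip_label]
        return frozenset(STATES) if state == UNKNOWN else frozenset({state})


@dataclass(frozen=True)
class TransitionEvent:
    parent_label: str
    child_label: str
    from_state: str
    to_state: str


@dataclass(frozen=True)
class EventSummary:
    min_changes: int
    events: tuple[TransitionEvent, ...]

    @property
    def n_reversals_to_cic(self) -> int:
        return sum(1 for e in self.events
                   if e.from_state == "aic" and e.to_state == "cic")


def _node_label(node: dendropy.Node) -> str:
    if node.taxon is not None and node.taxon.label:
        return node.taxon.label
    if node.label:
        return node.label
    return f"<node{id(node) & 0xFFFF:04x}>"


def _label_map(tree: dendropy.Tree) -> dict[dendropy.Node, str]:
    """Stable display labels: given names, else preorder indices."""
    labels: dict[dendropy.Node, str] = {}
    for i, node in enumerate(tree.preorder_node_iter()):
        given = (node.taxon.label if node.taxon is not None and node.taxon.label
                 else node.label)
        labels[node] = given if given else f"node{i}"
    return labels


def fitch_reconstruct(tree: dendropy.Tree, states: TipStateMap
                      ) -> tuple[int, dict[dendropy.Node, frozenset[str]]]:
    """Fitch bottom-up pass over the unordered initiation-codon alphabet.

    Every tip must have an entry in ``states`` (``unknown`` is allowed and
    excluded from scoring by carrying the full state set).  Returns the
    minimum change count and the preliminary state set of every node.
    Polytomies are folded child-by-child.
    """
    known = 0
    for leaf in tree.leaf_node_iter():
        label = _node_label(leaf)
        if label not in states.mapping:
            raise ValueError(f"tip {label!r} missing from the tip-state table")
        if states.mapping[label] != UNKNOWN:
            known += 1
    if known == 0:
        raise ValueError("all tips unknown: nothing to reconstruct")

    changes = 0
    sets: dict[dendropy.Node, frozenset[str]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            sets[node] = states.state_set(_node_label(node))
            continue
        children = node.child_nodes()
        current = sets[children[0]]
        for child in children[1:]:
            inter = current & sets[child]
            if inter:
                current = inter
            else:
                current = current | sets[child]
                changes += 1
        sets[node] = current
    return changes, sets


def summarize_transitions(tree: dendropy.Tree,
                          reconstruction: tuple[int, dict[dendropy.Node, frozenset[str]]],
                          root_state: str) -> EventSummary:
    """DELTRAN-style event history given a root state fixed from the outgroup.

    Top-down, each node keeps its parent's state whenever the Fitch set
    allows it (delaying changes toward the tips); otherwise the 5'-most state
    in the fixed ``STATES`` order is chosen and a transition event recorded.
    If ``root_state`` is not in the root's Fitch set a warning is issued and
    the state is used anyway (one extra change).
    """
    min_changes, sets = reconstruction
    labels = _label_map(tree)
    root = tree.seed_node
    if root_state not in sets[root]:
        warnings.warn(
            f"root state {root_state!r} not in the root's Fitch set "
            f"{sorted(sets[root])}; forcing it (one extra change)",
            stacklevel=2,
        )
        min_changes += 1
    assigned: dict[dendropy.Node, str] = {root: root_state}
    events: list[TransitionEvent] = []
    for node in tree.preorder_node_iter():
        if node is root:
            continue
        parent_state = assigned[node.parent_node]
        if parent_state in sets[node]:
            assigned[node] = parent_state
        else:
            new_state = next(s for s in STATES if s in sets[node])
            assigned[node] = new_state
            events.append(TransitionEvent(
                parent_label=labels[node.parent_node],
                child_label=labels[node],
                from_state=parent_state, to_state=new_state))
    return EventSummary(min_changes=min_changes, events=tuple(events))


def map_states(tree: dendropy.Tree, states: TipStateMap, root_state: str
               ) -> EventSummary:
    """Convenience wrapper: Fitch pass followed by transition enumeration."""
    return summarize_transitions(tree, fitch_reconstruct(tree, states), root_state)
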