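"""Dollo placement of neighborhood-defining functions on a species tree.

A function present (i.e. labeling a neighborhood) in a set of species is
placed at a single origin — the most recent common ancestor of the species
carrying it — with losses on the maximal subtrees below the origin that
lack it entirely. Under the single-gain (Dollo) model this MRCA placement
is the unique minimum-event reconstruction. Absence in poorly annotated
species can be coded as missing ('?'), which removes those leaves from
both the MRCA and the loss count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
import pandas as pd

__all__ = [
    "SpeciesTree",
    "PresenceMatrix",
    "Placement",
    "parse_tree",
    "build_presence_matrix",
    "dollo_place",
]

MISSING = "?"


class SpeciesTree:
    """A rooted species tree with uniquely labeled leaves (branch lengths ignored)."""

    def __init__(self, tree: dendropy.Tree) -> None:
        labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        if len(labels) != len(set(labels)):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise ValueError(f"duplicate leaf labels: {dupes}")
        if any(l is None for l in labels):
            raise ValueError("every leaf must be labeled")
        self.tree = tree
        self.leaf_labels = set(labels)

    @classmethod
    def from_newick(cls, newick: str) -> "SpeciesTree":
        try:
            tree = dendropy.Tree.get(
                data=newick, schema="newick",
                suppress_internal_node_taxa=True,
                preserve_underscores=True,
            )
        except Exception as exc:  # dendropy raises several error types
            raise ValueError(f"invalid Newick: {exc}") from exc
        tree.is_rooted = True
        return cls(tree)

    def _leafset(self, node) -> frozenset[str]:
        return frozenset(l.taxon.label for l in node.leaf_iter())

    def mrca(self, labels: Sequence[str]) -> dendropy.Node:
        missing = set(labels) - self.leaf_labels
        if missing:
            raise KeyError(f"labels not in tree: {sorted(missing)}")
        if len(set(labels)) == 1:
            (label,) = set(labels)
            return next(
                l for l in self.tree.leaf_node_iter() if l.taxon.label == label
            )
        return self.tree.mrca(taxon_labels=list(set(labels)))


def parse_tree(newick: str) -> SpeciesTree:
    return SpeciesTree.from_newick(newick)


@dataclass
class Placement:
    term_id: str
    gain_clade: frozenset[str]          # leaf set descending from the origin
    loss_clades: list[frozenset[str]]   # leaf sets of the lost subtrees

    @property
    def n_events(self) -> int:
        return 1 + len(self.loss_clades)


class PresenceMatrix:
    """Binary term x species matrix: 1 iff the term labels a neighborhood there."""

    def __init__(self, data: pd.DataFrame) -> None:
        self.data = data

    @property
    def terms(self) -> list[str]:
        return list(self.data.index)

    @property
    def species(self) -> list[str]:
        return list(self.data.columns)

    def row(self, term: str) -> dict[str, int]:
        return {sp: int(v) for sp, v in self.data.loc[term].items()}


def build_presence_matrix(neighborhood_sets_by_species: Mapping[str, Sequence]) -> PresenceMatrix:
    """Presence = species has >= 1 called neighborhood of the term."""
    if not neighborhood_sets_by_species:
        raise ValueError("need >= 1 species")
    species = sorted(neighborhood_sets_by_species)
    terms = sorted({
        n.term_id for neighs in neighborhood_sets_by_species.values() for n in neighs
    })
    data = pd.DataFrame(0, index=terms, columns=species, dtype=int)
    for sp, neighs in neighborhood_sets_by_species.items():
        for n in neighs:
            data.loc[n.term_id, sp] = 1
    return PresenceMatrix(data)


def dollo_place(
    presence: Mapping[str, int | str], tree: SpeciesTree, term_id: str = "term"
) -> Placement:
    """Minimum-event single-gain placement of a presence/absence pattern.

    Gain at the MRCA of present leaves; a loss on each maximal subtree below
    the gain containing no present leaf (subtrees made entirely of missing
    leaves need no event). Leaves absent from the mapping are treated as
    absent; values may be 0, 1 or '?'.
    """
    present = [sp for sp, v in presence.items() if v == 1]
    if not present:
        raise ValueError(f"term {term_id!r} present in no species")
    unknown = set(presence) - tree.leaf_labels
    if unknown:
        raise KeyError(f"species not in tree: {sorted(unknown)}")
    missing = {sp for sp, v in presence.items() if v == MISSING}

    gain = tree.mrca(present)
    present_set = set(present)

    losses: list[frozenset[str]] = []

    def scan(node) -> None:
        leafset = tree._leafset(node)
        if leafset & present_set:
            for child in node.child_nodes():
                scan(child)
            return
        if leafset - missing:
            losses.append(frozenset(leafset))
        # an all-missing subtree needs no event

    for child in gain.child_nodes():
        scan(child)
    if gain.is_leaf():
        pass  # gain at a single present leaf: no losses possible

    return Placement(term_id, tree._leafset(gain), sorted(losses, key=sorted))
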