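"""Smallest-clade taxonomy assignment on reference trees.

An unlabeled query leaf is assigned the longest lineage prefix shared by all
labeled reference leaves in the smallest clade containing the query and at
least one reference; queries that cannot be resolved to species level are
labeled with the ``__X<n>`` convention.
"""

from __future__ import annotations

import warnings
from collections.abc import Mapping
from dataclasses import dataclass, field

import dendropy

RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")


@dataclass
class RefTree:
    """A rooted reference tree plus lineage labels for a subset of leaves.

    Lineages are GTDB-style semicolon-delimited strings
    (``domain;phylum;...;species``).
    """

    tree: dendropy.Tree
    lineages: Mapping[str, str]

    @classmethod
    def from_newick(cls, newick: str, lineages: Mapping[str, str]) -> "RefTree":
        tree = dendropy.Tree.get(
            data=newick, schema="newick", preserve_underscores=True
        )
        basal = len(tree.seed_node.child_nodes())
        if not tree.is_rooted and basal <= 2:
            # a basal bifurcation is already an implicit rooting
            tree.is_rooted = True
        elif not tree.is_rooted:
            warnings.warn("input tree unrooted; midpoint-rooting", stacklevel=2)
            for edge in tree.preorder_edge_iter():
                if edge.length is None:
                    edge.length = 1.0
            tree.reroot_at_midpoint(update_bipartitions=False)
        return cls(tree, dict(lineages))

    def leaf(self, label: str) -> dendropy.Node:
        for lf in self.tree.leaf_node_iter():
            if lf.taxon is not None and lf.taxon.label == label:
                return lf
        raise KeyError(f"leaf {label!r} not in tree")


def _lineage_parts(lineage: str) -> list[str]:
    return [p.strip() for p in lineage.split(";") if p.strip()]


def _common_prefix(lineages: list[list[str]]) -> list[str]:
    prefix: list[str] = []
    for parts in zip(*lineages):
        if len(set(parts)) == 1:
            prefix.append(parts[0])
        else:
            break
    return prefix


def smallest_clade_assign(
    ref: RefTree, query_leaf: str
) -> tuple[str, str | None]:
    """Assign a lineage prefix and rank to `query_leaf`.

    Walks from the query toward the root and, at the first ancestor whose
    clade contains at least one labeled reference leaf, returns the longest
    lineage prefix shared by all labeled leaves in that clade, with its rank
    name; (``""``, None) when the labels share nothing.
    """
    if not ref.lineages:
        raise ValueError("tree has no labeled reference leaves")
    node = ref.leaf(query_leaf)
    anc = node.parent_node
    while anc is not None:
        labeled = [
            lf.taxon.label
            for lf in anc.leaf_iter()
            if lf.taxon is not None
            and lf.taxon.label != query_leaf
            and lf.taxon.label in ref.lineages
        ]
        if labeled:
            parts = _common_prefix([_lineage_parts(ref.lineages[l]) for l in labeled])
            if not parts:
                return "", None
            rank = RANKS[min(len(parts), len(RANKS)) - 1]
            return ";".join(parts), rank
        anc = anc.parent_node
    raise ValueError("no labeled reference leaf in tree")


@dataclass
class UnassignedLabeler:
    """Issues ``<prefix>__X<n>`` labels with per-prefix serial numbers."""

    counters: dict[str, int] = field(default_factory=dict)

    def label(self, lineage_prefix: str, rank: str | None = None) -> str:
        if rank == "species":
            raise ValueError("species-level assignments are not __X-labeled")
        n = self.counters.get(lineage_prefix, 0) + 1
        self.counters[lineage_prefix] = n
        return f"{lineage_prefix}__X{n}"


def label_unassigned(
    lineage_prefix: str, rank: str | None, counter: dict[str, int]
) -> str:
    """Functional form of :class:`UnassignedLabeler` over a shared counter."""
    if rank == "species":
        raise ValueError("species-level assignments are not __X-labeled")
    n = counter.get(lineage_prefix, 0) + 1
    counter[lineage_prefix] = n
    return f"{lineage_prefix}__X{n}"
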