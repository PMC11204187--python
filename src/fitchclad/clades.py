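"""Rooted-view clade queries and the taxon-coverage statistic.

An unrooted parsimony tree makes claims like "group X is monophyletic"
meaningful only relative to a root.  Here the display root sits on the
pendant edge of a designated outgroup taxon; a named group is monophyletic
when its members form exactly one complete rooted clade.  The module ships
the study's named groups (the new subfamily, its genera, the paraphyletic
subfamily *sensu lato*) resolved against the bundled matrix labels.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from importlib import resources
from typing import Iterable

from .tree import Tree, TreeError

__all__ = [
    "NamedGroup",
    "RootedView",
    "root_at_outgroup",
    "is_monophyletic",
    "coverage_percent",
    "bundled_groups",
]


@dataclass(frozen=True)
class NamedGroup:
    name: str
    members: frozenset

    def __post_init__(self):
        if not self.members:
            raise ValueError(f"group {self.name!r} has no members")


class RootedView:
    """A rooted orientation of an unrooted tree: the root is placed on the
    pendant edge of an outgroup taxon.  The underlying topology is
    unchanged; the view only fixes which side of each edge is 'down'."""

    def __init__(self, tree: Tree, root_taxon: str):
        if root_taxon not in tree.leaves:
            raise TreeError(f"unknown root taxon {root_taxon!r}")
        self.tree = tree
        self.root_taxon = root_taxon
        ingroup = tree.leaves - {root_taxon}
        clusters = {frozenset(ingroup)}
        for bp in tree.bipartitions():
            side = bp.side if root_taxon not in bp.side else bp.other_side
            clusters.add(frozenset(side))
        clusters.update(frozenset([lf]) for lf in ingroup)
        self.clusters = clusters

    def contains_clade(self, members: Iterable[str]) -> bool:
        return frozenset(members) in self.clusters

    def unroot(self) -> Tree:
        return self.tree


def root_at_outgroup(tree: Tree, outgroup_taxon: str) -> RootedView:
    return RootedView(tree, outgroup_taxon)


def is_monophyletic(tree: Tree, group, root_taxon: str) -> bool:
    """True iff the group's members form one complete clade when the tree is
    rooted at ``root_taxon`` (which must lie outside the group).

    Computed by two independent routes — cluster lookup in the rooted view,
    and unrooted-bipartition lookup — which always agree.
    """
    members = frozenset(group.members if isinstance(group, NamedGroup) else group)
    missing = members - tree.leaves
    if missing:
        raise TreeError(f"group members absent from tree: {sorted(missing)}")
    if root_taxon in members:
        raise ValueError("root taxon lies inside the queried group")
    view = root_at_outgroup(tree, root_taxon)
    by_cluster = view.contains_clade(members)
    if len(members) == 1 or members == tree.leaves - {root_taxon}:
        by_split = True
    else:
        sides = {bp.side for bp in tree.bipartitions()} | {
            bp.other_side for bp in tree.bipartitions()
        }
        by_split = members in sides
    assert by_cluster == by_split  # definitional equivalence
    return by_cluster


def coverage_percent(included: Iterable[str], universe: Iterable[str]) -> int:
    """100·|included|/|universe|, rounded half-up to the nearest integer."""
    included = frozenset(included)
    universe = frozenset(universe)
    if not universe:
        raise ValueError("empty universe")
    if not included <= universe:
        raise ValueError("included taxa must be a subset of the universe")
    return int(math.floor(100 * len(included) / len(universe) + 0.5))


def bundled_groups() -> dict[str, NamedGroup]:
    """The study's named groups keyed by name, with members spelled exactly
    as in the bundled matrix."""
    raw = json.loads(
        (resources.files("fitchclad.data") / "groups.json").read_text()
    )
    return {
        name: NamedGroup(name, frozenset(members)) for name, members in raw.items()
    }
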