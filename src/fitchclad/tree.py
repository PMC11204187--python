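"""Unrooted leaf-labeled trees and bipartitions.

The central container of the package: an unrooted topology whose leaves carry
taxon labels and whose internal nodes are anonymous.  Branch lengths are not
modeled (parsimony never consumes them); per-edge annotations such as
bootstrap support are attached to bipartitions, not to node objects, so they
survive re-rooting.

Two trees are considered equal exactly when their leaf sets and their sets of
non-trivial bipartitions coincide; :meth:`Tree.canonical_key` realises that
equivalence and is the basis of all deduplication in the search code.
"""

from __future__ import annotations

import io
from typing import Iterable, Iterator, Mapping

import dendropy

__all__ = ["Tree", "Bipartition", "TreeError"]


class TreeError(ValueError):
    """Raised for structurally invalid trees or tree operations."""


class Bipartition:
    """A split of the leaf set induced by removing one edge.

    Stored in canonical form: ``side`` is the half that does *not* contain
    the reference taxon (the lexicographically smallest leaf label), so two
    Bipartition objects over the same leaf set compare equal iff they denote
    the same edge.
    """

    __slots__ = ("side", "full")

    def __init__(self, subset: Iterable[str], full: Iterable[str]):
        full_fs = frozenset(full)
        side_fs = frozenset(subset)
        if not side_fs or side_fs == full_fs:
            raise TreeError("bipartition sides must both be non-empty")
        if not side_fs <= full_fs:
            raise TreeError("bipartition side is not a subset of the leaf set")
        ref = min(full_fs)
        if ref in side_fs:
            side_fs = full_fs - side_fs
        self.side = side_fs
        self.full = full_fs

    @property
    def other_side(self) -> frozenset:
        return self.full - self.side

    def is_trivial(self) -> bool:
        return len(self.side) == 1 or len(self.other_side) == 1

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Bipartition)
            and self.side == other.side
            and self.full == other.full
        )

    def __hash__(self) -> int:
        return hash((self.side, self.full))

    def __repr__(self) -> str:
        names = ",".join(sorted(self.side))
        return f"Bipartition({{{names}}})"


class Tree:
    """Unrooted, leaf-labeled, possibly multifurcating tree.

    Internally an adjacency map over integer node ids; leaves are the nodes
    with degree one (or a single isolated node).  The class is deliberately
    small: construction from/to Newick, bipartition extraction, and
    canonicalization.  Search algorithms operate on their own packed
    representations and convert at the boundary.
    """

    def __init__(
        self,
        adjacency: Mapping[int, Iterable[int]],
        leaf_labels: Mapping[int, str],
        support: Mapping[Bipartition, float] | None = None,
    ):
        self._adj: dict[int, tuple[int, ...]] = {
            int(u): tuple(vs) for u, vs in adjacency.items()
        }
        self._leaf_labels = dict(leaf_labels)
        if len(set(self._leaf_labels.values())) != len(self._leaf_labels):
            raise TreeError("duplicate leaf labels")
        for u, vs in self._adj.items():
            for v in vs:
                if u not in self._adj.get(v, ()):  # pragma: no cover - guard
                    raise TreeError("adjacency map is not symmetric")
        for node, label in self._leaf_labels.items():
            if len(self._adj.get(node, ())) > 1:
                raise TreeError(f"labeled node {label!r} is not a leaf")
        self.support: dict[Bipartition, float] = dict(support or {})

    # -- construction -----------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "Tree":
        """Parse a single Newick tree; underscores in unquoted labels become
        spaces (the usual Newick convention)."""
        try:
            dtree = dendropy.Tree.get(
                data=text, schema="newick", suppress_internal_node_taxa=True
            )
        except Exception as exc:
            raise TreeError(f"could not parse Newick: {exc}") from exc
        adj: dict[int, list[int]] = {}
        labels: dict[int, str] = {}
        ids: dict[int, int] = {}

        def nid(dnode) -> int:
            key = id(dnode)
            if key not in ids:
                ids[key] = len(ids)
                adj[ids[key]] = []
            return ids[key]

        for edge in dtree.preorder_edge_iter():
            if edge.tail_node is None:
                continue
            u, v = nid(edge.tail_node), nid(edge.head_node)
            adj[u].append(v)
            adj[v].append(u)
        for dnode in dtree.leaf_node_iter():
            if dnode.taxon is None:
                raise TreeError("leaf without a label")
            labels[nid(dnode)] = dnode.taxon.label
        tree = cls(adj, labels)
        tree = tree.suppress_degree_two()
        # internal node labels, if numeric, are read as support values
        full = frozenset(labels.values())
        for dnode in dtree.preorder_node_iter():
            if dnode.is_leaf() or dnode.label is None or dnode.parent_node is None:
                continue
            try:
                value = float(dnode.label)
            except ValueError:
                continue
            below = frozenset(
                lf.taxon.label for lf in dnode.leaf_iter() if lf.taxon is not None
            )
            if 0 < len(below) < len(full):
                bp = Bipartition(below, full)
                if not bp.is_trivial():
                    tree.support[bp] = value
        return tree

    @classmethod
    def from_clusters(cls, leaves: Iterable[str], clusters: Iterable[frozenset]) -> "Tree":
        """Build the (possibly multifurcating) unrooted tree whose rooted view
        at the reference taxon has exactly the given clusters.

        ``clusters`` must be a laminar family of proper subsets of
        ``leaves - {reference}`` where the reference taxon is the smallest
        label; singletons and the full ingroup cluster are implied.
        """
        leaf_list = sorted(set(leaves))
        if len(leaf_list) == 0:
            raise TreeError("empty leaf set")
        ref = leaf_list[0]
        rest = [lf for lf in leaf_list if lf != ref]
        cl = {frozenset(c) for c in clusters}
        cl = {c for c in cl if 1 < len(c) < len(leaf_list)}
        for c in cl:
            if ref in c:
                raise TreeError("clusters must exclude the reference taxon")
        for a in cl:
            for b in cl:
                if a & b and not (a <= b or b <= a):
                    raise TreeError("clusters are not mutually compatible")
        adj: dict[int, list[int]] = {}
        labels: dict[int, str] = {}
        counter = 0

        def new_node() -> int:
            nonlocal counter
            node = counter
            counter += 1
            adj[node] = []
            return node

        def link(u: int, v: int) -> None:
            adj[u].append(v)
            adj[v].append(u)

        root = new_node()
        ref_leaf = new_node()
        labels[ref_leaf] = ref
        link(root, ref_leaf)
        ordered = sorted(cl, key=len, reverse=True)
        owner: dict[str, int] = {lf: root for lf in rest}
        node_of: dict[frozenset, int] = {}
        for c in ordered:
            parents = {owner[lf] for lf in c}
            if len(parents) != 1:  # pragma: no cover - laminar guard
                raise TreeError("clusters are not laminar")
            parent = parents.pop()
            node = new_node()
            node_of[c] = node
            link(parent, node)
            for lf in c:
                owner[lf] = node
        for lf in rest:
            node = new_node()
            labels[node] = lf
            link(owner[lf], node)
        tree = cls(adj, labels)
        return tree.suppress_degree_two()

    # -- basic queries -----------------------------------------------------

    @property
    def leaves(self) -> frozenset:
        return frozenset(self._leaf_labels.values())

    @property
    def n_leaves(self) -> int:
        return len(self._leaf_labels)

    def nodes(self) -> Iterator[int]:
        return iter(self._adj)

    def degree(self, node: int) -> int:
        return len(self._adj[node])

    def neighbors_of(self, node: int) -> tuple[int, ...]:
        return self._adj[node]

    def leaf_node(self, label: str) -> int:
        for node, lab in self._leaf_labels.items():
            if lab == label:
                return node
        raise TreeError(f"no leaf labeled {label!r}")

    def label_of(self, node: int) -> str | None:
        return self._leaf_labels.get(node)

    def edges(self) -> list[tuple[int, int]]:
        return [(u, v) for u, vs in self._adj.items() for v in vs if u < v]

    def is_binary(self) -> bool:
        """Fully resolved: every internal node has degree three (n >= 4);
        trees with at most three leaves are vacuously binary."""
        if self.n_leaves <= 2:
            return True
        for node, vs in self._adj.items():
            if node in self._leaf_labels:
                if len(vs) != 1:
                    return False
            elif len(vs) != 3:
                return False
        return True

    # -- bipartitions ------------------------------------------------------

    def _leafset_below(self) -> dict[tuple[int, int], frozenset]:
        """For every directed edge (u, v): labels in the component containing
        v once edge {u, v} is removed."""
        memo: dict[tuple[int, int], frozenset] = {}

        def walk(u: int, v: int) -> frozenset:
            key = (u, v)
            if key in memo:
                return memo[key]
            if v in self._leaf_labels:
                result = frozenset([self._leaf_labels[v]])
            else:
                parts = [walk(v, w) for w in self._adj[v] if w != u]
                result = frozenset().union(*parts)
            memo[key] = result
            return result

        for u, vs in self._adj.items():
            for v in vs:
                walk(u, v)
        return memo

    def bipartitions(self, include_trivial: bool = False) -> set[Bipartition]:
        full = self.leaves
        below = self._leafset_below()
        out: set[Bipartition] = set()
        for side in below.values():
            if not 0 < len(side) < len(full):
                continue
            bp = Bipartition(side, full)
            if include_trivial or not bp.is_trivial():
                out.add(bp)
        return out

    def canonical_key(self) -> tuple[frozenset, frozenset]:
        return (self.leaves, frozenset(bp.side for bp in self.bipartitions()))

    def __eq__(self, other) -> bool:
        return isinstance(other, Tree) and self.canonical_key() == other.canonical_key()

    def __hash__(self) -> int:
        return hash(self.canonical_key())

    # -- surgery -----------------------------------------------------------

    def copy(self) -> "Tree":
        return Tree(self._adj, self._leaf_labels, self.support)

    def suppress_degree_two(self) -> "Tree":
        """Contract internal nodes of degree two (canonical unrooted form)."""
        adj = {u: list(vs) for u, vs in self._adj.items()}
        changed = True
        while changed:
            changed = False
            for node in list(adj):
                if node in self._leaf_labels or len(adj[node]) != 2:
                    continue
                a, b = adj[node]
                adj[a] = [x for x in adj[a] if x != node] + [b]
                adj[b] = [x for x in adj[b] if x != node] + [a]
                del adj[node]
                changed = True
        return Tree(adj, self._leaf_labels, self.support)

    def collapse(self, biparts: Iterable[Bipartition]) -> "Tree":
        """Return the tree with the given internal edges contracted."""
        drop = {bp.side for bp in biparts}
        keep = [bp.side for bp in self.bipartitions() if bp.side not in drop]
        return Tree.from_clusters(self.leaves, keep)

    # -- serialization -----------------------------------------------------

    def newick(
        self,
        root_label: str | None = None,
        support: Mapping[Bipartition, float] | None = None,
        support_decimals: int = 3,
    ) -> str:
        """Serialize to Newick, rooted for display on the pendant edge of
        ``root_label`` (default: smallest label).  Labels containing spaces
        are written with underscores; bipartition support values, if given
        (or stored on the tree), become internal node labels."""
        if self.n_leaves == 0:
            raise TreeError("cannot serialize an empty tree")
        if self.n_leaves == 1:
            (label,) = self.leaves
            return f"{_escape(label)};"
        support = dict(self.support if support is None else support)
        root_label = root_label if root_label is not None else min(self.leaves)
        root = self.leaf_node(root_label)
        full = self.leaves

        def write(u: int, v: int, out: io.StringIO) -> frozenset:
            if v in self._leaf_labels:
                label = self._leaf_labels[v]
                out.write(_escape(label))
                return frozenset([label])
            out.write("(")
            sides = []
            children = [w for w in self._adj[v] if w != u]
            for i, w in enumerate(children):
                if i:
                    out.write(",")
                sides.append(write(v, w, out))
            out.write(")")
            side = frozenset().union(*sides)
            if 1 < len(side) < len(full):
                bp = Bipartition(side, full)
                if not bp.is_trivial() and bp in support:
                    out.write(f"{support[bp]:.{support_decimals}f}")
            return side

        out = io.StringIO()
        if self.n_leaves == 2:
            a, b = sorted(self.leaves)
            out.write(f"({_escape(a)},{_escape(b)});")
            return out.getvalue()
        (start,) = self._adj[root]
        out.write("(")
        out.write(_escape(root_label))
        out.write(",")
        write(root, start, out)
        out.write(");")
        return out.getvalue()

    def __repr__(self) -> str:
        return f"Tree({self.n_leaves} leaves)"


def _escape(label: str) -> str:
    safe = label.replace(" ", "_")
    if any(ch in safe for ch in "():;,[]'\""):
        return "'" + label.replace("'", "''") + "'"
    return safe
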