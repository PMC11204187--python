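"""Parsimony lengths and ancestral-state reconstruction for unordered
characters.

The scoring model is equal-weight Fitch parsimony: the length of a character
on a binary leaf-labeled tree is the minimum number of state changes over
all assignments of single states to internal nodes.  A ``?`` cell enters the
computation as the set of states observed among the scored leaves of that
character, so missing data never add steps and an all-missing character
scores zero.

Alongside the linear-time Fitch pass the module carries a brute-force
enumerator (:func:`brute_force_length`) used as an independent oracle in the
test-suite, and a unit-cost dynamic program over explicit state vectors that
supports most-parsimonious-reconstruction queries (ACCTRAN/DELTRAN walks,
ambiguity sets, per-edge change bounds).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .matrix_io import MISSING, CharacterMatrix
from .tree import Tree, TreeError

__all__ = [
    "CharacterFit",
    "fitch_length",
    "brute_force_length",
    "min_steps",
    "max_steps",
    "ancestral_states",
    "Reconstruction",
    "Change",
]

_INF = 10**9


@dataclass(frozen=True)
class CharacterFit:
    """Per-character fit of one character on one tree.

    ``s`` observed steps, ``m`` minimum conceivable steps on any tree,
    ``g`` maximum conceivable steps (star-tree worst case).
    """

    char_index: int  # 1-based
    s: int
    m: int
    g: int

    @property
    def ci(self) -> float:
        return 1.0 if self.s == 0 else self.m / self.s

    @property
    def ri(self) -> float:
        return 1.0 if self.g == self.m else (self.g - self.s) / (self.g - self.m)

    @property
    def homoplastic(self) -> bool:
        return self.s > self.m


# ---------------------------------------------------------------------------
# column summaries
# ---------------------------------------------------------------------------

def _observed(column: Iterable[int]) -> list[int]:
    return [int(s) for s in column if s != MISSING]


def min_steps(column: Iterable[int]) -> int:
    """Minimum conceivable steps: one fewer than the number of distinct
    observed states (zero for constant or all-missing columns)."""
    return max(0, len(set(_observed(column))) - 1)


def max_steps(column: Iterable[int]) -> int:
    """Star-tree worst case: observed leaves minus the modal state count."""
    obs = _observed(column)
    if not obs:
        return 0
    counts: dict[int, int] = {}
    for s in obs:
        counts[s] = counts.get(s, 0) + 1
    return len(obs) - max(counts.values())


def _column_masks(
    matrix: CharacterMatrix, char_index: int, keep: frozenset | None = None
) -> dict[str, int]:
    """Per-taxon state-set bitmasks for one character; '?' becomes the set of
    states observed among the kept taxa (or {0} when all are missing)."""
    pairs = [
        (t, s)
        for t, s in zip(matrix.taxa, matrix.column(char_index))
        if keep is None or t in keep
    ]
    observed_mask = 0
    for _, s in pairs:
        if s != MISSING:
            observed_mask |= 1 << int(s)
    if observed_mask == 0:
        observed_mask = 1
    return {t: (observed_mask if s == MISSING else 1 << int(s)) for t, s in pairs}


# ---------------------------------------------------------------------------
# rooted orientation helpers
# ---------------------------------------------------------------------------

def _orient(tree: Tree, root_label: str):
    """Root the unrooted tree at a leaf: returns (preorder node list,
    parent map, children map).  The root leaf has exactly one child."""
    root = tree.leaf_node(root_label)
    parent: dict[int, int | None] = {root: None}
    order: list[int] = [root]
    stack = [root]
    while stack:
        u = stack.pop()
        for v in tree.neighbors_of(u):
            if v != parent[u]:
                parent[v] = u
                order.append(v)
                stack.append(v)
    children: dict[int, list[int]] = {u: [] for u in order}
    for v, u in parent.items():
        if u is not None:
            children[u].append(v)
    return order, parent, children


def _check_tree_matrix(tree: Tree, matrix: CharacterMatrix) -> None:
    extra = tree.leaves - set(matrix.taxa)
    if extra:
        raise KeyError(f"tree leaves absent from matrix: {sorted(extra)}")
    if not tree.is_binary():
        raise TreeError("tree must be fully resolved (binary) for Fitch scoring")


# ---------------------------------------------------------------------------
# Fitch pass
# ---------------------------------------------------------------------------

def _fitch_steps(tree: Tree, masks: Mapping[str, int], root_label: str) -> int:
    """Steps of one character: bottom-up set intersection/union pass."""
    if tree.n_leaves < 2:
        return 0
    order, _, children = _orient(tree, root_label)
    value: dict[int, int] = {}
    steps = 0
    for node in reversed(order):
        kids = children[node]
        if not kids:
            value[node] = masks[tree.label_of(node)]
            continue
        acc = None
        for kid in kids:
            if acc is None:
                acc = value[kid]
                continue
            inter = acc & value[kid]
            if inter:
                acc = inter
            else:
                acc = acc | value[kid]
                steps += 1
        if tree.label_of(node) is not None:  # the root leaf itself
            inter = acc & masks[tree.label_of(node)]
            if not inter:
                steps += 1
        value[node] = acc
    return steps


def fitch_length(tree: Tree, matrix: CharacterMatrix) -> tuple[int, list[CharacterFit]]:
    """Total parsimony length of the matrix on the tree plus per-character
    fits.  The result does not depend on the traversal root."""
    _check_tree_matrix(tree, matrix)
    root_label = min(tree.leaves)
    keep = tree.leaves
    fits: list[CharacterFit] = []
    total = 0
    for j in range(1, matrix.n_chars + 1):
        column = [
            s for t, s in zip(matrix.taxa, matrix.column(j)) if t in keep
        ]
        masks = _column_masks(matrix, j, keep)
        s = _fitch_steps(tree, masks, root_label)
        fit = CharacterFit(j, s, min_steps(column), max_steps(column))
        fits.append(fit)
        total += s
    return total, fits


# ---------------------------------------------------------------------------
# brute-force oracle
# ---------------------------------------------------------------------------

def brute_force_length(tree: Tree, char_column: Mapping[str, int]) -> int:
    """Exact minimum changes by enumerating every assignment of single states
    to internal nodes (and to missing leaves).  Guard: at most 8 leaves.

    For unordered characters the optimum is always attained using only
    observed states, so the enumeration alphabet is the observed state set.
    """
    if tree.n_leaves > 8:
        raise ValueError("brute_force_length is limited to 8 leaves")
    observed = sorted({int(s) for s in char_column.values() if s != MISSING})
    if not observed or tree.n_leaves < 2:
        return 0
    fixed: dict[int, int] = {}
    free: list[int] = []
    for node in tree.nodes():
        label = tree.label_of(node)
        if label is None:
            free.append(node)
        else:
            state = char_column[label]
            if state == MISSING:
                free.append(node)
            else:
                fixed[node] = int(state)
    edges = tree.edges()
    best = _INF
    for combo in itertools.product(observed, repeat=len(free)):
        assign = dict(zip(free, combo))
        assign.update(fixed)
        cost = sum(1 for u, v in edges if assign[u] != assign[v])
        if cost < best:
            best = cost
    return best


# ---------------------------------------------------------------------------
# unit-cost DP over explicit states (reconstruction machinery)
# ---------------------------------------------------------------------------

def _dp_tables(tree: Tree, masks: Mapping[str, int], root_label: str):
    """Down/up dynamic program with unit substitution costs.

    Returns ``(s, D, Up, A, order, parent, children, n_states)`` where for
    node ``v`` with parent ``u``:

    * ``D[v][a]`` — min cost of the subtree below ``v`` given ``v`` has
      state ``a``;
    * ``A[v][a]`` — min cost of everything outside that subtree given the
      parent endpoint ``u`` has state ``a`` (edge (u, v) excluded);
    * ``Up[v][a]`` — like ``A`` but including the edge, conditioned on ``v``.
    """
    n_states = max(mask.bit_length() for mask in masks.values())
    states = range(n_states)
    order, parent, children = _orient(tree, root_label)

    def leaf_vec(label: str) -> list[int]:
        mask = masks[label]
        return [0 if mask >> a & 1 else _INF for a in states]

    D: dict[int, list[int]] = {}
    for node in reversed(order):
        kids = children[node]
        if not kids:
            D[node] = leaf_vec(tree.label_of(node))
            continue
        vec = [0] * n_states
        for kid in kids:
            kd = D[kid]
            base = min(kd)
            for a in states:
                vec[a] += min(kd[a], base + 1)
        if tree.label_of(node) is not None:  # root leaf with its single child
            lv = leaf_vec(tree.label_of(node))
            vec = [vec[a] + lv[a] for a in states]
        D[node] = vec

    root = order[0]
    s = min(D[root])

    A: dict[int, list[int]] = {}
    Up: dict[int, list[int]] = {}
    for node in order:
        kids = children[node]
        if node == root:
            lv = leaf_vec(tree.label_of(root))
            for kid in kids:
                A[kid] = lv
        else:
            for kid in kids:
                vec = list(Up[node])
                for sib in kids:
                    if sib is kid:
                        continue
                    sd = D[sib]
                    base = min(sd)
                    for a in range(n_states):
                        vec[a] += min(sd[a], base + 1)
                A[kid] = vec
        for kid in kids:
            av = A[kid]
            base = min(av)
            Up[kid] = [min(av[a], base + 1) for a in range(n_states)]
    return s, D, Up, A, order, parent, children, n_states


@dataclass(frozen=True)
class Change:
    """One state change placed on one branch of a rooted view; the clade is
    the leaf set on the derived (root-distal) side."""

    clade: frozenset
    from_states: frozenset
    to_states: frozenset


@dataclass
class Reconstruction:
    """A most-parsimonious reconstruction (or the ambiguity summary)."""

    char_index: int
    policy: str
    root_taxon: str
    states: dict  # frozenset[leaf labels below node] -> frozenset[int]
    changes: list  # list[Change]
    steps: int


def _clade_sets(tree: Tree, order, children) -> dict[int, frozenset]:
    below: dict[int, frozenset] = {}
    for node in reversed(order):
        kids = children[node]
        label = tree.label_of(node)
        if not kids:
            below[node] = frozenset([label])
        else:
            acc: frozenset = frozenset().union(*(below[k] for k in kids))
            if label is not None:
                acc = acc | {label}
            below[node] = acc
    return below


def ancestral_states(
    tree: Tree,
    matrix: CharacterMatrix,
    char_index: int,
    policy: str = "unambiguous",
    root_taxon: str | None = None,
) -> Reconstruction:
    """Most-parsimonious ancestral states for one character.

    ``acctran`` prefers placing a change as close to the display root as a
    tie permits, ``deltran`` defers changes toward the tips, and
    ``unambiguous`` reports, per node, the full set of states over all MP
    reconstructions (a singleton exactly when every reconstruction agrees)
    together with the changes common to all reconstructions.

    The node map is keyed by the leaf set below each node in the rooted
    view; the implied change count for acctran/deltran equals the Fitch
    step count of the character.
    """
    if policy not in ("acctran", "deltran", "unambiguous"):
        raise ValueError(f"unknown policy {policy!r}")
    _check_tree_matrix(tree, matrix)
    root_label = root_taxon if root_taxon is not None else min(tree.leaves)
    masks = _column_masks(matrix, char_index, tree.leaves)
    s, D, Up, A, order, parent, children, n_states = _dp_tables(tree, masks, root_label)
    below = _clade_sets(tree, order, children)
    root = order[0]

    states_map: dict[frozenset, frozenset] = {}
    changes: list[Change] = []

    if policy == "unambiguous":
        states_map[below[root]] = frozenset(
            a for a in range(n_states) if D[root][a] == s
        )
        for node in order:
            if node == root:
                continue
            mpr = frozenset(
                a for a in range(n_states) if D[node][a] + Up[node][a] == s
            )
            states_map[below[node]] = mpr
            # change forced on this edge iff no reconstruction keeps the two
            # endpoint states equal
            forced = all(A[node][a] + D[node][a] > s for a in range(n_states))
            if forced:
                parent_states = frozenset(
                    a
                    for a in range(n_states)
                    if any(
                        A[node][a] + 1 + D[node][b] == s
                        for b in range(n_states)
                        if b != a
                    )
                )
                changes.append(Change(below[node], parent_states, mpr))
        return Reconstruction(char_index, policy, root_label, states_map, changes, s)

    assign: dict[int, int] = {}
    root_choices = [a for a in range(n_states) if D[root][a] == s]
    mask_root = masks[root_label]
    pref = [a for a in root_choices if mask_root >> a & 1]
    assign[root] = min(pref or root_choices)
    for node in order:
        if node == root:
            continue
        pa = assign[parent[node]]
        costs = [D[node][a] + (1 if a != pa else 0) for a in range(n_states)]
        best = min(costs)
        cands = [a for a in range(n_states) if costs[a] == best]
        if policy == "acctran":
            moved = [a for a in cands if a != pa]
            choice = min(moved) if moved else pa
        else:  # deltran
            choice = pa if pa in cands else min(cands)
        assign[node] = choice
        if choice != pa:
            changes.append(
                Change(below[node], frozenset([pa]), frozenset([choice]))
            )
    for node in order:
        states_map[below[node]] = frozenset([assign[node]])
    return Reconstruction(char_index, policy, root_label, states_map, changes, s)
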