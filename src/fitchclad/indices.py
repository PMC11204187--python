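"""Ensemble fit indices, homoplasy flags, synapomorphy mapping, consensus.

The ensemble consistency index CI = Σm/Σs and retention index
RI = (Σg−Σs)/(Σg−Σm) summarise how much homoplasy a tree imposes on a
matrix: CI is 1 exactly when every character fits without extra steps, RI
is 1 when all potential synapomorphy is retained.  By default every
character participates in the sums (constant and autapomorphic ones
included); ``informative_only`` restricts the sums to
parsimony-informative characters, a convention some programs use.

Rounding to the two decimals seen in publications happens only in the
report helpers (:func:`round2`); the dataclass keeps exact floats.
"""

from __future__ import annotations

import csv
import io
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from .fitch import (
    CharacterFit,
    _clade_sets,
    _column_masks,
    _dp_tables,
    ancestral_states,
    fitch_length,
)
from .matrix_io import MISSING, CharacterMatrix
from .tree import Bipartition, Tree, TreeError

__all__ = [
    "EnsembleFit",
    "ensemble_indices",
    "homoplasy_flags",
    "synapomorphies",
    "strict_consensus",
    "majority_rule",
    "round2",
    "fit_table_csv",
    "is_informative",
]


def round2(x: float) -> float:
    """Half-up rounding to two decimals (report convention)."""
    return math.floor(x * 100 + 0.5) / 100


def is_informative(column: Iterable[int]) -> bool:
    """Parsimony-informative: at least two states each seen in two or more
    scored taxa."""
    counts: dict[int, int] = {}
    for s in column:
        if s != MISSING:
            counts[int(s)] = counts.get(int(s), 0) + 1
    return sum(1 for c in counts.values() if c >= 2) >= 2


@dataclass(frozen=True)
class EnsembleFit:
    """Tree length plus ensemble and per-character fit indices."""

    L: int
    CI: float
    RI: float
    per_char: tuple
    informative_only: bool = False
    warning: str | None = None

    @property
    def CI_rounded(self) -> float:
        return round2(self.CI)

    @property
    def RI_rounded(self) -> float:
        return round2(self.RI)


def ensemble_indices(
    tree: Tree, matrix: CharacterMatrix, informative_only: bool = False
) -> EnsembleFit:
    """Ensemble CI and RI of the matrix on a binary tree.

    ``informative_only`` drops parsimony-uninformative characters from the
    index sums (the total length L always counts every character).
    """
    total, fits = fitch_length(tree, matrix)
    keep = tree.leaves
    if informative_only:
        used = [
            fit
            for fit, j in zip(fits, range(1, matrix.n_chars + 1))
            if is_informative(
                s for t, s in zip(matrix.taxa, matrix.column(j)) if t in keep
            )
        ]
    else:
        used = list(fits)
    sum_m = sum(f.m for f in used)
    sum_s = sum(f.s for f in used)
    sum_g = sum(f.g for f in used)
    warning = None
    if sum_s == 0:
        ci = 1.0
        warning = "no variation: every scored character is constant"
    else:
        ci = sum_m / sum_s
    ri = 1.0 if sum_g == sum_m else (sum_g - sum_s) / (sum_g - sum_m)
    return EnsembleFit(total, ci, ri, tuple(fits), informative_only, warning)


def homoplasy_flags(tree: Tree, matrix: CharacterMatrix) -> list[bool]:
    """Per-character flag: True when the character needs extra steps on this
    tree (s > m, i.e. per-character ci < 1)."""
    _, fits = fitch_length(tree, matrix)
    return [f.homoplastic for f in fits]


def fit_table_csv(fits: Sequence[CharacterFit]) -> str:
    out = io.StringIO()
    writer = csv.writer(out, lineterminator="\n")
    writer.writerow(["char", "m", "s", "g", "ci", "ri", "homoplastic"])
    for f in fits:
        writer.writerow(
            [f.char_index, f.m, f.s, f.g, f"{f.ci:.4f}", f"{f.ri:.4f}", int(f.homoplastic)]
        )
    return out.getvalue()


# ---------------------------------------------------------------------------
# synapomorphy mapping
# ---------------------------------------------------------------------------

def synapomorphies(
    tree: Tree,
    matrix: CharacterMatrix,
    branch,
    policy: str = "any",
    root_taxon: str | None = None,
) -> list[tuple[int, int]]:
    """Characters changing on a branch, with the derived state.

    ``branch`` is the clade side of a bipartition of the tree (an iterable
    of leaf labels or a :class:`Bipartition`); the display root
    (``root_taxon``, default: smallest label outside the clade) must lie
    outside it, so "derived" is well defined.  ``policy='any'`` lists a
    change when at least one most-parsimonious reconstruction places it on
    the branch; ``acctran``/``deltran`` query that specific reconstruction.
    """
    if policy not in ("any", "acctran", "deltran"):
        raise ValueError(f"unknown policy {policy!r}")
    leaves = tree.leaves
    if isinstance(branch, Bipartition):
        clade = set(branch.side)
        candidates = (clade, set(branch.other_side))
    else:
        clade = set(branch)
        candidates = (clade,)
    if root_taxon is None:
        outside = leaves - clade
        if not outside:
            raise TreeError("branch covers the whole leaf set")
        root_taxon = min(outside)
    clade = next((c for c in candidates if root_taxon not in c), None)
    if clade is None:
        raise TreeError("display root lies inside the queried clade")
    bp_sides = {frozenset(bp.side) for bp in tree.bipartitions()} | {
        frozenset(bp.other_side) for bp in tree.bipartitions()
    }
    clade_fs = frozenset(clade)
    if clade_fs not in bp_sides:
        raise KeyError(f"branch {sorted(clade)} not present in tree")

    out: list[tuple[int, int]] = []
    for j in range(1, matrix.n_chars + 1):
        if policy in ("acctran", "deltran"):
            rec = ancestral_states(tree, matrix, j, policy, root_taxon)
            for change in rec.changes:
                if change.clade == clade_fs:
                    (derived,) = change.to_states
                    out.append((j, derived))
        else:
            masks = _column_masks(matrix, j, leaves)
            s, D, Up, A, order, parent, children, n_states = _dp_tables(
                tree, masks, root_taxon
            )
            below = _clade_sets(tree, order, children)
            node = next(v for v in order if below[v] == clade_fs)
            for d in range(n_states):
                if any(
                    A[node][a] + 1 + D[node][d] == s
                    for a in range(n_states)
                    if a != d
                ):
                    out.append((j, d))
    return out


# ---------------------------------------------------------------------------
# consensus
# ---------------------------------------------------------------------------

def _common_leafset(trees: Sequence[Tree]) -> frozenset:
    if not trees:
        raise ValueError("consensus of an empty tree set")
    leafset = trees[0].leaves
    for t in trees[1:]:
        if t.leaves != leafset:
            raise TreeError("consensus requires identical leaf sets")
    return leafset


def strict_consensus(trees: Sequence[Tree]) -> Tree:
    """The tree whose internal bipartitions are exactly those shared by all
    input trees."""
    trees = list(trees)
    leafset = _common_leafset(trees)
    shared = set(bp.side for bp in trees[0].bipartitions())
    for t in trees[1:]:
        shared &= {bp.side for bp in t.bipartitions()}
    return Tree.from_clusters(leafset, shared)


def majority_rule(trees: Sequence[Tree], threshold: float = 0.5001) -> Tree:
    """Bipartitions occurring in at least ``threshold`` of the trees
    (threshold in (0.5, 1]; above one half guarantees compatibility), each
    annotated with its frequency.  Threshold 1.0 is the strict consensus."""
    if not 0.5 < threshold <= 1.0:
        raise ValueError("threshold must be in (0.5, 1]")
    trees = list(trees)
    leafset = _common_leafset(trees)
    counts: dict[frozenset, int] = {}
    for t in trees:
        for bp in t.bipartitions():
            counts[bp.side] = counts.get(bp.side, 0) + 1
    n = len(trees)
    needed = threshold * n - 1e-9
    kept = {side for side, c in counts.items() if c >= needed}
    tree = Tree.from_clusters(leafset, kept)
    tree.support.update(
        {
            Bipartition(side, leafset): counts[side] / n
            for side in kept
        }
    )
    return tree
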