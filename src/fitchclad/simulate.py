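"""Synthetic discrete-character matrices on known trees.

Every pipeline stage of the package is testable offline because test
matrices are generated, not downloaded.  The generator emulates the shape
of a desk-scale morphological study — around a dozen taxa, a few dozen
unordered characters with two to four states, sparse missing cells — by a
simple Mk-flavored process: a uniform root state per character, a constant
per-branch probability of switching to a different uniform state, and
independent missing-data masking of leaf cells.  Branch lengths are not
modeled; parsimony, the only consumer, never sees them.

:func:`perfect_matrix` is the homoplasy-free construction (one binary
character per internal edge), for which the generating tree is provably the
unique most parsimonious tree.
"""

from __future__ import annotations

import json
import random
from dataclasses import asdict, dataclass

import numpy as np

from .matrix_io import MISSING, CharacterMatrix, write_matrix
from .tree import Tree

__all__ = ["SimConfig", "SimResult", "random_tree", "simulate_matrix", "perfect_matrix"]


@dataclass(frozen=True)
class SimConfig:
    """Generator settings.

    Defaults mirror the bundled study's data shape: 13 taxa, 24 characters
    with up to four states, a per-branch change probability giving roughly
    1.8 expected changes per character across the tree (the bundled matrix
    averages 42/24 = 1.75 steps), and ~10% missing cells (the bundled
    matrix has 36/312 = 11.5%).
    """

    seed: int
    n_taxa: int = 13
    n_chars: int = 24
    n_states: int = 4
    change_prob: float = 0.08
    missing_frac: float = 0.10

    def __post_init__(self):
        if self.n_taxa < 3:
            raise ValueError("n_taxa must be >= 3")
        if self.n_chars < 1:
            raise ValueError("n_chars must be >= 1")
        if not 2 <= self.n_states <= 4:
            raise ValueError("n_states must be between 2 and 4")
        if not 0 <= self.change_prob < 1:
            raise ValueError("change_prob must be in [0, 1)")
        if not 0 <= self.missing_frac < 1:
            raise ValueError("missing_frac must be in [0, 1)")


@dataclass(frozen=True)
class SimResult:
    """A simulated matrix together with its generating tree and settings."""

    matrix: CharacterMatrix
    true_tree: Tree
    config: SimConfig

    def sidecar(self) -> dict:
        return {"config": asdict(self.config), "true_tree": self.true_tree.newick()}

    def emit(self, directory) -> None:
        """Write NEXUS matrix, Newick true tree, and JSON sidecar."""
        from pathlib import Path

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        (directory / "matrix.nex").write_text(write_matrix(self.matrix, "nexus"))
        (directory / "true_tree.nwk").write_text(self.true_tree.newick() + "\n")
        (directory / "sim.json").write_text(json.dumps(self.sidecar(), indent=2) + "\n")


def _default_labels(n: int) -> list[str]:
    width = len(str(n))
    return [f"t{str(i + 1).zfill(width)}" for i in range(n)]


def random_tree(n_taxa: int, seed: int, labels: list[str] | None = None) -> Tree:
    """Uniform random unrooted binary topology by sequential attachment of
    each new leaf to an edge chosen uniformly at random."""
    if n_taxa < 3:
        raise ValueError("a tree needs at least 3 taxa")
    labels = labels if labels is not None else _default_labels(n_taxa)
    if len(labels) != n_taxa:
        raise ValueError("label count does not match n_taxa")
    rng = random.Random(seed)
    n = n_taxa
    adj: dict[int, list[int]] = {0: [n], 1: [n], 2: [n], n: [0, 1, 2]}
    next_id = n + 1
    for leaf in range(3, n):
        edges = sorted((u, v) for u in adj for v in adj[u] if u < v)
        u, v = rng.choice(edges)
        adj[u].remove(v)
        adj[v].remove(u)
        adj[next_id] = [u, v, leaf]
        adj[u].append(next_id)
        adj[v].append(next_id)
        adj[leaf] = [next_id]
        next_id += 1
    return Tree(adj, dict(enumerate(labels)))


def simulate_matrix(tree: Tree, config: SimConfig) -> SimResult:
    """Evolve ``config.n_chars`` unordered characters down the tree.

    Per character: uniform root state; each branch switches to a different
    uniformly chosen state with probability ``change_prob``; finally each
    leaf cell is masked missing with probability ``missing_frac``.
    Deterministic per seed.
    """
    if not tree.is_binary():
        raise ValueError("simulation requires a binary tree")
    rng = np.random.default_rng(config.seed)
    taxa = sorted(tree.leaves)
    root = tree.leaf_node(taxa[0])
    # preorder traversal from the root leaf
    parent: dict[int, int | None] = {root: None}
    order = [root]
    stack = [root]
    while stack:
        u = stack.pop()
        for v in tree.neighbors_of(u):
            if v != parent[u]:
                parent[v] = u
                order.append(v)
                stack.append(v)
    k = config.n_states
    cells = np.empty((len(taxa), config.n_chars), dtype=np.int8)
    index = {lab: i for i, lab in enumerate(taxa)}
    for j in range(config.n_chars):
        state: dict[int, int] = {root: int(rng.integers(k))}
        for node in order[1:]:
            s = state[parent[node]]
            if rng.random() < config.change_prob:
                s = int((s + 1 + rng.integers(k - 1)) % k)
            state[node] = s
        for node in order:
            lab = tree.label_of(node)
            if lab is not None:
                cells[index[lab], j] = state[node]
    if config.missing_frac > 0:
        mask = rng.random(cells.shape) < config.missing_frac
        cells[mask] = MISSING
    matrix = CharacterMatrix(taxa, cells)
    return SimResult(matrix, tree, config)


def perfect_matrix(tree: Tree) -> CharacterMatrix:
    """One binary character per internal edge, homoplasy-free by
    construction: state 1 exactly on the canonical side of that edge.  The
    generating tree is the unique most parsimonious tree (every character
    fits with a single step, and only this topology fits all of them)."""
    if not tree.is_binary():
        raise ValueError("perfect_matrix requires a binary tree")
    if tree.n_leaves < 4:
        raise ValueError("perfect_matrix needs at least 4 leaves (an internal edge)")
    taxa = sorted(tree.leaves)
    splits = sorted(tree.bipartitions(), key=lambda bp: sorted(bp.side))
    cells = np.zeros((len(taxa), len(splits)), dtype=np.int8)
    for j, bp in enumerate(splits):
        for lab in bp.side:
            cells[taxa.index(lab), j] = 1
    return CharacterMatrix(taxa, cells)
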