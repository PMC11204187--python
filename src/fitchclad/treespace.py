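"""Tree-space enumeration, rearrangement, and parsimony search.

Three search layers, each exact about what it guarantees:

* :func:`enumerate_topologies` — every unrooted binary topology, for small
  leaf counts ((2n-5)!! growth);
* :func:`branch_and_bound` — the exact optimum and *all* optimal binary
  topologies, by depth-first taxon addition with an admissible bound;
* :func:`heuristic_search` — random-addition starting trees refined by
  NNI/SPR/TBR hill climbing, the strategy used by the parsimony programs
  this package mirrors (multiple TBR-refined replicates, then a TBR sweep
  over the pooled best trees).

Scoring in the hot loops packs all characters of a matrix into a single
arbitrary-precision integer, one ``w``-bit field per character, so a Fitch
bottom-up pass costs a handful of bitwise operations per internal node
regardless of character count.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Callable, Iterator

from .fitch import _clade_sets, _column_masks, _dp_tables
from .matrix_io import CharacterMatrix, MISSING
from .tree import Bipartition, Tree, TreeError

__all__ = [
    "SearchConfig",
    "MPTSet",
    "enumerate_topologies",
    "neighbors",
    "branch_and_bound",
    "heuristic_search",
    "collapse_min_length_zero",
]

_INF = 10**9


@dataclass(frozen=True)
class SearchConfig:
    """Settings for the heuristic search.

    The replicate default is desk-scale (the 13-taxon landscape of the
    bundled study converges in a handful of replicates); the published
    settings (1000 replicates, 10,000 trees) remain reachable by passing
    them explicitly.
    """

    seed: int
    n_replicates: int = 20
    max_trees: int = 10_000
    move: str = "tbr"
    steepest: bool = True
    final_pass: bool = True

    def __post_init__(self):
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.max_trees < 1:
            raise ValueError("max_trees must be >= 1")
        if self.move not in ("nni", "spr", "tbr"):
            raise ValueError(f"unknown move {self.move!r}")


@dataclass(frozen=True)
class MPTSet:
    """Equally optimal trees plus their shared score."""

    score: int
    trees: tuple
    exact: bool
    capped: bool = False

    def __post_init__(self):
        if len({t.canonical_key() for t in self.trees}) != len(self.trees):
            raise ValueError("duplicate topologies in MPT set")

    def newick(self) -> str:
        return "\n".join(t.newick() for t in self.trees) + "\n"

    def sidecar(self, config: SearchConfig | None = None) -> dict:
        out = {
            "score": self.score,
            "n_trees": len(self.trees),
            "exact": self.exact,
            "capped": self.capped,
        }
        if config is not None:
            out["config"] = {
                "seed": config.seed,
                "n_replicates": config.n_replicates,
                "max_trees": config.max_trees,
                "move": config.move,
                "steepest": config.steepest,
                "final_pass": config.final_pass,
            }
        return out


# ---------------------------------------------------------------------------
# packed Fitch scoring
# ---------------------------------------------------------------------------

class _Packed:
    """All characters of a matrix packed into one integer per taxon."""

    def __init__(self, matrix: CharacterMatrix):
        self.taxa = list(matrix.taxa)
        self.n = matrix.n_taxa
        w = max(1, int(matrix.cells.max(initial=0)) + 1)
        self.w = w
        nchars = matrix.n_chars
        low = (1 << (w - 1)) - 1
        high = 1 << (w - 1)
        self.low_mask = sum(low << (j * w) for j in range(nchars))
        self.high_mask = sum(high << (j * w) for j in range(nchars))
        self.field = (1 << w) - 1
        codes = [0] * self.n
        for j in range(1, nchars + 1):
            masks = _column_masks(matrix, j)
            shift = (j - 1) * w
            for i, taxon in enumerate(self.taxa):
                codes[i] |= masks[taxon] << shift
        self.codes = codes

    def score(self, adj: dict, cutoff: int = _INF) -> int:
        """Fitch length of the (possibly partial) binary tree ``adj``;
        returns ``cutoff`` as soon as the running count reaches it."""
        root = min(u for u in adj if u < self.n)
        parent = {root: -1}
        order = [root]
        children: dict[int, list[int]] = {root: []}
        stack = [root]
        while stack:
            u = stack.pop()
            for v in adj[u]:
                if v != parent[u]:
                    parent[v] = u
                    children[v] = []
                    children[u].append(v)
                    order.append(v)
                    stack.append(v)
        codes = self.codes
        w1 = self.w - 1
        low, high, ff = self.low_mask, self.high_mask, self.field
        value: dict[int, int] = {}
        steps = 0
        for u in reversed(order):
            kids = children[u]
            if not kids:
                value[u] = codes[u]
                continue
            acc = value[kids[0]]
            for kid in kids[1:]:
                b = value[kid]
                inter = acc & b
                zeros = ((((inter & low) + low) | inter) & high) ^ high
                if zeros:
                    steps += zeros.bit_count()
                    acc = inter | ((acc | b) & ((zeros >> w1) * ff))
                else:
                    acc = inter
            if u < self.n:  # root leaf closes the unrooted pass
                inter = acc & codes[u]
                zeros = ((((inter & low) + low) | inter) & high) ^ high
                steps += zeros.bit_count()
            if steps >= cutoff:
                return cutoff
            value[u] = acc
        return steps


# ---------------------------------------------------------------------------
# adjacency helpers (leaves are 0..n-1, internal ids >= n)
# ---------------------------------------------------------------------------

def _edges(adj: dict) -> list[tuple[int, int]]:
    return sorted((u, v) for u in adj for v in adj[u] if u < v)


def _insert_leaf(adj: dict, leaf: int, u: int, v: int, new_id: int) -> None:
    adj[u].remove(v)
    adj[v].remove(u)
    adj[new_id] = [u, v, leaf]
    adj[u].append(new_id)
    adj[v].append(new_id)
    adj[leaf] = [new_id]


def _remove_leaf(adj: dict, leaf: int, new_id: int, u: int, v: int) -> None:
    del adj[leaf]
    del adj[new_id]
    adj[u].remove(new_id)
    adj[v].remove(new_id)
    adj[u].append(v)
    adj[v].append(u)


def _adj_key(adj: dict, n_leaves: int) -> frozenset:
    """Canonical topology key: bitmasks (over leaf ids) of the side of each
    internal edge not containing the smallest leaf."""
    root = min(u for u in adj if isinstance(u, int) and len(adj[u]) == 1)
    parent = {root: -1}
    order = [root]
    stack = [root]
    while stack:
        u = stack.pop()
        for v in adj[u]:
            if v != parent[u]:
                parent[v] = u
                order.append(v)
                stack.append(v)
    below: dict[int, int] = {}
    for u in reversed(order):
        mask = 1 << u if len(adj[u]) == 1 and u != root else 0
        for v in adj[u]:
            if parent.get(v) == u:
                mask |= below[v]
        below[u] = mask
    masks = []
    for u in order[1:]:
        m = below[u]
        k = m.bit_count()
        if 1 < k < n_leaves - 1:
            masks.append(m)
    return frozenset(masks)


def _adj_to_tree(adj: dict, labels: dict[int, str]) -> Tree:
    return Tree(adj, {u: labels[u] for u in adj if u in labels})


def _tree_to_adj(tree: Tree) -> tuple[dict, dict[int, str]]:
    """Relabel a Tree onto the search convention: leaves 0..n-1 in sorted
    label order, internal ids from n."""
    labels = sorted(tree.leaves)
    index = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    mapping: dict[int, int] = {}
    nxt = n
    for node in tree.nodes():
        lab = tree.label_of(node)
        if lab is not None:
            mapping[node] = index[lab]
        else:
            mapping[node] = nxt
            nxt += 1
    adj = {
        mapping[u]: [mapping[v] for v in tree.neighbors_of(u)] for u in tree.nodes()
    }
    return adj, dict(enumerate(labels))


def _component(adj: dict, start: int, blocked: int) -> set[int]:
    """Nodes reachable from ``start`` with edge {start, blocked} removed."""
    seen = {start}
    stack = [start]
    while stack:
        u = stack.pop()
        for v in adj[u]:
            if u == start and v == blocked:
                continue
            if v not in seen:
                seen.add(v)
                stack.append(v)
    return seen


def _bisect_side(adj: dict, x: int, y: int):
    """Component containing ``x`` after removing edge {x, y}: returns
    (sub-adjacency, junction id, reattachment edges or None for a bare leaf).
    Internal endpoints of the cut are suppressed; the junction id is reused
    when the side is reattached."""
    nodes = _component(adj, x, y)
    if len(nodes) == 1:
        return {x: []}, x, None
    sub = {
        u: [v for v in adj[u] if v in nodes and not (u == x and v == y)]
        for u in nodes
    }
    p, q = sub[x]
    sub[p] = [w for w in sub[p] if w != x] + [q]
    sub[q] = [w for w in sub[q] if w != x] + [p]
    del sub[x]
    return sub, x, _edges(sub)


def _reattach(new: dict, junction: int, edge: tuple[int, int] | None) -> None:
    if edge is None:
        new[junction] = []
        return
    a, b = edge
    new[a] = [w for w in new[a] if w != b]
    new[b] = [w for w in new[b] if w != a]
    new[junction] = [a, b]
    new[a].append(junction)
    new[b].append(junction)


def _tbr_moves(adj: dict) -> Iterator[dict]:
    for x, y in _edges(adj):
        subA, jA, edgesA = _bisect_side(adj, x, y)
        subB, jB, edgesB = _bisect_side(adj, y, x)
        if edgesA is None and edgesB is None:
            continue
        for ea in edgesA or [None]:
            for eb in edgesB or [None]:
                new = {u: list(vs) for u, vs in subA.items()}
                new.update({u: list(vs) for u, vs in subB.items()})
                _reattach(new, jA, ea)
                _reattach(new, jB, eb)
                new[jA].append(jB)
                new[jB].append(jA)
                yield new


def _spr_moves(adj: dict) -> Iterator[dict]:
    for p in sorted(adj):
        if len(adj[p]) != 3:
            continue
        for s in sorted(adj[p]):
            prune = _component(adj, s, p)
            sub, _, regraft_edges = _bisect_side(adj, p, s)
            if regraft_edges is None:
                continue
            pruned = {
                u: [v for v in adj[u] if v in prune and not (u == s and v == p)]
                for u in prune
            }
            for a, b in regraft_edges:
                new = {u: list(vs) for u, vs in sub.items()}
                new.update({u: list(vs) for u, vs in pruned.items()})
                _reattach(new, p, (a, b))
                new[p].append(s)
                new[s].append(p)
                yield new


def _nni_moves(adj: dict) -> Iterator[dict]:
    for u, v in _edges(adj):
        if len(adj[u]) != 3 or len(adj[v]) != 3:
            continue
        a, b = [w for w in adj[u] if w != v]
        for c in [w for w in adj[v] if w != u]:
            new = {w: list(vs) for w, vs in adj.items()}
            new[u] = [w if w != b else c for w in new[u]]
            new[v] = [w if w != c else b for w in new[v]]
            new[b] = [w if w != u else v for w in new[b]]
            new[c] = [w if w != v else u for w in new[c]]
            yield new


_MOVES: dict[str, Callable[[dict], Iterator[dict]]] = {
    "nni": _nni_moves,
    "spr": _spr_moves,
    "tbr": _tbr_moves,
}


# ---------------------------------------------------------------------------
# enumeration
# ---------------------------------------------------------------------------

def enumerate_topologies(taxa: list[str]) -> Iterator[Tree]:
    """Yield every unrooted binary topology on the given labels exactly once
    (sequential leaf insertion; (2n-5)!! trees).  Guard: 3 <= n <= 10."""
    n = len(taxa)
    if not 3 <= n <= 10:
        raise ValueError("enumerate_topologies supports 3..10 taxa")
    if len(set(taxa)) != n:
        raise ValueError("duplicate taxon labels")
    labels = dict(enumerate(taxa))
    adj: dict[int, list[int]] = {0: [n], 1: [n], 2: [n], n: [0, 1, 2]}

    def rec(k: int, next_id: int) -> Iterator[Tree]:
        if k == n:
            yield _adj_to_tree({u: list(vs) for u, vs in adj.items()}, labels)
            return
        for u, v in _edges(adj):
            _insert_leaf(adj, k, u, v, next_id)
            yield from rec(k + 1, next_id + 1)
            _remove_leaf(adj, k, next_id, u, v)

    yield from rec(3, n + 1)


def neighbors(tree: Tree, move: str) -> Iterator[Tree]:
    """Distinct topologies one rearrangement away (the input itself is
    excluded).  NNI yields 2(n-3) trees; NNI ⊆ SPR ⊆ TBR."""
    if move not in _MOVES:
        raise ValueError(f"unknown move {move!r}")
    if not tree.is_binary():
        raise TreeError("rearrangements require a binary tree")
    if tree.n_leaves < 4:
        return
    adj, labels = _tree_to_adj(tree)
    n = len(labels)
    seen = {_adj_key(adj, n)}
    for cand in _MOVES[move](adj):
        key = _adj_key(cand, n)
        if key not in seen:
            seen.add(key)
            yield _adj_to_tree(cand, labels)


# ---------------------------------------------------------------------------
# exact search
# ---------------------------------------------------------------------------

def _addition_order(matrix: CharacterMatrix) -> list[int]:
    """Max-divergence taxon addition order: seed with the most distant pair
    (Hamming over shared scored cells), then maximin selection."""
    n = matrix.n_taxa
    cells = matrix.cells
    dist = [[0] * n for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            shared = (cells[i] != MISSING) & (cells[j] != MISSING)
            d = int(((cells[i] != cells[j]) & shared).sum())
            dist[i][j] = dist[j][i] = d
    best_pair = max(
        ((i, j) for i in range(n) for j in range(i + 1, n)),
        key=lambda p: (dist[p[0]][p[1]], -p[0], -p[1]),
    )
    chosen = list(best_pair)
    rest = [i for i in range(n) if i not in chosen]
    while rest:
        nxt = max(
            rest,
            key=lambda i: (
                min(dist[i][c] for c in chosen),
                sum(dist[i][c] for c in chosen),
                -i,
            ),
        )
        chosen.append(nxt)
        rest.remove(nxt)
    return chosen


def _future_bounds(matrix: CharacterMatrix, order: list[int]) -> list[int]:
    """future[k] = states present only among taxa not yet added after the
    first k of ``order`` — an admissible addition to any partial score."""
    n = matrix.n_taxa
    cols = [matrix.column(j) for j in range(1, matrix.n_chars + 1)]
    future = [0] * (n + 1)
    for k in range(n + 1):
        placed = set(order[:k])
        total = 0
        for col in cols:
            seen = {int(col[i]) for i in placed if col[i] != MISSING}
            ahead = {int(col[i]) for i in order[k:] if col[i] != MISSING}
            total += len(ahead - seen)
        future[k] = total
    return future


def _trivial_mpts(matrix: CharacterMatrix, exact: bool) -> MPTSet:
    labels = dict(enumerate(matrix.taxa))
    n = matrix.n_taxa
    if n == 1:
        tree = Tree({0: []}, labels)
        return MPTSet(0, (tree,), exact)
    if n == 2:
        tree = Tree({0: [1], 1: [0]}, labels)
    else:
        tree = Tree({0: [3], 1: [3], 2: [3], 3: [0, 1, 2]}, labels)
    eng = _Packed(matrix)
    adj, _ = _tree_to_adj(tree)
    return MPTSet(eng.score(adj), (tree,), exact)


def branch_and_bound(matrix: CharacterMatrix, max_trees: int = 10_000) -> MPTSet:
    """Exact optimum and all optimal binary topologies.

    Depth-first taxon addition in max-divergence order; a partial tree is
    abandoned when its score plus the future-state bound exceeds the best
    complete score seen (initialised from a greedy addition tree).
    Practical guard: 16 taxa.
    """
    n = matrix.n_taxa
    if n > 16:
        raise ValueError(
            "branch_and_bound is limited to 16 taxa; use heuristic_search"
        )
    if n < 4:
        return _trivial_mpts(matrix, exact=True)
    eng = _Packed(matrix)
    order = _addition_order(matrix)
    future = _future_bounds(matrix, order)
    labels = dict(enumerate(matrix.taxa))

    a, b, c = order[:3]
    base = {a: [n], b: [n], c: [n], n: [a, b, c]}

    # greedy addition tree -> initial upper bound
    adj = {u: list(vs) for u, vs in base.items()}
    next_id = n + 1
    for k in range(3, n):
        leaf = order[k]
        best_edge, best_s = None, _INF
        for u, v in _edges(adj):
            _insert_leaf(adj, leaf, u, v, next_id)
            s = eng.score(adj, cutoff=best_s)
            _remove_leaf(adj, leaf, next_id, u, v)
            if s < best_s:
                best_edge, best_s = (u, v), s
        _insert_leaf(adj, leaf, *best_edge, next_id)
        next_id += 1
    best = eng.score(adj)

    found: list[dict] = []
    capped = False
    adj = {u: list(vs) for u, vs in base.items()}

    def dfs(k: int, next_id: int) -> None:
        nonlocal best, found, capped
        leaf = order[k]
        for u, v in _edges(adj):
            _insert_leaf(adj, leaf, u, v, next_id)
            s = eng.score(adj, cutoff=best + 1 - future[k + 1])
            if s + future[k + 1] <= best:
                if k == n - 1:
                    if s < best:
                        best = s
                        found = []
                        capped = False
                    if len(found) < max_trees:
                        found.append({w: list(vs) for w, vs in adj.items()})
                    else:
                        capped = True
                else:
                    dfs(k + 1, next_id + 1)
            _remove_leaf(adj, leaf, next_id, u, v)

    dfs(3, n + 1)
    found.sort(key=lambda ad: tuple(sorted(_adj_key(ad, n))))
    trees = tuple(_adj_to_tree(ad, labels) for ad in found)
    return MPTSet(best, trees, exact=True, capped=capped)


# ---------------------------------------------------------------------------
# heuristic search
# ---------------------------------------------------------------------------

def _random_addition(eng: _Packed, rng: random.Random) -> dict:
    n = eng.n
    perm = rng.sample(range(n), n)
    adj: dict[int, list[int]] = {
        perm[0]: [n],
        perm[1]: [n],
        perm[2]: [n],
        n: [perm[0], perm[1], perm[2]],
    }
    next_id = n + 1
    for k in range(3, n):
        leaf = perm[k]
        best_s, ties = _INF, []
        for u, v in _edges(adj):
            _insert_leaf(adj, leaf, u, v, next_id)
            s = eng.score(adj, cutoff=best_s + 1)
            _remove_leaf(adj, leaf, next_id, u, v)
            if s < best_s:
                best_s, ties = s, [(u, v)]
            elif s == best_s:
                ties.append((u, v))
        _insert_leaf(adj, leaf, *rng.choice(ties), next_id)
        next_id += 1
    return adj


def heuristic_search(matrix: CharacterMatrix, config: SearchConfig) -> MPTSet:
    """Random-addition + hill-climbing search; deterministic per (matrix,
    config).  The returned score never beats (only possibly misses) the
    branch-and-bound optimum."""
    n = matrix.n_taxa
    if n < 4:
        return _trivial_mpts(matrix, exact=False)
    eng = _Packed(matrix)
    labels = dict(enumerate(matrix.taxa))
    rng = random.Random(config.seed)
    move_fn = _MOVES[config.move]
    best = _INF
    pool: dict[frozenset, dict] = {}
    capped = False

    for _ in range(config.n_replicates):
        adj = _random_addition(eng, rng)
        score = eng.score(adj)
        improved = True
        while improved:
            improved = False
            if config.steepest:
                cand_best, cand_adj = score, None
                for cand in move_fn(adj):
                    s = eng.score(cand, cutoff=cand_best)
                    if s < cand_best:
                        cand_best, cand_adj = s, cand
                if cand_adj is not None:
                    adj, score = cand_adj, cand_best
                    improved = True
            else:
                for cand in move_fn(adj):
                    s = eng.score(cand, cutoff=score)
                    if s < score:
                        adj, score = cand, s
                        improved = True
                        break
        if score < best:
            best = score
            pool = {}
            capped = False
        if score == best:
            key = _adj_key(adj, n)
            if key not in pool:
                if len(pool) < config.max_trees:
                    pool[key] = adj
                else:
                    capped = True

    if config.final_pass:
        queue = list(pool.values())
        while queue:
            current = queue.pop()
            for cand in move_fn(current):
                if eng.score(cand, cutoff=best + 1) != best:
                    continue
                key = _adj_key(cand, n)
                if key in pool:
                    continue
                if len(pool) >= config.max_trees:
                    capped = True
                    queue = []
                    break
                pool[key] = cand
                queue.append(cand)

    items = sorted(pool.items(), key=lambda kv: tuple(sorted(kv[0])))
    trees = tuple(_adj_to_tree(ad, labels) for _, ad in items)
    return MPTSet(best, trees, exact=False, capped=capped)


# ---------------------------------------------------------------------------
# collapsing
# ---------------------------------------------------------------------------

def collapse_min_length_zero(tree: Tree, matrix: CharacterMatrix) -> Tree:
    """Contract every internal edge whose minimum number of changes over all
    most-parsimonious reconstructions (summed over characters) is zero.

    Used to deduplicate binary optima into the multifurcating trees that
    collapsing parsimony programs report.
    """
    if not tree.is_binary():
        raise TreeError("collapse expects a binary tree")
    root_label = min(tree.leaves)
    n = tree.n_leaves
    collapsible: dict[frozenset, bool] = {}
    for j in range(1, matrix.n_chars + 1):
        masks = _column_masks(matrix, j, tree.leaves)
        s, D, Up, A, order, parent, children, n_states = _dp_tables(
            tree, masks, root_label
        )
        below = _clade_sets(tree, order, children)
        for node in order[1:]:
            clade = below[node]
            if not 1 < len(clade) < n - 1:
                continue
            zero_ok = any(
                A[node][a] + D[node][a] == s for a in range(n_states)
            )
            collapsible[clade] = collapsible.get(clade, True) and zero_ok
    to_drop = [
        Bipartition(clade, tree.leaves)
        for clade, ok in collapsible.items()
        if ok
    ]
    if not to_drop:
        return tree
    return tree.collapse(to_drop)
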