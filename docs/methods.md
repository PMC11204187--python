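# Methods

## Scoring model

Characters are unordered, equally weighted, multistate (digits 0–9), with
`?` the single missing token; no polymorphic or inapplicable codings are
supported because the target class of matrices uses none.  The length of a
character on a binary unrooted tree is the Fitch minimum number of state
changes; tree length is the sum over characters.  The bottom-up pass roots
arbitrarily at a leaf — the count is root-invariant, which the test suite
checks — and an independent brute-force enumerator over all internal-node
state assignments serves as the oracle at small sizes (for unordered
characters the optimum is always attained using observed states only, so
enumeration over the observed alphabet is exact).

**Missing data.** A `?` leaf enters the Fitch pass as the *set of states
observed among the scored leaves* of that character, not as the full digit
alphabet.  The two conventions give identical tree lengths (extra,
unobserved states can never reduce a Fitch count), but the observed-set
convention keeps all-missing columns at zero steps without special-casing
and matches how `m` and `g` ignore missing cells.  `m` = distinct observed
states − 1 (floor 0); `g` = scored leaves − modal state count, the
worst case realised on the star tree.

## Search

*Exact.* Branch-and-bound adds taxa depth-first in a max-divergence order
(seeded by the most distant pair under Hamming distance on shared scored
cells, then maximin).  Pruning uses the partial-tree score plus an
admissible look-ahead: states that occur only among not-yet-added taxa
must each eventually cost at least one step.  The initial upper bound is a
greedy addition tree in the same order.  All topologies attaining the
final optimum are returned (cap `max_trees`, flagged when hit).  Scoring
packs every character into one big integer, one `w`-bit field per
character (`w` = number of states), so a full Fitch pass is a dozen
bitwise operations; the 13-taxon bundled matrix solves exactly in about a
tenth of a second, and the practical guard is 16 taxa.

*Heuristic.* Each replicate shuffles the taxa (seeded RNG), inserts each
at its best position (score ties broken by an RNG draw), then hill-climbs
with the configured move — NNI, SPR, or TBR (TBR bisects every edge and
reconnects each pair of edges of the two fragments; the neighborhood
nests NNI ⊆ SPR ⊆ TBR, property-tested).  Steepest descent takes the best
neighbor, first found in canonical generation order on ties.  Equally
optimal endpoint trees are pooled across replicates, and a final TBR
sweep closes the pool under equal-score TBR neighbors (cap `max_trees`).
Replicate count defaults to 20, a desk-scale setting for landscapes of a
dozen taxa; the published large settings (1000 replicates, 10,000 trees)
remain reachable through `SearchConfig`.  Identical `(matrix, config)`
inputs give bit-identical results.

*Collapsing.* An internal edge is contracted when, for every character,
some most-parsimonious reconstruction places zero changes on it (computed
by a unit-cost two-pass dynamic program giving, per edge, subtree and
complement cost vectors).  Binary optima are deduplicated through this
rule and both counts are reported, since parsimony programs disagree on
which convention their "number of MPTs" uses.

## Indices and reconstruction

Ensemble CI and RI are computed from the per-character `m, s, g` sums.
Both conventions are exposed: all characters (default) and
parsimony-informative characters only (at least two states each in two or
more taxa).  Rounding (half-up, two decimals) happens only at the report
layer.  A character is flagged homoplastic on a tree when `s > m`.

Ancestral states come from the same two-pass dynamic program.  The
ACCTRAN walk prefers, on ties, a child state different from its parent
(changes accelerate toward the display root); DELTRAN prefers keeping the
parent state; remaining ties break to the smallest state, making both
walks deterministic.  Either walk realises exactly `s` changes per
character, so summed over branches they partition the tree length — the
`unambiguous` policy instead reports per-node sets of states over all
most-parsimonious reconstructions and only the changes common to all of
them, so its change list may undercount `s`.  Synapomorphy queries
default to the permissive criterion — a change is credited to a branch if
*some* most-parsimonious reconstruction places it there — because the
reconstruction policy behind published branch annotations is rarely
stated.

The display root for rooted-view queries sits on the pendant edge of the
Haglinae outgroup (*Euhagla saurensis*).  A two-outgroup rooting is not
usable for the bundled study because the analysis itself pulls the second
outgroup (*Liassophyllum caii*) into a clade with *Cyrtophyllites
rogeri*.

## Bootstrap

Nonparametric over characters: each replicate draws `n_chars` columns
with replacement, re-searches with a reduced budget (10 random-addition
replicates, TBR, ≤50 trees, no final sweep — the outer resampling makes
search cost multiplicative, and these matrices converge in a few
replicates), and tallies the bipartitions of the replicate's strict
consensus, avoiding tie-break bias from any single best tree.  Support is
the fraction of replicates containing the bipartition.  Per-replicate
seeds derive from the master seed; results are exactly reproducible.
Support values printed only in the source figure are not reproduced as
numbers; the qualitative claims (majority support and top rank for the
new subfamily's branch) are tested instead.

## Synthetic data

The generator emulates the bundled study's shape: defaults of 13 taxa, 24
characters, up to 4 states, per-branch change probability 0.08 (≈1.8
expected changes per character across ~23 branches, close to the bundled
matrix's 42/24 = 1.75 observed steps per character), 10% missing cells
(bundled: 11.5%).  Topologies are uniform over unrooted binary trees
(sequential uniform edge attachment); characters evolve by a uniform root
state and a constant per-branch switch probability to a different uniform
state (an Mk-style process without branch lengths or rate heterogeneity —
parsimony, the only consumer, sees neither); missing cells are masked
independently.  What this does *not* emulate: correlated characters,
ascertainment toward variable characters, clustered missingness from
fossil preservation.  Passing recovery tests therefore demonstrate
algorithmic correctness on clean Mk-like signal, not robustness to real
morphological data pathologies.  `perfect_matrix` (one binary character
per internal edge) gives instances whose unique optimum is known by
construction.  Recovery experiments in the tests use 8–10 taxa, 45–60
characters and 5–10 search replicates — sizes at which every run
completes in seconds while the trends under test are already stable.

## Known discrepancies with the source study

* **CI/RI appear transposed in print.**  From the bundled matrix,
  Σm = 34, Σs = 42, Σg = 74, so CI = 34/42 = 0.8095 → 0.81 and
  RI = 32/40 = 0.8000 → 0.80 (all characters; the informative-only
  convention gives 0.78/0.80).  The study prints CI 0.80, RI 0.81 —
  exactly the computed pair with the labels swapped.  An independent
  implementation (phangorn) agrees with the computed values, which this
  package reports as computed.
* **MPT counts.**  The complete optimal set comprises 54 binary
  topologies (cross-checked: an independent scorer assigns all 54 length
  42 and they are pairwise distinct), collapsing to 4 trees under the
  zero-minimum-length rule.  The study reports one tree from one program
  and two from another; those counts reflect incomplete heuristic tree
  collection and program-specific collapsing, not the full optimum set.
  Both package counts are reported side by side.  All topology-level
  conclusions (clade verdicts, synapomorphy placements) hold on *every*
  member of the complete set, so the discrepancy does not touch the
  study's systematic conclusions.

## Numerical and degenerate-input choices

Report rounding is half-up (`floor(100x + 0.5)/100`), applied only at the
report layer.  CI of a zero-length (no variation) matrix is defined 1.0
with a warning; per-character `ci` is 1.0 when `s = 0` and `ri` 1.0 when
`g = m`.  Trees with fewer than four leaves have a single topology and
skip search; rearrangements, collapse and Fitch scoring refuse non-binary
input rather than resolving it silently.  Taxon labels are normalised by
collapsing internal whitespace; Newick/NEXUS output uses the
underscore-for-space convention, quoting labels that cannot round-trip.
The printed spelling of the giant *Vitimoilus* species is preserved in
the fixture with an alias from the corrected spelling.
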