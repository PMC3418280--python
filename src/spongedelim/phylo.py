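"""Distance and parsimony phylogenetics.

Neighbor-joining (Saitou-Nei) with a deterministic tie-break, nonparametric
bootstrap support on bipartitions, Fitch parsimony length, and an exact
branch-and-bound maximum-parsimony search.  Trees are unrooted and carried
as :class:`dendropy.Tree` objects; newick I/O goes through dendropy with
bootstrap supports written as internal-node labels.

Determinism contracts
---------------------
* NJ ties on the Q criterion are broken by the lexicographically smallest
  pair of cluster representative labels (the representative of a cluster is
  its smallest member leaf label).
* Negative NJ branch-length estimates are clamped to zero with the deficit
  transferred to the sister edge.
* Branch-and-bound adds taxa in input order and enumerates insertion points
  in a fixed order, so the list of optimal trees is reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Literal

import dendropy
import numpy as np

from .distmat import DistanceError, DistanceMatrix, distance_matrix
from .seqio import GAP, MultipleAlignment

GapPolicy = Literal["missing", "fifth-state"]

#: IUPAC codes expanded to their nucleotide sets (for Fitch leaf sets).
IUPAC_SETS = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"),
}


class PhyloError(ValueError):
    pass


# ---------------------------------------------------------------------------
# newick I/O and tree utilities


def read_newick(text: str) -> dendropy.Tree:
    """Parse a newick string into an unrooted dendropy tree."""
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise PhyloError(f"malformed newick: {exc}") from exc
    tree.is_rooted = False
    return tree


def write_newick(tree: dendropy.Tree) -> str:
    """Serialize a tree to newick, supports as internal-node labels."""
    return tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
        preserve_spaces=True,  # labels with spaces stay quoted
    ).strip() + "\n"


def leaf_labels(tree: dendropy.Tree) -> set[str]:
    return {lf.taxon.label for lf in tree.leaf_node_iter()}


def bipartitions(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Nontrivial bipartitions as canonical leaf-label sets.

    Each internal edge is represented by the side *not* containing the
    lexicographically smallest leaf label (so the set is rooting-invariant).
    """
    labels = leaf_labels(tree)
    ref = min(labels)
    n = len(labels)
    out: set[frozenset[str]] = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        side = below if ref not in below else frozenset(labels - below)
        if 2 <= len(side) <= n - 2:
            out.add(side)
    return out


def is_monophyletic(tree: dendropy.Tree, taxa: Iterable[str]) -> bool:
    """True iff `taxa` forms one side of a bipartition of the unrooted tree."""
    taxa = set(taxa)
    labels = leaf_labels(tree)
    unknown = taxa - labels
    if unknown:
        raise PhyloError(f"unknown labels: {sorted(unknown)}")
    if len(taxa) <= 1 or len(taxa) >= len(labels) - 1:
        return True
    ref = min(labels)
    side = frozenset(taxa) if ref not in taxa else frozenset(labels - taxa)
    return side in bipartitions(tree)


# ---------------------------------------------------------------------------
# neighbor-joining


def nj(m: DistanceMatrix) -> dendropy.Tree:
    """Saitou-Nei neighbor-joining with deterministic tie-breaking."""
    n0 = m.n
    if n0 < 3:
        raise PhyloError("NJ requires >= 3 taxa")
    size = 2 * n0
    D = np.zeros((size, size))
    D[:n0, :n0] = m.values
    newick_of: dict[int, str] = {
        i: _quote(lbl) for i, lbl in enumerate(m.labels)
    }
    rep: dict[int, str] = {i: lbl for i, lbl in enumerate(m.labels)}
    active = list(range(n0))
    nxt = n0
    while len(active) > 3:
        na = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (na - 2) * sub - r[:, None] - r[None, :]
        # evaluate ties on the upper triangle only: Q[a,b] and Q[b,a] can
        # differ by one ulp from summation order
        iu = np.triu_indices(na, k=1)
        qmin = Q[iu].min()
        cand = [
            (a, b)
            for a, b in combinations(range(na), 2)
            if Q[a, b] == qmin
        ]
        a, b = min(
            cand,
            key=lambda p: tuple(sorted((rep[active[p[0]]], rep[active[p[1]]]))),
        )
        i, j = active[a], active[b]
        d_ij = sub[a, b]
        vi = 0.5 * d_ij + (r[a] - r[b]) / (2.0 * (na - 2))
        vj = d_ij - vi
        vi, vj = _clamp_pair(vi, vj)
        u = nxt
        nxt += 1
        newick_of[u] = f"({newick_of[i]}:{vi:.6f},{newick_of[j]}:{vj:.6f})"
        rep[u] = min(rep[i], rep[j])
        for c in active:
            if c in (i, j):
                continue
            duc = 0.5 * (D[i, c] + D[j, c] - d_ij)
            D[u, c] = D[c, u] = max(duc, 0.0)
        active = [c for c in active if c not in (i, j)] + [u]
    x, y, z = active
    vx = max(0.5 * (D[x, y] + D[x, z] - D[y, z]), 0.0)
    vy = max(0.5 * (D[x, y] + D[y, z] - D[x, z]), 0.0)
    vz = max(0.5 * (D[x, z] + D[y, z] - D[x, y]), 0.0)
    newick = (
        f"({newick_of[x]}:{vx:.6f},{newick_of[y]}:{vy:.6f},"
        f"{newick_of[z]}:{vz:.6f});"
    )
    return read_newick(newick)


def _clamp_pair(vi: float, vj: float) -> tuple[float, float]:
    """Clamp negative branch estimates to 0, moving the deficit to the sister."""
    if vi < 0:
        vj += vi
        vi = 0.0
    if vj < 0:
        vi += vj
        vj = 0.0
    return max(vi, 0.0), max(vj, 0.0)


def _quote(label: str) -> str:
    if any(ch in label for ch in " ()[]:;,'"):
        return "'" + label.replace("'", "''") + "'"
    return label


# ---------------------------------------------------------------------------
# bootstrap


@dataclass
class BootstrapResult:
    """NJ tree with bootstrap supports mapped onto its internal edges."""

    tree: dendropy.Tree
    supports: dict[frozenset[str], float]
    n_replicates: int
    n_discarded: int


def bootstrap_support(
    aln: MultipleAlignment,
    n_reps: int,
    seed: int,
    model: str = "p",
    deletion: str = "pairwise",
) -> BootstrapResult:
    """Nonparametric bootstrap support for the NJ tree of an alignment.

    Columns are resampled with replacement (seeded, reproducible), the
    distance matrix and NJ tree are recomputed per pseudo-replicate, and the
    support of a bipartition is the percentage of successful replicates
    containing it.  Replicates in which some pair has zero comparable sites
    are discarded (counted; a warning is issued above 1%).  Supports are
    annotated onto the full-data NJ tree as internal-node labels.
    """
    if aln.n < 4:
        raise PhyloError("bootstrap requires >= 4 rows")
    if n_reps < 1:
        raise PhyloError("n_reps must be >= 1")
    base = nj(distance_matrix(aln, model=model, deletion=deletion))
    rng = np.random.default_rng(seed)
    chars = np.array([list(s) for s in aln.seqs])
    counts: dict[frozenset[str], int] = {}
    discarded = 0
    for _ in range(n_reps):
        cols = rng.integers(0, aln.length, aln.length)
        seqs = ["".join(row) for row in chars[:, cols]]
        rep_aln = MultipleAlignment(aln.locus_name, list(aln.ids), seqs)
        try:
            tree = nj(distance_matrix(rep_aln, model=model, deletion=deletion))
        except DistanceError:
            discarded += 1
            continue
        for bp in bipartitions(tree):
            counts[bp] = counts.get(bp, 0) + 1
    used = n_reps - discarded
    if used == 0:
        raise PhyloError("every bootstrap replicate was discarded")
    if discarded > 0.01 * n_reps:
        import warnings

        warnings.warn(f"{discarded}/{n_reps} bootstrap replicates discarded")
    supports = {bp: 100.0 * c / used for bp, c in counts.items()}
    _annotate_supports(base, supports)
    return BootstrapResult(base, supports, used, discarded)


def _annotate_supports(
    tree: dendropy.Tree, supports: dict[frozenset[str], float]
) -> None:
    labels = leaf_labels(tree)
    ref = min(labels)
    n = len(labels)
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        side = below if ref not in below else frozenset(labels - below)
        if 2 <= len(side) <= n - 2 and side in supports:
            node.label = f"{supports[side]:.0f}"


# ---------------------------------------------------------------------------
# Fitch parsimony


def _leaf_sets(
    aln: MultipleAlignment, gap_policy: GapPolicy
) -> dict[str, list[frozenset[str]]]:
    full = (
        frozenset("ACGT-") if gap_policy == "fifth-state" else frozenset("ACGT")
    )
    out: dict[str, list[frozenset[str]]] = {}
    for sid, seq in zip(aln.ids, aln.seqs):
        sets = []
        for ch in seq:
            if ch == GAP:
                sets.append(frozenset("-") if gap_policy == "fifth-state" else full)
            else:
                sets.append(IUPAC_SETS.get(ch, full))
        out[sid] = sets
    return out


def fitch_length(
    aln: MultipleAlignment,
    tree: dendropy.Tree,
    gap_policy: GapPolicy = "missing",
) -> int:
    """Fitch parsimony length of `tree` on the alignment.

    Gaps and ambiguity codes contribute no cost under the default
    ``missing`` policy (the leaf receives the union of compatible states);
    under ``fifth-state`` the gap is a fifth character state.
    The count is invariant under rerooting.
    """
    if leaf_labels(tree) != set(aln.ids):
        raise PhyloError("tree leaves do not match alignment rows")
    leaf_sets = _leaf_sets(aln, gap_policy)
    # compress identical columns into weighted patterns
    patterns: dict[tuple[frozenset[str], ...], int] = {}
    order = list(aln.ids)
    for col in range(aln.length):
        key = tuple(leaf_sets[sid][col] for sid in order)
        patterns[key] = patterns.get(key, 0) + 1
    idx = {sid: k for k, sid in enumerate(order)}
    post = list(tree.postorder_node_iter())
    total = 0
    for key, weight in patterns.items():
        cost = 0
        states: dict[int, frozenset[str]] = {}
        for node in post:
            if node.is_leaf():
                states[id(node)] = key[idx[node.taxon.label]]
            else:
                acc: frozenset[str] | None = None
                for child in node.child_nodes():
                    s = states[id(child)]
                    if acc is None:
                        acc = s
                    else:
                        inter = acc & s
                        if inter:
                            acc = inter
                        else:
                            acc = acc | s
                            cost += 1
                states[id(node)] = acc if acc is not None else frozenset()
        total += cost * weight
    return total


# ---------------------------------------------------------------------------
# branch-and-bound maximum parsimony

# Internally trees are nested tuples rooted at the first taxon (index 0):
# a subtree is either a leaf index or a pair (left, right); the represented
# unrooted tree attaches taxon 0 to the subtree's root.  Every node of the
# rooted form corresponds to exactly one edge of the unrooted tree, so
# inserting the next taxon at every node enumerates every labeled topology
# exactly once.

Subtree = int | tuple


def _insertions(sub: Subtree, leaf: int) -> list[Subtree]:
    out: list[Subtree] = [(sub, leaf)]
    if isinstance(sub, tuple):
        left, right = sub
        out.extend((l2, right) for l2 in _insertions(left, leaf))
        out.extend((left, r2) for r2 in _insertions(right, leaf))
    return out


def _subtree_fitch(
    sub: Subtree, pattern: tuple[frozenset[str], ...]
) -> tuple[frozenset[str], int]:
    if isinstance(sub, int):
        return pattern[sub], 0
    (ls, lc), (rs, rc) = (
        _subtree_fitch(sub[0], pattern),
        _subtree_fitch(sub[1], pattern),
    )
    inter = ls & rs
    if inter:
        return inter, lc + rc
    return ls | rs, lc + rc + 1


def _tree_length(
    sub: Subtree, patterns: list[tuple[tuple[frozenset[str], ...], int]]
) -> int:
    total = 0
    for pattern, weight in patterns:
        s, c = _subtree_fitch(sub, pattern)
        if not (pattern[0] & s):  # join the root subtree to taxon 0
            c += 1
        total += c * weight
    return total


def _newick_of(sub: Subtree, names: list[str]) -> str:
    if isinstance(sub, int):
        return _quote(names[sub])
    return f"({_newick_of(sub[0], names)},{_newick_of(sub[1], names)})"


def branch_and_bound_mp(
    aln: MultipleAlignment,
    gap_policy: GapPolicy = "missing",
    max_taxa: int = 15,
) -> tuple[int, list[dendropy.Tree]]:
    """Exact maximum-parsimony search by branch and bound.

    Taxa are added in input order; the bound is the length of the current
    best complete tree, and a partial tree is pruned only when it already
    exceeds the bound (Fitch length never decreases as leaves are added),
    so every co-optimal topology is retained.  Returns the globally optimal
    length and every distinct optimal topology in deterministic order.
    """
    n = aln.n
    if n < 4:
        raise PhyloError("branch-and-bound requires >= 4 taxa")
    if n > max_taxa:
        raise PhyloError(
            f"{n} taxa exceeds the exact-search guard rail ({max_taxa}); "
            "heuristic search is out of scope"
        )
    leaf_sets = _leaf_sets(aln, gap_policy)
    names = list(aln.ids)
    pat_counts: dict[tuple[frozenset[str], ...], int] = {}
    for col in range(aln.length):
        key = tuple(leaf_sets[sid][col] for sid in names)
        pat_counts[key] = pat_counts.get(key, 0) + 1
    patterns = list(pat_counts.items())

    best: list[int] = []  # mutable best length box
    optimal: list[Subtree] = []

    def dfs(sub: Subtree, next_taxon: int) -> None:
        length = _tree_length(sub, patterns)
        if best and length > best[0]:
            return
        if next_taxon == n:
            if not best or length < best[0]:
                best[:] = [length]
                optimal[:] = [sub]
            elif length == best[0]:
                optimal.append(sub)
            return
        for child in _insertions(sub, next_taxon):
            dfs(child, next_taxon + 1)

    dfs((1, 2), 3)
    trees = []
    for sub in optimal:
        left, right = sub  # root subtree is always a pair for n >= 3
        trees.append(
            read_newick(
                f"({_quote(names[0])},{_newick_of(left, names)},"
                f"{_newick_of(right, names)});"
            )
        )
    return best[0], trees
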