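"""Independent brute-force oracles and random-instance generators for tests.

Everything here is deliberately written as plain enumeration loops, separate
from the package's implementations, so agreement is a genuine cross-check.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np

from spongedelim.seqio import MultipleAlignment, SpeciesPartition

DET = set("ACGT")


def random_alignment(
    rng: np.random.Generator,
    n_rows: int,
    n_cols: int,
    gap_prob: float = 0.05,
    missing_prob: float = 0.05,
    locus: str = "rand",
) -> MultipleAlignment:
    symbols = np.array(list("ACGT-N"))
    probs = [
        (1 - gap_prob - missing_prob) / 4.0
    ] * 4 + [gap_prob, missing_prob]
    seqs = [
        "".join(rng.choice(symbols, size=n_cols, p=probs))
        for _ in range(n_rows)
    ]
    ids = [f"t{i}" for i in range(n_rows)]
    return MultipleAlignment(locus, ids, seqs)


def random_partition(
    rng: np.random.Generator, ids: list[str], n_species: int
) -> SpeciesPartition:
    labels = [f"sp{k}" for k in range(n_species)]
    # guarantee every species nonempty
    order = list(rng.permutation(len(ids)))
    assignment = {}
    for k, idx in enumerate(order):
        assignment[ids[idx]] = labels[k] if k < n_species else labels[
            int(rng.integers(0, n_species))
        ]
    return SpeciesPartition(
        {sid: assignment[sid] for sid in ids},
        [l for l in labels if l in set(assignment.values())],
    )


def _determinate(gap_policy: str) -> set[str]:
    return DET | {"-"} if gap_policy == "fifth-state" else DET


def oracle_columns(aln: MultipleAlignment, gap_policy: str) -> list[int]:
    cols = []
    for pos in range(1, aln.length + 1):
        col = [s[pos - 1] for s in aln.seqs]
        if gap_policy == "exclude-column" and "-" in col:
            continue
        cols.append(pos)
    return cols


def oracle_pure(
    aln: MultipleAlignment, part: SpeciesPartition, gap_policy: str
) -> set[tuple[str, int, str]]:
    """All (species, position, state) pure diagnostics, by direct scan."""
    det = _determinate(gap_policy)
    out = set()
    for sp in part.species_order:
        members = set(part.members(sp))
        for pos in oracle_columns(aln, gap_policy):
            states_in = {
                s[pos - 1] for sid, s in zip(aln.ids, aln.seqs) if sid in members
            }
            if len(states_in) != 1:
                continue
            state = next(iter(states_in))
            if state not in det:
                continue
            ok = True
            for sid, s in zip(aln.ids, aln.seqs):
                if sid in members:
                    continue
                ch = s[pos - 1]
                if ch not in det or ch == state:
                    ok = False
                    break
            if ok:
                out.add((sp, pos, state))
    return out


def oracle_composites(
    aln: MultipleAlignment,
    part: SpeciesPartition,
    max_size: int,
    gap_policy: str,
) -> dict[str, set[tuple[tuple[int, str], ...]]]:
    """Minimal-cardinality composite sets per species, by full enumeration.

    Candidate columns are those fixed and determinate within the species but
    not pure-diagnostic for it; subsets of every size 2..max_size are tested
    and only the smallest size with any qualifying set is kept.
    """
    det = _determinate(gap_policy)
    pure = oracle_pure(aln, part, gap_policy)
    out: dict[str, set] = {}
    for sp in part.species_order:
        members = set(part.members(sp))
        others = [
            (sid, s) for sid, s in zip(aln.ids, aln.seqs) if sid not in members
        ]
        pure_pos = {p for s2, p, _ in pure if s2 == sp}
        fixed: list[tuple[int, str]] = []
        for pos in oracle_columns(aln, gap_policy):
            if pos in pure_pos:
                continue
            states_in = {
                s[pos - 1] for sid, s in zip(aln.ids, aln.seqs) if sid in members
            }
            if len(states_in) == 1 and next(iter(states_in)) in det:
                fixed.append((pos, next(iter(states_in))))
        found: set[tuple[tuple[int, str], ...]] = set()
        for k in range(2, max_size + 1):
            for combo in combinations(fixed, k):
                excluded = True
                for _, s in others:
                    matches_all = True
                    for pos, state in combo:
                        ch = s[pos - 1]
                        if ch in det and ch != state:
                            matches_all = False
                            break
                    if matches_all:
                        excluded = False
                        break
                if excluded:
                    found.add(tuple(combo))
            if found:
                break
        if found:
            out[sp] = found
    return out


# --- random additive trees for NJ consistency ------------------------------


def random_additive_tree(rng: np.random.Generator, n_taxa: int):
    """Random unrooted binary tree with edge lengths >= 0.01.

    Returns (adjacency dict node -> {neighbor: length}, leaf names,
    true nontrivial bipartitions as canonical frozensets).
    """
    def elen() -> float:
        return 0.01 + float(rng.uniform(0.0, 1.0))

    leaves = [f"L{i}" for i in range(n_taxa)]
    adj: dict[str, dict[str, float]] = {}

    def add_edge(a, b, w):
        adj.setdefault(a, {})[b] = w
        adj.setdefault(b, {})[a] = w

    def drop_edge(a, b):
        del adj[a][b]
        del adj[b][a]

    add_edge(leaves[0], "I0", elen())
    add_edge(leaves[1], "I0", elen())
    add_edge(leaves[2], "I0", elen())
    n_internal = 1
    for leaf in leaves[3:]:
        edges = sorted(
            {tuple(sorted((a, b))) for a in adj for b in adj[a]}
        )
        a, b = edges[int(rng.integers(0, len(edges)))]
        w = adj[a][b]
        mid = f"I{n_internal}"
        n_internal += 1
        drop_edge(a, b)
        add_edge(a, mid, w / 2)
        add_edge(mid, b, w / 2)
        add_edge(leaf, mid, elen())
    return adj, leaves, tree_bipartitions(adj, leaves)


def path_length_matrix(adj, leaves) -> np.ndarray:
    import heapq

    n = len(leaves)
    out = np.zeros((n, n))
    for i, src in enumerate(leaves):
        dist = {src: 0.0}
        heap = [(0.0, src)]
        while heap:
            d, u = heapq.heappop(heap)
            if d > dist.get(u, float("inf")):
                continue
            for v, w in adj[u].items():
                nd = d + w
                if nd < dist.get(v, float("inf")):
                    dist[v] = nd
                    heapq.heappush(heap, (nd, v))
        for j, dst in enumerate(leaves):
            out[i, j] = dist[dst]
    return (out + out.T) / 2.0  # exact symmetry (float summation order)


def tree_bipartitions(adj, leaves) -> set[frozenset[str]]:
    ref = min(leaves)
    n = len(leaves)
    out = set()
    edges = {tuple(sorted((a, b))) for a in adj for b in adj[a]}
    for a, b in edges:
        # leaves on b's side when edge (a, b) is removed
        seen = {a, b}
        stack = [b]
        side = set()
        while stack:
            u = stack.pop()
            if u in leaves:
                side.add(u)
            for v in adj[u]:
                if v not in seen:
                    seen.add(v)
                    stack.append(v)
        canon = (
            frozenset(side) if ref not in side else frozenset(set(leaves) - side)
        )
        if 2 <= len(canon) <= n - 2:
            out.add(canon)
    return out


# --- exhaustive MP enumeration ---------------------------------------------


def all_topologies(ids: list[str]):
    """Every unrooted binary topology on `ids` as newick strings."""

    def insertions(sub, leaf):
        yield (sub, leaf)
        if isinstance(sub, tuple):
            left, right = sub
            for l2 in insertions(left, leaf):
                yield (l2, right)
            for r2 in insertions(right, leaf):
                yield (left, r2)

    def grow(sub, k):
        if k == len(ids):
            yield sub
            return
        for child in insertions(sub, k):
            yield from grow(child, k + 1)

    def newick(sub):
        if isinstance(sub, int):
            return ids[sub]
        return f"({newick(sub[0])},{newick(sub[1])})"

    for sub in grow((1, 2), 3):
        left, right = sub
        yield f"({ids[0]},{newick(left)},{newick(right)});"
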