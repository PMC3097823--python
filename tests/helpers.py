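"""Independent oracles used by the test suite.

Everything here deliberately avoids the package's postorder-range machinery:
trees are walked through parent/child links only, losses are found by
exhaustive search, and network quantities by direct enumeration, so these
implementations can serve as independent cross-checks.
"""

from itertools import combinations

import numpy as np


def row_of(tree, pattern: str) -> np.ndarray:
    """Binary row from a 0/1 string in the tree's taxa (column) order."""
    assert len(pattern) == tree.n_leaves
    return np.array([c == "1" for c in pattern])


def leaves_under(tree, v) -> set:
    """Leaf node ids below (or equal to) v, via child links only."""
    out, stack = set(), [v]
    while stack:
        u = stack.pop()
        if tree.is_leaf[u]:
            out.add(int(u))
        else:
            stack.extend(tree.children[u])
    return out


def ancestors_of(tree, v) -> list:
    """Path v -> root inclusive, via parent links."""
    path = [int(v)]
    while tree.parent[path[-1]] != -1:
        path.append(int(tree.parent[path[-1]]))
    return path


def mrca_by_paths(tree, nodes) -> int:
    """MRCA via ancestor-path intersection (deepest common node)."""
    common = set(ancestors_of(tree, nodes[0]))
    for v in nodes[1:]:
        common &= set(ancestors_of(tree, v))
    return max(common, key=lambda u: len(ancestors_of(tree, u)))


def _leaf_bits(tree, v) -> int:
    bits = 0
    for leaf in leaves_under(tree, v):
        col = tree.taxa.index(tree.labels[leaf])
        bits |= 1 << col
    return bits


def min_losses_bruteforce(tree, row, origins) -> int:
    """Smallest loss set (over all node subsets) replaying to ``row``.

    Replay semantics: presence = union of origin subtrees minus union of loss
    subtrees.  Returns the minimum loss-set size; raises if no loss set works.
    """
    target = 0
    for col, bit in enumerate(np.asarray(row).astype(bool)):
        if bit:
            target |= 1 << col
    base = 0
    for o in origins:
        base |= _leaf_bits(tree, o)
    candidates = [v for o in origins for v in leaves_under_nodes(tree, o) if v != o]
    cand_bits = [_leaf_bits(tree, v) for v in candidates]
    for k in range(len(candidates) + 1):
        for combo in combinations(range(len(candidates)), k):
            mask = base
            for i in combo:
                mask &= ~cand_bits[i]
            if mask == target:
                return k
    raise AssertionError("no loss placement reproduces the row")


def leaves_under_nodes(tree, v) -> list:
    """All node ids (leaf or internal) below or equal to v, via child links."""
    out, stack = [], [v]
    while stack:
        u = stack.pop()
        out.append(int(u))
        stack.extend(tree.children[u])
    return out


def bor1_origins_oracle(tree, row):
    """Independent application of the per-clade-MRCA splitting rule (one split)."""
    row = np.asarray(row).astype(bool)
    present = [int(v) for v in tree.leaf_ids[row]]
    prelim = mrca_by_paths(tree, present)
    under = leaves_under(tree, prelim)
    if all(row[tree.taxa.index(tree.labels[l])] for l in under):
        return {prelim}
    out = set()
    for child in tree.children[prelim]:
        inside = [l for l in present if l in leaves_under(tree, child)]
        out.add(mrca_by_paths(tree, inside))
    return out


def best_bipartition_q(adj) -> float:
    """Brute-force maximum modularity over all 2-colourings (plus no split)."""
    from mlnet.cognate_network import modularity

    n = adj.shape[0]
    best = modularity(adj, [0] * n)
    for bits in range(1, 2 ** (n - 1)):
        member = [(bits >> i) & 1 for i in range(n)]
        best = max(best, modularity(adj, member))
    return best


def bfs_mean_path(edges, n_nodes) -> float:
    """Mean shortest path over unordered reachable pairs, by plain BFS."""
    adj = {v: set() for v in range(n_nodes)}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    total, pairs = 0, 0
    for s in range(n_nodes):
        dist = {s: 0}
        frontier = [s]
        while frontier:
            nxt = []
            for v in frontier:
                for u in adj[v]:
                    if u not in dist:
                        dist[u] = dist[v] + 1
                        nxt.append(u)
            frontier = nxt
        for t, d in dist.items():
            if t > s:
                total += d
                pairs += 1
    return total / pairs
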