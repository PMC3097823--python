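"""Shared-character networks, PAP summaries, and modularity communities.

The shared-character network connects taxa by the number of characters
(cognate sets / gene families) they hold in common.  Community structure is
found by Newman's leading-eigenvector spectral bisection, generalised to
weighted adjacency: recursive splits by the sign of the dominant eigenvector
of the (generalised) modularity matrix, each kept only when it increases the
global modularity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_model import PAPMatrix, ReferenceTree

__all__ = [
    "SharedMatrix",
    "CommunityPartition",
    "shared_matrix",
    "pap_summary",
    "is_congruent",
    "congruence_flags",
    "modularity",
    "leading_eigenvector_communities",
]


@dataclass
class SharedMatrix:
    """Symmetric taxon x taxon co-presence counts; diagonal = inventory size."""

    taxa: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.int64)
        n = len(self.taxa)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape does not match taxa")
        if not np.array_equal(self.matrix, self.matrix.T):
            raise ValueError("shared matrix must be symmetric")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.matrix, index=self.taxa, columns=self.taxa)


@dataclass
class CommunityPartition:
    """Taxon -> module assignment with its modularity score."""

    membership: dict
    q: float

    @property
    def n_modules(self) -> int:
        return len(set(self.membership.values()))

    def modules(self) -> dict[int, list]:
        out: dict[int, list] = {}
        for node, mod in self.membership.items():
            out.setdefault(mod, []).append(node)
        return out


def shared_matrix(pap: PAPMatrix) -> SharedMatrix:
    """Count, for every taxon pair, the characters present in both."""
    x = pap.values.astype(np.int64)
    return SharedMatrix(list(pap.taxa), x.T @ x)


def pap_summary(pap: PAPMatrix) -> tuple[int, int, int]:
    """(distinct patterns, patterns occurring once, recurring patterns)."""
    _, counts = np.unique(pap.values, axis=0, return_counts=True)
    n_distinct = int(counts.size)
    n_unique = int(np.sum(counts == 1))
    return n_distinct, n_unique, n_distinct - n_unique


def is_congruent(tree: ReferenceTree, pap_row, taxa=None) -> bool:
    """True iff the present taxa form exactly one complete clade of the tree.

    A congruent pattern is explainable by a single origin with zero losses.
    ``taxa`` gives the column order of ``pap_row`` when it differs from the
    tree's.
    """
    row = np.asarray(pap_row).astype(bool)
    if taxa is not None:
        order = {t: i for i, t in enumerate(taxa)}
        row = row[[order[t] for t in tree.taxa]]
    if row.shape != (tree.n_leaves,) or not row.any():
        raise ValueError("row must be aligned to the tree and non-empty")
    v = tree.mrca_of_mask(row)
    return tree.subtree_leaf_count(v) == int(row.sum())


def congruence_flags(tree: ReferenceTree, pap: PAPMatrix) -> np.ndarray:
    """Per-character congruence with the tree branching pattern."""
    values = pap.aligned_values(tree.taxa)
    return np.array([is_congruent(tree, values[i]) for i in range(pap.n_characters)])


# ---------------------------------------------------------------------------
# Modularity
# ---------------------------------------------------------------------------

def _as_adjacency(adj) -> tuple[np.ndarray, list]:
    """Dense zero-diagonal adjacency plus node labels, from any input form."""
    if isinstance(adj, SharedMatrix):
        a = adj.matrix.astype(float).copy()
        labels = list(adj.taxa)
    elif isinstance(adj, np.ndarray):
        a = adj.astype(float).copy()
        labels = list(range(a.shape[0]))
    else:  # networkx graph
        import networkx as nx

        labels = list(adj.nodes)
        a = nx.to_numpy_array(adj, nodelist=labels, weight="weight")
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(a, a.T):
        raise ValueError("adjacency must be symmetric")
    if (a < 0).any():
        raise ValueError("adjacency weights must be non-negative")
    np.fill_diagonal(a, 0.0)
    return a, labels


def _as_membership(partition, labels) -> np.ndarray:
    if isinstance(partition, dict):
        groups = [partition[l] for l in labels]
    elif isinstance(partition, (list, tuple)) and partition and not np.isscalar(partition[0]):
        # list of collections of labels
        lookup = {}
        for i, group in enumerate(partition):
            for l in group:
                lookup[l] = i
        groups = [lookup[l] for l in labels]
    else:
        groups = list(partition)
        if len(groups) != len(labels):
            raise ValueError("membership length does not match node count")
    _, member = np.unique(np.asarray(groups, dtype=object), return_inverse=True)
    return member


def modularity(adj, partition) -> float:
    """Weighted modularity Q of a partition.

    ``Q = sum_c [ W_c / W - (S_c / 2W)^2 ]`` with W the total edge weight,
    W_c the intra-community weight and S_c the community's summed weighted
    degree; self-loops are excluded.
    """
    a, labels = _as_adjacency(adj)
    member = _as_membership(partition, labels)
    strength = a.sum(axis=1)
    two_w = strength.sum()
    if two_w <= 0:
        raise ValueError("modularity of an empty graph is undefined")
    q = 0.0
    for c in np.unique(member):
        idx = member == c
        w_c = a[np.ix_(idx, idx)].sum() / 2.0
        s_c = strength[idx].sum()
        q += w_c / (two_w / 2.0) - (s_c / two_w) ** 2
    return float(q)


def _components(a: np.ndarray) -> list[np.ndarray]:
    n = a.shape[0]
    seen = np.zeros(n, dtype=bool)
    comps = []
    for start in range(n):
        if seen[start]:
            continue
        stack = [start]
        seen[start] = True
        comp = [start]
        while stack:
            v = stack.pop()
            for u in np.flatnonzero(a[v] > 0):
                if not seen[u]:
                    seen[u] = True
                    comp.append(int(u))
                    stack.append(int(u))
        comps.append(np.array(sorted(comp)))
    return comps


def leading_eigenvector_communities(adj, tol: float = 1e-10) -> CommunityPartition:
    """Recursive spectral bisection of the (generalised) modularity matrix.

    Each candidate split follows the sign of the leading eigenvector (ties to
    the positive side) and is kept only if its modularity contribution is
    positive; indivisible groups (leading eigenvalue <= 0) stay whole.
    Disconnected components are handled separately.
    """
    a, labels = _as_adjacency(adj)
    strength = a.sum(axis=1)
    two_w = strength.sum()
    if two_w <= 0:
        raise ValueError("community detection needs positive total edge weight")

    final_groups: list[np.ndarray] = []

    def divide(idx: np.ndarray) -> None:
        if idx.size == 1:
            final_groups.append(idx)
            return
        b = a[np.ix_(idx, idx)] - np.outer(strength[idx], strength[idx]) / two_w
        bg = b - np.diag(b.sum(axis=1))
        evals, evecs = np.linalg.eigh(bg)
        if evals[-1] <= tol:
            final_groups.append(idx)
            return
        s = np.where(evecs[:, -1] >= 0, 1.0, -1.0)
        if np.all(s > 0) or np.all(s < 0):
            final_groups.append(idx)
            return
        delta_q = s @ bg @ s / (2.0 * two_w)
        if delta_q <= tol:
            final_groups.append(idx)
            return
        divide(idx[s > 0])
        divide(idx[s < 0])

    for comp in _components(a):
        divide(comp)

    membership_arr = np.zeros(len(labels), dtype=int)
    for mod_id, group in enumerate(final_groups):
        membership_arr[group] = mod_id
    membership = {labels[i]: int(membership_arr[i]) for i in range(len(labels))}
    q = modularity(a, membership_arr)
    return CommunityPartition(membership, q)
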