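"""Minimal lateral network assembly and statistics.

The MLN is the reference tree plus the minimum set of lateral edges implied by
an accepted borrowing allowance: every split performed during BOR-k inference
links the two sibling origins it produced, so the summed lateral edge weight
equals the total number of inferred borrowings.  Edges between internal nodes
represent transfers among ancestral lineages; edges touching leaves represent
comparatively recent borrowing.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from . import stats as _stats
from .core_model import GainLossScenario, InventoryProfile, ReferenceTree

__all__ = [
    "LateralNetwork",
    "build_mln",
    "degree_stats",
    "graph_stats",
    "edge_weight_histogram",
    "classify_edges",
    "recent_borrowing_fraction",
    "group_edge_analysis",
    "validate_known_borrowings",
]


@dataclass
class LateralNetwork:
    """Reference tree + symmetric lateral-sharing counts over all tree nodes."""

    tree: ReferenceTree
    inventory: InventoryProfile
    weights: dict[tuple[int, int], int] = field(default_factory=dict)
    edge_chars: dict[tuple[int, int], list[str]] = field(default_factory=dict)

    @property
    def n_lateral_edges(self) -> int:
        return len(self.weights)

    @property
    def total_lateral_weight(self) -> int:
        return sum(self.weights.values())

    def matrix(self) -> np.ndarray:
        """Dense symmetric node x node matrix of laterally shared counts."""
        n = self.tree.n_nodes
        a = np.zeros((n, n), dtype=np.int64)
        for (i, j), w in self.weights.items():
            a[i, j] = a[j, i] = w
        return a

    def union_graph(self):
        """Undirected, unweighted union of tree branches and lateral edges."""
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(range(self.tree.n_nodes))
        for v in range(self.tree.n_nodes - 1):
            g.add_edge(v, int(self.tree.parent[v]))
        g.add_edges_from(self.weights.keys())
        return g


def build_mln(
    tree: ReferenceTree,
    scenarios,
    inventory: InventoryProfile | None = None,
) -> LateralNetwork:
    """Assemble the MLN: one lateral increment per recorded origin-sibling pair."""
    from .origin_loss import ancestral_inventory

    if isinstance(scenarios, dict):
        scenarios = list(scenarios.values())
    if inventory is None:
        inventory = ancestral_inventory(tree, scenarios)
    weights: dict[tuple[int, int], int] = {}
    edge_chars: dict[tuple[int, int], list[str]] = {}
    for sc in scenarios:
        for a, b in sc.sibling_pairs:
            key = (min(a, b), max(a, b))
            weights[key] = weights.get(key, 0) + 1
            edge_chars.setdefault(key, []).append(sc.char_id)
    net = LateralNetwork(tree, inventory, weights, edge_chars)
    total_borrowings = sum(sc.n_borrowings for sc in scenarios)
    if net.total_lateral_weight != total_borrowings:  # conservation check
        raise AssertionError("lateral weight does not match borrowing count")
    return net


def degree_stats(net: LateralNetwork) -> tuple[np.ndarray, int, int, float]:
    """Lateral connectivity per node (distinct neighbours) with min/max/median.

    Tree branches are not counted; a node untouched by lateral edges has
    connectivity zero.
    """
    conn = np.zeros(net.tree.n_nodes, dtype=np.int64)
    neighbours: dict[int, set[int]] = {}
    for i, j in net.weights:
        neighbours.setdefault(i, set()).add(j)
        neighbours.setdefault(j, set()).add(i)
    for v, ns in neighbours.items():
        conn[v] = len(ns)
    return conn, int(conn.min()), int(conn.max()), float(np.median(conn))


def graph_stats(net: LateralNetwork) -> tuple[float, float]:
    """(mean local clustering coefficient, mean shortest path length).

    Both computed on the unweighted union of tree branches and lateral edges;
    nodes of degree < 2 contribute 0 to the clustering mean, and the mean path
    averages over all unordered reachable node pairs.
    """
    import networkx as nx

    g = net.union_graph()
    clustering = nx.average_clustering(g)
    total = 0.0
    pairs = 0
    for _, dists in nx.all_pairs_shortest_path_length(g):
        for d in dists.values():
            total += d
            pairs += 1
    # every unordered pair counted twice, self-distances are zero
    mean_path = total / (pairs - g.number_of_nodes()) if pairs > g.number_of_nodes() else 0.0
    return float(clustering), float(mean_path)


def edge_weight_histogram(net: LateralNetwork) -> dict[int, int]:
    """weight -> number of distinct lateral edges of that weight."""
    return dict(sorted(Counter(net.weights.values()).items()))


def classify_edges(net: LateralNetwork) -> dict[str, int]:
    """Counts of external–external, external–internal, internal–internal edges."""
    counts = {"external-external": 0, "external-internal": 0, "internal-internal": 0}
    for i, j in net.weights:
        n_external = int(net.tree.is_leaf[i]) + int(net.tree.is_leaf[j])
        kind = ("internal-internal", "external-internal", "external-external")[n_external]
        counts[kind] += 1
    return counts


def recent_borrowing_fraction(net: LateralNetwork) -> tuple[dict[str, float | None], float, float]:
    """Percentage of each leaf's inventory involved in lateral edges at that leaf.

    Returns (taxon -> percentage, mean, SD); a leaf with zero inventory gets
    ``None`` and is excluded from the mean/SD.
    """
    tree = net.tree
    chars_at: dict[int, set[str]] = {}
    for (i, j), chars in net.edge_chars.items():
        for v in (i, j):
            if tree.is_leaf[v]:
                chars_at.setdefault(v, set()).update(chars)
    fractions: dict[str, float | None] = {}
    values = []
    for col, v in enumerate(tree.leaf_ids):
        inv = int(net.inventory.sizes[v])
        taxon = tree.taxa[col]
        if inv == 0:
            fractions[taxon] = None
            continue
        pct = 100.0 * len(chars_at.get(int(v), ())) / inv
        fractions[taxon] = pct
        values.append(pct)
    mean = float(np.mean(values)) if values else float("nan")
    sd = float(np.std(values)) if values else float("nan")
    return fractions, mean, sd


def _node_groups(tree: ReferenceTree, groups: dict[str, str]) -> list[str | None]:
    """Group of every tree node; internal nodes need all leaves in one group."""
    missing = [t for t in tree.taxa if t not in groups]
    if missing:
        raise ValueError(f"taxa without a group assignment: {missing}")
    node_group: list[str | None] = [None] * tree.n_nodes
    for v in range(tree.n_nodes):
        if tree.is_leaf[v]:
            node_group[v] = groups[tree.labels[v]]
        else:
            leaf_groups = {groups[tree.taxa[j]] for j in range(tree.leaf_lo[v], tree.leaf_hi[v])}
            node_group[v] = leaf_groups.pop() if len(leaf_groups) == 1 else None
    return node_group


def group_edge_analysis(net: LateralNetwork, groups: dict[str, str]):
    """Within- vs between-group lateral edge analysis (one row per group).

    An edge is *internal* to a group when both endpoints belong to it and
    *external* when exactly one does; frequencies are normalized by the number
    of group nodes (internal) or non-group nodes (external).  The one-sided KS
    test asks whether internal edge weights are stochastically larger than
    external ones (H0: internal <= external).
    """
    import pandas as pd

    tree = net.tree
    node_group = _node_groups(tree, groups)
    rows = []
    for g in sorted(set(groups.values())):
        nodes_in = [v for v in range(tree.n_nodes) if node_group[v] == g]
        if not nodes_in:
            warnings.warn(f"group {g!r} has no tree nodes; skipped")
            continue
        n_in = len(nodes_in)
        n_out = tree.n_nodes - n_in
        int_w, ext_w = [], []
        for (i, j), w in net.weights.items():
            inside = (node_group[i] == g) + (node_group[j] == g)
            if inside == 2:
                int_w.append(w)
            elif inside == 1:
                ext_w.append(w)
        if int_w and ext_w:
            _, ks_p = _stats.ks_one_sided(int_w, ext_w)
        else:
            ks_p = float("nan")
        rows.append(
            {
                "group": g,
                "n_leaves": sum(1 for t in tree.taxa if groups[t] == g),
                "n_nodes": n_in,
                "internal_edges": len(int_w),
                "external_edges": len(ext_w),
                "internal_freq": len(int_w) / n_in,
                "external_freq": len(ext_w) / n_out if n_out else float("nan"),
                "median_internal_weight": float(np.median(int_w)) if int_w else float("nan"),
                "median_external_weight": float(np.median(ext_w)) if ext_w else float("nan"),
                "ks_p": ks_p,
            }
        )
    return pd.DataFrame(rows)


def validate_known_borrowings(
    tree: ReferenceTree,
    scenarios: dict[str, GainLossScenario],
    known: list[tuple[str, str]],
):
    """Classify known borrowings against inferred scenarios.

    A borrowing is *detected* when the character's scenario has more than one
    origin (borrowing direction is never inferred, so any origin may be the
    borrowed one): ``external`` when the taxon itself is an origin node,
    ``internal`` when it descends from an internal origin node,
    ``not_detected`` when the scenario has a single origin.  Returns the
    per-item table and a summary with the detection percentage.
    """
    import pandas as pd

    rows = []
    for char_id, taxon in known:
        if char_id not in scenarios:
            raise ValueError(f"unknown character: {char_id!r}")
        try:
            leaf = tree.node(taxon)
        except KeyError:
            raise ValueError(f"unknown taxon: {taxon!r}") from None
        if not tree.is_leaf[leaf]:
            raise ValueError(f"{taxon!r} is not a leaf taxon")
        sc = scenarios[char_id]
        if sc.n_origins == 1:
            cls = "not_detected"
        elif leaf in sc.origins:
            cls = "external"
        elif any(tree.is_ancestor(o, leaf) for o in sc.origins if not tree.is_leaf[o]):
            cls = "internal"
        else:
            cls = "not_detected"
        rows.append({"character": char_id, "taxon": taxon, "classification": cls})
    table = pd.DataFrame(rows)
    counts = Counter(r["classification"] for r in rows)
    n = len(rows)
    detected = counts["external"] + counts["internal"]
    summary = {
        "n": n,
        "external": counts["external"],
        "internal": counts["internal"],
        "not_detected": counts["not_detected"],
        "detected_pct": 100.0 * detected / n if n else float("nan"),
    }
    return table, summary
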