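"""Readers and writers: Newick trees, PAP matrices, cognate tables, reports.

All tabular formats are plain TSV/CSV (chosen by file extension, tab by
default) in UTF-8; networks are exported as GraphML or a weighted edge list
whose edges are flagged ``vertical`` (tree branches) or ``lateral``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core_model import (
    CognateTable,
    PAPMatrix,
    ReferenceTree,
    _BuildNode,
    resolve_and_validate,
)

__all__ = [
    "NewickParseError",
    "parse_newick",
    "read_newick",
    "write_newick",
    "read_pap_matrix",
    "write_pap_matrix",
    "read_cognate_table",
    "cognate_table_to_pap",
    "write_scenario_report",
    "NetworkExport",
    "network_export",
    "write_network",
    "read_network_edgelist",
    "write_shared_matrix",
    "write_communities",
]


class NewickParseError(ValueError):
    """Raised when a Newick string cannot be parsed."""


def _sep(path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

def parse_newick(text: str, resolve: bool = True) -> ReferenceTree:
    """Parse a rooted Newick string (branch lengths ignored, quotes supported).

    With ``resolve`` (default) polytomies are resolved deterministically so
    the result is binary with ``2n - 1`` nodes.
    """
    import dendropy

    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise NewickParseError(f"malformed Newick: {exc}") from exc

    def convert(node) -> _BuildNode:
        if node.is_leaf():
            label = node.taxon.label if node.taxon is not None else node.label
            if not label:
                raise NewickParseError("leaf without a label")
            return _BuildNode(str(label))
        return _BuildNode(
            str(node.label) if node.label else None,
            [convert(c) for c in node.child_nodes()],
        )

    leaf_labels = [
        (lf.taxon.label if lf.taxon is not None else lf.label)
        for lf in dtree.leaf_node_iter()
    ]
    dupes = sorted({l for l in leaf_labels if leaf_labels.count(l) > 1})
    if dupes:
        raise ValueError(f"duplicate leaf labels: {dupes}")

    tree = ReferenceTree(convert(dtree.seed_node))
    return resolve_and_validate(tree) if resolve else tree


def read_newick(path, resolve: bool = True) -> ReferenceTree:
    """Read a rooted tree from a Newick file."""
    return parse_newick(Path(path).read_text(encoding="utf-8"), resolve=resolve)


def write_newick(tree: ReferenceTree, path) -> None:
    Path(path).write_text(tree.newick() + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# PAP matrices
# ---------------------------------------------------------------------------

def read_pap_matrix(path) -> PAPMatrix:
    """Read a characters x taxa 0/1 matrix (first column = character id)."""
    df = pd.read_csv(path, sep=_sep(path), index_col=0, dtype=str, encoding="utf-8")
    char_ids = [str(c) for c in df.index]
    taxa = [str(t) for t in df.columns]
    values = np.zeros(df.shape, dtype=np.uint8)
    raw = df.to_numpy()
    for i in range(df.shape[0]):
        for j in range(df.shape[1]):
            cell = str(raw[i, j]).strip()
            if cell not in ("0", "1"):
                raise ValueError(
                    f"non-binary value {cell!r} at ({char_ids[i]}, {taxa[j]})"
                )
            values[i, j] = int(cell)
    zero = np.flatnonzero(values.sum(axis=1) == 0)
    if zero.size:
        raise ValueError(f"all-zero rows for characters: {[char_ids[i] for i in zero]}")
    return PAPMatrix(char_ids, taxa, values)


def write_pap_matrix(pap: PAPMatrix, path) -> None:
    df = pd.DataFrame(pap.values, index=pap.char_ids, columns=pap.taxa)
    df.index.name = "character"
    df.to_csv(path, sep=_sep(path), encoding="utf-8")


# ---------------------------------------------------------------------------
# Cognate tables
# ---------------------------------------------------------------------------

def read_cognate_table(path) -> CognateTable:
    """Read long-format records: columns concept, taxon, class [, loan]."""
    df = pd.read_csv(path, sep=_sep(path), dtype=str, encoding="utf-8")
    if "loan" in df.columns:
        df["loan"] = df["loan"].fillna("0").str.lower().isin(("1", "true", "yes"))
    return CognateTable(df)


def cognate_table_to_pap(table: CognateTable) -> PAPMatrix:
    """One binary character per (concept, class) pair over the union of taxa.

    The entry for a taxon is 1 iff it has at least one record in that class;
    character ids are ``concept:class``.  Loan flags are annotations only and
    never change the presence values.
    """
    df = table.records
    if df.empty:
        raise ValueError("empty cognate table")
    taxa = sorted(df["taxon"].unique())
    col = {t: j for j, t in enumerate(taxa)}
    keys = sorted(set(zip(df["concept"], df["class"])))
    row = {k: i for i, k in enumerate(keys)}
    values = np.zeros((len(keys), len(taxa)), dtype=np.uint8)
    for _, rec in df.iterrows():
        values[row[(rec["concept"], rec["class"])], col[rec["taxon"]]] = 1
    char_ids = [f"{concept}:{cls}" for concept, cls in keys]
    return PAPMatrix(char_ids, taxa, values)


# ---------------------------------------------------------------------------
# Scenario reports
# ---------------------------------------------------------------------------

def write_scenario_report(scenarios, tree: ReferenceTree, path) -> None:
    """One row per character: origins (primary first), losses, borrowings."""
    if isinstance(scenarios, dict):
        scenarios = list(scenarios.values())
    rows = []
    for sc in scenarios:
        rows.append(
            {
                "character": sc.char_id,
                "n_origins": sc.n_origins,
                "origins": ",".join(tree.label(o) for o in sc.origins),
                "n_losses": len(sc.losses),
                "losses": ",".join(tree.label(l) for l in sorted(sc.losses)),
                "n_borrowings": sc.n_borrowings,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep=_sep(path), index=False, encoding="utf-8")


# ---------------------------------------------------------------------------
# Network exports
# ---------------------------------------------------------------------------

@dataclass
class NetworkExport:
    """Flat node/edge tables of an MLN, ready for writing."""

    nodes: pd.DataFrame  # id, kind, inventory
    edges: pd.DataFrame  # source, target, weight, kind

    def __post_init__(self) -> None:
        lateral = self.edges[self.edges["kind"] == "lateral"]
        if (lateral["weight"] <= 0).any():
            raise ValueError("lateral edge weights must be positive")


def network_export(net) -> NetworkExport:
    """Build the export tables from a LateralNetwork."""
    tree = net.tree
    nodes = pd.DataFrame(
        {
            "id": [tree.label(v) for v in range(tree.n_nodes)],
            "kind": ["external" if tree.is_leaf[v] else "internal" for v in range(tree.n_nodes)],
            "inventory": net.inventory.sizes,
        }
    )
    rows = []
    for v in range(tree.n_nodes - 1):
        rows.append(
            {
                "source": tree.label(v),
                "target": tree.label(int(tree.parent[v])),
                "weight": 1,
                "kind": "vertical",
            }
        )
    for (i, j), w in sorted(net.weights.items()):
        rows.append(
            {"source": tree.label(i), "target": tree.label(j), "weight": int(w), "kind": "lateral"}
        )
    return NetworkExport(nodes, pd.DataFrame(rows))


def write_network(export: NetworkExport, path, format: str = "graphml") -> None:
    """Write a network export as GraphML or a weighted edge list (TSV)."""
    if format == "graphml":
        import networkx as nx

        g = nx.Graph()
        for _, r in export.nodes.iterrows():
            g.add_node(r["id"], kind=r["kind"], inventory=int(r["inventory"]))
        for _, r in export.edges.iterrows():
            g.add_edge(r["source"], r["target"], weight=int(r["weight"]), kind=r["kind"])
        nx.write_graphml(g, path)
    elif format == "edgelist":
        export.edges.to_csv(path, sep="\t", index=False, encoding="utf-8")
    else:
        raise ValueError(f"unsupported network format: {format!r}")


def read_network_edgelist(path) -> pd.DataFrame:
    """Read back an edge-list export (source, target, weight, kind)."""
    df = pd.read_csv(path, sep="\t", dtype={"source": str, "target": str}, encoding="utf-8")
    required = {"source", "target", "weight", "kind"}
    if not required.issubset(df.columns):
        raise ValueError(f"edge list needs columns {sorted(required)}")
    return df


# ---------------------------------------------------------------------------
# Small table writers used by the CLI
# ---------------------------------------------------------------------------

def write_shared_matrix(shared, path) -> None:
    df = shared.to_frame()
    df.index.name = "taxon"
    df.to_csv(path, sep=_sep(path), encoding="utf-8")


def write_communities(partition, path) -> None:
    rows = [{"taxon": t, "module": m} for t, m in partition.membership.items()]
    pd.DataFrame(rows).to_csv(path, sep=_sep(path), index=False, encoding="utf-8")
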