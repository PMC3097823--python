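"""Core domain types: reference trees, presence/absence matrices, models, scenarios.

The reference tree is stored in postorder: node ids are the postorder positions
``0 .. n_nodes-1``, the root is the last id, and the subtree of node ``v`` is the
contiguous id range ``first_descendant[v] .. v``.  Leaves appear in left-to-right
postorder and map one-to-one onto the columns of a :class:`PAPMatrix` aligned to
the tree, which makes per-character presence counts a single prefix-sum.
"""

from __future__ import annotations

from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ModelSpec",
    "LO",
    "SO",
    "BOR1",
    "BOR3",
    "BOR7",
    "BOR15",
    "MODEL_LADDER",
    "MODELS",
    "ReferenceTree",
    "PAPMatrix",
    "CognateTable",
    "GainLossScenario",
    "InventoryProfile",
    "mrca",
    "resolve_and_validate",
]


# ---------------------------------------------------------------------------
# Borrowing-allowance models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelSpec:
    """A borrowing-allowance model: at most ``max_origins`` character origins.

    ``LO`` forces the single origin to the tree root; ``SO`` places it at the
    most recent common ancestor of the present taxa; ``BOR1/3/7/15`` allow
    2/4/8/16 origins, of which one is the primary origin and the rest are
    borrowings.
    """

    name: str
    max_origins: int
    root_forced: bool = False

    def __post_init__(self) -> None:
        if self.max_origins not in (1, 2, 4, 8, 16):
            raise ValueError(f"max_origins must be in {{1,2,4,8,16}}, got {self.max_origins}")
        if self.root_forced and self.max_origins != 1:
            raise ValueError("a root-forced model must have max_origins == 1")


LO = ModelSpec("LO", 1, root_forced=True)
SO = ModelSpec("SO", 1)
BOR1 = ModelSpec("BOR1", 2)
BOR3 = ModelSpec("BOR3", 4)
BOR7 = ModelSpec("BOR7", 8)
BOR15 = ModelSpec("BOR15", 16)

#: Models ordered by increasing borrowing allowance (the model-selection ladder).
MODEL_LADDER: tuple[ModelSpec, ...] = (LO, SO, BOR1, BOR3, BOR7, BOR15)
MODELS: dict[str, ModelSpec] = {m.name: m for m in MODEL_LADDER}


# ---------------------------------------------------------------------------
# Reference tree
# ---------------------------------------------------------------------------

class _BuildNode:
    """Mutable node used only while assembling a ReferenceTree."""

    __slots__ = ("label", "children")

    def __init__(self, label: str | None = None, children: Iterable["_BuildNode"] | None = None):
        self.label = label
        self.children: list[_BuildNode] = list(children or [])


class ReferenceTree:
    """Rooted tree over named taxa; hosts contemporary (leaf) and ancestral nodes.

    Internal nodes without an input label receive the stable name ``N<postorder
    index>``.  Trees may be multifurcating at construction;
    :func:`resolve_and_validate` produces the binary form required by the
    origin–loss algorithms.
    """

    def __init__(self, root: _BuildNode):
        root = _suppress_unary(root)
        # postorder traversal (iterative, preserving child order)
        order: list[_BuildNode] = []
        stack: list[tuple[_BuildNode, bool]] = [(root, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
                order.append(node)
            else:
                stack.append((node, True))
                for child in reversed(node.children):
                    stack.append((child, False))
        n_nodes = len(order)
        index = {id(node): i for i, node in enumerate(order)}

        self.parent = np.full(n_nodes, -1, dtype=np.int64)
        self.children: list[tuple[int, ...]] = [()] * n_nodes
        self.is_leaf = np.zeros(n_nodes, dtype=bool)
        self._auto_label = np.zeros(n_nodes, dtype=bool)
        labels: list[str] = [""] * n_nodes
        for i, node in enumerate(order):
            self.children[i] = tuple(index[id(c)] for c in node.children)
            for c in self.children[i]:
                self.parent[c] = i
            if not node.children:
                self.is_leaf[i] = True
                if not node.label:
                    raise ValueError("leaf without a label")
                labels[i] = node.label
            elif node.label:
                labels[i] = node.label
            else:
                labels[i] = f"N{i}"
                self._auto_label[i] = True

        leaf_ids = np.flatnonzero(self.is_leaf)
        if leaf_ids.size < 2:
            raise ValueError("a reference tree needs at least two leaves")
        taxa = [labels[i] for i in leaf_ids]
        if len(set(taxa)) != len(taxa):
            dupes = sorted({t for t in taxa if taxa.count(t) > 1})
            raise ValueError(f"duplicate leaf labels: {dupes}")
        if len(set(labels)) != len(labels):
            dupes = sorted({t for t in labels if labels.count(t) > 1})
            raise ValueError(f"duplicate node labels: {dupes}")

        self.labels = labels
        self.taxa: list[str] = taxa              # leaf labels in postorder (= column) order
        self._leaf_ids = leaf_ids                # node id of column j is _leaf_ids[j]
        self._node_of_label = {lab: i for i, lab in enumerate(labels)}

        # subtree of v = postorder range [first_descendant[v], v];
        # its leaves = column range [leaf_lo[v], leaf_hi[v])
        first = np.arange(n_nodes)
        leaf_lo = np.zeros(n_nodes, dtype=np.int64)
        leaf_hi = np.zeros(n_nodes, dtype=np.int64)
        leaf_counter = 0
        for v in range(n_nodes):
            if self.is_leaf[v]:
                leaf_lo[v] = leaf_counter
                leaf_counter += 1
                leaf_hi[v] = leaf_counter
            else:
                kids = self.children[v]
                first[v] = first[kids[0]]
                leaf_lo[v] = leaf_lo[kids[0]]
                leaf_hi[v] = leaf_hi[kids[-1]]
        self.first_descendant = first
        self.leaf_lo = leaf_lo
        self.leaf_hi = leaf_hi

        depth = np.zeros(n_nodes, dtype=np.int64)
        for v in range(n_nodes - 2, -1, -1):
            depth[v] = depth[self.parent[v]] + 1
        self.depth = depth

    # -- basic accessors ----------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    @property
    def n_leaves(self) -> int:
        return len(self.taxa)

    @property
    def root(self) -> int:
        return self.n_nodes - 1

    @property
    def is_binary(self) -> bool:
        return all(len(c) in (0, 2) for c in self.children)

    @property
    def leaf_ids(self) -> np.ndarray:
        """Node ids of the leaves, in column order."""
        return self._leaf_ids

    def label(self, v: int) -> str:
        return self.labels[v]

    def node(self, label: str) -> int:
        try:
            return self._node_of_label[label]
        except KeyError:
            raise KeyError(f"unknown node label: {label!r}") from None

    def leaf_column(self, taxon: str) -> int:
        v = self.node(taxon)
        if not self.is_leaf[v]:
            raise KeyError(f"{taxon!r} is not a leaf")
        return int(self.leaf_lo[v])

    def subtree(self, v: int) -> range:
        """All node ids in the subtree rooted at ``v`` (postorder range)."""
        return range(int(self.first_descendant[v]), v + 1)

    def is_ancestor(self, a: int, b: int) -> bool:
        """True iff ``a`` is an ancestor of ``b`` or equal to it."""
        return self.first_descendant[a] <= b <= a

    def leafset_mask(self, v: int) -> np.ndarray:
        mask = np.zeros(self.n_leaves, dtype=bool)
        mask[self.leaf_lo[v]:self.leaf_hi[v]] = True
        return mask

    def subtree_leaf_count(self, v: int) -> int:
        return int(self.leaf_hi[v] - self.leaf_lo[v])

    # -- per-character machinery --------------------------------------------

    def present_counts(self, row: np.ndarray) -> np.ndarray:
        """Number of present leaves under every node, for one 0/1 row.

        ``row`` must be aligned to :attr:`taxa`.  O(n_nodes) via a prefix sum
        over the postorder leaf layout.
        """
        row = np.asarray(row)
        if row.shape != (self.n_leaves,):
            raise ValueError("row length does not match the number of leaves")
        vals = np.zeros(self.n_nodes, dtype=np.int64)
        vals[self._leaf_ids] = row.astype(np.int64)
        prefix = np.concatenate(([0], np.cumsum(vals)))
        return prefix[np.arange(self.n_nodes) + 1] - prefix[self.first_descendant]

    def mrca_of_mask(self, mask: np.ndarray) -> int:
        """Lowest node whose leaf set covers every True column of ``mask``."""
        m = int(np.sum(mask))
        if m == 0:
            raise ValueError("mrca of an empty leaf set is undefined")
        cnt = self.present_counts(mask)
        return int(np.argmax(cnt == m))  # first postorder hit is the lowest cover

    # -- reconstruction helpers ---------------------------------------------

    def _to_build(self) -> _BuildNode:
        # keep explicit internal labels, drop auto-assigned N<idx> ones
        nodes = [
            _BuildNode(None if self._auto_label[v] else self.labels[v])
            for v in range(self.n_nodes)
        ]
        for v in range(self.n_nodes):
            nodes[v].children = [nodes[c] for c in self.children[v]]
        return nodes[self.root]

    def with_leaf_labels(self, mapping: dict[str, str]) -> "ReferenceTree":
        """Same topology with leaf labels replaced via ``mapping``."""
        build = self._to_build()

        def rename(node: _BuildNode) -> None:
            if not node.children:
                node.label = mapping[node.label]
            for c in node.children:
                rename(c)

        rename(build)
        return ReferenceTree(build)

    def newick(self) -> str:
        """Newick string (no branch lengths; auto internal names omitted)."""

        def fmt(label: str) -> str:
            if any(ch in label for ch in "();:, '\t"):
                return "'" + label.replace("'", "''") + "'"
            return label

        def render(v: int) -> str:
            if self.is_leaf[v]:
                return fmt(self.labels[v])
            inner = ",".join(render(c) for c in self.children[v])
            lab = "" if self._auto_label[v] else fmt(self.labels[v])
            return f"({inner})" + lab

        return render(self.root) + ";"

    def topology_signature(self):
        """Nested tuple of labels; equal signatures mean equal trees."""

        def sig(v: int):
            if self.is_leaf[v]:
                return self.labels[v]
            return tuple(sig(c) for c in self.children[v])

        return sig(self.root)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"<ReferenceTree {self.n_leaves} leaves, {self.n_nodes} nodes>"


def _suppress_unary(root: _BuildNode) -> _BuildNode:
    """Collapse nodes with exactly one child (keeps the deeper node's label)."""

    def collapse(node: _BuildNode) -> _BuildNode:
        while len(node.children) == 1:
            child = node.children[0]
            if child.label is None:
                child.label = node.label
            node = child
        node.children = [collapse(c) for c in node.children]
        return node

    return collapse(root)


def resolve_and_validate(tree: ReferenceTree) -> ReferenceTree:
    """Return a binary version of ``tree``; validates node-count bookkeeping.

    Polytomies are resolved deterministically into a left-leaning caterpillar in
    input child order, which preserves every clade present in the input.
    """
    build = tree._to_build()

    def resolve(node: _BuildNode) -> None:
        for c in node.children:
            resolve(c)
        while len(node.children) > 2:
            merged = _BuildNode(None, node.children[:2])
            node.children = [merged] + node.children[2:]

    resolve(build)
    out = ReferenceTree(build)
    if out.n_nodes != 2 * out.n_leaves - 1:
        raise AssertionError("binary tree bookkeeping failed")  # pragma: no cover
    if set(out.taxa) != set(tree.taxa):
        raise AssertionError("leaf set changed during resolution")  # pragma: no cover
    return out


def mrca(tree: ReferenceTree, leaves: Iterable[str]) -> int:
    """Lowest node whose descendant leaves include every taxon in ``leaves``."""
    leaves = list(leaves)
    if not leaves:
        raise ValueError("mrca of an empty taxon set is undefined")
    mask = np.zeros(tree.n_leaves, dtype=bool)
    for name in leaves:
        mask[tree.leaf_column(name)] = True
    return tree.mrca_of_mask(mask)


# ---------------------------------------------------------------------------
# Presence/absence matrix
# ---------------------------------------------------------------------------

@dataclass
class PAPMatrix:
    """Binary characters x taxa matrix (one row per cognate set / gene family)."""

    char_ids: list[str]
    taxa: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != (len(self.char_ids), len(self.taxa)):
            raise ValueError("matrix shape does not match character/taxon lists")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("PAP values must be exactly 0 or 1")
        self.values = self.values.astype(np.uint8)
        zero = np.flatnonzero(self.values.sum(axis=1) == 0)
        if zero.size:
            bad = [self.char_ids[i] for i in zero]
            raise ValueError(f"all-zero rows are not allowed: {bad}")
        if len(set(self.char_ids)) != len(self.char_ids):
            raise ValueError("duplicate character ids")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxa")
        self._col = {t: j for j, t in enumerate(self.taxa)}
        self._row = {c: i for i, c in enumerate(self.char_ids)}

    @property
    def n_characters(self) -> int:
        return len(self.char_ids)

    def row(self, char_id: str) -> np.ndarray:
        return self.values[self._row[char_id]]

    def column_sums(self) -> np.ndarray:
        return self.values.sum(axis=0)

    def aligned_values(self, taxa_order: Sequence[str]) -> np.ndarray:
        """Columns permuted into ``taxa_order``; taxa sets must match exactly."""
        if set(taxa_order) != set(self.taxa):
            missing = sorted(set(taxa_order) ^ set(self.taxa))
            raise ValueError(f"taxa do not match the tree leaf set; differing: {missing}")
        perm = [self._col[t] for t in taxa_order]
        return self.values[:, perm]


@dataclass
class CognateTable:
    """Long-format cognate/gene-family class records.

    Each record assigns one taxon's word (or gene) for a concept/family to a
    cognate class; an optional loan flag marks known borrowings.  Records are
    deduplicated on (concept, taxon, class); the loan flag never alters
    presence/absence values downstream.
    """

    records: "object"  # pandas.DataFrame with columns concept, taxon, class, loan

    def __post_init__(self) -> None:
        import pandas as pd

        df = pd.DataFrame(self.records)
        required = {"concept", "taxon", "class"}
        if not required.issubset(df.columns):
            raise ValueError(f"cognate table needs columns {sorted(required)}")
        if "loan" not in df.columns:
            df["loan"] = False
        df["loan"] = df["loan"].astype(bool)
        for col in ("concept", "taxon", "class"):
            df[col] = df[col].astype(str)
            if (df[col].str.len() == 0).any():
                raise ValueError(f"empty values in column {col!r}")
        df = df.drop_duplicates(subset=["concept", "taxon", "class"]).reset_index(drop=True)
        self.records = df

    @property
    def known_borrowings(self) -> list[tuple[str, str]]:
        """(character id, taxon) pairs for records flagged as loans."""
        df = self.records
        flagged = df[df["loan"]]
        return [(f"{r.concept}:{r['class']}", r.taxon) for _, r in flagged.iterrows()]


# ---------------------------------------------------------------------------
# Scenarios and inventories
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GainLossScenario:
    """Origin–loss explanation of one character on a reference tree.

    ``origins[0]`` is the primary origin; every further origin is a borrowing.
    ``sibling_pairs`` records, for each split performed during BOR-k inference,
    the pair of origins that the split produced — these pairs become the
    lateral edges of the MLN (intermediate origins that were themselves split
    later still carry their edge, linking ancestral nodes).
    """

    char_id: str
    origins: tuple[int, ...]
    losses: frozenset[int]
    sibling_pairs: tuple[tuple[int, int], ...] = ()

    @property
    def n_origins(self) -> int:
        return len(self.origins)

    @property
    def n_borrowings(self) -> int:
        return len(self.origins) - 1


@dataclass
class InventoryProfile:
    """Per-node inventory sizes (characters present at each node)."""

    tree: ReferenceTree
    sizes: np.ndarray

    def __post_init__(self) -> None:
        self.sizes = np.asarray(self.sizes, dtype=np.int64)
        if self.sizes.shape != (self.tree.n_nodes,):
            raise ValueError("sizes must have one entry per tree node")
        if (self.sizes < 0).any():
            raise ValueError("inventory sizes must be non-negative")

    @property
    def ancestral(self) -> np.ndarray:
        """Inventory sizes of the internal nodes (root included)."""
        return self.sizes[~self.tree.is_leaf]

    @property
    def contemporary(self) -> np.ndarray:
        """Inventory sizes of the leaves, in taxa (column) order."""
        return self.sizes[self.tree.leaf_ids]

    def size_of(self, label: str) -> int:
        return int(self.sizes[self.tree.node(label)])
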