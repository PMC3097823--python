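"""Gain–loss–borrowing simulation of binary characters on a reference tree.

Each character originates at a node drawn from the stationary gain–loss
distribution (weight 1 at the root, weight ``q`` at every other node, the
unique choice that keeps the expected inventory size equal at every node when
there is no borrowing) and is inherited vertically, with each branch losing
the character independently with probability ``q``.  A Poisson(``lam``) number of borrowing events then each
copy the character to a uniformly chosen node not yet carrying it (internal
recipients model ancestral transfers), after which presence again propagates
down with the same loss process.  All events are logged as ground truth and
replay deterministically to the emitted presence/absence matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_model import PAPMatrix, ReferenceTree, _BuildNode

__all__ = [
    "CharTruth",
    "SimTruth",
    "simulate_pap",
    "replay_truth",
    "reinsert_borrowings",
    "sample_cross_clade_insertions",
    "randomize_tree_labels",
    "random_yule_tree",
    "model_recovery_trial",
    "reinsertion_recovery_trial",
]


@dataclass(frozen=True)
class CharTruth:
    """Ground truth for one simulated character.

    ``propagation_losses[0]`` holds the loss nodes drawn while propagating
    from the true origin; entry ``i+1`` those drawn while propagating from
    borrowing recipient ``borrowings[i]``.  Replay must respect this event
    order: presence is monotone (never removed by later events) and a loss
    node only blocks the propagation that drew it.
    """

    origin: int
    borrowings: tuple[int, ...]
    propagation_losses: tuple[frozenset, ...]

    @property
    def n_borrowings(self) -> int:
        return len(self.borrowings)

    @property
    def loss_nodes(self) -> frozenset:
        out: set[int] = set()
        for s in self.propagation_losses:
            out |= s
        return frozenset(out)


@dataclass
class SimTruth:
    """Ground truth of a simulation run (aligned with the PAP row order)."""

    seed: int | None
    n_characters: int
    loss_prob: float
    borrow_rate: float
    chars: list[CharTruth]

    @property
    def mean_borrowings(self) -> float:
        return float(np.mean([c.n_borrowings for c in self.chars]))


def _propagate(tree: ReferenceTree, source: int, carriers: np.ndarray, rng, q: float) -> frozenset:
    """Mark carriers below ``source``; returns loss nodes drawn on the way."""
    lost: set[int] = set()
    carriers[source] = True
    stack = [source]
    while stack:
        v = stack.pop()
        for c in tree.children[v]:
            if rng.random() < q:
                lost.add(int(c))
            else:
                carriers[c] = True
                stack.append(int(c))
    return frozenset(lost)


def _replay_char(tree: ReferenceTree, truth: CharTruth) -> np.ndarray:
    """Deterministic node-presence replay of one character's event log."""
    carriers = np.zeros(tree.n_nodes, dtype=bool)
    for source, losses in zip((truth.origin,) + truth.borrowings, truth.propagation_losses):
        carriers[source] = True
        stack = [source]
        while stack:
            v = stack.pop()
            for c in tree.children[v]:
                if c not in losses:
                    carriers[c] = True
                    stack.append(int(c))
    return carriers


def simulate_pap(
    tree: ReferenceTree,
    n_characters: int,
    q: float,
    lam: float,
    seed: int | np.random.Generator | None = None,
    prefix: str = "char",
) -> tuple[PAPMatrix, SimTruth]:
    """Simulate ``n_characters`` binary characters; returns (PAP, ground truth).

    ``q`` is the per-branch loss probability, ``lam`` the expected number of
    borrowing events per character.  Characters absent from every leaf are
    redrawn, so all emitted rows are non-empty.
    """
    if not (0 <= q < 1):
        raise ValueError("loss probability must be in [0, 1)")
    if lam < 0:
        raise ValueError("borrowing rate must be non-negative")
    if n_characters < 1:
        raise ValueError("need at least one character")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    seed_val = seed if isinstance(seed, (int, np.integer)) else None

    # stationary origin distribution: weight 1 at the root, q elsewhere, so the
    # expected inventory size is the same at every node when lam == 0
    origin_w = np.full(tree.n_nodes, q, dtype=float)
    origin_w[tree.root] = 1.0
    origin_w /= origin_w.sum()

    rows = np.zeros((n_characters, tree.n_leaves), dtype=np.uint8)
    chars: list[CharTruth] = []
    for i in range(n_characters):
        while True:
            origin = int(rng.choice(tree.n_nodes, p=origin_w))
            carriers = np.zeros(tree.n_nodes, dtype=bool)
            losses = [_propagate(tree, origin, carriers, rng, q)]
            recipients: list[int] = []
            for _ in range(int(rng.poisson(lam))):
                candidates = np.flatnonzero(~carriers)
                if candidates.size == 0:
                    break
                recipient = int(rng.choice(candidates))
                recipients.append(recipient)
                losses.append(_propagate(tree, recipient, carriers, rng, q))
            leaf_presence = carriers[tree.leaf_ids]
            if leaf_presence.any():
                break
        rows[i] = leaf_presence
        chars.append(CharTruth(origin, tuple(recipients), tuple(losses)))

    pap = PAPMatrix([f"{prefix}{i:04d}" for i in range(n_characters)], list(tree.taxa), rows)
    truth = SimTruth(seed_val, n_characters, q, lam, chars)
    return pap, truth


def replay_truth(tree: ReferenceTree, truth: SimTruth) -> np.ndarray:
    """Leaf presence matrix reconstructed from the event logs alone."""
    out = np.zeros((len(truth.chars), tree.n_leaves), dtype=np.uint8)
    for i, char in enumerate(truth.chars):
        out[i] = _replay_char(tree, char)[tree.leaf_ids]
    return out


def reinsert_borrowings(pap: PAPMatrix, known: list[tuple[str, str]]) -> PAPMatrix:
    """Set the listed (character, taxon) cells to present (idempotent)."""
    values = pap.values.copy()
    for char_id, taxon in known:
        if char_id not in pap._row:
            raise ValueError(f"unknown character: {char_id!r}")
        if taxon not in pap._col:
            raise ValueError(f"unknown taxon: {taxon!r}")
        values[pap._row[char_id], pap._col[taxon]] = 1
    return PAPMatrix(list(pap.char_ids), list(pap.taxa), values)


def sample_cross_clade_insertions(
    tree: ReferenceTree,
    pap: PAPMatrix,
    n_insertions: int,
    seed: int | np.random.Generator | None = None,
) -> list[tuple[str, str]]:
    """Sample (character, taxon) pairs with the taxon outside the character's clade.

    Eligible characters have a single-origin (SO) clade smaller than the whole
    tree, so at least one absent taxon lies outside it — emulating the
    reinsertion of known borrowings into otherwise tree-like characters.
    """
    from .origin_loss import infer_SO

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    values = pap.aligned_values(tree.taxa)
    eligible: list[tuple[str, list[str]]] = []
    for i, cid in enumerate(pap.char_ids):
        origin = infer_SO(tree, values[i], cid).origins[0]
        if origin == tree.root:
            continue
        inside = set(range(tree.leaf_lo[origin], tree.leaf_hi[origin]))
        outside = [tree.taxa[j] for j in range(tree.n_leaves) if j not in inside]
        if outside:
            eligible.append((cid, outside))
    if len(eligible) < n_insertions:
        raise ValueError("not enough characters with a proper clade to sample from")
    picks = rng.choice(len(eligible), size=n_insertions, replace=False)
    out = []
    for k in picks:
        cid, outside = eligible[int(k)]
        out.append((cid, str(outside[int(rng.integers(len(outside)))])))
    return out


def randomize_tree_labels(
    tree: ReferenceTree, seed: int | np.random.Generator | None = None
) -> ReferenceTree:
    """Permute the leaf labels uniformly at random; topology unchanged."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    perm = rng.permutation(tree.n_leaves)
    mapping = {tree.taxa[i]: tree.taxa[perm[i]] for i in range(tree.n_leaves)}
    return tree.with_leaf_labels(mapping)


def random_yule_tree(
    n_leaves: int,
    seed: int | np.random.Generator | None = None,
    prefix: str = "L",
) -> ReferenceTree:
    """Random binary topology grown by uniform leaf splitting (Yule process)."""
    if n_leaves < 2:
        raise ValueError("need at least two leaves")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    root = _BuildNode(None, [_BuildNode("t0"), _BuildNode("t1")])
    leaves = list(root.children)
    for k in range(2, n_leaves):
        target = leaves[int(rng.integers(len(leaves)))]
        left = _BuildNode(target.label)
        right = _BuildNode(f"t{k}")
        target.label = None
        target.children = [left, right]
        leaves.remove(target)
        leaves.extend([left, right])
    # final deterministic names in left-to-right order
    width = len(str(n_leaves))
    counter = [0]

    def rename(node: _BuildNode) -> None:
        if not node.children:
            node.label = f"{prefix}{counter[0]:0{width}d}"
            counter[0] += 1
        for c in node.children:
            rename(c)

    rename(root)
    return ReferenceTree(root)


# ---------------------------------------------------------------------------
# Canned validation experiments (shared by the test suite and the
# acceptance script)
# ---------------------------------------------------------------------------

def model_recovery_trial(
    seed: int,
    lam: float,
    n_leaves: int = 32,
    n_characters: int = 500,
    q: float = 0.05,
    alpha: float = 0.05,
    randomize_labels: bool = False,
):
    """One replicate of the borrowing-rate recovery experiment.

    Simulates characters at borrowing rate ``lam`` on a fresh random Yule
    tree, optionally randomizes the tree's leaf labels (the robustness
    control), and runs model selection.  Returns the ModelSelectionResult.
    """
    from .origin_loss import select_model

    rng = np.random.default_rng(seed)
    tree = random_yule_tree(n_leaves, rng)
    pap, _ = simulate_pap(tree, n_characters, q, lam, rng)
    if randomize_labels:
        tree = randomize_tree_labels(tree, rng)
    return select_model(tree, pap, alpha=alpha)


def reinsertion_recovery_trial(
    seed: int,
    n_leaves: int = 32,
    n_characters: int = 500,
    q: float = 0.05,
    lam: float = 0.6,
    n_insertions: int = 60,
):
    """One replicate of the reinserted-borrowing detection experiment.

    Simulates characters under the accepted borrowing regime and reinserts a
    borrowing into each sampled character at a recipient node drawn outside
    the character's clade: a leaf recipient adds one presence cell (a recent
    borrowing), an internal recipient adds its whole leaf clade (an ancestral
    borrowing).  One descendant language per insertion is tracked as the known
    borrowing and classified from re-inferred BOR1 scenarios.  Returns the
    summary dict from ``validate_known_borrowings``.
    """
    from .core_model import BOR1
    from .mln import validate_known_borrowings
    from .origin_loss import infer_SO, infer_scenarios

    rng = np.random.default_rng(seed)
    tree = random_yule_tree(n_leaves, rng)
    pap, _ = simulate_pap(tree, n_characters, q, lam, rng)
    values = pap.aligned_values(tree.taxa)

    eligible = []
    for i, cid in enumerate(pap.char_ids):
        origin = infer_SO(tree, values[i], cid).origins[0]
        # recipients whose subtree is disjoint from the origin clade
        outside = [
            v
            for v in range(tree.n_nodes)
            if not tree.is_ancestor(origin, v) and not tree.is_ancestor(v, origin)
        ]
        if outside:
            eligible.append((cid, outside))
    if len(eligible) < n_insertions:
        raise ValueError("not enough characters with a proper clade to sample from")

    cells: list[tuple[str, str]] = []
    known: list[tuple[str, str]] = []
    for k in rng.choice(len(eligible), size=n_insertions, replace=False):
        cid, outside = eligible[int(k)]
        recipient = int(outside[int(rng.integers(len(outside)))])
        leaves = [tree.taxa[j] for j in range(tree.leaf_lo[recipient], tree.leaf_hi[recipient])]
        cells.extend((cid, t) for t in leaves)
        known.append((cid, leaves[int(rng.integers(len(leaves)))]))

    edited = reinsert_borrowings(pap, cells)
    scenarios = infer_scenarios(tree, edited, BOR1)
    _, summary = validate_known_borrowings(tree, scenarios, known)
    return summary
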