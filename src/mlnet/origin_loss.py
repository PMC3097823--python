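"""Origin–loss parsimony under bounded borrowing allowances (LO/SO/BOR-k).

For each binary character on a rooted binary reference tree:

* **LO** (loss-only) roots the single origin at the tree root; every maximal
  clade in which the character is absent receives one loss event at its root.
* **SO** (single origin) places the origin at the most recent common ancestor
  of the taxa carrying the character; losses as in LO inside that subtree.
* **BOR-k** allows up to ``k`` extra origins (borrowings).  Starting from the
  SO origin, an origin whose subtree still contains an absent leaf is split —
  while the budget permits — into the MRCAs of the present leaves inside each
  of its two child clades; losses are then inferred per final origin subtree.

The model-selection criterion is uniformitarian: accept the smallest borrowing
allowance whose reconstructed ancestral inventory sizes are statistically
indistinguishable (Wilcoxon rank-sum) from the contemporary ones.
"""

from __future__ import annotations

from collections import Counter, deque
from dataclasses import dataclass

import numpy as np

from . import stats as _stats
from .core_model import (
    MODEL_LADDER,
    GainLossScenario,
    InventoryProfile,
    ModelSpec,
    PAPMatrix,
    ReferenceTree,
)

__all__ = [
    "infer_LO",
    "infer_SO",
    "infer_BORk",
    "infer_scenario",
    "infer_scenarios",
    "replay_row",
    "ancestral_inventory",
    "event_counts",
    "EventCounts",
    "ModelSelectionResult",
    "select_model",
]


def _as_row(tree: ReferenceTree, row) -> np.ndarray:
    row = np.asarray(row).astype(bool)
    if row.shape != (tree.n_leaves,):
        raise ValueError("row is not aligned to the tree's taxa")
    if not row.any():
        raise ValueError("a character must be present in at least one leaf")
    return row


def _losses_below(tree: ReferenceTree, cnt: np.ndarray, origin: int) -> list[int]:
    """Roots of maximal absent clades strictly below ``origin``."""
    lo = int(tree.first_descendant[origin])
    vs = np.arange(lo, origin)  # strictly below: excludes origin itself
    if vs.size == 0:
        return []
    mask = (cnt[vs] == 0) & (cnt[tree.parent[vs]] > 0)
    return [int(v) for v in vs[mask]]


def infer_LO(tree: ReferenceTree, row, char_id: str = "") -> GainLossScenario:
    """Loss-only scenario: origin at the root, minimal losses below it."""
    row = _as_row(tree, row)
    cnt = tree.present_counts(row)
    losses = _losses_below(tree, cnt, tree.root)
    return GainLossScenario(char_id, (tree.root,), frozenset(losses))


def _mrca_within(tree: ReferenceTree, cnt: np.ndarray, v: int) -> int:
    """MRCA of the present leaves inside the subtree of ``v`` (cnt[v] > 0)."""
    while not tree.is_leaf[v]:
        carriers = [c for c in tree.children[v] if cnt[c] > 0]
        if len(carriers) != 1:
            break
        v = carriers[0]
    return int(v)


def infer_SO(tree: ReferenceTree, row, char_id: str = "") -> GainLossScenario:
    """Single-origin scenario: origin at the MRCA of the present leaves."""
    row = _as_row(tree, row)
    cnt = tree.present_counts(row)
    origin = _mrca_within(tree, cnt, tree.root)
    losses = _losses_below(tree, cnt, origin)
    return GainLossScenario(char_id, (origin,), frozenset(losses))


def infer_BORk(tree: ReferenceTree, row, spec: ModelSpec, char_id: str = "") -> GainLossScenario:
    """Bounded-origin scenario with up to ``spec.max_origins`` origins.

    FIFO splitting: the queue is seeded with the SO origin; a popped origin
    whose subtree contains an absent leaf is split (if the budget allows)
    into the per-child-clade MRCAs, which are recorded as a sibling pair.
    The primary origin is the final origin reached by following the first
    child at every split of the seed origin.
    """
    if spec.max_origins < 2:
        raise ValueError("infer_BORk needs a model with max_origins >= 2")
    if not tree.is_binary:
        raise ValueError("BOR-k inference requires a binary tree; resolve it first")
    row = _as_row(tree, row)
    cnt = tree.present_counts(row)
    seed = _mrca_within(tree, cnt, tree.root)

    pending: deque[tuple[int, bool]] = deque([(seed, True)])
    final: list[tuple[int, bool]] = []
    pairs: list[tuple[int, int]] = []
    count = 1
    while pending:
        v, primary = pending.popleft()
        has_absent = tree.subtree_leaf_count(v) > cnt[v]
        if has_absent and count + 1 <= spec.max_origins:
            c1, c2 = tree.children[v]
            o1 = _mrca_within(tree, cnt, c1)
            o2 = _mrca_within(tree, cnt, c2)
            pairs.append((min(o1, o2), max(o1, o2)))
            pending.append((o1, primary))
            pending.append((o2, False))
            count += 1
        else:
            final.append((v, primary))

    ordered = [v for v, primary in final if primary] + [v for v, primary in final if not primary]
    losses: set[int] = set()
    for origin in ordered:
        losses.update(_losses_below(tree, cnt, origin))
    return GainLossScenario(char_id, tuple(ordered), frozenset(losses), tuple(pairs))


def infer_scenario(tree: ReferenceTree, row, model: ModelSpec, char_id: str = "") -> GainLossScenario:
    if model.root_forced:
        return infer_LO(tree, row, char_id)
    if model.max_origins == 1:
        return infer_SO(tree, row, char_id)
    return infer_BORk(tree, row, model, char_id)


def infer_scenarios(tree: ReferenceTree, pap: PAPMatrix, model: ModelSpec) -> dict[str, GainLossScenario]:
    """Infer one scenario per character of ``pap`` (columns aligned by name)."""
    values = pap.aligned_values(tree.taxa)
    return {
        cid: infer_scenario(tree, values[i], model, cid)
        for i, cid in enumerate(pap.char_ids)
    }


def replay_row(tree: ReferenceTree, scenario: GainLossScenario) -> np.ndarray:
    """Leaf presence obtained by replaying origins then losses down the tree."""
    present = np.zeros(tree.n_leaves, dtype=bool)
    for o in scenario.origins:
        present[tree.leaf_lo[o]:tree.leaf_hi[o]] = True
    for l in scenario.losses:
        present[tree.leaf_lo[l]:tree.leaf_hi[l]] = False
    return present


def _node_presence(tree: ReferenceTree, scenario: GainLossScenario) -> np.ndarray:
    """Boolean presence of the character at every tree node."""
    n = tree.n_nodes
    cover = np.zeros(n + 1, dtype=np.int64)
    for o in scenario.origins:
        cover[tree.first_descendant[o]] += 1
        cover[o + 1] -= 1
    blocked = np.zeros(n + 1, dtype=np.int64)
    for l in scenario.losses:
        blocked[tree.first_descendant[l]] += 1
        blocked[l + 1] -= 1
    return (np.cumsum(cover[:-1]) > 0) & (np.cumsum(blocked[:-1]) == 0)


def ancestral_inventory(
    tree: ReferenceTree,
    scenarios,
    mode: str = "presence",
    pap: PAPMatrix | None = None,
) -> InventoryProfile:
    """Inventory size per node under a scenario set.

    ``mode="presence"`` (default) counts the characters present at each node —
    origins replayed down the tree minus losses; ``mode="origins"`` counts only
    the origin events placed at the node.  If ``pap`` is given, leaf
    inventories are checked against its column sums.
    """
    if isinstance(scenarios, dict):
        scenarios = list(scenarios.values())
    sizes = np.zeros(tree.n_nodes, dtype=np.int64)
    for sc in scenarios:
        if max(sc.origins) >= tree.n_nodes:
            raise ValueError("scenario refers to nodes outside the tree")
        if mode == "presence":
            sizes += _node_presence(tree, sc)
        elif mode == "origins":
            for o in sc.origins:
                sizes[o] += 1
        else:
            raise ValueError(f"unknown inventory mode: {mode!r}")
    profile = InventoryProfile(tree, sizes)
    if pap is not None and mode == "presence":
        expected = pap.aligned_values(tree.taxa).sum(axis=0)
        if not np.array_equal(profile.contemporary, expected):
            raise AssertionError("leaf inventories disagree with PAP column sums")
    return profile


@dataclass(frozen=True)
class EventCounts:
    mean_losses: float
    mean_borrowings: float
    origin_histogram: dict[int, int]


def event_counts(scenarios) -> EventCounts:
    """Mean losses/borrowings per character and the histogram of origin counts."""
    if isinstance(scenarios, dict):
        scenarios = list(scenarios.values())
    if not scenarios:
        raise ValueError("no scenarios given")
    losses = np.array([len(sc.losses) for sc in scenarios], dtype=float)
    borrow = np.array([sc.n_borrowings for sc in scenarios], dtype=float)
    hist = Counter(sc.n_origins for sc in scenarios)
    return EventCounts(float(losses.mean()), float(borrow.mean()), dict(sorted(hist.items())))


@dataclass
class ModelSelectionResult:
    """Outcome of the uniformitarian model-selection ladder."""

    accepted: ModelSpec
    none_accepted: bool
    p_values: dict[str, float]
    iqr_fractions: dict[str, float]
    event_summary: dict[str, EventCounts]
    scenarios: dict[str, GainLossScenario]
    inventory: InventoryProfile

    def table(self):
        """Per-model report as a pandas DataFrame."""
        import pandas as pd

        rows = []
        for name in self.p_values:
            ev = self.event_summary[name]
            rows.append(
                {
                    "model": name,
                    "p_wilcoxon": self.p_values[name],
                    "iqr_fraction": self.iqr_fractions[name],
                    "mean_losses": ev.mean_losses,
                    "mean_borrowings": ev.mean_borrowings,
                    "accepted": (name == self.accepted.name) and not self.none_accepted,
                }
            )
        return pd.DataFrame(rows)


def select_model(
    tree: ReferenceTree,
    pap: PAPMatrix,
    alpha: float = 0.05,
    models: tuple[ModelSpec, ...] = MODEL_LADDER,
    mode: str = "presence",
) -> ModelSelectionResult:
    """Accept the first model whose ancestral sizes pass the Wilcoxon test.

    Models are tried in order of increasing borrowing allowance; the accepted
    model is the first with a two-sided rank-sum p > ``alpha`` when comparing
    internal-node inventory sizes with leaf inventory sizes.  If none passes,
    the last model is returned flagged ``none_accepted``.
    """
    if tree.n_nodes - tree.n_leaves < 2:
        raise ValueError("model selection needs at least two internal nodes")
    p_values: dict[str, float] = {}
    iqr_fractions: dict[str, float] = {}
    event_summary: dict[str, EventCounts] = {}
    kept: dict[str, tuple[dict[str, GainLossScenario], InventoryProfile]] = {}

    accepted: ModelSpec | None = None
    for model in models:
        scenarios = infer_scenarios(tree, pap, model)
        profile = ancestral_inventory(tree, scenarios, mode=mode, pap=pap)
        p = _stats.wilcoxon_rank_sum(profile.ancestral, profile.contemporary)
        try:
            frac = _stats.iqr_fraction(profile.ancestral, profile.contemporary)
        except ValueError:
            frac = float("nan")
        p_values[model.name] = p
        iqr_fractions[model.name] = frac
        event_summary[model.name] = event_counts(scenarios)
        kept[model.name] = (scenarios, profile)
        if accepted is None and p > alpha:
            accepted = model

    none_accepted = accepted is None
    if accepted is None:
        accepted = models[-1]
    scenarios, profile = kept[accepted.name]
    return ModelSelectionResult(
        accepted=accepted,
        none_accepted=none_accepted,
        p_values=p_values,
        iqr_fractions=iqr_fractions,
        event_summary=event_summary,
        scenarios=scenarios,
        inventory=profile,
    )
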