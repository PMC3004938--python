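"""Weighted-parsimony reconstruction of insertion/inversion/deletion events.

Each strain's locus state is one of {absent=0, canonical=1, inverted=2}.
Given a rooted strain phylogeny and a per-leaf state (or state set, for
ambiguous calls), the Sankoff dynamic programme finds an internal-state
assignment minimising the summed transition cost, with the root fixed to
"absent" by default (IS gain is the derived condition).  Transitions are
reported as per-branch events: 0->1 insertion, 1<->2 inversion, {1,2}->0
deletion, 0->2 an insertion-in-inverted-orientation (cost 2 by default, so
it is never preferred over insertion followed by inversion).

Ties in the backtrace are broken toward the lowest state index so output is
reproducible; the number of co-optimal assignments quantifies the ambiguity.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

from .errors import FormatError, ReconciliationError

STATES = {"absent": 0, "canonical": 1, "inverted": 2}
STATE_NAMES = ("absent", "canonical", "inverted")

EVENT_NAMES = {
    (0, 1): "insertion",
    (1, 2): "inversion",
    (2, 1): "inversion",
    (1, 0): "deletion",
    (2, 0): "deletion",
    (0, 2): "insertion_inverted",
}


@dataclass
class EventModel:
    """State-transition costs.  Rows = parent state, columns = child state."""

    cost: np.ndarray = field(default_factory=lambda: np.array(
        [[0.0, 1.0, 2.0],
         [1.0, 0.0, 1.0],
         [1.0, 1.0, 0.0]]))

    def validate(self) -> None:
        c = np.asarray(self.cost, dtype=float)
        if c.shape != (3, 3):
            raise ValueError("cost matrix must be 3x3")
        if np.any(np.diag(c) != 0) or np.any(c < 0):
            raise ValueError("cost matrix needs zero diagonal, no negatives")
        self.cost = c


@dataclass
class EventReconstruction:
    node_states: dict  # node label -> state index
    events: list  # [{"branch": child label, "type": ..., "from": ..., "to": ...}]
    total_cost: float
    n_co_optimal: int


def read_tree(newick: str, outgroup: str | None = None) -> dendropy.Tree:
    """Parse a newick tree (string or path) into a rooted dendropy tree.

    Leaf labels must be unique.  If ``outgroup`` is given, the tree is
    re-rooted on the edge above that leaf.
    """
    try:
        if "(" in newick:
            tree = dendropy.Tree.get(data=newick, schema="newick",
                                     preserve_underscores=True)
        else:
            tree = dendropy.Tree.get(path=newick, schema="newick",
                                     preserve_underscores=True)
    except Exception as exc:  # dendropy raises various parse errors
        raise FormatError(f"could not parse newick input: {exc}") from exc
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        raise FormatError("duplicate leaf labels in tree")
    if outgroup is not None:
        node = next((lf for lf in tree.leaf_node_iter()
                     if lf.taxon.label == outgroup), None)
        if node is None:
            raise ReconciliationError(f"outgroup {outgroup!r} not in tree")
        tree.reroot_at_edge(node.edge, update_bipartitions=False)
    i = 0
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            node.label = node.taxon.label
        elif node.label is None:
            i += 1
            node.label = f"n{i:02d}"
    return tree


def _leaf_allowed(state) -> set:
    if isinstance(state, (set, frozenset, list, tuple)):
        allowed = {int(s) for s in state}
    else:
        allowed = {int(state)}
    if not allowed or not allowed <= {0, 1, 2}:
        raise ReconciliationError(f"invalid leaf state {state!r}")
    return allowed


def reconstruct_events(tree: dendropy.Tree, leaf_states: dict,
                       model: EventModel | None = None,
                       root_state: int | None = 0) -> EventReconstruction:
    """Sankoff parsimony over a rooted tree.

    ``leaf_states`` maps every leaf label to a state index or set of indices
    (ambiguous leaves are free over their set).  ``root_state`` pins the root
    (default absent); pass ``None`` to minimise over root states too.
    """
    model = model or EventModel()
    model.validate()
    C = model.cost

    leaves = {lf.taxon.label for lf in tree.leaf_node_iter()}
    missing = leaves - leaf_states.keys()
    extra = leaf_states.keys() - leaves
    if missing or extra:
        raise ReconciliationError(
            f"leaf/state mismatch: missing states for {sorted(missing)}, "
            f"states without leaves {sorted(extra)}"
        )

    cost: dict = {}
    count: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            allowed = _leaf_allowed(leaf_states[node.taxon.label])
            vec = np.full(3, np.inf)
            cnt = np.zeros(3)
            for s in allowed:
                vec[s] = 0.0
                cnt[s] = 1
        else:
            vec = np.zeros(3)
            cnt = np.ones(3)
            for child in node.child_nodes():
                trans = C + cost[id(child)][None, :]  # [parent s, child s']
                best = trans.min(axis=1)
                nbest = np.array([
                    count[id(child)][np.isclose(trans[s], best[s])].sum()
                    for s in range(3)
                ])
                vec = vec + best
                cnt = cnt * nbest
        cost[id(node)] = vec
        count[id(node)] = cnt

    root = tree.seed_node
    root_vec = cost[id(root)]
    if root_state is None:
        total = float(root_vec.min())
        choice = int(np.flatnonzero(np.isclose(root_vec, total))[0])
        n_co = int(count[id(root)][np.isclose(root_vec, total)].sum())
    else:
        total = float(root_vec[root_state])
        if not np.isfinite(total):
            raise ReconciliationError(
                "root state constraint is infeasible for these leaf states"
            )
        choice = root_state
        n_co = int(count[id(root)][root_state])

    # deterministic backtrace, lowest state index on ties
    node_states: dict = {root.label: choice}
    assigned = {id(root): choice}
    events = []
    for node in tree.preorder_node_iter():
        s = assigned[id(node)]
        for child in node.child_nodes():
            opts = C[s] + cost[id(child)]
            sc = int(np.flatnonzero(np.isclose(opts, opts.min()))[0])
            assigned[id(child)] = sc
            node_states[child.label] = sc
            if sc != s:
                events.append({
                    "branch": child.label,
                    "type": EVENT_NAMES.get((s, sc), f"{s}->{sc}"),
                    "from": STATE_NAMES[s],
                    "to": STATE_NAMES[sc],
                })
    return EventReconstruction(
        node_states=node_states,
        events=events,
        total_cost=total,
        n_co_optimal=n_co,
    )


def annotated_newick(tree: dendropy.Tree, rec: EventReconstruction) -> str:
    """Newick string with reconstructed node states as comments."""

    def render(node) -> str:
        state = STATE_NAMES[rec.node_states[node.label]]
        blen = f":{node.edge.length}" if node.edge.length is not None else ""
        if node.is_leaf():
            return f"{node.taxon.label}[&state={state}]{blen}"
        inside = ",".join(render(c) for c in node.child_nodes())
        return f"({inside}){node.label}[&state={state}]{blen}"

    return render(tree.seed_node) + ";"
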