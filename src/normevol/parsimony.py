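"""Sankoff parsimony: minimal-change scores, MPR state sets, origin counts.

One engine — the Sankoff cost-matrix recursion — serves the three questions
asked of a discrete character on a rooted tree:

* the parsimony score (minimum number of weighted state changes);
* for every internal node, the set of states it takes in at least one
  most-parsimonious reconstruction (MPR), computed by a bottom-up cost pass
  followed by a top-down feasibility pass;
* the minimum and maximum number of independent *gains* of a derived state
  set across all MPRs, where a gain is an edge whose parent state is
  ancestral and whose child state is derived.

Reporting a (min, max) gain range rather than one ACCTRAN/DELTRAN pick keeps
the ambiguity among equally parsimonious histories explicit — the quantity
of interest when asking how many times a plastic phenotype originated.

Missing data ('?') contributes zero cost for every state; polytomies are
handled natively by the recursion.  Branch lengths are ignored.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Iterable, Mapping, Sequence

import numpy as np

from .trees import PhyloTree, TreeError

__all__ = [
    "ParsimonyResult",
    "MISSING",
    "sankoff",
    "sankoff_score",
    "mpr_sets",
    "count_origins",
    "unit_cost_matrix",
]

#: missing-state token accepted in character tables
MISSING = "?"

_INF = float("inf")


@dataclass(frozen=True)
class ParsimonyResult:
    """Full output of one Sankoff analysis.

    Attributes
    ----------
    score : float
        Minimal total change cost (an integer under unit costs).
    states : tuple
        The ordered state alphabet the matrices are indexed by.
    node_state_sets : dict[int, frozenset]
        Per node id, the states realized in at least one MPR.  Tips with
        observed states map to the singleton of their state; '?' tips may
        have larger sets.
    """

    score: float
    states: tuple
    node_state_sets: Mapping[int, frozenset]


def unit_cost_matrix(n_states: int) -> np.ndarray:
    """Unordered (Fitch-equivalent) cost matrix: 0 diagonal, 1 elsewhere."""
    c = np.ones((n_states, n_states)) - np.eye(n_states)
    return c


def _check_cost(cost: np.ndarray, n_states: int) -> np.ndarray:
    cost = np.asarray(cost, dtype=float)
    if cost.shape != (n_states, n_states):
        raise ValueError(f"cost matrix must be {n_states}x{n_states}")
    if np.any(np.diag(cost) != 0):
        raise ValueError("cost matrix diagonal must be zero")
    off = cost[~np.eye(n_states, dtype=bool)]
    if np.any(off <= 0):
        raise ValueError("off-diagonal costs must be positive")
    return cost


def _resolve_states(
    coding: Mapping[str, Hashable], states: Sequence | None
) -> tuple:
    observed = sorted(
        {s for s in coding.values() if s != MISSING}, key=repr
    )
    if states is None:
        if not observed:
            raise ValueError("all tips are missing and no state alphabet given")
        return tuple(observed)
    states = tuple(states)
    extra = [s for s in observed if s not in states]
    if extra:
        raise ValueError(f"tip states {extra} not in declared alphabet {states}")
    return states


def _check_labels(tree: PhyloTree, coding: Mapping[str, Hashable]) -> None:
    tips = set(tree.tip_labels)
    coded = set(coding)
    only_tree = sorted(tips - coded)
    only_coding = sorted(coded - tips)
    if only_tree or only_coding:
        raise TreeError(
            "tip/character label mismatch: "
            f"in tree but uncoded {only_tree}; coded but not in tree {only_coding}"
        )


def _down_pass(
    tree: PhyloTree,
    coding: Mapping[str, Hashable],
    states: tuple,
    cost: np.ndarray,
) -> np.ndarray:
    """Sankoff bottom-up costs g[v, s] = min subtree cost given state s at v."""
    k = len(states)
    idx = {s: i for i, s in enumerate(states)}
    g = np.zeros((tree.n_nodes, k))
    for v in range(tree.n_nodes):
        if tree.is_tip(v):
            s = coding[tree.tip_label[v]]
            if s != MISSING:
                g[v, :] = _INF
                g[v, idx[s]] = 0.0
        else:
            for c in tree.children[v]:
                # min over child state t of cost(s, t) + g[c, t]
                g[v, :] += np.min(cost + g[c, None, :], axis=1)
    return g


def sankoff(
    tree: PhyloTree,
    coding: Mapping[str, Hashable],
    cost: np.ndarray | None = None,
    states: Sequence | None = None,
) -> ParsimonyResult:
    """Run the full Sankoff analysis (score + per-node MPR state sets)."""
    _check_labels(tree, coding)
    states = _resolve_states(coding, states)
    k = len(states)
    cost = unit_cost_matrix(k) if cost is None else _check_cost(cost, k)
    g = _down_pass(tree, coding, states, cost)

    root = tree.root_id
    score = float(np.min(g[root]))
    # top-down feasibility: state s is in node v's MPR set iff some MPR
    # realizes it; a child's feasible states are the argmins of
    # cost(parent_state, t) + g[child, t] over its parent's feasible states
    feas: list[set[int]] = [set() for _ in range(tree.n_nodes)]
    feas[root] = set(np.flatnonzero(g[root] <= score + 1e-9))
    for v in range(tree.n_nodes - 1, -1, -1):  # preorder
        for c in tree.children[v]:
            opts: set[int] = set()
            for s in feas[v]:
                vals = cost[s] + g[c]
                m = vals.min()
                opts |= set(np.flatnonzero(vals <= m + 1e-9))
            feas[c] = opts
    sets = {
        v: frozenset(states[i] for i in feas[v]) for v in range(tree.n_nodes)
    }
    return ParsimonyResult(score=score, states=states, node_state_sets=sets)


def sankoff_score(
    tree: PhyloTree,
    coding: Mapping[str, Hashable],
    cost: np.ndarray | None = None,
    states: Sequence | None = None,
) -> float:
    """Minimal total change cost (see :func:`sankoff`)."""
    return sankoff(tree, coding, cost=cost, states=states).score


def mpr_sets(
    tree: PhyloTree,
    coding: Mapping[str, Hashable],
    cost: np.ndarray | None = None,
    states: Sequence | None = None,
) -> Mapping[int, frozenset]:
    """Per-node MPR state sets (see :func:`sankoff`)."""
    return sankoff(tree, coding, cost=cost, states=states).node_state_sets


def count_origins(
    tree: PhyloTree,
    coding: Mapping[str, Hashable],
    derived: Iterable[Hashable],
    cost: np.ndarray | None = None,
    states: Sequence | None = None,
) -> tuple[int, int]:
    """(min, max) independent origins of ``derived`` states across all MPRs.

    An origin is an edge whose parent state is outside ``derived`` and whose
    child state is inside it — a gain — or a derived state at the root
    itself (an origin at or before the root of the sampled clade).  Without
    the root term, reconstructions that push the derived state rootward
    would undercount how many times the trait arose.  The range is computed
    exactly by dynamic programming over the same optimal-substructure
    decomposition that defines the MPRs: conditional on a node's state, each
    child independently takes any of its cost-argmin states, so origin
    min/max propagate bottom-up.
    """
    _check_labels(tree, coding)
    states = _resolve_states(coding, states)
    k = len(states)
    derived = set(derived)
    if not derived <= set(states):
        raise ValueError(f"derived states {sorted(derived, key=repr)} not all in alphabet")
    if not (set(states) - derived):
        raise ValueError("ancestral state complement is empty")
    cost = unit_cost_matrix(k) if cost is None else _check_cost(cost, k)
    g = _down_pass(tree, coding, states, cost)
    is_derived = np.array([s in derived for s in states])

    # gmin/gmax[v, s]: min/max gains within v's subtree (edges below v),
    # conditional on v taking state s and the subtree being reconstructed
    # optimally.  Tips contribute 0; '?' tips behave like free nodes.
    gmin = np.zeros((tree.n_nodes, k))
    gmax = np.zeros((tree.n_nodes, k))
    for v in range(tree.n_nodes):
        if tree.is_tip(v):
            continue
        for c in tree.children[v]:
            add_min = np.empty(k)
            add_max = np.empty(k)
            for s in range(k):
                vals = cost[s] + g[c]
                m = vals.min()
                opts = np.flatnonzero(vals <= m + 1e-9)
                gains = (~is_derived[s]) & is_derived[opts]
                add_min[s] = np.min(gains + gmin[c, opts])
                add_max[s] = np.max(gains + gmax[c, opts])
            gmin[v] += add_min
            gmax[v] += add_max

    root = tree.root_id
    best = np.flatnonzero(g[root] <= g[root].min() + 1e-9)
    lo = np.min(gmin[root, best] + is_derived[best])
    hi = np.max(gmax[root, best] + is_derived[best])
    return int(round(lo)), int(round(hi))
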