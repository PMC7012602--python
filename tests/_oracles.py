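"""Independent brute-force oracles the test suite checks the package against.

Everything here enumerates or solves the small-instance problem directly,
sharing no traversal code with the package: parsimony by exhaustive
assignment enumeration, Mk likelihoods by summing over all internal-node
state assignments, Fitch's algorithm for binary trees, and BM ancestral
estimates by explicit GLS on a dendropy-re-rooted tree.
"""

from __future__ import annotations

import itertools
import math

import dendropy
import numpy as np

from normevol.mk import MkModel, transition_matrix
from normevol.parsimony import MISSING
from normevol.trees import PhyloTree


def _free_nodes(tree: PhyloTree, coding):
    """Nodes whose state is unconstrained: internal nodes and '?' tips."""
    free = list(tree.internal_ids)
    fixed = {}
    for v in tree.tip_ids:
        s = coding[tree.tip_label[v]]
        if s == MISSING:
            free.append(v)
        else:
            fixed[v] = s
    return sorted(free), fixed


def enumerate_parsimony(tree: PhyloTree, coding, states, cost=None):
    """Exhaustive parsimony: (score, node state sets, origin min/max fn).

    Returns ``(score, sets, origins)`` where ``sets`` maps node id to the
    frozenset of states seen in at least one minimum-cost assignment and
    ``origins(derived)`` gives the (min, max) origin count over those
    assignments, counting an edge gain or a derived root state as an origin.
    """
    k = len(states)
    idx = {s: i for i, s in enumerate(states)}
    if cost is None:
        cost = np.ones((k, k)) - np.eye(k)
    free, fixed = _free_nodes(tree, coding)
    best = math.inf
    assignments = []
    for combo in itertools.product(range(k), repeat=len(free)):
        state = {v: idx[s] for v, s in fixed.items()}
        state.update(dict(zip(free, combo)))
        c = sum(
            cost[state[tree.parent[v]], state[v]] for v in range(tree.n_nodes - 1)
        )
        if c < best - 1e-9:
            best = c
            assignments = [state]
        elif c <= best + 1e-9:
            assignments.append(state)

    sets = {
        v: frozenset(states[a[v]] for a in assignments)
        for v in range(tree.n_nodes)
    }

    def origins(derived):
        der = {idx[s] for s in derived}
        counts = []
        for a in assignments:
            n = sum(
                1
                for v in range(tree.n_nodes - 1)
                if a[tree.parent[v]] not in der and a[v] in der
            )
            n += a[tree.root_id] in der
            counts.append(n)
        return min(counts), max(counts)

    return best, sets, origins


def fitch_score(tree: PhyloTree, coding) -> int:
    """Fitch parsimony count (unordered states, no missing data required)."""
    sets = {}
    score = 0
    for v in range(tree.n_nodes):
        if tree.is_tip(v):
            s = coding[tree.tip_label[v]]
            sets[v] = None if s == MISSING else {s}
        else:
            cur = None
            for c in tree.children[v]:
                if sets[c] is None:
                    continue
                if cur is None:
                    cur = set(sets[c])
                else:
                    inter = cur & sets[c]
                    if inter:
                        cur = inter
                    else:
                        cur = cur | sets[c]
                        score += 1
            sets[v] = cur
    return score


def enumerate_mk_loglik(
    tree: PhyloTree, coding, model: MkModel, states, constraint=None
):
    """Mk likelihood by explicit summation over internal-node assignments.

    ``constraint`` is ``(node_id, state)`` fixing one internal node.  '?'
    tips are summed over like internal nodes.
    """
    idx = {s: i for i, s in enumerate(states)}
    k = model.n_states
    free, fixed = _free_nodes(tree, coding)
    P = {v: transition_matrix(model, tree.edge_length[v])
         for v in range(tree.n_nodes - 1)}
    prior = model.prior
    total = 0.0
    for combo in itertools.product(range(k), repeat=len(free)):
        state = {v: idx[s] for v, s in fixed.items()}
        state.update(dict(zip(free, combo)))
        if constraint is not None and state[constraint[0]] != constraint[1]:
            continue
        p = prior[state[tree.root_id]]
        for v in range(tree.n_nodes - 1):
            p *= P[v][state[tree.parent[v]], state[v]]
        total += p
    return math.log(total)


def rerooted_gls_estimates(newick: str, trait: dict):
    """BM ancestral estimates/vars by GLS after literally re-rooting the tree.

    For each internal node (identified by its tip set) the dendropy tree is
    cloned, re-rooted at that node, the tip covariance C taken as shared
    path length from the *new* root by direct traversal, and the estimate
    computed as â = (1'C⁻¹1)⁻¹ 1'C⁻¹ x with unit-rate variance (1'C⁻¹1)⁻¹.
    Returns {frozenset(tip labels): (estimate, unit_variance)}.
    """
    base = dendropy.Tree.get(
        data=newick, schema="newick", preserve_underscores=True
    )
    out = {}
    for nd in base.preorder_node_iter():
        if nd.is_leaf():
            continue
        target = frozenset(l.taxon.label for l in nd.leaf_iter())
        clone = dendropy.Tree(base)
        cn = next(
            m for m in clone.preorder_node_iter()
            if not m.is_leaf()
            and frozenset(l.taxon.label for l in m.leaf_iter()) == target
        )
        if cn.parent_node is not None:
            clone.reroot_at_node(cn, update_bipartitions=False)
        # shared path length from the new root, by traversal
        leaves = [l for l in clone.leaf_node_iter()]
        labels = [l.taxon.label for l in leaves]
        n = len(leaves)
        depth = {}
        for m in clone.preorder_node_iter():
            depth[m] = (
                0.0 if m.parent_node is None
                else depth[m.parent_node] + (m.edge.length or 0.0)
            )
        anc = {
            l: set(l.ancestor_iter(inclusive=True)) for l in leaves
        }
        C = np.empty((n, n))
        for i, a in enumerate(leaves):
            C[i, i] = depth[a]
            for j in range(i + 1, n):
                b = leaves[j]
                m = max(anc[a] & anc[b], key=depth.get)
                C[i, j] = C[j, i] = depth[m]
        x = np.array([trait[l] for l in labels])
        Cinv = np.linalg.inv(C)
        ones = np.ones(n)
        denom = ones @ Cinv @ ones
        out[target] = (float((ones @ Cinv @ x) / denom), float(1.0 / denom))
    return out


def random_tree_with_lengths(
    n_tips: int, rng: np.random.Generator, min_len=0.05, max_len=2.0,
    allow_polytomy: bool = True,
) -> PhyloTree:
    """Random topology (random coalescent-style joins) with uniform lengths."""
    taxa = [f"t{i + 1}" for i in range(n_tips)]
    nodes = [f"{t}:{rng.uniform(min_len, max_len):.6f}" for t in taxa]
    p_poly = 0.15 if allow_polytomy else 0.0
    while len(nodes) > 1:
        take = 2 if len(nodes) == 2 or rng.random() > p_poly else 3
        take = min(take, len(nodes))
        picks = [nodes.pop(int(rng.integers(len(nodes)))) for _ in range(take)]
        if len(nodes) == 0:
            nodes.append("(" + ",".join(picks) + ")")
        else:
            nodes.append(
                "(" + ",".join(picks) + f"):{rng.uniform(min_len, max_len):.6f}"
            )
    return PhyloTree.from_newick(nodes[0] + ";")


def random_coding(tree: PhyloTree, states, rng, p_missing=0.0):
    out = {}
    for lbl in tree.tip_labels:
        if p_missing and rng.random() < p_missing:
            out[lbl] = MISSING
        else:
            out[lbl] = states[int(rng.integers(len(states)))]
    return out
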