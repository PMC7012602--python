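"""Brownian-motion ancestral reconstruction of continuous traits.

Under Brownian motion with rate σ², trait values at all nodes of a rooted
tree are jointly Gaussian: each edge contributes an independent increment
with variance σ²·t.  Given tip values x, the maximum-likelihood ancestral
states are the conditional expectations of the internal node values, found
by solving one sparse linear system on the edge-weighted tree "Laplacian"
(edge weight 1/t) — the linear-time formulation used by Rphylopars'
``anc.recon``.  Equivalently, each internal node's estimate is the GLS root
estimate â = (1ᵀC⁻¹1)⁻¹·1ᵀC⁻¹x of the tree re-rooted at that node, with C
the tip covariance matrix (C_ab = shared path length from the root); the
test suite checks the two routes against each other.

σ² is estimated by ML from the tips (divide by n, not n−1; REML available),
standard errors come from the conditional variance scaled by σ̂², and each
node is classified by whether zero falls inside the normal-approximation
95 % interval estimate ± 1.96·SE — the rule used to call an ancestral
reaction-norm slope significantly non-zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .trees import PhyloTree, TreeError

__all__ = [
    "AncestralEstimate",
    "bm_ancestral_states",
    "classify_ancestral_slopes",
    "tip_covariance",
]

Z_95 = 1.959963984540054  # normal 97.5 % quantile

NEGATIVE_CAT, ZERO_CAT, POSITIVE_CAT = "negative", "zero", "positive"


@dataclass(frozen=True)
class AncestralEstimate:
    """Per-node BM reconstruction with uncertainty.

    ``table`` has one row per node of the (pruned) tree with columns
    node (postorder id), taxa (sorted tip labels below the node, ';'-joined),
    estimate, SE, ci_lo, ci_hi, category, is_tip.  ``sigma2`` is the ML (or
    REML) rate estimate; ``root_estimate`` is the reconstruction at the root.
    """

    table: pd.DataFrame
    sigma2: float
    tree: PhyloTree

    @property
    def root_estimate(self) -> float:
        return float(self.table.loc[self.table["node"] == self.tree.root_id,
                                    "estimate"].iloc[0])


def tip_covariance(tree: PhyloTree) -> tuple[list[str], np.ndarray]:
    """BM tip covariance structure: C_ab = shared path length from the root."""
    tree.require_branch_lengths("BM covariance")
    depth = tree.node_depths()
    anc: list[set[int]] = [set() for _ in range(tree.n_nodes)]
    for i in reversed(range(tree.n_nodes)):
        anc[i].add(i)
        if tree.parent[i] is not None:
            anc[i] |= anc[tree.parent[i]]
    tips = tree.tip_ids
    n = len(tips)
    C = np.empty((n, n))
    for a_i, a in enumerate(tips):
        C[a_i, a_i] = depth[a]
        for b_i in range(a_i + 1, n):
            b = tips[b_i]
            m = max(anc[a] & anc[b], key=depth.__getitem__)
            C[a_i, b_i] = C[b_i, a_i] = depth[m]
    return [tree.tip_label[i] for i in tips], C


def _laplacian_solve(tree: PhyloTree, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Conditional mean and unit-rate variance of internal values given tips.

    Builds the edge-weighted Laplacian L (weights 1/t), partitions into
    internal (I) and tip (T) blocks, and solves L_II μ = −L_IT x.  The
    conditional covariance of the internal values is σ²·L_II⁻¹; the root has
    an implicit flat prior, which makes μ the joint-ML reconstruction.
    """
    n = tree.n_nodes
    L = np.zeros((n, n))
    for v in range(n - 1):
        p = tree.parent[v]
        t = tree.edge_length[v]
        w = 1.0 / t
        L[v, v] += w
        L[p, p] += w
        L[v, p] -= w
        L[p, v] -= w
    tips = tree.tip_ids
    internal = tree.internal_ids
    LII = L[np.ix_(internal, internal)]
    LIT = L[np.ix_(internal, tips)]
    LII_inv = np.linalg.inv(LII)
    mu = LII_inv @ (-LIT @ x)
    var_unit = np.diag(LII_inv).copy()
    return mu, var_unit


def bm_ancestral_states(
    tree: PhyloTree,
    trait: Mapping[str, float],
    reml: bool = False,
    z: float = Z_95,
) -> AncestralEstimate:
    """Reconstruct ancestral values of a continuous trait under BM.

    ``trait`` maps tip labels to values; missing taxa (absent keys or NaN)
    are pruned before reconstruction, never imputed.  At least 3 scored taxa
    and strictly positive branch lengths on the induced subtree are required
    — a zero-length pendant edge would force the ancestor to equal the tip
    exactly and collapse the conditional variance.
    """
    scored = {k: float(v) for k, v in trait.items() if v == v}  # drop NaN
    extra = sorted(set(scored) - set(tree.tip_labels))
    if extra:
        raise TreeError(f"trait taxa not in tree: {extra}")
    if len(scored) < 3:
        raise ValueError("BM reconstruction needs >= 3 scored taxa")
    if set(scored) != set(tree.tip_labels):
        tree = tree.prune_to_taxa(set(scored))
    tree.require_branch_lengths("BM reconstruction")
    lens = [tree.edge_length[v] for v in range(tree.n_nodes - 1)]
    if any(t <= 0 for t in lens):
        raise ValueError(
            "BM reconstruction requires strictly positive branch lengths on "
            "the induced subtree; collapse or lengthen zero-length edges "
            "(e.g. replace hard polytomies rather than zero-length resolutions)"
        )

    tips = tree.tip_ids
    x = np.array([scored[tree.tip_label[i]] for i in tips])
    n = len(tips)

    mu_internal, var_unit = _laplacian_solve(tree, x)

    # ML / REML estimate of sigma^2 from the tips
    labels, C = tip_covariance(tree)
    Cinv = np.linalg.inv(C)
    ones = np.ones(n)
    denom = ones @ Cinv @ ones
    a_root = (ones @ Cinv @ x) / denom
    resid = x - a_root
    q = resid @ Cinv @ resid
    sigma2 = float(q / (n - 1)) if reml else float(q / n)

    internal = tree.internal_ids
    rows = []
    for j, v in enumerate(internal):
        est = float(mu_internal[j])
        se = float(np.sqrt(max(sigma2 * var_unit[j], 0.0)))
        lo, hi = est - z * se, est + z * se
        rows.append(
            dict(node=v, taxa=";".join(sorted(tree.subtree_taxa(v))),
                 estimate=est, SE=se, ci_lo=lo, ci_hi=hi,
                 category=_categorize(est, lo, hi), is_tip=False)
        )
    for v in tips:
        val = scored[tree.tip_label[v]]
        rows.append(
            dict(node=v, taxa=tree.tip_label[v], estimate=val, SE=0.0,
                 ci_lo=val, ci_hi=val, category=_categorize(val, val, val),
                 is_tip=True)
        )
    table = pd.DataFrame(rows).sort_values("node", ignore_index=True)
    return AncestralEstimate(table=table, sigma2=sigma2, tree=tree)


def _categorize(est: float, lo: float, hi: float) -> str:
    if lo <= 0.0 <= hi:
        return ZERO_CAT
    return POSITIVE_CAT if est > 0 else NEGATIVE_CAT


def classify_ancestral_slopes(est: AncestralEstimate) -> Mapping[int, str]:
    """node id → {'negative','zero','positive'}; zero iff 0 ∈ 95 % CI."""
    return dict(zip(est.table["node"], est.table["category"]))
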