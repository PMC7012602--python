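"""Equal-rates Mk likelihoods with node constraints; LRT / AICc comparisons.

The Mk model is a continuous-time Markov chain on k character states with
equal exchange rates.  We parameterize by the total leaving rate q (per unit
branch length): off-diagonal entries of the generator are q/(k−1), so

    Q = −μ (I − J/k),   μ = q·k/(k−1),   P(t) = e^{Qt} = J/k + e^{−μt}(I − J/k),

with J the all-ones matrix.  The closed form is the exact matrix
exponential; for k = 2 it reduces to P_same(t) = 1/2 + 1/2·e^{−2qt}.  The
stationary (and default root) distribution is uniform.

Hypotheses about particular ancestors are tested by *clamping* an internal
node: during the Felsenstein pruning pass, the node's partial likelihoods are
zeroed except at the fixed state.  Summing the clamped likelihoods over
states recovers the unclamped likelihood (law of total probability), a
machine-precision identity used by the test suite.  The single rate is
re-estimated under each constraint, and models are compared by raw
log-likelihood differences (the 2-unit rule), AICc and AICc weights.

Constrained nodes are addressed as the MRCA of a taxon set, never by index.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Hashable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .parsimony import MISSING, _check_labels, _resolve_states
from .trees import PhyloTree

__all__ = [
    "MkModel",
    "MkFit",
    "transition_matrix",
    "mk_loglik",
    "fit_mk",
    "aicc",
    "aicc_weights",
    "compare_hypotheses",
    "DegenerateDataError",
]

Q_MIN, Q_MAX = 1e-8, 1e3


class DegenerateDataError(ValueError):
    """The data carry no information about the rate (e.g. all tips '?')."""


@dataclass(frozen=True)
class MkModel:
    """Equal-rates k-state Markov model with total leaving rate ``q``."""

    n_states: int
    q: float
    root_prior: tuple[float, ...] | None = None

    def __post_init__(self):
        if self.n_states < 2:
            raise ValueError("n_states must be >= 2")
        if self.q < 0:
            raise ValueError("rate q must be >= 0")
        if self.root_prior is not None:
            pi = np.asarray(self.root_prior, float)
            if len(pi) != self.n_states or not math.isclose(pi.sum(), 1.0):
                raise ValueError("root prior must sum to 1 over n_states")

    @property
    def prior(self) -> np.ndarray:
        if self.root_prior is None:
            return np.full(self.n_states, 1.0 / self.n_states)
        return np.asarray(self.root_prior, float)

    @property
    def rate_matrix(self) -> np.ndarray:
        k = self.n_states
        Q = np.full((k, k), self.q / (k - 1))
        np.fill_diagonal(Q, -self.q)
        return Q


def transition_matrix(model: MkModel, t: float) -> np.ndarray:
    """P(t) = e^{Qt} for the equal-rates model, in closed form.

    Row-stochastic for every t ≥ 0; the identity at t = 0; every row tends
    to the uniform stationary distribution as t → ∞.
    """
    if t < 0:
        raise ValueError("branch length t must be >= 0")
    k = model.n_states
    mu = model.q * k / (k - 1)
    e = math.exp(-mu * t)
    P = np.full((k, k), (1.0 - e) / k)
    np.fill_diagonal(P, (1.0 - e) / k + e)
    return P


@dataclass(frozen=True)
class MkFit:
    """Result of maximizing the Mk likelihood over the single rate."""

    q_hat: float
    lnL: float
    k: int  # free parameters (1: the rate)
    n_states: int
    constraint: tuple[frozenset, Hashable] | None = None
    converged: bool = True
    at_bound: bool = False


def _resolve_constraint(
    tree: PhyloTree,
    constraint: tuple[Iterable[str], Hashable] | None,
    states: tuple,
) -> tuple[int, int] | None:
    if constraint is None:
        return None
    taxa, state = constraint
    if state not in states:
        raise ValueError(f"constraint state {state!r} not in alphabet {states}")
    node = tree.mrca(taxa)
    if tree.is_tip(node):
        raise ValueError("constraint must name an internal node (>= 2 taxa)")
    return node, states.index(state)


def mk_loglik(
    tree: PhyloTree,
    coding: Mapping[str, Hashable],
    model: MkModel,
    constraint: tuple[Iterable[str], Hashable] | None = None,
    states: Sequence | None = None,
) -> float:
    """Log-likelihood of a discrete character by Felsenstein pruning.

    ``constraint`` is ``(taxon_set, state)``: the MRCA of the taxon set is
    clamped to the state.  '?' tips contribute all-ones partials.  Partial
    vectors are rescaled at each internal node and the log scalers
    accumulated, so deep trees do not underflow.
    """
    tree.require_branch_lengths("Mk likelihood")
    _check_labels(tree, coding)
    states = _resolve_states(coding, states)
    k = len(states)
    if k > model.n_states:
        raise ValueError("more observed states than model states")
    k = model.n_states
    idx = {s: i for i, s in enumerate(states)}
    clamp = _resolve_constraint(tree, constraint, states)

    logscale = 0.0
    partial = np.empty((tree.n_nodes, k))
    for v in range(tree.n_nodes):
        if tree.is_tip(v):
            s = coding[tree.tip_label[v]]
            if s == MISSING:
                partial[v] = 1.0
            else:
                partial[v] = 0.0
                partial[v, idx[s]] = 1.0
        else:
            p = np.ones(k)
            for c in tree.children[v]:
                P = transition_matrix(model, tree.edge_length[c])
                p *= P @ partial[c]
            if clamp is not None and clamp[0] == v:
                keep = p[clamp[1]]
                p = np.zeros(k)
                p[clamp[1]] = keep
            m = p.max()
            if m <= 0.0:
                return -math.inf
            partial[v] = p / m
            logscale += math.log(m)

    like = float(model.prior @ partial[tree.root_id])
    if like <= 0.0:
        return -math.inf
    return math.log(like) + logscale


def fit_mk(
    tree: PhyloTree,
    coding: Mapping[str, Hashable],
    n_states: int | None = None,
    constraint: tuple[Iterable[str], Hashable] | None = None,
    states: Sequence | None = None,
    q_bounds: tuple[float, float] = (Q_MIN, Q_MAX),
    root_prior: tuple[float, ...] | None = None,
) -> MkFit:
    """ML estimate of the single Mk rate, optionally under a node constraint.

    Bounded scalar optimization on log(q); the profile is unimodal for the
    equal-rates model so no restarts are used.  A ``q_hat`` at either bound
    is flagged via ``at_bound`` (typical for uninformative data, e.g. two
    identical tips, where the likelihood increases monotonically toward
    q → 0).
    """
    _check_labels(tree, coding)
    states = _resolve_states(coding, states) if any(
        s != MISSING for s in coding.values()
    ) else None
    if states is None:
        raise DegenerateDataError("all tips are missing ('?'): rate not identifiable")
    k = n_states if n_states is not None else len(states)
    if k < 2:
        # a constant character observed in one state still needs an alphabet
        raise DegenerateDataError(
            "only one observed state; pass n_states (and states) explicitly"
        )
    if n_states is not None and len(states) < n_states:
        # pad the alphabet deterministically for binary/three-state schemes
        pad = [s for s in range(k) if s not in states]
        states = tuple(sorted(list(states) + pad, key=repr))

    lo, hi = math.log(q_bounds[0]), math.log(q_bounds[1])

    def nll(log_q: float) -> float:
        model = MkModel(n_states=k, q=math.exp(log_q), root_prior=root_prior)
        return -mk_loglik(tree, coding, model, constraint=constraint, states=states)

    res = optimize.minimize_scalar(
        nll, bounds=(lo, hi), method="bounded", options={"xatol": 1e-10}
    )
    q_hat = float(math.exp(res.x))
    lnL = -float(res.fun)
    at_bound = (
        q_hat <= q_bounds[0] * (1 + 1e-4) or q_hat >= q_bounds[1] * (1 - 1e-4)
    )
    clamp = None
    if constraint is not None:
        clamp = (frozenset(constraint[0]), constraint[1])
    return MkFit(
        q_hat=q_hat,
        lnL=lnL,
        k=1,
        n_states=k,
        constraint=clamp,
        converged=bool(res.success),
        at_bound=at_bound,
    )


# ----------------------------------------------------------------------
# information criteria
# ----------------------------------------------------------------------

def aicc(lnL: float, k: int, n: int) -> float:
    """AICc = −2·lnL + 2k + 2k(k+1)/(n−k−1); n is the number of tips here."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n} <= k+1={k + 1}")
    return -2.0 * lnL + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def aicc_weights(aiccs: Sequence[float], normalize: bool = False) -> np.ndarray:
    """Relative evidence w_i = exp((AICc_min − AICc_i)/2); best model gets 1.

    ``normalize=True`` divides by the sum (conventional Akaike weights); the
    default leaves the weights unnormalized so the best model's weight is
    exactly 1 and a 0.2 threshold reads as evidence relative to the best.
    """
    a = np.asarray(aiccs, float)
    if a.size == 0 or not np.all(np.isfinite(a)):
        raise ValueError("AICc values must be a non-empty finite list")
    w = np.exp((a.min() - a) / 2.0)
    if normalize:
        w = w / w.sum()
    return w


def compare_hypotheses(
    tree: PhyloTree,
    coding: Mapping[str, Hashable],
    hypotheses: Sequence[tuple[str, Iterable[str], Hashable]],
    n_states: int | None = None,
    states: Sequence | None = None,
    delta_lnl_rule: float = 2.0,
    weight_threshold: float = 0.2,
    normalize_weights: bool = False,
) -> pd.DataFrame:
    """Fit the unconstrained model and each node-constrained alternative.

    ``hypotheses`` is a sequence of ``(name, taxon_set, state)`` entries; the
    MRCA of each taxon set is clamped to the state and the rate re-fit.  The
    returned table reports, per model, lnL, q̂, AICc (with n = number of
    tips), ΔlnL against the unconstrained reference, ΔAICc, the AICc weight,
    a χ²₁ LRT p-value (a conventional df=1 reading of the likelihood-ratio
    statistic, labelled as such), and a significance verdict: a constrained
    model differs significantly from the reference iff ΔlnL ≥ 2 (the 2-unit
    rule) or its AICc weight falls below 0.2.
    """
    n_tips = len(tree.tip_labels)
    fits = [("unconstrained", fit_mk(tree, coding, n_states=n_states, states=states))]
    for name, taxa, state in hypotheses:
        fits.append(
            (name, fit_mk(tree, coding, n_states=n_states, states=states,
                          constraint=(taxa, state)))
        )
    ref_lnl = fits[0][1].lnL
    rows = []
    for name, f in fits:
        rows.append(
            dict(model=name, lnL=f.lnL, q_hat=f.q_hat, k=f.k,
                 AICc=aicc(f.lnL, f.k, n_tips))
        )
    tab = pd.DataFrame(rows)
    tab["delta_lnL"] = ref_lnl - tab["lnL"]
    tab["delta_AICc"] = tab["AICc"] - tab["AICc"].min()
    tab["w"] = aicc_weights(tab["AICc"].to_numpy(), normalize=normalize_weights)
    lrt = 2.0 * tab["delta_lnL"].clip(lower=0.0)
    tab["LRT"] = lrt
    tab["LRT_p_chi2_df1"] = stats.chi2.sf(lrt, df=1)
    tab["significant"] = (tab["delta_lnL"] >= delta_lnl_rule) | (
        tab["w"] < weight_threshold
    )
    tab.loc[0, "significant"] = False  # reference compared with itself
    return tab
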