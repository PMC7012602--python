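"""Synthetic inputs with known truth for every pipeline stage.

Generates the four kinds of data the analysis consumes:

* specimen tables with log-log allometry between eyespot and wing area and a
  configurable temperature effect per species (two rearing temperatures
  ΔT apart, 10 °C by default, females only);
* random ultrametric trees from a constant-rate birth–death process;
* discrete tip characters evolved under the equal-rates Mk model;
* continuous tip traits evolved under Brownian motion.

All randomness flows from one top-level seed through named
:class:`numpy.random.SeedSequence` streams, so outputs are reproducible
byte-for-byte and adding a new stream never perturbs existing ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .mk import MkModel, transition_matrix
from .trees import PhyloTree

__all__ = [
    "SimulationConfig",
    "stream_rng",
    "simulate_specimens",
    "simulate_tree",
    "simulate_mk_tips",
    "simulate_bm_tips",
]


def stream_rng(seed: int, stream: str) -> np.random.Generator:
    """Deterministic per-stream generator derived from one top-level seed."""
    h = np.frombuffer(stream.encode(), dtype=np.uint8).astype(np.uint32)
    return np.random.default_rng(np.random.SeedSequence([seed, *h.tolist()]))


@dataclass
class SimulationConfig:
    """Study-design parameters for the specimen-table generator.

    Defaults mirror the comparative rearing design: two temperatures 10 °C
    apart (17/27 °C), ~20 females per temperature group, eyespot area scaling
    nearly isometrically with wing area on the log10 scale, and a per-species
    temperature effect expressed in log10-area units at the high temperature.
    """

    seed: int = 0
    n_species: int = 6
    n_per_group: int = 20
    t_low: float = 17.0
    delta_T: float = 10.0
    allometric_intercept: float = -1.2   # log10 mm^2 at log10 wing area 0
    allometric_slope: float = 1.0        # log10 eyespot per log10 wing
    temp_effect: float | Sequence[float] = 0.0  # log10-units shift at high T
    residual_sd: float = 0.05            # log10-scale residual SD
    wing_log_mean: float = 2.0           # log10 mm^2; ~100 mm^2 hindwing
    wing_log_sd: float = 0.05
    species_prefix: str = "sp"

    def __post_init__(self):
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if self.residual_sd < 0 or self.wing_log_sd < 0:
            raise ValueError("SDs must be >= 0")
        if self.delta_T <= 0:
            raise ValueError("delta_T must be > 0")


def simulate_specimens(cfg: SimulationConfig) -> pd.DataFrame:
    """Specimen table with known allometry and temperature effects.

    log10(eyespot) = a + b·log10(wing) + δ_sp·1[high T] + ε,
    ε ~ Normal(0, residual_sd).  Returns the canonical specimen columns.
    """
    rng = stream_rng(cfg.seed, "specimens")
    effects = np.broadcast_to(
        np.asarray(cfg.temp_effect, float), (cfg.n_species,)
    ) if np.ndim(cfg.temp_effect) else np.full(cfg.n_species, cfg.temp_effect)
    rows = []
    for i in range(cfg.n_species):
        sp = f"{cfg.species_prefix}{i + 1:02d}"
        for temp, is_high in ((cfg.t_low, 0.0), (cfg.t_low + cfg.delta_T, 1.0)):
            lw = rng.normal(cfg.wing_log_mean, cfg.wing_log_sd, cfg.n_per_group)
            le = (
                cfg.allometric_intercept
                + cfg.allometric_slope * lw
                + effects[i] * is_high
                + rng.normal(0.0, cfg.residual_sd, cfg.n_per_group)
            )
            for w, e in zip(lw, le):
                rows.append(
                    dict(species=sp, sex="female", temperature=temp,
                         wing_area=10.0 ** w, eyespot_area=10.0 ** e)
                )
    return pd.DataFrame(rows)


def simulate_tree(
    n_tips: int,
    birth: float = 1.0,
    death: float = 0.0,
    seed: int = 0,
    taxon_prefix: str = "t",
) -> PhyloTree:
    """Ultrametric tree from a constant-rate birth–death process.

    Forward simulation conditioned on reaching ``n_tips`` extant lineages
    (restarting on total extinction); all extant tips end at the same age.
    """
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    if not birth > death or death < 0:
        raise ValueError("need birth > death >= 0")
    rng = stream_rng(seed, "tree")

    while True:  # restart on extinction
        taxon_ns = dendropy.TaxonNamespace()
        tree = dendropy.Tree(taxon_namespace=taxon_ns)
        tree.seed_node.edge.length = 0.0
        left, right = tree.seed_node.new_child(), tree.seed_node.new_child()
        extant = [left, right]
        for nd in extant:
            nd.edge.length = 0.0
        extinct_all = False
        while len(extant) < n_tips:
            n = len(extant)
            wait = rng.exponential(1.0 / (n * (birth + death)))
            for nd in extant:
                nd.edge.length += wait
            k = rng.integers(n)
            if rng.random() < birth / (birth + death):
                parent = extant.pop(k)
                a, b = parent.new_child(), parent.new_child()
                a.edge.length = b.edge.length = 0.0
                extant.extend([a, b])
            else:
                nd = extant.pop(k)
                nd.parent_node.remove_child(nd)
                if not extant:
                    extinct_all = True
                    break
        if extinct_all:
            continue
        # final stretch so tips do not end exactly at a speciation event
        tail = rng.exponential(1.0 / (n_tips * (birth + death)))
        for nd in extant:
            nd.edge.length += tail
        for i, nd in enumerate(extant):
            nd.taxon = taxon_ns.require_taxon(f"{taxon_prefix}{i + 1}")
        tree.suppress_unifurcations()
        out = PhyloTree(tree)
        if len(out.tip_labels) == n_tips:
            return out


def simulate_mk_tips(
    tree: PhyloTree,
    model: MkModel,
    root_state: Hashable | None = None,
    seed: int = 0,
    states: Sequence | None = None,
) -> dict[str, Hashable]:
    """Evolve a discrete character edge-wise along the tree under Mk.

    ``root_state`` fixes the state at the root; otherwise it is drawn from
    the model's root prior.  Returns tip label → state.
    """
    tree.require_branch_lengths("Mk simulation")
    rng = stream_rng(seed, "mk")
    states = tuple(states) if states is not None else tuple(range(model.n_states))
    if len(states) != model.n_states:
        raise ValueError("states alphabet must match model.n_states")
    state_at = {}
    root = tree.root_id
    if root_state is None:
        state_at[root] = int(rng.choice(model.n_states, p=model.prior))
    else:
        state_at[root] = states.index(root_state)
    for v in reversed(range(tree.n_nodes - 1)):  # preorder below root
        P = transition_matrix(model, tree.edge_length[v])
        row = P[state_at[tree.parent[v]]]
        state_at[v] = int(rng.choice(model.n_states, p=row))
    return {
        tree.tip_label[i]: states[state_at[i]] for i in tree.tip_ids
    }


def simulate_bm_tips(
    tree: PhyloTree,
    sigma2: float,
    root_value: float = 0.0,
    seed: int = 0,
) -> dict[str, float]:
    """Evolve a continuous trait by Gaussian edge increments (variance σ²·t)."""
    tree.require_branch_lengths("BM simulation")
    if sigma2 < 0:
        raise ValueError("sigma2 must be >= 0")
    rng = stream_rng(seed, "bm")
    value = {tree.root_id: float(root_value)}
    for v in reversed(range(tree.n_nodes - 1)):
        t = tree.edge_length[v]
        value[v] = value[tree.parent[v]] + rng.normal(0.0, np.sqrt(sigma2 * t))
    return {tree.tip_label[i]: value[i] for i in tree.tip_ids}
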