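"""Config-driven end-to-end analysis: specimens → norms → codings → trees.

One YAML config describes a full comparative analysis of reaction-norm
evolution; :func:`run_pipeline` executes the chain and writes a bundle of
TSV tables plus a plain-text report:

* ``reaction_norms.tsv`` — per-species slope, ANCOVA F/p, coded state;
* ``codings.tsv`` — the tip character matrix actually analysed;
* ``parsimony.tsv`` / ``parsimony_annotated.nwk`` — score, per-node MPR
  state sets, origin ranges for each derived-state set;
* ``mk_tests.tsv`` — unconstrained vs node-constrained Mk fits with lnL,
  AICc, ΔlnL, AICc weights and the 2-unit / 0.2-weight verdicts;
* ``bm_ancestral.tsv`` — BM reconstruction of continuous slopes with SE,
  95 % CI and the negative/zero/positive significance category;
* ``report.txt`` — run log with the seed, stage summary and decision flags.

Identical configs produce byte-identical outputs.  Any stage failure aborts
with the stage name attached.
"""

from __future__ import annotations

import dataclasses
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Hashable, Mapping, Sequence

import pandas as pd
import yaml

from . import __version__, bm, mk, morphometry, parsimony
from .fixtures import nymphalid_fixture
from .trees import PhyloTree, load_tree

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "load_config"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the stage name prefixes the message."""


@dataclass
class PipelineConfig:
    """Inputs and switches for one end-to-end run.

    Either ``specimens`` (a specimen table to be reduced to norms and
    codings) or ``codings`` (a precomputed taxon/state TSV) must be given;
    ``slopes`` (taxon/value TSV) enables the BM stage.  ``use_fixture``
    loads the packaged nymphalid dataset for any input not supplied.
    ``hypotheses`` entries are mappings with keys ``name``, ``character``,
    ``taxa`` (list), ``state``.
    """

    out_dir: str = "normevol_out"
    seed: int = 0
    tree: str | None = None
    specimens: str | None = None
    codings: str | None = None
    slopes: str | None = None
    use_fixture: bool = False
    character: str = "size_plasticity"
    n_states: int = 3
    alpha: float = 0.05
    delta_T_overrides: dict[str, float] = field(default_factory=dict)
    derived_states: list[list[int]] = field(
        default_factory=lambda: [[1, 2], [1], [2]]
    )
    hypotheses: list[dict[str, Any]] = field(default_factory=list)
    normalize_weights: bool = False

    @classmethod
    def from_mapping(cls, m: Mapping[str, Any]) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(m) - known)
        if unknown:
            raise ValueError(f"unknown config keys: {unknown}")
        return cls(**m)


def load_config(path: str) -> PipelineConfig:
    with open(path) as fh:
        return PipelineConfig.from_mapping(yaml.safe_load(fh) or {})


def _stage(name: str):
    def deco(fn):
        def wrapped(*a, **k):
            try:
                return fn(*a, **k)
            except Exception as exc:
                raise PipelineError(f"[stage {name}] {exc}") from exc
        return wrapped
    return deco


@_stage("inputs")
def _load_inputs(cfg: PipelineConfig):
    fx = nymphalid_fixture() if cfg.use_fixture else None
    tree: PhyloTree | None = None
    if cfg.tree:
        tree = load_tree(cfg.tree)
    elif fx is not None:
        tree = fx.tree
    if tree is None:
        raise ValueError("no tree given (set 'tree' or use_fixture: true)")

    specimens = morphometry.load_specimens(cfg.specimens) if cfg.specimens else None

    coding: dict[str, Hashable] | None = None
    if cfg.codings:
        tab = pd.read_csv(cfg.codings, sep="\t", dtype=str)
        coding = {
            r["taxon"]: (r["state"] if r["state"] == "?" else int(r["state"]))
            for _, r in tab.iterrows()
        }
    elif fx is not None and specimens is None:
        coding = fx.coding(cfg.character)

    slopes: dict[str, float] | None = None
    if cfg.slopes:
        tab = pd.read_csv(cfg.slopes, sep="\t")
        slopes = dict(zip(tab["taxon"], tab["value"].astype(float)))
    elif fx is not None:
        slopes = dict(fx.slopes)

    hypotheses = list(cfg.hypotheses)
    if not hypotheses and fx is not None:
        hypotheses = [
            dict(name=n, character=c, taxa=sorted(t), state=s)
            for n, c, t, s in fx.hypotheses
            if c == cfg.character
        ]
    return fx, tree, specimens, coding, slopes, hypotheses


@_stage("norms")
def _norms_stage(cfg: PipelineConfig, specimens: pd.DataFrame) -> pd.DataFrame:
    return morphometry.species_summary(
        specimens, alpha=cfg.alpha, delta_T_overrides=cfg.delta_T_overrides
    )


@_stage("parsimony")
def _parsimony_stage(cfg, tree, coding):
    states = tuple(range(cfg.n_states))
    res = parsimony.sankoff(tree, coding, states=states)
    origin_rows = []
    for derived in cfg.derived_states:
        lo, hi = parsimony.count_origins(tree, coding, set(derived), states=states)
        origin_rows.append(
            dict(derived=",".join(map(str, derived)), min_origins=lo, max_origins=hi)
        )
    node_rows = [
        dict(node=v,
             taxa=";".join(sorted(tree.subtree_taxa(v))),
             mpr_states=",".join(map(str, sorted(res.node_state_sets[v]))))
        for v in tree.internal_ids
    ]
    return res, pd.DataFrame(origin_rows), pd.DataFrame(node_rows)


@_stage("mktest")
def _mk_stage(cfg, tree, coding, hypotheses):
    hyps = [(h["name"], set(h["taxa"]), h["state"]) for h in hypotheses]
    return mk.compare_hypotheses(
        tree, coding, hyps, n_states=cfg.n_states,
        states=tuple(range(cfg.n_states)),
        normalize_weights=cfg.normalize_weights,
    )


@_stage("bmrecon")
def _bm_stage(cfg, tree, slopes):
    est = bm.bm_ancestral_states(tree, slopes)
    return est.table.assign(sigma2=est.sigma2)


def run_pipeline(cfg: PipelineConfig, log=sys.stderr) -> dict[str, Any]:
    """Execute every stage the config enables; write the bundle; return it."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    lines = [
        f"normevol {__version__} pipeline run",
        f"seed: {cfg.seed}",
        f"alpha: {cfg.alpha}",
        f"character: {cfg.character} ({cfg.n_states} states)",
        f"weights: {'normalized' if cfg.normalize_weights else 'relative-to-best'}",
    ]
    results: dict[str, Any] = {}

    fx, tree, specimens, coding, slopes, hypotheses = _load_inputs(cfg)
    lines.append(f"tree: {len(tree.tip_labels)} tips")

    if specimens is not None:
        norms = _norms_stage(cfg, specimens)
        norms.to_csv(out / "reaction_norms.tsv", sep="\t", index=False)
        results["norms"] = norms
        if coding is None:
            shared = [sp for sp in norms["species"] if sp in tree.tip_labels]
            coding = dict(zip(norms["species"], norms["state"].astype(int)))
            coding = {sp: coding[sp] for sp in shared}
            tree = tree.prune_to_taxa(shared)
        lines.append(f"norms: {len(norms)} species")

    if coding is not None:
        pd.DataFrame(
            dict(taxon=list(coding), state=[coding[t] for t in coding])
        ).to_csv(out / "codings.tsv", sep="\t", index=False)
        pres, origins, nodes = _parsimony_stage(cfg, tree, coding)
        origins.to_csv(out / "parsimony_origins.tsv", sep="\t", index=False)
        nodes.to_csv(out / "parsimony_nodes.tsv", sep="\t", index=False)
        results["parsimony"] = pres
        results["origins"] = origins
        lines.append(
            f"parsimony: score {pres.score:g}; origins "
            + "; ".join(
                f"{r.derived}:[{r.min_origins},{r.max_origins}]"
                for r in origins.itertuples()
            )
        )
        if hypotheses:
            tab = _mk_stage(cfg, tree, coding, hypotheses)
            tab.to_csv(out / "mk_tests.tsv", sep="\t", index=False)
            results["mk_tests"] = tab
            lines.append(
                "mk tests: max |delta lnL| "
                f"{tab['delta_lnL'].iloc[1:].abs().max():.4f}; "
                f"min weight {tab['w'].min():.4f}; "
                f"significant: {', '.join(tab.loc[tab.significant, 'model']) or 'none'}"
            )

    if slopes is not None:
        bm_tab = _bm_stage(cfg, tree, slopes)
        bm_tab.to_csv(out / "bm_ancestral.tsv", sep="\t", index=False)
        results["bm"] = bm_tab
        root_row = bm_tab[bm_tab["node"] == bm_tab["node"].max()].iloc[0]
        lines.append(
            f"bm: sigma2 {root_row['sigma2']:.6g}; root estimate "
            f"{root_row['estimate']:.6g} [{root_row['ci_lo']:.6g}, "
            f"{root_row['ci_hi']:.6g}] ({root_row['category']})"
        )

    report = "\n".join(lines) + "\n"
    (out / "report.txt").write_text(report)
    if log is not None:
        print(report, file=log, end="")
    results["report"] = report
    return results
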