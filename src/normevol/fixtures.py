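"""The shipped nymphalid fixture: tree, character codings, slopes, hypotheses.

Bundles the comparative dataset the package's worked analyses run on: a
15-taxon chronogram (13 reared species — 12 nymphalids plus a papilionid
outgroup — and two literature-derived satyrines), the discrete plasticity /
hormone / receptor codings, continuous reaction-norm slopes, and the four
constrained-node hypothesis tests.  Every character cell carries a
provenance note in the TSV; cells not fixed by the published prose are
synthetic, sign-consistent reconstructions and are labelled as such.  The
chronogram's calibrations are likewise documented placeholders that users
can replace with their own dated tree.

Hypothesis nodes are addressed by taxon sets: "node 14" is the MRCA of all
sampled butterflies (the root), "node 17" the MRCA of the eyespot-bearing
clade (heliconiines + nymphalines + satyrines).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Hashable, Mapping, Sequence

import pandas as pd

from .trees import PhyloTree

__all__ = ["NymphalidFixture", "nymphalid_fixture"]

#: states that count as "plastic" in the three-state size-plasticity scheme
PLASTIC_STATES = (1, 2)


@dataclass(frozen=True)
class NymphalidFixture:
    tree: PhyloTree
    characters: pd.DataFrame           # indexed by species
    slopes: Mapping[str, float]        # species -> Cu1 slope (mm^2 / degC)
    node14_taxa: frozenset             # MRCA of all butterflies
    node17_taxa: frozenset             # MRCA of eyespot-bearing clade
    hypotheses: Sequence[tuple[str, str, frozenset, Hashable]]
    #: (test name, character column, constrained-node taxa, fixed state)

    def coding(self, character: str) -> dict[str, Hashable]:
        """species → state for one character column; '?' kept as missing."""
        col = self.characters[character]
        out = {}
        for sp, v in col.items():
            out[sp] = v if v == "?" else int(v)
        return out

    @property
    def reared_species(self) -> list[str]:
        return list(self.characters.index[self.characters["reared"] == 1])


def _read(name: str) -> str:
    return resources.files("normevol.data").joinpath(name).read_text()


def nymphalid_fixture() -> NymphalidFixture:
    """Load the packaged comparative dataset."""
    nwk = "".join(
        line for line in _read("nymphalid_tree.nwk").splitlines()
        if not line.startswith("#")
    )
    tree = PhyloTree.from_newick(nwk)

    import io

    chars = pd.read_csv(
        io.StringIO(_read("nymphalid_characters.tsv")), sep="\t", dtype=str
    ).set_index("species")
    chars["reared"] = chars["reared"].astype(int)
    slopes_df = pd.read_csv(
        io.StringIO(_read("nymphalid_slopes.tsv")), sep="\t"
    )
    slopes = dict(zip(slopes_df["species"], slopes_df["cu1_slope"].astype(float)))

    node14 = frozenset(tree.tip_labels)
    eyespot_clade = frozenset(
        sp for sp in tree.tip_labels
        if sp not in {"Papilio_polytes", "Danaus_chrysippus", "Idea_leuconoe"}
    )
    hypotheses = (
        ("size_node14_nonplastic", "size_plasticity", node14, 0),
        ("size_node14_negative", "size_plasticity", node14, 1),
        ("size_node17_nonplastic", "size_plasticity", eyespot_clade, 0),
        ("size_node17_negative", "size_plasticity", eyespot_clade, 1),
        ("titer_node14_nonplastic", "titer_20e", node14, 0),
        ("titer_node14_positive", "titer_20e", node14, 1),
        ("ecr_node17_absent", "ecr_eyespot", eyespot_clade, 0),
        ("ecr_node17_present", "ecr_eyespot", eyespot_clade, 1),
    )
    return NymphalidFixture(
        tree=tree,
        characters=chars,
        slopes=slopes,
        node14_taxa=node14,
        node17_taxa=eyespot_clade,
        hypotheses=hypotheses,
    )
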