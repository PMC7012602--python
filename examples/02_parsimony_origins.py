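"""Count independent origins of eyespot-size plasticity by parsimony.

Loads the shipped nymphalid dataset (15 taxa, three-state plasticity coding)
and reports the Sankoff score, the MPR state sets at the two hypothesis
nodes, and the origin ranges for plastic / negative / positive states.
"""

from normevol import count_origins, nymphalid_fixture, sankoff

fx = nymphalid_fixture()
coding = fx.coding("size_plasticity")
res = sankoff(fx.tree, coding, states=(0, 1, 2))
print(f"parsimony score (minimum state changes): {res.score:g}")

for label, taxa in [("MRCA of all butterflies", fx.node14_taxa),
                    ("MRCA of eyespot-bearing clade", fx.node17_taxa)]:
    node = fx.tree.mrca(taxa)
    print(f"{label}: MPR states {sorted(res.node_state_sets[node])}")

for name, derived in [("any plasticity", {1, 2}), ("negative", {1}),
                      ("positive", {2})]:
    lo, hi = count_origins(fx.tree, coding, derived, states=(0, 1, 2))
    print(f"independent origins of {name}: min {lo}, max {hi}")

print()
print(
    "an origin is an edge gaining a derived state (or a derived root);\n"
    "the range spans all most-parsimonious reconstructions."
)
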