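"""Constrained-node Mk maximum-likelihood hypothesis tests.

For each character (size plasticity, 20E-titer plasticity, EcR expression),
fits the unconstrained equal-rates Mk model and re-fits with the hypothesis
node clamped to each contending state, then compares models by the 2-unit
log-likelihood rule and AICc weights (threshold 0.2).
"""

from normevol import compare_hypotheses, nymphalid_fixture

fx = nymphalid_fixture()
for char, k in [("size_plasticity", 3), ("titer_20e", 2), ("ecr_eyespot", 2)]:
    hyps = [(n, t, s) for n, c, t, s in fx.hypotheses if c == char]
    tab = compare_hypotheses(
        fx.tree, fx.coding(char), hyps, n_states=k, states=tuple(range(k))
    )
    print(f"== {char} ==")
    cols = ["model", "lnL", "q_hat", "AICc", "delta_lnL", "w", "significant"]
    print(tab[cols].to_string(index=False, float_format=lambda v: f"{v:.4f}"))
    print()

print(
    "delta_lnL is the log-likelihood cost of clamping the node; a model is\n"
    "'significant(ly different)' iff delta_lnL >= 2 or its AICc weight < 0.2."
)
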