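# Methods

This note documents the statistical models, the numerical choices, and the
limits of what the shipped analyses can show.

## Reaction norms and the allometric ANCOVA

Eyespot area scales allometrically with wing area, so the temperature test
is run on log₁₀-transformed areas: OLS of log₁₀(eyespot) on an intercept,
log₁₀(wing) and a two-level temperature factor. The F statistic for
temperature is the marginal (Type-III-style) test comparing residual sums
of squares of the full model against the model with the factor dropped,
with the covariate always retained; no temperature × wing interaction is
fitted by default (`include_interaction=True` adds it, and the factor and
interaction are then dropped jointly). This matches the classic univariate
ANCOVA layout. Only females enter the analysis by default
(`females_only=False` to override); rows with zero eyespot area are
excluded from the log model with a warning, and a species whose eyespot is
absent at both temperatures is coded non-plastic directly.

The reaction norm itself is computed on the **back-transformed** scale:
group means of raw areas at each temperature, and
`slope = (mean_high − mean_low)/ΔT`. ΔT defaults to the observed
temperature difference (10 °C in the rearing design); literature-derived
species reared at 21/27 °C use ΔT = 6 via per-species overrides. Arithmetic
means of raw areas (not geometric means of the log data) are used, since
the slope is defined on the measurement scale; this is a configuration
point (`trait` column switch) rather than a hidden convention.

Coding: significance at α (default 0.05, configurable) gates states; the
sign of the slope then separates negative (1) from positive (2). Binary
schemes collapse through an explicit mapping (any-plasticity vs
positive-only), used for the hormone-titer and receptor characters.

Degenerate fits: when the full model is exact (residual SS at rounding
level relative to the response's total SS), the F ratio is reported as an
overflow-safe ∞ with p = 0, or as 0 with p = 1 when the reduced model is
equally exact (the exact-null, zero-noise case).

## Sankoff parsimony and origin counting

A single Sankoff cost-matrix recursion covers unordered multistate
characters, '?' tips (zero cost in every state) and polytomies. The default
cost matrix is 0 on the diagonal and 1 off it (Fitch-equivalent); user
matrices must have a zero diagonal and positive off-diagonals. Branch
lengths are ignored, and trees without lengths are legal here — operations
that do need lengths fail loudly instead of assuming unit lengths
(`assign_unit_lengths()` makes that assumption explicit).

MPR state sets come from the bottom-up cost pass plus a top-down
feasibility pass: a state is feasible at a node iff it extends some
minimum-cost reconstruction. The decomposition is exact because, given a
parent's state, each child independently takes any state in the argmin of
(cost + subtree cost); every MPR arises this way.

**Origins.** An origin of a derived state set is an edge whose parent state
is ancestral and whose child state is derived, *or* a derived state at the
root (an origin at or before the root of the sampled clade). The root term
matters: without it, reconstructions that push the derived state rootward
would report fewer "origins" than the number of times the trait actually
arose within the reconstruction. The (min, max) range over all MPRs is
computed by propagating per-state min/max counts through the same argmin
decomposition, and is reported instead of a single ACCTRAN/DELTRAN pick so
that ambiguity among equally parsimonious histories stays visible.

## Equal-rates Mk likelihoods and constrained nodes

The discrete-character model is equal-rates Mk with k states and total
leaving rate q (off-diagonal generator entries q/(k−1)), uniform stationary
distribution and, by default, a uniform root prior. Because the generator
is −μ(I − J/k) with μ = qk/(k−1), the transition matrix has the exact
closed form P(t) = J/k + e^{−μt}(I − J/k); this *is* the matrix exponential
and is used directly (cheap and exact inside the optimizer). For k = 2 it
reduces to P_same(t) = ½ + ½e^{−2qt}.

Likelihoods use Felsenstein pruning with per-node rescaling of partials
(log scalers accumulated), so deep trees cannot underflow. A hypothesis
about an ancestor clamps one internal node — always addressed as the MRCA
of a taxon set, never a bare node number, so hypotheses survive pruning and
re-indexing — by zeroing all partial-likelihood entries except the fixed
state before the pass continues. Summing clamped likelihoods over states
recovers the unclamped likelihood exactly (law of total probability); the
test suite enforces this at relative 1e−10.

The single rate is estimated by bounded scalar minimization on log q over
[1e−8, 1e3] (xatol 1e−10); the 1-D profile is unimodal for this model so no
restarts are needed. Estimates at either bound are flagged (`at_bound`) —
the expected outcome for uninformative data such as a constant character.
Constrained and unconstrained fits share k = 1 free parameter, so the
"LRT" is reported as the raw ΔlnL against the 2-unit rule; a χ²₁ p-value is
emitted alongside, labelled as the conventional df = 1 reading, since the
appropriate reference distribution for a constrained-node comparison is not
settled. AICc uses n = number of tips — the only sample-size notion
available for a single character — and AICc weights default to the
*relative-evidence* form exp((AICc_min − AICc_i)/2) (best model exactly 1,
0.2 threshold applied to evidence relative to the best); sum-normalized
weights are available behind `normalize_weights=True`.

## Brownian-motion ancestral slopes

Under BM with rate σ², node values are jointly Gaussian with edge
increments of variance σ²t. Ancestral estimates are the conditional
expectations of internal values given tips, obtained from one linear solve
on the edge-weighted tree Laplacian (weights 1/t): L_II μ = −L_IT x, with
conditional covariance σ²(L_II)⁻¹. With a flat root prior this equals the
joint-ML reconstruction and, node by node, the GLS estimate
â = (1ᵀC⁻¹1)⁻¹1ᵀC⁻¹x of the tree re-rooted at that node — the test suite
checks the package against a literally re-rooted GLS oracle.

σ² is estimated from the tips by ML (quadratic form divided by n;
`reml=True` divides by n−1). SEs are √(σ̂²·diag(L_II⁻¹)); intervals are the
normal approximation estimate ± 1.96·SE, and a node is called
negative/zero/positive by whether 0 falls outside/inside its 95 % CI.
Because σ̂² is the ML (divide-by-n) estimate and the intervals are normal
rather than t, root CI coverage is slightly below nominal at small n
(≈0.94 at 50 tips in the shipped calibration); this is a property of the
documented estimator choice, not a defect, and REML + t intervals narrow
the gap. Missing taxa are pruned before reconstruction, never imputed;
zero-length pendant edges are rejected with guidance (they collapse the
conditional variance), as are trait vectors with fewer than 3 scored taxa.

## Synthetic data

The generator produces exactly the structures the analyses assume:

* **Specimen tables**: log₁₀(eyespot) = a + b·log₁₀(wing) + δ·1[high T] + ε
  with ε ~ N(0, sd). Defaults emulate the rearing design: two temperatures
  10 °C apart (17/27 °C), 20 females per group, near-isometric allometry
  (b = 1), wing areas ~100 mm², residual SD 0.05 log₁₀ units — the scatter
  of repeated wing measurements at this scale. δ is the per-species effect
  in log₁₀ units at the high temperature.
* **Trees**: forward-simulated constant-rate birth–death conditioned on n
  extant tips (restart on extinction), ultrametric by construction.
* **Discrete characters**: edge-wise sampling from the Mk transition matrix
  given a root state or a draw from the prior.
* **Continuous traits**: edge-wise Gaussian increments, so tip covariance
  is σ²C by construction.

One top-level seed fans out to named `SeedSequence` streams
("specimens"/"tree"/"mk"/"bm"), so adding a stream never perturbs existing
ones and identical configs give byte-identical outputs.

What the generator does **not** emulate: measurement error distinct from
biological residual variance, sexual dimorphism (all simulated specimens
are female), unequal group sizes, multi-eyespot correlation, or
non-Brownian (e.g. OU) trait dynamics. Passing calibrations therefore show
the estimators are correct under their stated models, not that real
morphometric data satisfy those models.

## The shipped comparative dataset

`nymphalid_fixture()` bundles a 15-taxon tree (13 reared species including
the papilionid outgroup, plus two literature-derived satyrines whose slopes
use the 6 °C correction) and four characters: three-state eyespot-size
plasticity, binary 20E-titer plasticity, binary EcR expression in eyespot
centers, and binary 20E sensitivity. Cells fixed by the published prose
(the single positive reared species; five non-plastic reared species; the
negative nymphalines and outgroup; the satyrine positives) are marked as
such in the provenance column; the remaining assignments and all continuous
slope magnitudes are synthetic, sign-consistent reconstructions, and the
chronogram's ages are placeholders anchored only on the ~85 Myr origin of
eyespots at the eyespot-clade MRCA. Both files are plain TSV/newick and are
meant to be replaced by users with measured data and a calibrated tree; all
node-addressed hypotheses (taxon sets, not node numbers) survive such
replacement.

The four shipped hypothesis tests clamp the MRCA of all butterflies and
the MRCA of the eyespot-bearing clade to the contending states of each
character (non-plastic vs negative for size plasticity — the plastic form
adjacent to those nodes; absent vs present/positive for the binary
characters).

## Problem sizes used in the shipped calibrations

Oracle-agreement suites use 200 random trees of ≤ 6 tips (likelihood, where
brute-force summation is exact) and ≤ 8 tips (parsimony enumeration);
ANCOVA calibration uses 2000 null tables of 10 specimens per group and a
4-point effect grid at 150 replicates; BM coverage uses 1000 replicates on
a 50-tip tree; Mk rate recovery uses 200 replicates on 200-tip trees
(median q̂ expected within [0.8, 1.25] of the true q = 1, a bracket set by
pilot runs) with a 25-tip companion run to show bias shrinking with tree
size. These sizes give Monte-Carlo error comfortably inside each check's
tolerance while keeping the whole suite around half a minute.

## Known limitations

* The equal-rates Mk model has one rate for all transitions; asymmetric
  gain/loss rates (all-rates-different, hidden states) are out of scope.
* Parsimony cost matrices must be user-supplied for non-unit costs; Dollo
  and ordered variants are not implemented.
* The BM module does not fit OU or multi-rate models and does not perform
  phylogenetic regression; hormone-titer slope vectors are treated as plain
  trait vectors.
* Tree inference, dating and re-rooting heuristics are out of scope; the
  tree is consumed as given.
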