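# Methods

## Sequencing-error model in the tip likelihoods

The likelihood of an alignment on a tree is computed by the pruning
(peeling) algorithm: conditional likelihood 4-vectors over the true base
(A, C, G, T) are propagated from the tips to the root. The vector stored at
a tip holds Pr(observation | true base), not a distribution over bases, so
its entries need not sum to one.

The error model assumes each base call is independently misread as one of
the three other bases with probability ε, uniformly (ε/3 each). Ambiguity
codes are assumed to arise *after* the error process — the sequencer calls
concrete (possibly wrong) bases which are then summarized into IUPAC codes —
so no separate ambiguity-generation probability is needed. For an observed
symbol with resolution set S, |S| = k:

* Pr(observation | true base ∈ S) = 1 − ε + (k−1)ε/3
* Pr(observation | true base ∉ S) = kε/3

At ε = 0 this degenerates to the classical 0/1 indicator vectors; `N`, `-`
and `?` give (1, 1, 1, 1) at any ε. ε is restricted to [0, 0.75): at 0.75 a
call carries no information and beyond it the model inverts. ε may be set
globally or per sequence (`ErrorSpec.per_taxon`); it is a *declared* input
of inference, never estimated. RNA is handled by mapping U to T at parse
time.

## Substitution model

Kimura 2-parameter with uniform base frequencies: transitions (A↔G, C↔T)
at rate α, each transversion target at rate β, normalized so α + 2β = 1 —
branch lengths are expected substitutions per site. The one free parameter
is R = α/(2β), the equilibrium transition/transversion ratio (default 2.0,
the value used throughout the simulations). Note that under this
normalization the equal-rates (Jukes–Cantor) limit R = 0.5 gives
α = β = 1/3. Transition probabilities use the closed form

* P(transition) = ¼ + ¼e^(−4βb) − ½e^(−2(α+β)b)
* P(each transversion) = ¼ − ¼e^(−4βb)

The same model serves simulation and inference so that declared-vs-true
error effects are isolated from model misspecification.

## Likelihood computation

Site patterns are compressed with first-occurrence ordering. Conditional
vectors are renormalized per pattern at every internal node, with the log
factors accumulated separately, so 20 taxa × 20,000 sites is stable in
double precision. Root frequencies are uniform (¼); by reversibility the
likelihood is invariant to root placement, which the tests verify.

For branch-length optimization the workspace also maintains, per edge, the
conditional likelihood of the data *outside* the edge's subtree as a
function of the state at the parent node. The likelihood as a function of a
single branch length is then an O(patterns) expression, which is what the
one-dimensional optimizer evaluates.

## Optimization and tree search

Branch lengths (non-clock) and node heights (clock) are optimized by
bounded one-dimensional search per parameter (Brent's method), swept until
the log-likelihood gain falls below `tol_lnl`. A 1-D step is accepted only
if it improves the likelihood, so the trajectory is monotone. Because the
likelihood flattens once a branch saturates, a naive bounded search over
the full [bl_min, bl_max] range can stall on the plateau; the search
therefore uses a window around the current value that widens only while
the optimum presses against its upper edge. Defaults: bl_min = 10⁻⁸,
bl_max = 100, tol_lnl = 10⁻⁶, max_passes = 20. One-dimensional search was
chosen over Newton steps because the curvature can vanish near bl_min when
error-adjusted tips absorb all mismatches.

Topology search is seeded random-order stepwise addition — each new taxon
is tried on every branch with local re-optimization of the three affected
branches, best log-likelihood kept, ties broken by first encounter —
followed by nearest-neighbor-interchange sweeps over all internal edges
until no exchange improves the log-likelihood by more than `tol_lnl`, then
a final full optimization. Clock-mode search works on the rooted tree
(placements include above the root; NNI respects height feasibility) and
re-optimizes heights instead of free branch lengths; its output is
ultrametric. Everything is deterministic given the run seed.

The two-taxon pairwise distance (`ml_pairwise_distance`, used for
diagnostics and as an independent check) maximizes the likelihood over the
transition and transversion path components jointly, i.e. the
transition/transversion ratio is profiled out. With ε = 0 this maximizer is
the closed-form K2P distance −½ln(1−2P−Q) − ¼ln(1−2Q); a fixed-ratio
maximization would differ from the closed form (by ~8×10⁻⁴ at P = 0.1,
Q = 0.05), which is why the ratio is left free here while tree inference
proper keeps the model ratio fixed.

## Simulators

`simulate_yule_tree` draws clocklike pure-birth trees: starting from two
lineages at the root, each of k extant lineages splits at rate 1/t, so the
interval spent with k lineages is Exp(k/t) — mean t/2 for the rootmost
interval — and after reaching `n_taxa` lineages one final Exp(n_taxa/t)
interval keeps terminal branches non-degenerate. Expected total tree length
is (n_taxa − 1)·t. The scaling parameter t is therefore the single knob for
mutational signal.

`evolve_alignment` draws a uniform root sequence and mutates each site
independently along each branch from the K2P transition matrix; only
resolved bases are produced. `inject_errors` then miscalls each base
independently with its taxon's ε (uniform over the three other bases); it
refuses input containing ambiguity codes, since error injection models the
sequencing step. `bernoulli_snp_alignment` is a simpler polymorphism
fixture — each site is polymorphic with probability m, in which case one
uniformly chosen taxon carries a different base — used to study the
composition of mutational and error-driven segregating sites analytically:
the expected segregating fraction of the composite is
1 − (1−m)(1−ε)^n up to tiny reversion terms.

These simulators emulate the study design (matched simulation/inference
model, independent error realizations on shared base data sets) but not
real-data features: no rate heterogeneity across sites, no indels, no
clustered or assembly errors, no base-composition bias. Passing tests
therefore demonstrate the internal consistency of the correction, not its
adequacy for any particular empirical data set.

## Replication harness and scale

`run_condition` simulates `n_replicates` (tree, alignment, error) triples
and analyzes each once per declared-ε grid point, so comparisons along the
grid are paired; per-replicate random streams are derived from the master
seed by fixed spawn keys. Reported metrics are RF (topology-only symmetric
bipartition difference), RFL and the inferred/true total-length ratio.

RFL is implemented as the sum of absolute branch-length differences over
the union of bipartitions, pendant edges included and absent splits counted
as length zero — pendant branches carry most of the error-inflation signal.
A squared-difference (branch-score) variant would be a one-line change in
`rfl_distance` if needed for comparison. Rooted (clock) inferences are
unrooted before either metric so clock and non-clock outputs are scored
identically; zero-length branches retain their splits.

The package's replication experiments run at desk scale — 20 replicates of
10 taxa × 2,000 sites per condition, against the full-scale profile of 100
replicates of 20 taxa × 20,000 sites, which remains available through
`SimulationConfig`. The qualitative regimes are preserved at this scale:
declaring the true ε gives the most accurate branch lengths; with extreme
true error the inferred/true length ratio falls monotonically with declared
ε, passing 1 near the true rate and collapsing toward zero under aggressive
overcorrection (all variable sites read as error, topology randomized).

## Degenerate inputs and numerical notes

* Saturated pairwise data (log arguments ≤ 0) return bl_max with a warning.
* All-missing data give log-likelihood 0 up to ~10⁻¹⁵ rounding in
  transition-matrix row sums.
* Identical sequences drive all branches to bl_min rather than exactly 0,
  keeping transition matrices well-conditioned.
* PHYLIP input accepts sequential and interleaved dialects with relaxed
  (whitespace-delimited) names; output is sequential relaxed. Validation
  errors name the offending taxon and 1-based column.
* Newick writing uses 12 significant digits; round-trips preserve lengths
  to well below 10⁻⁹.

## Known limitations

Search is stepwise addition + NNI only (no SPR/TBR), so hard topologies can
land in local optima; there is no bootstrap, no Bayesian treatment of ε, no
rate heterogeneity, and only nucleotide data are supported. The error model
assumes independent, uniform miscalls — sequence-specific rates are
supported, site-specific and clustered errors are not.
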