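# Methods

## The model

A one-mode network on N elements is a square adjacency matrix **A**
with zero diagonal. Self-interactions (e.g. cannibalism in food webs)
are disregarded throughout: nonzero diagonal entries are zeroed at load
time with a warning, and the zero diagonal is what keeps UNODF strictly
below 1 even for maximally nested matrices. Networks with fewer than
3 nodes are rejected — the metric is degenerate there rather than zero.

UNODF averages, over all N(N−1)/2 node pairs, the overlap of the
lower-degree node's neighbourhood with the higher-degree node's,
*excluding* pairs with tied degrees (the decreasing-fill condition: a
set can only be a proper subset of a strictly larger set). Design
choices where the definition is silent:

* **Tied pairs stay in the denominator.** The prefactor is the literal
  2/(N(N−1)); a perfectly nested matrix with a tied middle pair
  therefore scores below 1 by construction.
* **Pairs whose smaller degree is zero contribute 0.** Isolated nodes
  (including those produced by thresholding) remain in N and in the
  normalization; the sweep reports their count (`n_isolated`) so the
  alternative convention (dropping them) can be evaluated externally.
* **Exact arithmetic.** Shared-link counts are integers; they are
  grouped by min-degree, summed as exact rationals and divided once at
  the end. The value is therefore bit-identical under any relabelling
  of the nodes, and the optimized implementation agrees bit-exactly
  with the naive triple-loop reference (`unodf_reference`), which
  exists purely as an independent testing oracle.
* **The earlier one-mode metric S** (`s_lee`) is implemented literally:
  the overlap sum runs over all l (immaterial for zero-diagonal
  matrices) and tied pairs contribute their full overlap. The only
  practical difference from UNODF is the missing Kronecker delta.

Directed networks have two values: rows (overlap of outgoing links) and
columns (incoming). For a symmetric matrix both orientations coincide
exactly and the column value is reused from the row computation. The
food-web reading of the two orientations is printed by the CLI with
explicit definitions rather than a bare label, because the field's
usage of "consumers"/"resources" for the two is not consistent.

## Thresholding sweep

Weighted networks are standardized by dividing all weights by the
global maximum, making cut-offs comparable across systems. At cut-off c
a link is present iff its standardized weight is ≥ c and > 0; cut-off 0
therefore keeps exactly the recorded interactions. The default grid is
0.0–0.9 in steps of 0.1. Comparison uses a 1e-9 tolerance below the
nominal cut-off so that a weight exactly equal to the cut-off is always
kept even when the grid value carries float artifacts (3×0.1 ≠ 0.3).

A binarized network is **dismantled** when no pair of nodes could
contribute to UNODF on any orientation: fewer than 3 nodes with degree
≥ 1, or no pair with unequal positive degrees. Dismantled records carry
no UNODF or significance values (the quantity is uninformative, not
zero). For directed networks the single flag requires degeneracy on
both orientations.

## Null model

The benchmark ensemble links each pair independently with probability
p_ij = (k_i + k_j)/(2(N−1)) (for directed networks,
(k_i^out + k_j^in)/(2(N−1)) per ordered pair). This preserves network
size exactly and connectance and degree heterogeneity in expectation:
the expected link count equals the observed one analytically, and the
expected degree of node i is affine in k_i with positive slope. The
exact one-mode formula is a design choice among "proportional to the
links of both nodes" rules; this one is the direct analogue of the
standard two-mode probabilistic null and reproduces connectance without
any rescaling.

Each binary network (one per cut-off in a sweep) gets its own ensemble,
by default 1000 replicates; samples are never re-standardized or
re-thresholded. Degenerate samples keep their trivial UNODF of 0 rather
than being resampled — resampling would bias the ensemble upward — and
their count is logged. Per-cutoff seeds are derived from the configured
seed through a `SeedSequence`, so sweeps are reproducible end to end
while cut-offs get independent ensembles.

Significance is two-sided: the observed value is flagged when outside
the percentile interval of the ensemble (95% by default, linear
interpolation between order statistics). The reported p-value is the
one-tailed upper add-one estimate p = (1 + #{null ≥ observed})/(1 + R),
so an observation above all 1000 replicates reports p = 1/1001 < 0.001
and an anti-nested observation below all replicates reports p = 1.0
while still being flagged by the CI rule. Both conventions are exposed
because the flag and the p-value answer different questions.

## Generators and what the synthetic conditions show

* `gen_perfectly_nested(N)`: nodes i, j (1-based) linked iff
  i + j ≤ N + 1 — the maximal staircase compatible with a symmetric
  zero-diagonal matrix. UNODF is 0.5 at N=4, 25/36 at N=6, rises
  monotonically and is ≈0.97 at N=50, approaching but never reaching 1.
* `gen_regular(N, k)`: circulant graph, k/2 neighbours each side. Any
  regular graph has UNODF exactly 0 (all pairs tied), which is the
  property the checkerboard archetype illustrates.
* `gen_random(N, C)`: Erdős–Rényi with link probability C.
* `gen_modular(N, blocks, p_in, p_out)`: planted partition with equal
  blocks (remainder nodes join the last block); p_in > p_out required.
* `gen_preferential(N, m)`: Barabási–Albert growth (via networkx).
* `attach_weights` gives each link an independent uniform-(0,1],
  unit-exponential or constant weight (symmetric for undirected
  networks) and standardizes, so the sweep can be exercised end to end.

At matched size and connectance the archetypes order as the theory
says: regular = 0 ≤ modular ≤ random < perfectly nested.

These generators produce idealized conditions: independent links, no
sampling effort structure, no weight–degree correlation. Passing tests
show the estimator, sweep and null model behave correctly under those
conditions; they do not certify behavior under the observational biases
of real association or interaction data (the null model's
degree-proportionality is designed to absorb some, not all, of that).

## Calibration conditions used by the tests and acceptance script

Detection power uses the perfectly nested N=30 network (100 runs of
1000 replicates; flagged in ≥95% of runs); the false-positive rate uses
Erdős–Rényi networks at the same N and connectance (flagged at the ~5%
two-sided nominal rate). The sweep check uses the N=40 staircase with
uniform weights over 9 seeds: link counts never increase with the
cut-off, and in a majority of seeds significance is lost at a cut-off
strictly below the first dismantled one. Oracle agreement is checked on
200 random networks with N between 3 and 12 across all densities, both
directed and undirected. These sizes keep the full suite and the
acceptance script within a couple of minutes on one core while leaving
the Monte-Carlo bands far narrower than the effects being asserted.

## Cross-network summaries

Connectance is L/(N(N−1)/2) (undirected) or L/(N(N−1)) (directed),
diagonal excluded. The per-network summary reports the sweep record
with maximal UNODF, ties broken toward the smallest cut-off (weak links
preserve more of the network and the smallest threshold is the least
manipulated binarization). Because UNODF rises with connectance on
random networks, the cross-network table also reports
connectance-corrected UNODF: residuals of an OLS regression (intercept
included) of column-wise UNODF on connectance, defined when at least
three networks with non-identical connectance are summarized.

## Known limitations

* The null model fixes expected, not realized, degrees; for very small
  or very sparse networks many replicates are degenerate and the CI is
  wide (the count of degenerate replicates is logged).
* The cut-off grid is fixed at 0.1 steps; no data-driven threshold
  selection is attempted beyond reporting the maximizing grid point.
* Weighted (quantitative) nestedness variants, fixed-degree-sequence
  (swap/curveball) nulls and alternative unipartite metrics
  (node-overlap/segregation, spectral radius) are out of scope.
* Matrix and edge-list text files are the only interchange formats.
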