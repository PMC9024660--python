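# Methods

This note documents the models, the synthetic-data design, and the
numerical choices behind `empanet`, in the spirit of a package methods
appendix. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Pipeline model

The pipeline starts at node time series (or precomputed connectivity
matrices); image acquisition and preprocessing are out of scope.

**Connectome stage.** Weighted connectomes are Fisher-z Pearson
correlations between nodal time series; |r| ≥ 1 − 1e−7 is capped before
atanh so duplicated series yield a large finite weight rather than
infinity. Binarization keeps exactly ⌊density · n(n−1)/2⌋ upper-triangle
entries (default density 0.10), ranked by **signed** z — the conventional
reading of "strongest connections" for binarized resting-state graphs; an
absolute-value mode is available by flag. Ties at the cutoff break by
lexicographic (i, j) order so the retained set is reproducible, and the
edge count is byte-identical across subjects by construction. Rounding uses
floor. Connectedness is *not* enforced after thresholding; all downstream
measures are defined on disconnected graphs.

**Community stage.** Modularity with resolution γ is maximized by a
Louvain implementation (randomized node order per pass, greedy local moves
plus aggregation) wrapped in iterated fine-tuning: each full Louvain pass
is re-seeded with the previous optimum and the loop stops when Q improves
by less than 1e−10. Q is non-decreasing over cycles by construction, and
every stochastic step takes an explicit seed. The modularity machinery
accepts arbitrary non-negative weights, so the same optimizer clusters
binary connectomes and weighted agreement matrices.

Group-level modules use Lancichinetti–Fortunato-style iterative consensus
clustering: the co-assignment proportion matrix is thresholded at the
chance co-assignment level of label-permuted input partitions (computed in
closed form from the partitions' module-size profiles), re-clustered with
many independently seeded restarts (default 1000) at γ = 1, and iterated
until all restarts agree (error after 50 iterations). Consensus of
identical partitions is idempotent. The module screen is a permutation
test: a module is kept when its mean within-module co-assignment exceeds
the 95th percentile of the distribution obtained by permuting node labels
of every subject partition. A module spanning the whole graph (or a
singleton module) is permutation-invariant and is kept vacuously with a
warning. This permutation operationalization is a documented design
choice; the classical module-significance procedure it stands in for is
not specified precisely enough in the literature to pin one variant.

**Nodal measures.** Degree, betweenness and closeness are delegated to
networkx; betweenness is reported unnormalized (raw shortest-path-fraction
sums over unordered pairs), which keeps slope magnitudes on the scale of
link counts, and closeness uses the Wasserman–Faust composite
(r_v/(n−1)) · (r_v/Σd), which is deterministic on disconnected graphs.
Participation and within-module degree are computed directly; the
within-module degree is z-scored with the **population** SD within each
module (modules with zero spread give z = 0), with the raw count available
by flag. All five measures are verified against exhaustive brute-force
oracles on every random graph with ≤ 8 nodes in the test suite.

**Behavior stage.** Subscale sums (15 odd items → VE, 15 even → IU, no
reverse-coding) are Box–Cox transformed with profile-ML λ (λ is stored per
subscale) and standardized to mean 0, SD 1 before entering association
models, so slope units are "metric change per SD of trait"; a raw-scale
option is retained. Sex contrasts use the pooled-variance two-sample
t-test with df = n − 2 — the df that a 116-subject two-group comparison
reports — not Welch. (A paired test is impossible for a male/female
contrast with unequal group sizes; the unpaired form is the only coherent
reading.)

**Association stage.** The nodal metric is the *outcome* and the trait the
predictor — the orientation in which "module nodes as random groupings"
and node-level random slopes are coherent. Sex is coded female = −0.5,
male = +0.5, so the trait main effect is the sex-averaged slope and
partial slopes follow exactly as slope(sex) = β + code(sex) · β_int.
Estimation is REML via statsmodels MixedLM with the crossed random
structure (subject intercepts, per-node trait slopes, scanning-group
intercepts) expressed as variance components in a single group. "Robust"
means the two-step screen the framework itself prescribes — per-node
Anderson–Darling normality of conditional residuals at α = 0.05, refit on
surviving nodes — not an M-estimator. FDR families are modules × metrics
within each (γ, trait) pair; the cross-γ model (modules significant at
≥ 2 resolutions) adds a random intercept per γ level and nests node slopes
within γ, and is the headline estimate.

## Numerical choices

* t statistics for fixed effects use a Satterthwaite-style between-subject
  denominator df of n_subjects − 5 (the subject-level fixed design has five
  parameters). This is slightly conservative; the type-I error of the trait
  effect measures ≈ 0.01–0.05 at the simulated sizes (computed by the
  calibration suite).
* Singular fits (a variance component pinned at ~0, non-convergence, or a
  non-finite standard error) trigger a refit without the weakest droppable
  random term — the γ-level intercept first, then the scanning group, never
  the node slope — and are flagged in the result. Boundary fits that leave
  an indefinite Hessian are retried with alternative optimizers
  (l-bfgs, cg, powell) before any term is dropped.
* The Anderson–Darling p-value uses the D'Agostino–Stephens
  piecewise-exponential approximation with the small-sample correction
  A*² = A²(1 + 0.75/n + 2.25/n²); it matches R's `nortest::ad.test` to
  four digits on fixed draws (frozen in the tests). The screen is
  approximately calibrated on conditional residuals; in very small cohorts
  BLUP estimation error induces mild scale-mixing and the realized
  exclusion rate rises above the nominal 5%, which is why calibration
  checks run at ≥ 60 subjects.
* Box–Cox λ is found by Brent maximization of the profile log-likelihood
  (scipy); the tests verify the fitted λ dominates a surrounding λ grid.
* Louvain tie-breaks: a node moves only on strict gain (> 1e−12); among
  equal-gain targets the lowest community label wins via argmax order.

## The synthetic cohort generator

The generator defines the study conditions under which the pipeline is
validated. Defaults mirror the emulated study design: 116 subjects, 62
female; age ~ N(23, 3²) truncated to [18, 35]; four scanning groups in
proportions 38/28/22/28; 418 nodes; VE–IU correlation 0.315; standardized
female−male VE difference d = 0.90 (the value implied by t₁₁₄ = 4.85 at
62/54); subscale reliabilities α = 0.92 (VE) and 0.95 (IU); planted
trait slope β = 3.2 per SD of transformed trait on degree in the first
planted module; variance components subject_sd = 1.0, node_slope_sd = 0.5,
group_sd = 0.5, residual_sd = 1.0 (not reported by any study; chosen once
as moderate heterogeneity, with between-subject noise comparable to the
residual and node-level slope spread at half the planted effect's scale).

**Items.** No generative model of the questionnaire exists in the
literature, so responses come from a two-factor ordinal model — a
stand-in, not an inference about the instrument: item latent
y = λF + ε with ε ~ N(0,1), thresholded into five equal-width categories
at ±0.5s, ±1.5s (s the pooled latent item SD); 15 odd items load on the
VE factor, 15 even on the IU factor; the VE factor mean is shifted for
females. Discretization attenuates correlations and the sex mixture
inflates pooled VE variance, so the loadings, latent correlation and
latent shift are *calibrated*: Gauss–Hermite moments of the discretized
mixture model are solved (hybrid Newton + Brent) so the **observed** pooled
α's, subscale-sum correlation and standardized sex difference hit their
configured targets. The calibration is exact to ~0.005 at large n
(verified by the marginal-calibration test at n = 2000).

**Connectomes.** Mode A draws binary adjacencies from a planted-partition
model (p_in = 0.4 within, p_out = 0.05 between by default) — the fast test
path. Mode B draws node time series from a block covariance
(within-block correlation 0.5, between 0.1, 400 time points by default)
and pushes them through the real Fisher-z + thresholding chain — the
integration path. Under hard proportional thresholding, planted blocks
survive binarization cleanly when the within-block pair fraction is close
to the retained density (e.g. 9 blocks of ~11 nodes at 10% density on 100
nodes); when blocks are much larger, the cut selects among equally strong
within-block pairs by sampling noise and between-block noise edges
concentrate on node pairs with aligned noise, so the modularity optimum
can genuinely deviate from the planted partition. Recovery tests use the
clean regime; this is a property of thresholded correlation graphs, not of
the detector.

**Planted effects.** `plant_effect` superimposes the generative
counterpart of the association model on a metric table: target-module
rows of the target metric gain (β + b_node + β_sex·sex_code)·trait, and
every row gains subject, group and residual noise. In pipeline runs from
the simulator the effect is superimposed on the graph-derived metric
baseline, so planted-effect demos exercise the full chain.

**What the simulator does not emulate.** BOLD hemodynamics, head motion,
preprocessing artifacts, spatial autocorrelation of parcels, non-Gaussian
trait distributions, and missing item responses. Passing calibration tests
therefore demonstrate the correctness and statistical calibration of the
*pipeline* under its own model assumptions, not robustness to real fMRI
artifacts.

## Problem sizes in the validation suite

The calibration studies run at reduced sizes chosen to keep a full
validation run at a few minutes on one CPU while leaving the statistics
well-posed: type-I error at 200 null replicates and recovery at 50
replicates of 30-subject cohorts (40 nodes, 10-node target module);
empirical FDR at 500 replicates of 12-subject families (2 modules × 2
metrics); consensus recovery on 25 subjects × 60 nodes. Sizes are function
arguments, not constants, and scale up unchanged.

## Known limitations

* The γ-level repeated-measures model treats resolutions as exchangeable
  levels; partitions at neighboring γ are in fact correlated, so its df
  are optimistic when many resolutions are pooled.
* Satterthwaite-style df are approximated, not computed from the
  information matrix; at ≥ 30 subjects the difference is negligible (the
  calibration suite measures the realized type-I error).
* The consensus procedure assumes the agreement structure stabilizes to
  block-constant; highly unstable cohorts raise a diagnostic error rather
  than returning a forced partition.
* An optional "adjusted modularity" (Q z-scored against degree-preserving
  rewired nulls, `community.adjusted_modularity`) is provided for
  exploration but deliberately excluded from the validated surface.
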