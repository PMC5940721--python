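# Methods

This note documents the statistical machinery in `dioxmark`, the choices
made where the underlying methodology leaves room, and what the synthetic
cohort does and does not establish.

## Data model

An `ExposureDataset` holds one subjects x congeners concentration table per
biological matrix (maternal blood, cord blood, cord tissue) with identical
subject and congener ordering, a same-shape boolean detect table (true =
measured above the LOD), and panel metadata (compound class, chlorine
count, WHO-2005 TEF, per-matrix LOD). Concentrations are positive and
carried either raw (pg/g fat) or TEQ-weighted (pg-TEQ/g fat); TEQ values
are additive across congeners, which is what makes group sums (total
PCDD/F, marker sums) meaningful.

## Preprocessing

* **LOD/2 substitution.** Every cell flagged below the LOD is replaced by
  half the congener's matrix-specific LOD. This is deliberate simplicity:
  substitution is the convention in this literature and keeps downstream
  ranks well defined; no likelihood-based censored imputation is offered.
  Substitution produces ties among censored values, which is why the
  clustering stage exposes a random tie-splitting rule (below).
* **Detection filter.** A congener is retained iff its detected fraction is
  >= 0.5 (inclusive) in *every* matrix, the denominator being the number of
  subjects. The filter reads only detect flags, so it commutes with
  substitution. On the bundled reference-cohort detection pattern
  (41 subjects) the rule retains 20 of 29 congeners: 9 PCDD/Fs and 11
  dl-PCBs (all except PCB#81), verified by a hand count in the tests.

## Spearman dissimilarity and clustering

Dissimilarity is `d = 1 - |rho|` with Spearman's rho computed as the
Pearson correlation of within-congener ranks; the absolute value makes the
measure direction-blind and `d` invariant under strictly monotone
re-expression of any congener. Ties take average ranks by default
(deterministic); `tie_rule="random"` splits them uniformly with a seed,
mirroring the rank-splitting used with LOD/2-substituted data. A congener
constant across subjects has no defined rank correlation and is rejected
under average ties (inside the bootstrap such degenerate resampled columns
are assigned zero correlation, i.e. maximal dissimilarity, rather than
aborting the replicate).

Agglomeration is hand-written Lance-Williams (average default, complete and
single available) with a documented tie-break — among equally close pairs,
the lexicographically smallest sorted pair of member index tuples merges
first — so dendrograms are bit-reproducible. Correctness is checked against
`scipy.cluster.hierarchy` on random tie-free instances; `min_decision_gap`
reports the margin of the closest merge decision, since merge order is only
comparable across implementations when no decision was a tie. Dendrograms
export to Newick with branch lengths equal to height differences; raw merge
heights are preserved (no rescaling).

## Multiscale bootstrap stability

For each internal node of the reference dendrogram, and for each sampling
fraction `lambda` in the default grid {0.5, 0.6, ..., 1.4} (the
conventional range with step 0.1), `B = 1000` resamples of
`round(lambda * n)` subjects are drawn with replacement and re-clustered
with the identical configuration. BP(node, lambda) is the fraction of
resample dendrograms containing exactly that member set. Fractions giving
fewer than 3 subjects are skipped with a warning.

The AU p-value comes from the two-parameter multiscale model: with
`z(lambda) = Phi^-1(1 - BP(lambda))`, the curve
`z = alpha*sqrt(lambda) + beta/sqrt(lambda)` separates a signed distance
(`alpha`) from boundary curvature (`beta`), and `AU = Phi(-alpha + beta)`.
A genuinely supported cluster has BP rising with `lambda`, `alpha`
negative, AU near 1. Note the orientation: `z` is the normal quantile of
the *complement* of BP. This is the convention of the multiscale bootstrap
as implemented in the standard cluster-stability software; with the
quantile taken of BP itself the resulting "AU" would *decrease* with
cluster support.

Three fitting schemes:

* `ml` (default): binomial maximum likelihood of the BP counts under
  `BP = 1 - Phi(z(lambda))`, over all sampling fractions. This is the only
  scheme that uses the information in *unanimous* fractions (BP exactly 0
  or 1, where the z-scale saturates at `±Phi^-1(1/(2B))`). At `B = 1000` a
  strongly supported cluster is typically recovered in every replicate at
  most fractions; least-squares fits through the few informative points
  are then noisy, while ML correctly pushes AU toward 1. Optimisation is
  L-BFGS-B with coefficients bounded in [-10, 10] (beyond the resolvable z
  range) and the least-squares fit as the start; the objective clips z to
  [-8, 8] so the likelihood stays finite.
* `wls`: weighted least squares on `z` at the informative fractions with
  delta-method binomial weights `B * phi(z)^2 / (BP(1-BP))`.
* `ols`: unweighted; on BP values lying exactly on a generating curve it
  reproduces `(alpha, beta)` to numerical precision (the exact-fit test).

Degenerate BP values are excluded from the least-squares fits. When fewer
than two informative fractions exist, the evidence is unanimous and AU
snaps to the clipped bound `1/(2B)` or `1 - 1/(2B)` on the majority side
(`alpha`/`beta` reported as NaN): a cluster recovered in all `B x
|lambdas|` resamples is reported as maximally supported, not discarded.

Stable clusters are those with `AU >= 0.95` (inclusive). Singletons and
the root are never flagged: their presence is vacuous. On planted
two-block cohorts (n=41, within-block latent correlation 0.9, between
0.1, B=1000, 10 fractions) both blocks are flagged stable in 20 of 20
seeds (the acceptance suite requires >= 18).

## MGV transformation

The maximum generalized variance method re-expresses each congener so the
set is maximally mutually predictable. Each congener gets a restricted
cubic spline basis (k = 3 knots at its 10th/50th/90th percentiles; a
k-knot RCS contributes k-1 columns and is linear beyond the boundary
knots). Sweeping congeners in fixed column order (Gauss-Seidel), column j
is replaced by the basis-side first canonical variate against the current
transformed scores of the others, standardized to mean 0 / variance 1
(ddof = 1) with its sign anchored to non-negative Spearman correlation
with the raw values (canonical variates are sign-indeterminate). Sweeps
stop when the largest entry change falls below `tol = 1e-6` (default cap
50 sweeps).

Numerical choices: spline-basis columns are centred and scaled to unit
variance before the canonical step — canonical variates are scale
invariant in exact arithmetic, but raw cubic terms of concentrations
spanning orders of magnitude are catastrophically ill-conditioned without
this; a rank-deficient canonical system gets a 1e-8 ridge with a warning.
Initialisation is standardized Blom normal scores of the ranks
(deterministic); `init="raw"` makes an exactly linear pair a fixed point
of the first sweep, and `init_scores` warm-starts from a previous result
(the converged state is a fixed point of the sweep operator to within
10 x tol).

Two caveats discovered and documented rather than papered over. First,
exact invariance of the output under monotone re-expression of an input
column requires the spline bases themselves to be rank-based
(`basis_scale="rank_normal"`); with the conventional raw-scale bases
(default) the RCS function space is not closed under monotone maps and
invariance holds only approximately. Second, the per-congener canonical
correlation is *not* monotone across sweeps (columns are jointly
optimised and trade off early on, with fluctuations around 2e-3); it
settles, and the tests assert convergence to within 1e-2 of the running
maximum rather than a false monotonicity.

By default MGV is applied within each stable cluster separately (the
cluster is the unit being summarised); applying it jointly to all
congeners is possible by passing the full table.

## PC1 summary and marker selection

Clusters with more than two members are summarised by the first principal
component of the correlation matrix of the MGV scores; `pc1_var` is the
leading eigenvalue over the member count, and the sign is fixed so the
loading sum is positive. Two-member stable clusters bypass PCA and are
reported as their own markers.

Marker selection regresses the PC1 score on the concatenated 3-knot
spline bases of the members' original-scale (imputed TEQ) concentrations,
with intercept, and deletes whole congeners (both spline columns at once)
greedily: at each step the congener whose removal leaves the largest
refitted R² goes, stopping before R² would cross below the 0.95 target.
If even the full model misses the target, all members are kept and the
result flagged. R² is weakly decreasing along the path (nested models).
Greedy deletion can in principle miss the exhaustive-search minimal
subset; on planted two-driver six-congener problems (n=41) it matched the
exhaustive oracle in 20/20 seeds, and the acceptance suite logs any
disagreement instead of hiding it.

## Correlation analyses

Spearman rho with percentile bootstrap CIs: subjects are resampled in
pairs (B = 10,000 default), interval endpoints are the
`(1±level)/2` percentiles of the resampled rho distribution, and the
interval is widened to include the point estimate in the rare resampling
configurations where a percentile bound crosses it (keeping the invariant
`ci_low <= rho <= ci_high`). All-tied degenerate resamples are dropped.
Coverage at true Spearman rho = 0.7 (bivariate normal via the sine rule,
n = 41, 500 simulations, B = 2000) measures 94-95%.

The marker-sum analysis correlates, per matrix, the TEQ sum of the
selected dl-PCB markers (plus PCB#77, configurable — PCB#77 behaves
idiosyncratically across matrices and is conventionally added to the
representative sum) against the total of the retained PCDD/Fs. For cord
tissue a second variant adds the higher-chlorinated dl-PCBs (#114, #156,
#157, #167, #169, #189), so the standard report has four rows.

## Synthetic cohort: what it emulates and what it does not

The generator draws, per subject, a latent multivariate normal with a
block-structured correlation matrix (`rho_within` inside planted blocks,
`rho_between` elsewhere; compound-symmetric blocks are always positive
semi-definite given `rho_between <= rho_within`). A single shared
subject-level factor with loading 0.8 ties the three matrices together
(implied same-congener cross-matrix latent correlation 0.64). Marginals
are lognormal, located so the concentration-scale median equals the
target and scaled so Q3/Q1 matches the target IQR ratio. LODs sit at the
`1 - detect_target` quantile (theoretical, or between order statistics
with `lod_placement="empirical"` for exact detection counts); censored
cells keep their true values until `impute_lod` runs.

Defaults reproduce the study conditions: 41 subjects, 29 congeners, per
congener-and-matrix medians/IQRs/detection counts from the bundled
reference-cohort summary, planted blocks mirroring the reported stable
clusters (low/medium dl-PCBs #105/#118/#123/#126; medium/high
#114/#156/#157/#167/#169/#189; the HxCDF pair; the PeCDD/PeCDF pair),
`rho_within = 0.9`, `rho_between = 0.3`. Fully censored congeners carry
small placeholder locations (only their censoring behaviour matters).

What passing tests on this cohort do *not* show: real congener panels
have heavier-than-lognormal tails, matrix-specific measurement error,
exposure-source correlation structure that is not block-constant, and
cross-matrix transfer that depends on molecular weight rather than a
single shared factor. The planted-block experiments validate the
machinery (the pipeline recovers structure that is truly there), not the
epidemiological conclusions of any particular cohort; marker-sum
correlations under the default `rho_between = 0.3` are intentionally
moderate and below those reported for real cohorts.

## Problem sizes and determinism

Default experiment sizes (20 seeds x 10 fractions x 1000 replicates for
planted-block recovery; 500 simulations x 2000 replicates for CI
coverage; 100 instances for the clustering oracle) were chosen so the
whole suite and the acceptance script each run in minutes on one CPU.
Every stochastic stage takes an explicit seed; the pipeline derives
per-stage substreams from one master seed via `SeedSequence([seed,
stage])`, and two runs with the same configuration write byte-identical
report bundles (verified in the tests).

## Known limitations

* LOD/2 substitution biases low-detection congeners' ranks; the filter
  keeps such congeners out, but at thresholds below 0.5 the random
  tie-splitting rule should be preferred.
* AU p-values inherit the known small-sample optimism of the two-parameter
  multiscale model when BP is near-degenerate; the ML fit mitigates but
  does not remove it.
* Greedy backward deletion is not guaranteed minimal; the exhaustive
  oracle is exponential and only feasible for small clusters.
* The generator's single shared cross-matrix factor cannot represent
  congener-specific placental transfer efficiency.
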