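# dioxmark

Identifying **fetal-exposure marker congeners** among dioxins (PCDD/Fs) and
dioxin-like PCBs measured in maternal blood, umbilical cord blood and
umbilical cord tissue.

Biomonitoring panels report dozens of congeners per specimen, each weighted
by its WHO-2005 toxic equivalency factor (TEF) so that congener TEQs
(concentration x TEF, pg-TEQ/g fat) are additive. Measuring all of them in
every matrix is expensive, and many sit below the assay's limit of detection
(LOD). If groups of congeners co-vary tightly across subjects, a small
representative subset can stand in for the whole group. This package
implements that marker-identification pipeline for 41-subject, three-matrix
cohorts, together with a calibrated synthetic-cohort generator so every
stage is testable without access to restricted human data.

## Method

For each biological matrix:

1. **Censoring and detection filtering.** Values below the LOD are set to
   LOD/2; only congeners detected in >= 50% of samples in *all three*
   matrices are analysed further.
2. **Co-variation clustering.** Congeners are clustered hierarchically
   (average linkage) on the dissimilarity `d = 1 - |rho|`, with `rho`
   Spearman's rank correlation over subjects.
3. **Cluster stability.** Multiscale bootstrap: subjects are resampled at
   sampling fractions `lambda in {0.5, ..., 1.4}` (B = 1000 per fraction);
   the bootstrap probability BP(lambda) of each dendrogram node is mapped
   to `z = Phi^-1(1 - BP)` and the curve
   `z(lambda) = alpha*sqrt(lambda) + beta/sqrt(lambda)` is fitted
   (binomial maximum likelihood by default), giving the approximately
   unbiased p-value `AU = Phi(-alpha + beta)`. Clusters with AU >= 0.95 are
   *stable*.
4. **Marker selection.** Each stable cluster with more than two members is
   transformed by the maximum generalized variance (MGV) method —
   restricted cubic splines plus iterated canonical variates — and
   summarised by its first principal component. A linear model predicts
   the PC1 score from 3-knot spline bases (knots at the 10th/50th/90th
   percentiles) of the member concentrations, and congeners are deleted
   backwards until R² would fall below 0.95; the survivors are the
   cluster's markers (`PCB_R` for the dl-PCB clusters).
5. **Marker-sum validation.** The TEQ sum of the selected dl-PCB markers
   (plus PCB#77) is correlated with total PCDD/F per matrix (Spearman rho,
   10,000-replicate percentile-bootstrap 95% CIs), and per-congener
   correlations between matrix pairs quantify how well one specimen type
   proxies another.

The synthetic generator draws block-correlated lognormal concentrations
whose medians, IQR ratios and per-matrix detection counts match the
published summary of a 41 mother-infant pair cohort (29 congeners:
7 PCDDs, 10 PCDFs, 12 dl-PCBs), with planted co-variation blocks and a
shared latent factor tying the three matrices together.

## Worked example

```bash
python analysis/01_simulate_cohort.py --seed 1
python analysis/02_preprocess.py
python analysis/03_cluster_stability.py --seed 1
python analysis/04_select_markers.py
python analysis/05_correlations.py --seed 1
```

The run above prints (abridged):

```
20 of 29 congeners pass the 50% detection rule in all three matrices
maternal_blood: 4 stable clusters (AU >= 0.95)
  AU=1.000  {PCB114, PCB156, PCB157, PCB167, PCB169, PCB189}
  AU=1.000  {PCB105, PCB118, PCB123, PCB126}
  ...
maternal_blood: cluster of 4 -> markers [PCB118+PCB126]  (PC1 var share 0.93, R2 0.98)
...
marker sum (PCB77 + selected dl-PCBs) vs total PCDD/F:
  maternal_blood         rho= 0.38  95% CI [ 0.06,  0.64]
  cord_blood             rho= 0.55  95% CI [ 0.30,  0.74]
  cord_tissue            rho= 0.43  95% CI [ 0.12,  0.67]
  cord_tissue+extra      rho= 0.50  95% CI [ 0.20,  0.72]
```

Reading it: the detection filter keeps 20 of 29 congeners (11 dl-PCBs and
9 PCDD/Fs); both planted dl-PCB blocks are recovered as stable clusters
with AU ~ 1; the low/medium chlorinated cluster {#105, #118, #123, #126}
reduces to the marker pair {#118, #126} whose spline model still explains
98% of the cluster's PC1; and the marker TEQ sum tracks total PCDD/F with
moderate positive rank correlations (the synthetic between-block latent
correlation is 0.3, so these are lower than in real cohorts where shared
exposure sources couple the groups more tightly).

Equivalently, one call runs everything: `run_pipeline(RunConfig(seed=1,
outdir="out"))`.

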