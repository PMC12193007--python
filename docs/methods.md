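# Methods

## The model

`substage` implements subtype-and-stage inference for cross-sectional
biomarker cohorts in the event-based modelling tradition. Disease
progression is treated as a monotone accumulation of *events* — each
biomarker transitions once from a "normal" to an "abnormal" state.
To keep the ordering search tractable for high-dimensional panels
(d ≈ 100+ features), biomarkers are grouped into K *event clusters*
that transition together, so a trajectory is a permutation σ of the K
clusters and a subject's stage s ∈ {0, …, K} counts the clusters that
have transitioned. With K = 5 (the study-scale preset) this yields a
six-stage progression. Heterogeneity is captured by a mixture of C
subtypes, each with its own ordering σ_c and mixing fraction f_c.

Per feature j, a two-component Gaussian mixture supplies the normal
density f_no(x_j) and abnormal density f_ab(x_j). The data likelihood
of subject i with feature vector x_i is

    P(x_i) = Σ_c f_c Σ_{s=0}^{K} π(s) ·
             Π_{r≤s} Π_{j∈cluster σ_c(r)} f_ab(x_ij) ·
             Π_{r>s} Π_{j∈cluster σ_c(r)} f_no(x_ij)

with a uniform stage prior π(s) = 1/(K+1). All computation is in log
space with log-sum-exp, and per-feature log densities are floored at
−700 so a subject's likelihood is finite whenever any (subtype, stage)
explains them at all.

## Preprocessing

* **Orientation.** Each feature is multiplied by ±1 so that the AD-arm
  mean is at least the CN-arm mean; abnormality then always points
  upward (ventricular expansion and cortical atrophy end up on the same
  footing). Signs learned on the training arms are reused verbatim on
  validation data.
* **QC filters.** Features are dropped and logged when (a) their
  variance is ≤ `variance_eps` (default 0: exactly constant), (b) their
  excess kurtosis exceeds 10 (too heavy-tailed for a Gaussian mixture),
  or (c) the mixture fit degenerates — no EM convergence within 500
  iterations, a component SD collapsing below 1e-6 of the feature SD, a
  mixing weight within 0.01 of the boundary, or component means closer
  than 0.5 within-component SD. The last rule exists because EM on
  genuinely single-component data happily converges to two coincident
  means; such a fit carries no event information and must be flagged
  rather than used.
* **Mixture fit.** Two Gaussians with a *shared* variance, normal
  component initialised from the CN arm and abnormal from the AD arm,
  relabelled if necessary so the abnormal mean is the larger. The tied
  variance is a deliberate restriction: it makes the event posterior
  p_event(x) = w·f_ab / (w·f_ab + (1−w)·f_no) monotone in the oriented
  value, which free variances cannot guarantee (their likelihood ratio
  is non-monotone in the tails).
* **Missing values** contribute posterior 0.5 and unit densities to
  both components — the subject-level likelihood is unchanged by an
  unobserved feature, which keeps staging well-defined under arbitrary
  missingness without imputation.
* Covariate adjustment of features before mixture fitting is *not*
  performed; an orientation-sign override hook exists for callers who
  pre-adjust.

## Event clustering

Features are grouped by average-linkage agglomerative clustering on
correlation distance (1 − r) between their event-probability vectors
across training subjects, cut at K clusters. If a cluster falls below
the minimum size (default 8), undersized clusters are merged into their
nearest neighbour and the dendrogram cut is deepened until exactly K
admissible clusters remain. The clustering algorithm is a replaceable
strategy — the compound-event semantics (all members flip together) is
what the rest of the model depends on.

## Fitting

1. **C = 1.** Greedy ascent over orderings from 16 random restarts.
   The move set is pairwise swaps *plus* remove-and-reinsert
   (insertion) moves; swap-only ascent provably stalls when restoring a
   displaced event requires two coordinated swaps whose intermediate
   ordering is worse.
2. **Hierarchical buildup.** To reach C subtypes, every current
   subtype is tentatively split — its hard-assigned subjects are
   randomly bipartitioned and a one-subtype model fitted to each half —
   the full model re-optimised for each candidate split, and the most
   likely kept. The whole buildup is restarted a few times (default 3)
   with different bipartitions.
3. **EM refinement.** Joint local optima in which two orderings must
   change together are escaped by EM over the latent subtype
   assignment: responsibilities form the E-step and a *full* greedy
   refit of each subtype's ordering on its responsibility-weighted
   subjects forms the M-step, which never decreases the likelihood.
   Local ascent and EM alternate to convergence. (We observed valleys
   ~1400 log-likelihood units deep that single-ordering moves cannot
   cross; this step removes them.)
4. **MCMC.** Metropolis–Hastings from the fitted state characterises
   uncertainty. Moves alternate between swapping two positions in one
   randomly chosen subtype's ordering and perturbing the fractions with
   renormalised Gaussian noise (step 0.05); both are accepted by
   likelihood ratio. Joint swap+fraction proposals were rejected
   essentially always on well-separated data, freezing the chain, which
   is why the moves alternate. The returned point model is the most
   likely state ever visited, including the initialisation, so sampling
   can only improve on the optimiser. The study-scale schedule is
   2×10⁶ draws with 10⁶ burn-in; tests and the acceptance script use
   2×10⁴/10⁴, which recovers planted orderings exactly at the effect
   sizes simulated.
5. **Model selection.** The subtype count is chosen by maximum fitted
   log likelihood over a candidate set (default {2, 3, 4}); ties within
   1e-6 resolve to the smaller count. Note that raw-likelihood
   selection has no complexity penalty: on finite data a C+1 model
   typically fits at least as well, so selection is meaningful only
   when the planted/true structure separates candidates clearly.

Exact likelihood ties in the greedy search resolve toward the
lexicographically smallest ordering. Every stochastic operation
requires an explicit seed and refuses to run without one.

## Assignment of held-out subjects

Validation subjects never influence mixture fits, orientation signs or
clustering. For each of `n_draw` (default 1000) MCMC samples drawn
without replacement, a subject's joint weight over (subtype, stage) is
w(c, s) ∝ f_c π(s) P(x | σ_c, s), normalised; the reported posterior is
the mean over draws, and point labels are marginal argmaxes (ties to
the smaller index). The expected stage is emitted alongside as a
sensitivity column, and a per-sample majority-vote variant is available
(`method="vote"`). Subjects whose likelihood underflows everywhere get
a uniform posterior and a warning.

A structural caveat: at stage 0 and stage K every ordering yields the
same likelihood, so the subtype posterior there reduces to the mixing
fractions — subtype is unidentifiable at the extremes of progression
from a single visit. Recovery metrics therefore report subtype accuracy
over subjects with 1 ≤ true stage ≤ K−1; stage error is reported over
everyone.

## Statistical validation layer

* **Cox comparison** (lifelines, Efron ties): baseline model with age,
  gender (0 = female reference), education and APOE4 allele count
  versus a full model adding stage and one-hot subtype with the most
  prevalent subtype as reference. Reported per model: in-sample
  concordance index, AIC = 2k − 2 log PL, hazard ratios with 95% CIs;
  plus a log-rank test of stage ≤ median versus the rest (the grouping
  for the headline log-rank statistic is a package choice).
* **Nested linear models** (statsmodels OLS): covariates / +stage /
  +stage+subtype, reporting the adjusted-R² ladder, the stage
  coefficient from the full model and the full-model F-test p.
* **Logistic associations**: the full logistic fit with a
  likelihood-ratio test against the covariate-only model; McFadden
  pseudo-R² fills the ladder. Perfect separation is flagged
  ("non-estimable") rather than raised.
* **Subtype contrasts**: outcome values are residualised on covariates
  + stage by OLS, then all subtype pairs are compared with two-sided
  Mann–Whitney tests and Benjamini–Hochberg adjustment over the pair
  family. Residualisation is our reading of "adjusted" rank tests;
  stratified or regression-based analogues would be alternatives, and
  the choice is isolated in one function.

## The synthetic cohort generator

The generator emulates the structure of an ADNI-style study and is the
ground truth for every end-to-end test. Defaults: 123 raw features of
which 4 are exactly constant and 1 is standard Cauchy (so the QC layer
has real work and retains 118); 5 event clusters with features assigned
round-robin; 4 subtypes with orderings chosen so the *set* of
transitioned clusters differs between every pair of subtypes at every
intermediate stage (otherwise subtype recovery is structurally capped
below any reasonable threshold); subtype fractions (0.40, 0.25, 0.20,
0.15) so a unique most-prevalent reference subtype exists; CN (n = 504)
at stage 0 and AD (n = 346) uniform on the last two stages — the
training arms are diagnostic extremes — and MCI (n = 808) uniform over
all stages with subtype drawn from the fractions.

Feature values are unit-variance Gaussians separated by `effect_size`
(default 2.0 SD, a typical CN/AD separation for volumetric z-scores;
recovery experiments use 2.0–2.5). About 30% of features are
sign-flipped to emulate markers measured on an inverted scale.
Conversion times for the MCI arm follow an exponential proportional
hazards model: baseline 4×10⁻⁴/month (≈35–40% conversion over the
follow-up window), per-stage log HR log(1.77), subtype log HRs
(0, log 2.50, log 2.03, log 2.24) against subtype 1, mild covariate
effects, administrative censoring at 96 months. Outcome scores are
linear (or logistic) in stage after covariate effects, with defaults on
the scale of delayed-recall (β_stage = −0.8), FDG-PET (−0.035) and a
binary drawing task (−0.33).

Because the CN/AD training arms occupy only stages {0, K−1, K}, they
identify the mixtures, the orientation and the clustering but *not*
the order of the first K−1 events — a property of any design that
trains on diagnostic extremes. Ordering-recovery experiments therefore
fit the subtype model on a stage-spanning arm (the MCI-type cohort)
while keeping mixtures and clustering strictly training-derived; the
pipeline's default end-to-end run still fits on the training arm, as a
real study would, and its staging of held-out subjects is dominated by
the last-event information that design provides.

What the generator does **not** emulate: longitudinal within-subject
trajectories, realistic spatial covariance between regional features
(features are conditionally independent given the latent state),
measurement batch effects, and informative missingness. Passing tests
therefore demonstrate correctness of the inference machinery under the
model's own assumptions, not robustness to their violation on real
imaging data.

## Problem sizes and numerics

Tests and the acceptance script run the sampler at 2×10⁴ total /
1×10⁴ burn-in draws, select the subtype count on a 1000-subject
stage-spanning arm, and evaluate recovery on a held-out 500-subject
arm across three seeds — sizes at which the planted structure is
recovered exactly while a full run stays in minutes on one CPU. The
study-scale MCMC schedule (2×10⁶/10⁶) is available as the pipeline
preset. Fraction EM runs to a 1e-10 log-likelihood tolerance with
fractions floored at 1e-12; posterior normalisation is checked to
1e-9; stage priors and fractions are validated to sum to one.

## Known limitations

* Raw-likelihood subtype-count selection will overfit C upward on weak
  or abundant data; cross-validated or penalised selection is out of
  scope.
* The concordance index is computed in-sample, as in the validation it
  mirrors; with few events and several covariates it is optimistic.
* Subtype labels are only identifiable up to permutation; all recovery
  metrics match labels by Kendall-tau assignment before scoring.
* Single-visit staging cannot distinguish subtypes at the extremes of
  progression (see above); longitudinal smoothing is a non-goal.
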