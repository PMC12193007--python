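# substage

Subtype and stage inference for event-based disease progression, with
the survival and regression machinery used to judge whether a staging
model carries clinical signal.

## The problem

Neurodegenerative diseases such as Alzheimer's progress heterogeneously:
different patients accumulate biomarker abnormalities in different
orders and at different rates, and a single cross-sectional visit gives
no direct handle on either. Event-based models infer the *order* in
which biomarkers turn abnormal from purely cross-sectional data, and
place each subject at a *stage* along that order. `substage` implements
the scalable clustered variant of this idea for high-dimensional
biomarker panels: features are grouped into K event clusters that
transition together, a trajectory is a permutation σ of the clusters,
and a population is a mixture of C subtypes with orderings σ₁…σ_C and
fractions f₁…f_C. The likelihood of subject i is

    P(xᵢ) = Σ_c f_c Σ_{s=0}^{K} π(s) ∏_{r≤s} ∏_{j∈σ_c(r)} f_ab(xᵢⱼ)
                                     ∏_{r>s} ∏_{j∈σ_c(r)} f_no(xᵢⱼ)

where f_no/f_ab are per-feature normal/abnormal Gaussian mixture
components and π is a uniform stage prior. With the default K = 5 this
gives a six-stage progression (stages 0–5). Orderings are fitted by
greedy search with hierarchical subtype splitting and EM refinement,
uncertainty is sampled by Metropolis–Hastings over orderings and
fractions, and held-out subjects are subtyped/staged by averaging their
joint (subtype, stage) posterior over stored MCMC samples.

The package is aimed at methodologists who want a fully testable
progression-modelling pipeline: every stage — cohort simulation with
planted ground truth, feature QC and mixture fitting, event clustering,
model fitting and selection, out-of-sample assignment, and the Cox /
nested-regression / contrast validation layer — is a documented,
seedable component.

## Worked example

```python
import numpy as np
from substage import (default_study_config, generate_cohort,
                      EventMixturePreprocessor, SubtypeStagingModel,
                      cox_compare, assignments_to_frame, assign_subjects)

cfg = default_study_config().replace(seed=1, effect_size=2.5)
train, mci, survival, outcomes, truth = generate_cohort(cfg)

pre = EventMixturePreprocessor().fit(train)
print(len(pre.retained_features_), len(pre.removal_log_))
# 118 5       <- 4 constant + 1 heavy-tailed column removed from 123

est = SubtypeStagingModel(n_subtypes=(2, 3, 4), n_mcmc=20_000,
                          n_burn_in=10_000, random_state=1)
est.fit(pre.transform(mci))
print(est.n_subtypes_, {c: round(ll) for c, ll in
                        est.candidate_log_likelihoods_.items()})
# 4 {2: -152138, 3: -143752, 4: -137792}   <- four subtypes most likely

labels = est.predict(pre.transform(mci))   # columns: subtype, stage
survival[["subtype", "stage"]] = labels
comp = cox_compare(survival)
print(round(comp.base.concordance_index, 2),
      round(comp.full.concordance_index, 2))
# 0.59 0.75   <- stage+subtype add prognostic value over demographics+APOE4
```

The preprocessor learns orientation signs, QC filters and per-feature
two-component mixtures on the CN/AD training arms only; `transform`
maps any cohort into event-probability space with those frozen
parameters, so validation subjects never leak into training. The
estimator clusters features into five compound events, compares 2–4
subtypes by likelihood, and keeps the MCMC samples used later for
posterior-averaged subject assignment.

A command-line interface mirrors the library
(`substage simulate | preprocess | fit | assign | run-all`), driven by
a YAML config with one global seed; `run-all` writes every intermediate
artifact plus a manifest of seeds, runtimes and output hashes.

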