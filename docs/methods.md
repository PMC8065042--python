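# Methods

## Observation model

Each row of the ID table is one published stage-specific estimate of
inbreeding depression, δ = 1 − w_self/w_out, together with its reported
standard error. Depression is positive when inbred progeny do worse;
negative values (outbreeding depression) are admitted. Values above 1 are
impossible for a true fitness ratio but can arise from digitized figures
and from the unbounded observation model, so the loader flags them with a
warning rather than rejecting.

The meta-regression is a non-nested multilevel model with a location-scale
Student-t likelihood:

    y_i ~ t(Θ_i, σ_y·SE_i, df)
    Θ_i = μ + α·F_i + β_l + γ_m + δ_lm + ε_l·F_i + a_j + b_o

* the t tails protect the fit against the occasional wild estimate that a
  normal likelihood would let dominate;
* the residual scale is proportional to each study's reported SE, so
  precise studies are weighted up, with a single free multiplier σ_y that
  absorbs over- or under-statement of the published errors (σ_y ≈ 1 would
  mean the reported SEs are calibrated);
* study intercepts a_j and species intercepts b_o are crossed ("non-nested")
  normal random effects that absorb study design and species baseline
  differences;
* F enters as a covariate (its values 0.125–0.75 are directly comparable
  across crossing designs); α is the overall per-unit-F slope and ε_l its
  stage-specific deviation. A configuration flag (`f_as_factor`) instead
  treats F as a categorical factor, as a sensitivity analysis, because the
  linearity of ID in F is an assumption, not a law.

Life stages are coded 1 embryonic (seed-quality traits), 2 juvenile
vegetative (first-year germination traits), 3 adult vegetative and 4 adult
reproductive (height/diameter/survival, split at 12 growing seasons, the
assumed age of first reproduction). Stem volume and sectional area are
rejected as fitness traits: as powers of height and diameter they inflate
apparent depression. Where a study reports the same treatment combination
(study, species, stage, F, trait) for several populations, only the
lowest-SE estimate is kept; ties keep the first row and warn.

## Identification and priors

Each categorical effect vector is constrained to sum to zero by giving it
K−1 free coefficients with the last element equal to minus their sum.
The stage×connectivity interaction δ is treated as a single 8-level vector
under this scheme (7 free coefficients, total sum zero). Because the
8-level interaction space contains the row- and column-shift directions
already spanned by β and γ, individual β/γ/δ levels are only weakly
likelihood-identified; their marginal posteriors are regularized by the
N(0, 5²) priors and can remain wide, while every estimable combination
(fitted means, predictions, contrasts) is tight. This is a property of the
chosen coding, kept deliberately; interval-based significance labels for
individual interaction levels should be read with that in mind.

Default priors: N(0, 5²) on all location parameters (effects are on the
ID scale, where |δ| ≤ 1, so 5 is diffuse); U(0, 10) on σ_a, σ_b, σ_y;
Gamma(2, 0.1) (mean 20, sd ≈ 14) on the t degrees of freedom, which keeps
mass both on heavy-tailed (df < 10) and effectively normal (df > 30)
regimes. All are overridable through `MetaPriors`.

Significance labelling follows the two-level convention: *significant* if
zero is outside the central 95% credible interval, *marginal* if outside
the 90% interval.

## Posterior computation

The sampler is an exact blocked Gibbs scheme built on the normal/gamma
scale-mixture representation of the Student-t
(y_i | λ_i ~ N(Θ_i, σ_y²SE_i²/λ_i), λ_i ~ Gamma(df/2, df/2)):

1. all location parameters (fixed effects plus both random-intercept
   blocks, typically 50–80 dimensions) are drawn **jointly** from their
   exact multivariate-normal conditional via one Cholesky factorization
   per sweep — cross-correlations, including the weakly identified
   directions, are handled exactly;
2. σ_a², σ_b² have truncated inverse-gamma conditionals under the uniform
   priors on σ (shape (K−1)/2, scale Σx²/2, truncated at the prior bound),
   sampled by inverse-CDF;
3. σ_y and df are updated by univariate slice sampling (stepping-out +
   shrinkage, on the log scale) against the **λ-marginalized** Student-t
   likelihood; marginalizing the mixing weights removes the strong
   λ–(σ_y, df) coupling that otherwise slows mixing by an order of
   magnitude;
4. λ is then re-imputed from its exact gamma conditional, serving only as
   the auxiliary variable for the next location update.

Every conditional is exact, so there is no step-size tuning and no
rejection. Defaults: 4 chains × 1000 kept draws after 1000 warmup sweeps.
Chains are seeded from a single `SeedSequence`; runs are bitwise
reproducible. Convergence is summarized by split-R̂ and ESS (arviz) on the
scalar parameters; R̂ > 1.01 or ESS < 100 flags the fit (returned anyway,
with the report in `diagnostics`). The pointwise log-likelihood matrix
(chain × draw × observation) is evaluated analytically from the t density
and drives PSIS-LOO.

The Fst beta regression (Fst_i ~ Beta(μ_iφ, (1−μ_i)φ), logit(μ_i) =
intercept + marker + species, both effect vectors sum-to-zero) is a
22–25-parameter posterior sampled with emcee's affine-invariant ensemble
(64 walkers, 1500 burn-in steps, thinned to 10,000 stored draws). Priors:
N(0, 2²) on logit-scale effects (Fst spans roughly 0.002–0.65, i.e. about
±3 logit units, so 2 is weakly informative), Gamma(2, 0.1) on the
precision φ. Because ensemble walkers are not independent chains,
convergence is judged from the integrated autocorrelation time: the run is
flagged unless the effective sample size (total draws / ACT) exceeds 400
and the chain spans at least 10 ACTs.

## Connectivity clustering

For the model-2 partition, each of 10,000 repetitions takes one posterior
draw of the species-effect vector and splits it into k = 2 groups. In one
dimension the converged k-means solution is a threshold split of the
sorted values, so the split is computed **exactly** by scanning all n−1
thresholds with prefix sums — this removes initialization nondeterminism
and is verified in the tests against both brute force and scikit-learn's
KMeans. Repetitions where the draw is constant are skipped and counted.
Label switching is fixed by anchoring: the cluster containing the anchor
species (default: the species with the highest observed mean Fst, the
Serbian spruce in the bundled table) is "fragmented". A species'
`prob_fragmented` is its across-repetition frequency in the anchor's
cluster and the final assignment is the majority vote.

Clustering operates on the marker-adjusted species-level Fst,
inv_logit(intercept + species effect), rather than on raw logit effects:
distances between species are then expressed in differentiation units,
whereas logit distances exaggerate the separation between weakly
differentiated species (0.006 vs 0.02 is two logit units but biologically
negligible). Group Fst summaries are reported as the mean and sd of the
**observed** per-species average Fst within each group, computed over the
records given to the regression.

Marker filtering retains codominant nuclear systems only (SNP, nuclear
SSR including EST-SSR, isozymes/allozymes); organellar (cpSSR) and
dominant (AFLP, RAPD) markers are dropped, since their Fst values are not
comparable with codominant nuclear estimates. One consequence on the
bundled table is that *Pinus nigra* (organellar data only) drops out of
the regression and is left unpartitioned.

### Reference values for the bundled table

On the bundled compilation the pipeline yields a fragmented group of
{*Picea omorica*, *Pinus pinaster*, *P. radiata*, *P. pinceana*,
*P. monticola*} with observed group Fst means of about 0.178 (fragmented)
and 0.042 (continuous), stable across seeds. The survey from which the
table derives prints 0.241 and 0.037 for these quantities. The continuous
group reproduces; the fragmented group's printed value is arithmetically
consistent only with averaging **all** of the table's rows — including the
dominant/organellar marker rows (one of them an Fst of 1.000, outside the
admissible open interval) — over the survey's published 8-species
partition, which includes two species whose only admissible data are
organellar. Under the survey's own stated marker filter, which this
package enforces, that value is not reachable; the package reports the
filtered computation and treats the difference as a property of the source
table, not a tunable.

## Synthetic data generator

`simulate_id_dataset` draws from exactly the observation model above:
study and species intercepts once per group, then location-scale t noise
around the linear predictor, scaled by per-row SEs. Defaults (600 rows, 30
studies, 15 species, one species per study, species split evenly between
the two connectivity groups, rows spread round-robin over the stage × F
grid) mirror the shape, not the imbalance, of real compilations. Reported
SEs are drawn from a log-normal law with median 0.1 and log-sd 0.5; no
SE-generating law is stated in the source literature, so this default is
an explicit stand-in chosen to resemble the spread of published errors.
`simulate_fst_dataset` draws beta-distributed Fst with logit-scale marker
and species effects.

What passing recovery tests show is therefore internal consistency —
the samplers recover parameters of data generated by the model they fit.
They cannot show robustness to what the generator omits: publication bias,
correlated traits within studies, non-lognormal SEs, unbalanced designs
with empty cells (the real compilation has both), or phylogenetic
correlation between species.

## Problem sizes used in the test suite

Parameter recovery runs 20 independent simulate/fit cycles at 600 rows,
30 studies, 15 species, with 2 chains × 700 kept draws per fit; the
PSIS-LOO check refits a 25-observation dataset 25 times (2 × 800 draws);
the ensemble-sampler cross-check of the Gaussian limit uses a 30-row
dataset. These sizes give each check comfortable Monte-Carlo resolution on
a single CPU; all thresholds (90% coverage at 90% nominal, 2·SE agreement
for LOO, exact equality for the 1-D split) are independent of the sizes.

## Known limitations

* Individual levels of the 8-level interaction coding are prior-dominated
  (see Identification); margin-constrained coding (3 free parameters)
  would identify them at the cost of forcing mirror symmetry between the
  two connectivity groups.
* The exact-refit LOO oracle and PSIS agree within importance-sampling
  error; observations with Pareto k > 0.7 are flagged but not refit
  automatically.
* `manual_partition` requires every species to carry a code; the bundled
  table's manual-group column is internally inconsistent (11 species coded
  fragmented where the accompanying text describes 8) and is stored
  verbatim with a warning.
* Predictions average over study and species effects (a = b = 0); they are
  population-level, not study-level, statements.
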