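# idmeta

Life-stage-resolved Bayesian meta-regression of inbreeding depression (ID)
in *Pinaceae*, with Fst-based modelling of species connectivity.

## The problem

Conifers of the *Pinaceae* carry some of the highest genetic loads ever
measured, and the fitness cost of inbreeding is expected to differ between
the embryonic, juvenile, adult vegetative and adult reproductive phases of
these long-lived trees — and between species whose populations are
well-connected versus small and fragmented. Published crossing experiments
report stage-specific ID estimates

δ = 1 − w_self / w_out

(with w the mean fitness of inbred and outcrossed progeny) at inbreeding
coefficients F ∈ {0.125, 0.25, 0.5, 0.75} fixed by the crossing design
(half-sib, full-sib, one and two generations of selfing). `idmeta` provides
the full analysis pipeline for such a compilation: data validation and
deduplication, effect-size and delta-method-SE arithmetic, a homogeneity
(Cochran's Q) test, connectivity modelling from published Fst estimates,
the meta-regression itself, PSIS-LOO model comparison, prediction, and a
synthetic-data generator for end-to-end and parameter-recovery testing.

## The model

Each ID estimate y_i with reported standard error SE_i is modelled with a
robust location-scale Student-t likelihood,

```
y_i ~ t(Θ_i, σ_y·SE_i, df)
Θ_i = μ + α·F_i + β_l(i) + γ_m(i) + δ_lm(i) + ε_l(i)·F_i + a_j(i) + b_o(i)
a_j ~ N(0, σ_a²)      (study intercepts)
b_o ~ N(0, σ_b²)      (species intercepts)
df  ~ Gamma(2, 0.1),  σ_a, σ_b, σ_y ~ U(0, 10)
```

where l indexes the four life stages, m the two connectivity groups, and
each categorical effect vector (β, γ, the stage×connectivity interaction δ
and the stage-specific F slope ε) is constrained to sum to zero. Three
variants differ in how connectivity enters:

1. **manual partition** — species grouped by range continuity;
2. **clustered partition** — a Bayesian beta regression
   `Fst ~ Beta(μφ, (1−μ)φ)`, `logit(μ) = intercept + marker + species`
   adjusts published Fst estimates for marker system; 10,000 posterior
   draws of the species effects are each split by exact two-group k-means,
   with the highest-Fst species anchored to the "fragmented" cluster, and
   the majority vote defines the partition (propagating regression
   uncertainty into the grouping);
3. **continuous covariate** — the posterior-mean species effect on Fst
   replaces the group factor.

Variants are compared by PSIS-LOO (elpd_loo / LOOIC). Posterior sampling
for the meta-regression uses an exact blocked Gibbs sampler (Student-t as
a normal/gamma scale mixture); the beta regression is sampled with an
affine-invariant ensemble sampler. See `docs/methods.md` for details.

## Worked example

A published compilation of *Pinaceae* Fst estimates is bundled with the
package. The model-2 connectivity pipeline — marker filtering, beta
regression, anchored clustering over posterior draws — runs in about a
minute:

```python
from idmeta import (load_table1_fixture, fit_fst_beta_regression,
                    cluster_species)

records = load_table1_fixture(filtered=True)   # codominant nuclear markers
fit = fit_fst_beta_regression(records, seed=0)
part = cluster_species(fit, n_reps=10_000, anchor="Picea omorica", seed=0)
print(part.to_frame().sort_values("prob_fragmented", ascending=False).head(8))
print(part.group_fst_means)
```

```
        species  group  prob_fragmented
  Picea omorica      2           1.0000
 Pinus pinaster      2           0.7607
  Pinus radiata      2           0.6992
 Pinus pinceana      2           0.6964
Pinus monticola      2           0.5951
  Abies procera      1           0.4459
  Picea pungens      1           0.2773
Pinus ponderosa      1           0.1500
{1: (0.0417, 0.0314), 2: (0.1783, 0.0466)}
```

`prob_fragmented` is the fraction of the 10,000 clustering repetitions in
which a species lands in the anchor's (fragmented, high-Fst) cluster; the
Serbian spruce is the anchor so its probability is 1 by construction, and
borderline species such as *Abies procera* express the partition
uncertainty inherited from the regression. `group_fst_means` gives the
(mean, sd) of observed per-species average Fst in the well-connected (1)
and fragmented (2) groups: strongly differentiated species (mean Fst
0.178) separate from well-connected ones (0.042).

Effect-size arithmetic works the same way from fitness pairs:

```python
from idmeta import FitnessPair, compute_id, taylor_se
pair = FitnessPair(w_out=0.82, se_out=0.04, w_self=0.37, se_self=0.05)
compute_id(pair), taylor_se(pair)   # -> (0.549, 0.065)
```

A shell interface mirrors the library (`idmeta validate / simulate /
qtest / summarize / fst-fit / partition / fit / report`); see
`idmeta --help`.

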