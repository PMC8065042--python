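"""Design construction, Gibbs sampler correctness and prediction."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from idmeta import (
    IDRecord, ModelSpec, MetaPriors, PartitionResult, build_design,
    fit_meta_regression, TrueParams, SimDesign, simulate_id_dataset,
)
from idmeta.meta import _slice_sample, _t_logpdf
from tests.conftest import two_group_partition, RECOVERY_TRUTH


def toy_records():
    return [
        IDRecord(0.8, 0.1, "spA", "s1", 1, 0.5, connectivity=1),
        IDRecord(0.2, 0.2, "spA", "s1", 2, 0.5, connectivity=1),
        IDRecord(0.5, 0.1, "spB", "s2", 1, 0.25, connectivity=2),
        IDRecord(0.1, 0.3, "spB", "s3", 2, 0.25, connectivity=2),
    ]


def toy_partition():
    return PartitionResult({"spA": 1, "spB": 2}, {"spA": 0.0, "spB": 1.0},
                           {}, 0, method="manual")


class TestBuildDesign:
    def test_toy_index_arrays_hand_enumerated(self):
        d = build_design(toy_records(), ModelSpec(variant=2, partition=toy_partition()))
        assert d.l_idx.tolist() == [0, 1, 0, 1]
        assert d.m_idx.tolist() == [0, 0, 1, 1]
        assert d.j_idx.tolist() == [0, 0, 1, 2]
        assert d.o_idx.tolist() == [0, 0, 1, 1]
        assert np.allclose(d.F, [0.5, 0.5, 0.25, 0.25])
        # fixed effects: mu, alpha, epsilon(3), beta(3), gamma(1), delta(7)
        assert d.n_fixed == 1 + 1 + 3 + 3 + 1 + 7
        assert d.Z.shape == (4, d.n_fixed + 3 + 2)

    def test_missing_partition_species_raises(self):
        part = PartitionResult({"spA": 1}, {"spA": 0.0}, {}, 0)
        with pytest.raises(ValueError, match="spB"):
            build_design(toy_records(), ModelSpec(variant=2, partition=part))

    def test_variant3_requires_full_covariate(self):
        cov = pd.Series({"spA": 0.1})
        with pytest.raises(ValueError, match="spB"):
            build_design(toy_records(), ModelSpec(variant=3, covariate=cov))

    def test_variant3_design_uses_covariate_columns(self):
        cov = pd.Series({"spA": -0.5, "spB": 0.5})
        d = build_design(toy_records(), ModelSpec(variant=3, covariate=cov))
        # gamma column is the per-observation covariate
        g = d.Z[:, d.blocks["gamma"]][:, 0]
        assert np.allclose(g, [-0.5, -0.5, 0.5, 0.5])

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            ModelSpec(variant=2)
        with pytest.raises(ValueError):
            ModelSpec(variant=3)
        with pytest.raises(ValueError):
            ModelSpec(variant=5, partition=toy_partition())


class TestSamplerCorrectness:
    def test_sum_to_zero_preserved_in_every_draw(self, small_fit):
        p = small_fit.params
        assert np.max(np.abs(p["beta"].sum(axis=-1))) < 1e-8
        assert np.max(np.abs(p["gamma"].sum(axis=-1))) < 1e-8
        assert np.max(np.abs(p["delta"].sum(axis=(-2, -1)))) < 1e-8
        assert np.max(np.abs(p["epsilon"].sum(axis=-1))) < 1e-8

    def test_sigma_draws_within_prior_bounds_and_df_positive(self, small_fit):
        p = small_fit.params
        for s in ("sigma_a", "sigma_b", "sigma_y"):
            assert np.all(p[s] > 0) and np.all(p[s] < 10.0)
        assert np.all(p["df"] > 0)

    def test_pointwise_loglik_matches_direct_t_density(self, small_fit):
        ll = small_fit.log_likelihood()
        d = small_fit.design
        rng = np.random.default_rng(0)
        C, D, n = ll.shape
        for _ in range(100):
            c, k, i = rng.integers(C), rng.integers(D), rng.integers(n)
            theta = float(d.Z[i] @ small_fit._coef[c, k])
            ref = stats.t.logpdf(d.y[i], small_fit.params["df"][c, k],
                                 loc=theta,
                                 scale=small_fit.params["sigma_y"][c, k] * d.se[i])
            assert ll[c, k, i] == pytest.approx(ref, abs=1e-10)

    def test_null_effects_posterior_covers_zero(self):
        p = TrueParams.centered(mu=0.0, alpha=0.0, beta=(0,) * 4,
                                gamma=(0, 0), delta=((0, 0),) * 4,
                                epsilon=(0,) * 4, sigma_a=0.05,
                                sigma_b=0.05, sigma_y=1.0, df=10)
        recs = simulate_id_dataset(p, SimDesign(n_studies=10, n_species=6,
                                                n_rows=120, seed=17))
        fit = fit_meta_regression(
            recs, ModelSpec(variant=2, partition=two_group_partition(6)),
            chains=2, draws=500, warmup=500, seed=5)
        tab = fit.summary().set_index("parameter")
        for name in ("alpha", "beta[1]", "gamma[1]", "epsilon[1]"):
            row = tab.loc[name]
            assert row.q025 < 0 < row.q975

    def test_gaussian_limit_matches_independent_sampler(self):
        # df fixed large: the t likelihood degenerates to a normal; an
        # affine-invariant ensemble sampler on the same posterior is the
        # independent reference
        import emcee

        p = TrueParams.centered(mu=0.3, alpha=0.5, sigma_a=0.05,
                                sigma_b=0.05, sigma_y=1.0, df=30)
        recs = simulate_id_dataset(p, SimDesign(n_studies=4, n_species=2,
                                                n_rows=30, seed=23))
        priors = MetaPriors(fix_df=1e4)
        spec = ModelSpec(variant=2, partition=two_group_partition(2),
                         priors=priors)
        fit = fit_meta_regression(recs, spec, chains=2, draws=1500,
                                  warmup=800, seed=9)
        d = fit.design
        P = d.Z.shape[1]
        sl_j, sl_o = d.blocks["study"], d.blocks["species"]
        nj = sl_j.stop - sl_j.start
        no = sl_o.stop - sl_o.start

        def log_post(theta):
            coef = theta[:P]
            log_sa, log_sb, log_sy = theta[P:]
            sa, sb, sy = np.exp(log_sa), np.exp(log_sb), np.exp(log_sy)
            if max(sa, sb, sy) >= 10.0:
                return -np.inf
            resid = d.y - d.Z @ coef
            ll = float(np.sum(stats.norm.logpdf(resid, scale=sy * d.se)))
            a = coef[sl_j]; b = coef[sl_o]
            lp = float(np.sum(stats.norm.logpdf(a, scale=sa)))
            lp += float(np.sum(stats.norm.logpdf(b, scale=sb)))
            fixed = np.concatenate([coef[:sl_j.start]])
            lp += float(np.sum(stats.norm.logpdf(fixed, scale=5.0)))
            # uniform prior on each sigma with log-scale Jacobian
            lp += log_sa + log_sb + log_sy
            return ll + lp

        ndim = P + 3
        nw = 2 * ndim + 2
        rng = np.random.default_rng(1)
        start = np.concatenate([np.zeros(P), np.log([0.1, 0.1, 1.0])])
        p0 = start + 0.02 * rng.standard_normal((nw, ndim))
        sampler = emcee.EnsembleSampler(nw, ndim, log_post)
        state = sampler.run_mcmc(p0, 3000, progress=False,
                                 rstate0=np.random.RandomState(1).get_state())
        sampler.reset()
        sampler.run_mcmc(state, 2500, progress=False)
        ref = sampler.get_chain(flat=True, thin=5)

        # compare likelihood-identified quantities: the per-observation
        # fitted means and the residual scale (the diffuse sum-to-zero
        # directions are prior-dominated and carry large MC error)
        theta_gibbs = np.einsum("cdp,np->n", fit._coef,
                                d.Z) / np.prod(fit._coef.shape[:2])
        theta_ref = (ref[:, :P] @ d.Z.T).mean(axis=0)
        assert np.max(np.abs(theta_gibbs - theta_ref)) < 0.06
        ref_sy = np.exp(ref[:, P + 2]).mean()
        assert fit.params["sigma_y"].mean() == pytest.approx(ref_sy, abs=0.06)

    def test_df_slice_sampler_reproduces_gamma_prior(self):
        # no-data limit: the df update targets its gamma(2, 0.1) prior
        rng = np.random.default_rng(11)

        def logp(x):
            v = np.exp(x)
            if not np.isfinite(v) or v > 1e6:
                return -np.inf
            return 2.0 * x - 0.1 * v     # gamma(2, 0.1) + log Jacobian

        x = np.log(10.0)
        draws = []
        for _ in range(6000):
            x = _slice_sample(x, logp, rng)
            draws.append(np.exp(x))
        draws = np.array(draws[500:])
        assert draws.mean() == pytest.approx(20.0, rel=0.1)
        assert draws.std() == pytest.approx(np.sqrt(2) / 0.1, rel=0.15)


class TestRecoveryMedium:
    def test_identified_parameters_recovered(self, medium_fit_and_truth):
        fit, truth = medium_fit_and_truth
        tab = fit.summary().set_index("parameter")
        checks = {
            "mu": truth.mu, "alpha": truth.alpha,
            "sigma_a": truth.sigma_a, "sigma_b": truth.sigma_b,
            "sigma_y": truth.sigma_y, "df": truth.df,
            "epsilon[1]": truth.epsilon[0], "epsilon[2]": truth.epsilon[1],
        }
        missed = [k for k, v in checks.items()
                  if not (tab.loc[k].q025 <= v <= tab.loc[k].q975)]
        assert len(missed) <= 1, f"missed: {missed}"

    def test_classification_flags_strong_slope(self, medium_fit_and_truth):
        fit, _ = medium_fit_and_truth
        labels = fit.classify_effects().set_index("parameter")["label"]
        assert labels["alpha"] == "significant"
        assert labels["epsilon[1]"] == "significant"


class TestPrediction:
    def test_degenerate_scale_returns_posterior_theta_mean(self, small_fit):
        pred = small_fit.predict_id(stage=1, f_coef=0.5, group=1, se_ref=1e-9)
        p = small_fit.params
        theta = (p["mu"] + p["alpha"] * 0.5 + p["beta"][..., 0]
                 + p["gamma"][..., 0] + p["delta"][..., 0, 0]
                 + p["epsilon"][..., 0] * 0.5)
        assert pred.mean == pytest.approx(float(theta.mean()), abs=1e-9)
        assert pred.q05 == pytest.approx(np.quantile(theta, 0.05), abs=1e-4)

    def test_quantiles_ordered_and_widen_with_se(self, small_fit):
        p1 = small_fit.predict_id(stage=2, f_coef=0.25, group=2, se_ref=0.05)
        p2 = small_fit.predict_id(stage=2, f_coef=0.25, group=2, se_ref=0.5)
        assert p1.q025 <= p1.q05 <= p1.q95 <= p1.q975
        assert (p2.q975 - p2.q025) > (p1.q975 - p1.q025)

    def test_monotone_in_f_when_slopes_positive(self, medium_fit_and_truth):
        fit, _ = medium_fit_and_truth
        slope = fit._flat("alpha") + fit._flat("epsilon")[:, 0]
        assert np.all(slope > 0)    # embryonic-stage F response positive here
        means = [fit.predict_id(stage=1, f_coef=f, group=1, se_ref=1e-9).mean
                 for f in (0.125, 0.25, 0.5, 0.75)]
        assert all(a < b for a, b in zip(means, means[1:]))

    def test_invalid_inputs_rejected(self, small_fit):
        with pytest.raises(ValueError):
            small_fit.predict_id(stage=9, f_coef=0.5, group=1)
        with pytest.raises(ValueError):
            small_fit.predict_id(stage=1, f_coef=0.5, group=1, se_ref=0.0)
        with pytest.raises(ValueError):
            small_fit.predict_id(stage=1, f_coef=0.5, group=7)
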