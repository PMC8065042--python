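"""Beta regression, exact 1-D clustering and partition construction."""

import warnings

import numpy as np
import pandas as pd
import pytest

from idmeta import (
    FstRecord, FstBetaRegression, BetaRegResults, BetaRegPriors,
    fit_fst_beta_regression, cluster_species, manual_partition,
    fst_covariate, kmeans_1d_two, simulate_fst_dataset,
)


def make_results(species, effect_means, effect_sds, intercept=-2.0,
                 n_draws=500, seed=0, observed=None):
    """Hand-built posterior for cheap clustering tests."""
    rng = np.random.default_rng(seed)
    eff = rng.normal(effect_means, effect_sds, size=(n_draws, len(species)))
    draws = {
        "intercept": np.full(n_draws, intercept),
        "marker_effects": np.zeros((n_draws, 1)),
        "species_effects": eff,
        "phi": np.full(n_draws, 50.0),
    }
    if observed is None:
        from scipy.special import expit
        observed = pd.Series(expit(intercept + np.asarray(effect_means)),
                             index=species)
    return BetaRegResults(draws, species, ["SNP"], observed,
                          {"ok": True, "min_ess": 1e4}, BetaRegPriors())


class TestExactKmeans1D:
    def test_matches_sklearn_kmeans_on_random_instances(self):
        from sklearn.cluster import KMeans

        rng = np.random.default_rng(2024)
        for trial in range(40):
            n = int(rng.integers(2, 21))
            x = np.round(rng.normal(0, 1, n), 3)   # rounding induces ties
            if np.all(x == x[0]):
                continue
            labels, wss = kmeans_1d_two(x)
            km = KMeans(n_clusters=2, n_init=20, random_state=0).fit(x[:, None])
            km_wss = km.inertia_
            # identical partitions up to label naming, identical objective
            same = (labels == km.labels_).all() or (labels == 1 - km.labels_).all()
            assert wss <= km_wss + 1e-9
            assert same or wss < km_wss - 1e-12

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            kmeans_1d_two(np.ones(5))

    def test_low_high_labelling(self):
        labels, _ = kmeans_1d_two(np.array([5.0, 0.1, 0.2, 5.2]))
        assert labels.tolist() == [1, 0, 0, 1]


class TestBetaRegression:
    def test_recovers_separated_species_effects(self):
        truth = {"frag1": 1.5, "frag2": 1.2, "cont1": -1.0, "cont2": -1.7}
        recs = simulate_fst_dataset(truth, {"SNP": 0.3, "ncSSR": -0.3},
                                    phi=60.0, n_per_species=6, seed=21)
        fit = fit_fst_beta_regression(
            recs, seed=21,
            sampler_config={"n_draws": 1500, "n_burn": 1000, "thin": 4})
        est = fit.draws["species_effects"].mean(axis=0)
        truth_c = {k: v - np.mean(list(truth.values())) for k, v in truth.items()}
        order_true = sorted(truth, key=truth_c.get)
        order_est = [fit.species[i] for i in np.argsort(est)]
        assert order_true == order_est
        # posterior means within 2 posterior SDs of centred truth
        sds = fit.draws["species_effects"].std(axis=0, ddof=1)
        for i, sp in enumerate(fit.species):
            assert abs(est[i] - truth_c[sp]) < 2.5 * sds[i]

    def test_exchangeable_species_have_null_contrast(self):
        recs = simulate_fst_dataset({"a": 0.0, "b": 0.0}, {"SNP": 0.0},
                                    phi=40.0, n_per_species=12, seed=3)
        fit = fit_fst_beta_regression(
            recs, seed=3,
            sampler_config={"n_draws": 1500, "n_burn": 800, "thin": 4})
        contrast = (fit.draws["species_effects"][:, 0]
                    - fit.draws["species_effects"][:, 1])
        lo, hi = np.quantile(contrast, [0.05, 0.95])
        assert lo < 0 < hi

    def test_preconditions(self):
        with pytest.raises(ValueError, match="2 species"):
            FstBetaRegression([FstRecord("only", 0.1, "SNP")])

    def test_seed_reproducible(self):
        recs = simulate_fst_dataset({"a": -0.5, "b": 0.5}, {"SNP": 0.0},
                                    phi=40.0, n_per_species=4, seed=1)
        cfg = {"n_draws": 300, "n_burn": 200, "thin": 2}
        f1 = fit_fst_beta_regression(recs, seed=5, sampler_config=cfg)
        f2 = fit_fst_beta_regression(recs, seed=5, sampler_config=cfg)
        assert np.array_equal(f1.draws["species_effects"],
                              f2.draws["species_effects"])


class TestClusterSpecies:
    def test_well_separated_clusters_recovered_with_certainty(self):
        species = ["c1", "c2", "c3", "f1", "f2"]
        fit = make_results(species, [-2, -2.1, -1.9, 2.0, 2.2],
                           [0.05] * 5)
        part = cluster_species(fit, n_reps=400, anchor="f2", seed=0)
        assert part.assignment == {"c1": 1, "c2": 1, "c3": 1, "f1": 2, "f2": 2}
        assert set(part.prob_fragmented.values()) == {0.0, 1.0}

    def test_anchor_probability_is_one_by_construction(self):
        fit = make_results(["a", "b", "c"], [-1, 0.0, 1.0], [0.8] * 3)
        part = cluster_species(fit, n_reps=500, anchor="c", seed=1)
        assert part.prob_fragmented["c"] == 1.0

    def test_default_anchor_is_highest_observed_fst(self):
        fit = make_results(["a", "b"], [-1.0, 1.0], [0.1, 0.1],
                           observed=pd.Series([0.05, 0.3], index=["a", "b"]))
        part = cluster_species(fit, n_reps=100, seed=0)
        assert part.anchor == "b"

    def test_assignment_invariant_to_species_order(self):
        rng = np.random.default_rng(8)
        recs = simulate_fst_dataset({"a": -1.5, "b": -1.2, "c": 1.3, "d": 1.5},
                                    {"SNP": 0.0}, phi=60.0,
                                    n_per_species=5, seed=8)
        cfg = {"n_draws": 800, "n_burn": 600, "thin": 3}
        f1 = fit_fst_beta_regression(recs, seed=2, sampler_config=cfg)
        shuffled = list(recs)[::-1]
        f2 = fit_fst_beta_regression(shuffled, seed=2, sampler_config=cfg)
        p1 = cluster_species(f1, n_reps=500, anchor="d", seed=0)
        p2 = cluster_species(f2, n_reps=500, anchor="d", seed=0)
        assert p1.assignment == p2.assignment

    def test_prob_fragmented_monotone_in_separation(self):
        probs = []
        for sep in (0.2, 1.0, 3.0):
            fit = make_results(["a", "b", "c", "d"],
                               [-sep, -sep, sep, sep], [0.6] * 4, seed=3)
            part = cluster_species(fit, n_reps=800, anchor="d", seed=3)
            probs.append(part.prob_fragmented["c"])
        assert probs[0] <= probs[1] <= probs[2]

    def test_group_means_computed_from_observed_fst(self):
        obs = pd.Series([0.02, 0.04, 0.2, 0.3], index=["a", "b", "c", "d"])
        fit = make_results(["a", "b", "c", "d"], [-2, -2, 2, 2], [0.05] * 4,
                           observed=obs)
        part = cluster_species(fit, n_reps=200, anchor="d", seed=0)
        assert part.group_fst_means[1][0] == pytest.approx(0.03)
        assert part.group_fst_means[2][0] == pytest.approx(0.25)


class TestManualPartition:
    def _recs(self, codes):
        return [FstRecord(s, f, "SNP", manual_group=g)
                for (s, f, g) in codes]

    def test_group_means_are_hand_computed_averages(self):
        part = manual_partition(self._recs([
            ("a", 0.02, 1), ("b", 0.04, 1), ("c", 0.2, 2), ("d", 0.4, 2)]))
        assert part.assignment == {"a": 1, "b": 1, "c": 2, "d": 2}
        assert part.group_fst_means[1][0] == pytest.approx(0.03)
        assert part.group_fst_means[2][0] == pytest.approx(0.3)
        assert part.prob_fragmented == {"a": 0, "b": 0, "c": 1, "d": 1}

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="two non-empty"):
            manual_partition(self._recs([("a", 0.1, 1), ("b", 0.2, 1)]))

    def test_missing_code_lists_species(self):
        recs = self._recs([("a", 0.1, 1), ("b", 0.2, 2)])
        recs.append(FstRecord("c", 0.3, "SNP"))
        with pytest.raises(ValueError, match="c"):
            manual_partition(recs)


class TestFstCovariate:
    def test_posterior_mean_per_species(self):
        fit = make_results(["a", "b"], [-1.0, 1.0], [0.3, 0.3], n_draws=4000)
        cov = fst_covariate(fit)
        assert cov["a"] == pytest.approx(-1.0, abs=0.05)
        assert cov["b"] == pytest.approx(1.0, abs=0.05)
        # symmetric posterior: mean close to median
        med = np.median(fit.draws["species_effects"], axis=0)
        assert np.allclose(cov.values, med, atol=0.05)

    def test_missing_species_raises(self):
        fit = make_results(["a", "b"], [0.0, 0.0], [0.1, 0.1])
        with pytest.raises(KeyError, match="zz"):
            fst_covariate(fit, species=["a", "zz"])

    def test_constant_fst_input_gives_near_zero_spread(self):
        recs = [FstRecord(s, 0.1, "SNP") for s in "abcd" for _ in range(4)]
        fit = fit_fst_beta_regression(
            recs, seed=4, sampler_config={"n_draws": 800, "n_burn": 500, "thin": 3})
        cov = fst_covariate(fit)
        assert cov.abs().max() < 0.5
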