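"""Species-connectivity modelling from published Fst estimates.

Three encodings of species connectivity feed the ID meta-regression:

1. a manual two-group partition from range maps (:func:`manual_partition`);
2. a Bayesian beta regression of Fst on marker type and species followed by
   k-means (k = 2) clustering over posterior draws of the species effects,
   which propagates regression uncertainty into the partition
   (:class:`FstBetaRegression` + :func:`cluster_species`); and
3. the posterior-mean species effect used directly as a continuous
   covariate (:func:`fst_covariate`).

The beta regression uses the mean/precision parametrization
Fst_i ~ Beta(mu_i * phi, (1 - mu_i) * phi) with
logit(mu_i) = intercept + marker_{m(i)} + species_{s(i)}; marker and
species effect vectors are each constrained to sum to zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, gammaln, logit

from .data import FstRecord

__all__ = [
    "BetaRegPriors",
    "BetaRegResults",
    "FstBetaRegression",
    "PartitionResult",
    "fit_fst_beta_regression",
    "cluster_species",
    "manual_partition",
    "fst_covariate",
    "kmeans_1d_two",
]


def kmeans_1d_two(values: np.ndarray) -> tuple[np.ndarray, float]:
    """Exact 2-cluster k-means of scalar values.

    In one dimension the converged k-means solution with k = 2 is a
    threshold split of the sorted values; this routine evaluates all n-1
    splits and returns the within-cluster sum of squares minimizer, which
    removes any initialization nondeterminism.

    Returns ``(labels, wss)`` where ``labels`` is 0 for the low cluster and
    1 for the high cluster, in input order.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 values to split")
    if np.all(x == x[0]):
        raise ValueError("degenerate input: all values equal")
    order = np.argsort(x, kind="stable")
    xs = x[order]
    c1 = np.cumsum(xs)
    c2 = np.cumsum(xs * xs)
    k = np.arange(1, n)            # size of the low cluster
    ss_lo = c2[:-1] - c1[:-1] ** 2 / k
    s1_hi = c1[-1] - c1[:-1]
    s2_hi = c2[-1] - c2[:-1]
    ss_hi = s2_hi - s1_hi ** 2 / (n - k)
    best = int(np.argmin(ss_lo + ss_hi))
    labels = np.empty(n, dtype=int)
    labels[order[: best + 1]] = 0
    labels[order[best + 1:]] = 1
    return labels, float((ss_lo + ss_hi)[best])


def _batch_split(values: np.ndarray) -> np.ndarray:
    """Vectorized exact 2-means over rows; returns high-cluster masks.

    Rows where all values coincide get an all-False mask (degenerate,
    caller counts and skips them).
    """
    v = np.asarray(values, dtype=float)
    r, n = v.shape
    order = np.argsort(v, axis=1, kind="stable")
    xs = np.take_along_axis(v, order, axis=1)
    c1 = np.cumsum(xs, axis=1)
    c2 = np.cumsum(xs * xs, axis=1)
    k = np.arange(1, n)
    with np.errstate(invalid="ignore"):
        ss_lo = c2[:, :-1] - c1[:, :-1] ** 2 / k
        ss_hi = (c2[:, -1:] - c2[:, :-1]) - (c1[:, -1:] - c1[:, :-1]) ** 2 / (n - k)
    best = np.argmin(ss_lo + ss_hi, axis=1)
    ranks = np.argsort(order, axis=1, kind="stable")
    high = ranks > best[:, None]
    degenerate = xs[:, 0] == xs[:, -1]
    high[degenerate] = False
    return high, degenerate


@dataclass(frozen=True)
class BetaRegPriors:
    """Priors for the Fst beta regression (logit-scale effects, precision)."""

    effect_sd: float = 2.0     # normal sd on intercept and each effect
    phi_shape: float = 2.0     # gamma shape on the precision phi
    phi_rate: float = 0.1      # gamma rate on phi


class BetaRegResults:
    """Posterior sample of the Fst beta regression.

    Attributes
    ----------
    draws : dict of arrays
        ``intercept`` (S,), ``marker_effects`` (S, M), ``species_effects``
        (S, K) and ``phi`` (S,) over S posterior draws; effect vectors are
        the full sum-to-zero vectors.
    species, markers : lists of level labels.
    observed_species_fst : pandas.Series
        Observed per-species average Fst over the training records.
    """

    def __init__(self, draws, species, markers, observed_species_fst,
                 diagnostics, priors):
        self.draws = draws
        self.species = list(species)
        self.markers = list(markers)
        self.observed_species_fst = observed_species_fst
        self.diagnostics = diagnostics
        self.priors = priors

    @property
    def n_draws(self) -> int:
        return len(self.draws["phi"])

    @property
    def converged(self) -> bool:
        return self.diagnostics.get("ok", False)

    def check_converged(self, ess_floor: float = 400.0) -> None:
        ess = self.diagnostics.get("min_ess", np.nan)
        if not np.isfinite(ess) or ess < ess_floor:
            raise RuntimeError(
                f"beta regression did not converge: min effective sample size "
                f"{ess:.0f} < {ess_floor:.0f}; diagnostics: {self.diagnostics}")

    def species_effect_draws(self, scale: str = "logit") -> np.ndarray:
        """Posterior draws of species effects, (n_draws, n_species).

        ``scale='logit'`` returns the raw sum-to-zero effects;
        ``scale='response'`` maps intercept + effect through the inverse
        logit, i.e. the marker-adjusted species-level Fst.
        """
        eff = self.draws["species_effects"]
        if scale == "logit":
            return eff
        if scale == "response":
            return expit(self.draws["intercept"][:, None] + eff)
        raise ValueError(f"unknown scale {scale!r}")

    def summary(self) -> pd.DataFrame:
        rows = []
        for name, arr, labels in (
            ("intercept", self.draws["intercept"][:, None], [""]),
            ("marker", self.draws["marker_effects"], self.markers),
            ("species", self.draws["species_effects"], self.species),
            ("phi", self.draws["phi"][:, None], [""]),
        ):
            q = np.quantile(arr, [0.05, 0.5, 0.95], axis=0)
            for i, lab in enumerate(labels):
                rows.append({
                    "parameter": f"{name}[{lab}]" if lab else name,
                    "mean": arr[:, i].mean(), "sd": arr[:, i].std(ddof=1),
                    "q05": q[0, i], "median": q[1, i], "q95": q[2, i],
                })
        return pd.DataFrame(rows)


#: Backwards-compatible alias: the fitted object of the beta regression.
BetaRegFit = BetaRegResults


class FstBetaRegression:
    """Beta regression of published Fst on marker type and species.

    Parameters
    ----------
    records
        Validated, marker-filtered :class:`~idmeta.data.FstRecord` rows;
        at least two species and one marker type, all Fst in (0, 1).
    priors
        :class:`BetaRegPriors`; defaults are weakly informative.
    """

    def __init__(self, records: Sequence[FstRecord],
                 priors: BetaRegPriors | None = None):
        if not records:
            raise ValueError("no Fst records")
        self.records = list(records)
        self.priors = priors or BetaRegPriors()
        self.species = sorted({r.species for r in records})
        self.markers = sorted({r.marker_type for r in records})
        if len(self.species) < 2:
            raise ValueError("need at least 2 species")
        self.fst = np.array([r.fst for r in records])
        if np.any((self.fst <= 0) | (self.fst >= 1)):
            raise ValueError("all fst must lie in (0, 1); validate/filter first")
        self._s_idx = np.array([self.species.index(r.species) for r in records])
        self._m_idx = np.array([self.markers.index(r.marker_type) for r in records])
        self.n_species = len(self.species)
        self.n_markers = len(self.markers)
        # free parameters: intercept, M-1 marker, K-1 species, log phi
        self.ndim = 1 + (self.n_markers - 1) + (self.n_species - 1) + 1

    # -- parameter packing --------------------------------------------------

    def _expand(self, theta: np.ndarray):
        icpt = theta[0]
        m_free = theta[1:self.n_markers]
        s_free = theta[self.n_markers:self.n_markers + self.n_species - 1]
        m_full = np.append(m_free, -m_free.sum())
        s_full = np.append(s_free, -s_free.sum())
        phi = np.exp(theta[-1])
        return icpt, m_full, s_full, phi

    def log_posterior(self, theta: np.ndarray) -> float:
        icpt, m_full, s_full, phi = self._expand(theta)
        pr = self.priors
        sd2 = pr.effect_sd ** 2
        lp = -0.5 * (icpt ** 2 + np.sum(m_full ** 2) + np.sum(s_full ** 2)) / sd2
        # gamma prior on phi, sampled as log phi (Jacobian: + log phi)
        lp += pr.phi_shape * np.log(phi) - pr.phi_rate * phi
        eta = icpt + m_full[self._m_idx] + s_full[self._s_idx]
        mu = expit(eta)
        p = mu * phi
        q = (1.0 - mu) * phi
        if np.any(p <= 0) or np.any(q <= 0) or not np.isfinite(phi):
            return -np.inf
        ll = np.sum((p - 1) * np.log(self.fst) + (q - 1) * np.log1p(-self.fst)
                    + gammaln(p + q) - gammaln(p) - gammaln(q))
        return float(lp + ll)

    # -- sampling -----------------------------------------------------------

    def fit(self, n_draws: int = 10_000, n_walkers: int = 64,
            n_burn: int = 1500, thin: int = 8, seed: int = 0) -> BetaRegResults:
        """Sample the posterior with an affine-invariant ensemble sampler."""
        import emcee

        rng = np.random.default_rng(seed)
        nw = max(n_walkers, 2 * self.ndim + 2)
        nw += nw % 2
        start = np.zeros(self.ndim)
        start[0] = logit(float(np.mean(self.fst)))
        start[-1] = np.log(20.0)
        p0 = start + 0.05 * rng.standard_normal((nw, self.ndim))

        sampler = emcee.EnsembleSampler(nw, self.ndim, self.log_posterior)
        state = sampler.run_mcmc(p0, n_burn, progress=False,
                                 rstate0=np.random.RandomState(seed).get_state())
        sampler.reset()
        n_steps = int(np.ceil(n_draws * thin / nw))
        sampler.run_mcmc(state, n_steps, thin_by=1, progress=False)

        chain = sampler.get_chain(thin=thin)          # (steps, walkers, dim)
        flat = chain.reshape(-1, self.ndim)
        if len(flat) > n_draws:
            keep = rng.choice(len(flat), size=n_draws, replace=False)
            flat = flat[np.sort(keep)]

        diagnostics = self._diagnose(chain, sampler)
        icpt = flat[:, 0]
        m_free = flat[:, 1:self.n_markers]
        s_free = flat[:, self.n_markers:self.n_markers + self.n_species - 1]
        draws = {
            "intercept": icpt,
            "marker_effects": np.hstack([m_free, -m_free.sum(axis=1, keepdims=True)]),
            "species_effects": np.hstack([s_free, -s_free.sum(axis=1, keepdims=True)]),
            "phi": np.exp(flat[:, -1]),
        }
        observed = (pd.Series(self.fst, index=[self.species[i] for i in self._s_idx])
                    .groupby(level=0).mean().reindex(self.species))
        observed.name = "mean_fst"
        return BetaRegResults(draws, self.species, self.markers, observed,
                              diagnostics, self.priors)

    def _diagnose(self, chain: np.ndarray, sampler) -> dict:
        # Walkers of an affine-invariant ensemble are exchangeable but not
        # independent chains, so convergence is judged from the integrated
        # autocorrelation time: total draws / ACT gives the effective
        # sample size, and the chain must span many ACTs.
        n_steps = int(sampler.iteration)
        n_walkers = sampler.nwalkers
        try:
            act = sampler.get_autocorr_time(quiet=True)
            max_act = float(np.nanmax(act))
        except Exception:
            max_act = float("nan")
        ess = (n_steps * n_walkers / max_act if np.isfinite(max_act)
               else float("nan"))
        diag = {
            "min_ess": float(ess),
            "max_autocorr_time": max_act,
            "n_steps": n_steps,
            "acceptance_fraction": float(np.mean(sampler.acceptance_fraction)),
        }
        diag["ok"] = (np.isfinite(ess) and ess >= 400
                      and n_steps >= 10 * max_act)
        if not diag["ok"]:
            warnings.warn(f"beta regression convergence suspect: {diag}")
        return diag


def fit_fst_beta_regression(records: Sequence[FstRecord],
                            priors: BetaRegPriors | None = None,
                            sampler_config: Mapping | None = None,
                            seed: int = 0) -> BetaRegResults:
    """Fit the marker-adjusted species beta regression (functional façade)."""
    model = FstBetaRegression(records, priors=priors)
    return model.fit(seed=seed, **(sampler_config or {}))


@dataclass
class PartitionResult:
    """Two-group species partition with assignment uncertainty.

    ``assignment`` maps species to 1 (well-connected) or 2 (fragmented);
    ``prob_fragmented`` is the across-repetition frequency of landing in
    the fragmented (anchor's) cluster; ``group_fst_means`` maps each group
    to (mean, sd) of the observed per-species average Fst.
    """

    assignment: dict
    prob_fragmented: dict
    group_fst_means: dict
    n_reps: int
    n_skipped: int = 0
    anchor: str | None = None
    method: str = "kmeans_posterior"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "species": list(self.assignment),
            "group": [self.assignment[s] for s in self.assignment],
            "prob_fragmented": [self.prob_fragmented[s] for s in self.assignment],
        })


def _group_means(species_fst: pd.Series, assignment: Mapping[str, int]) -> dict:
    out = {}
    for g in (1, 2):
        vals = np.array([species_fst[s] for s, a in assignment.items() if a == g])
        out[g] = (float(vals.mean()), float(vals.std(ddof=1)) if len(vals) > 1 else 0.0)
    return out


def cluster_species(fit: BetaRegResults, n_reps: int = 10_000,
                    anchor: str | None = None, seed: int = 0,
                    scale: str = "response") -> PartitionResult:
    """Partition species into two groups over posterior draws.

    For each repetition one posterior draw of the species-effect vector is
    clustered into k = 2 groups by the exact 1-D k-means split; the cluster
    containing the anchor species is labelled "fragmented", which fixes the
    label-switching ambiguity.  The anchor defaults to the species with the
    highest observed average Fst.  Final assignment is the majority vote
    across repetitions; ``prob_fragmented`` records the per-species vote
    frequency.  Clustering operates on the marker-adjusted species-level
    Fst (``scale='response'``) by default, where between-species distances
    are expressed in differentiation units rather than logits.
    """
    species = fit.species
    if anchor is None:
        anchor = fit.observed_species_fst.idxmax()
    if anchor not in species:
        raise ValueError(f"anchor species {anchor!r} not among {species}")
    a_idx = species.index(anchor)

    rng = np.random.default_rng(seed)
    eff = fit.species_effect_draws(scale=scale)
    idx = (np.arange(n_reps) % len(eff) if n_reps <= len(eff)
           else rng.integers(0, len(eff), size=n_reps))
    values = eff[idx]

    high, degenerate = _batch_split(values)
    n_skipped = int(degenerate.sum())
    ok = ~degenerate
    if not ok.any():
        raise ValueError("all repetitions degenerate (constant species effects)")
    # fragmented := anchor's cluster in each repetition
    frag = high[ok] == high[ok, a_idx][:, None]
    prob = frag.mean(axis=0)

    assignment = {s: (2 if prob[i] > 0.5 else 1) for i, s in enumerate(species)}
    prob_fragmented = {s: float(prob[i]) for i, s in enumerate(species)}
    if len(set(assignment.values())) < 2:
        raise ValueError("majority vote produced a single group; "
                         "no meaningful two-group structure")
    return PartitionResult(
        assignment=assignment,
        prob_fragmented=prob_fragmented,
        group_fst_means=_group_means(fit.observed_species_fst, assignment),
        n_reps=n_reps,
        n_skipped=n_skipped,
        anchor=anchor,
    )


def manual_partition(records: Sequence[FstRecord]) -> PartitionResult:
    """Partition species by their published manual connectivity codes."""
    codes: dict[str, int] = {}
    missing = set()
    for r in records:
        if r.manual_group is None:
            missing.add(r.species)
        elif r.species in codes and codes[r.species] != r.manual_group:
            raise ValueError(f"conflicting manual codes for {r.species}")
        else:
            codes[r.species] = r.manual_group
    missing -= set(codes)
    if missing:
        raise ValueError(f"species lacking a manual connectivity code: {sorted(missing)}")
    if len(set(codes.values())) < 2:
        raise ValueError("manual partition requires two non-empty groups")
    fst = (pd.Series([r.fst for r in records], index=[r.species for r in records])
           .groupby(level=0).mean())
    return PartitionResult(
        assignment=dict(codes),
        prob_fragmented={s: float(g == 2) for s, g in codes.items()},
        group_fst_means=_group_means(fst, codes),
        n_reps=0,
        method="manual",
    )


def fst_covariate(fit: BetaRegResults,
                  species: Sequence[str] | None = None) -> pd.Series:
    """Posterior-mean species effect on Fst, keyed by species.

    This is the per-species scalar used as a continuous connectivity
    covariate (model 3).  Requesting a species absent from the fit raises.
    """
    means = fit.draws["species_effects"].mean(axis=0)
    cov = pd.Series(means, index=fit.species, name="fst_effect")
    if species is not None:
        missing = sorted(set(species) - set(fit.species))
        if missing:
            raise KeyError(f"species absent from the beta regression fit: {missing}")
        cov = cov.reindex(species)
    return cov
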