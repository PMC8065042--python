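"""Multilevel Student-t meta-regression of inbreeding depression.

The observation model for the i-th ID estimate is a location-scale
Student-t,

    y_i ~ t(Theta_i, sigma_y * SE_i, df),
    Theta_i = mu + alpha F_i + beta_{l(i)} + gamma_{m(i)} + delta_{l(i)m(i)}
              + epsilon_{l(i)} F_i + a_{j(i)} + b_{o(i)},

with study intercepts a_j ~ N(0, sigma_a^2), species intercepts
b_o ~ N(0, sigma_b^2), df ~ Gamma(2, 0.1) and uniform priors on the three
scale parameters.  Each categorical effect vector (beta over 4 life
stages, gamma over 2 connectivity groups, the flattened 8-level stage x
connectivity interaction delta and the stage-specific F slopes epsilon)
is constrained to sum to zero by parameterizing K-1 free coefficients
with the last equal to minus their sum.  Three variants differ only in
how connectivity enters: a manual partition (variant 1), a clustered
partition (variant 2) or a continuous per-species Fst covariate that
replaces gamma_m and delta_lm by gamma * Fst_o and delta_l * Fst_o
(variant 3).

Posterior sampling is by a blocked Gibbs sampler that exploits the
normal/gamma scale-mixture representation of the Student-t: conditional
on per-observation mixing weights lambda_i the model is linear-Gaussian,
so all location parameters are drawn jointly from one multivariate
normal; the variance parameters have truncated inverse-gamma
conditionals under their uniform priors; and the degrees of freedom are
updated by univariate slice sampling.  Every conditional is exact, so no
step-size tuning is required and the sampler has no rejections.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln
from scipy.linalg import cho_factor, cho_solve, cholesky

from .data import IDRecord, F_LEVELS, LIFE_STAGES
from .connectivity import PartitionResult

__all__ = [
    "MetaPriors",
    "SamplerSettings",
    "ModelSpec",
    "Design",
    "IDMetaRegression",
    "MetaResults",
    "PredictiveDraw",
    "build_design",
    "fit_meta_regression",
    "classify_effects",
    "predict_id",
]


@dataclass(frozen=True)
class MetaPriors:
    """Prior configuration (weakly informative defaults)."""

    normal_scale: float = 5.0     # sd of N(0, .) priors on location params
    sigma_upper: float = 10.0     # upper bound of uniform priors on sigmas
    df_shape: float = 2.0         # gamma shape on t degrees of freedom
    df_rate: float = 0.1          # gamma rate on t degrees of freedom
    fix_df: float | None = None   # hold df fixed (e.g. large, for a normal limit)


@dataclass(frozen=True)
class SamplerSettings:
    chains: int = 4
    draws: int = 1000
    warmup: int = 1000
    seed: int = 0


@dataclass(frozen=True)
class ModelSpec:
    """Which model variant to fit and where connectivity comes from."""

    variant: int = 2
    partition: PartitionResult | None = None
    covariate: pd.Series | None = None     # per-species Fst effect (variant 3)
    f_as_factor: bool = False
    priors: MetaPriors = field(default_factory=MetaPriors)

    def __post_init__(self):
        if self.variant not in (1, 2, 3):
            raise ValueError(f"variant must be 1, 2 or 3 (got {self.variant})")
        if self.variant in (1, 2) and self.partition is None:
            raise ValueError(f"variant {self.variant} requires a partition")
        if self.variant == 3 and self.covariate is None:
            raise ValueError("variant 3 requires a per-species Fst covariate")


def _contrast(K: int) -> np.ndarray:
    """K x (K-1) sum-to-zero coding: identity rows, last row all -1."""
    C = np.vstack([np.eye(K - 1), -np.ones(K - 1)])
    return C


class Design:
    """Model inputs assembled from records: index vectors and design matrix.

    The full design matrix ``Z`` stacks the fixed-effect columns (built
    with sum-to-zero contrasts on the free coefficients) and the study and
    species indicator blocks.  ``blocks`` maps parameter-block names to
    column slices of ``Z``.
    """

    def __init__(self, records: Sequence[IDRecord], spec: ModelSpec):
        if not records:
            raise ValueError("no records")
        self.spec = spec
        self.records = list(records)
        n = len(records)
        self.y = np.array([r.id_value for r in records])
        self.se = np.array([r.se for r in records])
        self.F = np.array([r.f_coef for r in records])
        self.stage = np.array([r.life_stage for r in records])
        self.studies = sorted({r.study for r in records})
        self.species = sorted({r.species for r in records})
        self.j_idx = np.array([self.studies.index(r.study) for r in records])
        self.o_idx = np.array([self.species.index(r.species) for r in records])
        self.l_idx = self.stage - 1

        if spec.variant in (1, 2):
            part = spec.partition
            missing = sorted(set(self.species) - set(part.assignment))
            if missing:
                raise ValueError(f"species missing from partition: {missing}")
            self.m_idx = np.array([part.assignment[s] - 1 for s in
                                   (self.species[o] for o in self.o_idx)])
            self.fst_cov = None
        else:
            cov = spec.covariate
            missing = sorted(set(self.species) - set(cov.index))
            if missing:
                raise ValueError(f"species missing from Fst covariate: {missing}")
            self.m_idx = None
            self.fst_cov = np.array([cov[self.species[o]] for o in self.o_idx])

        self._build_matrix()
        self._report_cells()

    # -- fixed-effect columns ------------------------------------------------

    def _build_matrix(self):
        n = len(self.y)
        spec = self.spec
        cols: list[np.ndarray] = []
        blocks: dict[str, slice] = {}

        def add(name, mat):
            start = sum(c.shape[1] for c in cols)
            cols.append(mat)
            blocks[name] = slice(start, start + mat.shape[1])

        add("mu", np.ones((n, 1)))

        C4 = _contrast(4)
        if spec.f_as_factor:
            f_levels = sorted(set(np.round(self.F, 6)))
            self.f_level_list = f_levels
            k_idx = np.array([f_levels.index(round(f, 6)) for f in self.F])
            Cf = _contrast(len(f_levels))
            add("alpha", Cf[k_idx])
            # stage x F-level interaction, total sum to zero
            KE = 4 * len(f_levels)
            e_idx = self.l_idx * len(f_levels) + k_idx
            add("epsilon", _contrast(KE)[e_idx])
        else:
            self.f_level_list = None
            add("alpha", self.F[:, None])
            add("epsilon", C4[self.l_idx] * self.F[:, None])

        add("beta", C4[self.l_idx])

        if spec.variant in (1, 2):
            C2 = _contrast(2)
            add("gamma", C2[self.m_idx])
            d_idx = self.l_idx * 2 + self.m_idx
            add("delta", _contrast(8)[d_idx])
        else:
            add("gamma", self.fst_cov[:, None])
            add("delta", C4[self.l_idx] * self.fst_cov[:, None])

        X = np.hstack(cols)
        self.n_fixed = X.shape[1]

        J, O = len(self.studies), len(self.species)
        Zj = np.zeros((n, J)); Zj[np.arange(n), self.j_idx] = 1.0
        Zo = np.zeros((n, O)); Zo[np.arange(n), self.o_idx] = 1.0
        blocks["study"] = slice(self.n_fixed, self.n_fixed + J)
        blocks["species"] = slice(self.n_fixed + J, self.n_fixed + J + O)
        self.Z = np.hstack([X, Zj, Zo])
        self.blocks = blocks

    def _report_cells(self):
        if self.m_idx is None:
            self.empty_cells = []
            return
        counts = pd.crosstab(
            pd.Series(self.F, name="F"),
            [pd.Series(self.stage, name="stage"), pd.Series(self.m_idx + 1, name="group")])
        sparse = []
        for f in sorted(set(self.F)):
            for l in LIFE_STAGES:
                for m in (1, 2):
                    nobs = int(((self.F == f) & (self.stage == l)
                                & (self.m_idx + 1 == m)).sum())
                    if nobs == 0:
                        sparse.append((f, l, m))
        self.empty_cells = sparse
        if sparse:
            warnings.warn(f"{len(sparse)} empty F x stage x group cells "
                          "(regularized by the hierarchical priors)", stacklevel=3)


def build_design(records: Sequence[IDRecord], spec: ModelSpec) -> Design:
    """Assemble index vectors, covariates and the design matrix."""
    return Design(records, spec)


def _t_logpdf(y, loc, scale, df):
    """Location-scale Student-t log density (vectorized)."""
    z = (y - loc) / scale
    return (gammaln((df + 1) / 2) - gammaln(df / 2)
            - 0.5 * np.log(df * np.pi) - np.log(scale)
            - (df + 1) / 2 * np.log1p(z * z / df))


def _trunc_invgamma(rng, shape, scale, upper):
    """Draw tau ~ InvGamma(shape, scale) truncated to (0, upper)."""
    hi = stats.invgamma.cdf(upper, a=shape, scale=scale)
    if hi <= 0:  # numerically all mass above the bound: pin at the bound
        return upper
    u = rng.uniform(0.0, hi)
    return float(stats.invgamma.ppf(u, a=shape, scale=scale))


def _slice_sample(x0, logp, rng, w=1.0, max_steps=50):
    """Univariate slice sampler (stepping out + shrinkage)."""
    y = logp(x0) + np.log(rng.uniform())
    lo = x0 - w * rng.uniform()
    hi = lo + w
    for _ in range(max_steps):
        if logp(lo) < y:
            break
        lo -= w
    for _ in range(max_steps):
        if logp(hi) < y:
            break
        hi += w
    for _ in range(100):
        x1 = rng.uniform(lo, hi)
        if logp(x1) >= y:
            return x1
        if x1 < x0:
            lo = x1
        else:
            hi = x1
    return x0


class IDMetaRegression:
    """Bayesian multilevel Student-t meta-regression of ID estimates.

    Statsmodels-style entry point: construct from records (or a DataFrame)
    plus a :class:`ModelSpec`, then call :meth:`fit`.
    """

    def __init__(self, records: Sequence[IDRecord], spec: ModelSpec):
        self.spec = spec
        self.design = build_design(records, spec)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, spec: ModelSpec,
                       **colmap) -> "IDMetaRegression":
        from .data import IDRecord as R
        records = []
        for _, row in df.iterrows():
            records.append(R(
                id_value=float(row[colmap.get("id_value", "id_value")]),
                se=float(row[colmap.get("se", "se")]),
                species=str(row[colmap.get("species", "species")]),
                study=str(row[colmap.get("study", "study")]),
                life_stage=int(row[colmap.get("life_stage", "life_stage")]),
                f_coef=float(row[colmap.get("f_coef", "f_coef")]),
            ))
        return cls(records, spec)

    # -- Gibbs sampler -------------------------------------------------------

    def _run_chain(self, rng, draws, warmup):
        d = self.design
        pr = self.spec.priors
        y, se, Z = d.y, d.se, d.Z
        n, P = Z.shape
        J = len(d.studies)
        O = len(d.species)
        sl_j, sl_o = d.blocks["study"], d.blocks["species"]
        se2 = se ** 2
        upper2 = pr.sigma_upper ** 2

        # prior precision layout: fixed effects N(0, normal_scale^2);
        # study/species precisions updated each sweep
        prior_prec = np.full(P, 1.0 / pr.normal_scale ** 2)

        # initial state
        lam = np.ones(n)
        sig2_a = sig2_b = 0.25
        sig2_y = 1.0
        df = pr.fix_df if pr.fix_df is not None else 10.0
        coef = np.zeros(P)

        n_keep = draws
        out_coef = np.empty((n_keep, P))
        out_sig = np.empty((n_keep, 3))
        out_df = np.empty(n_keep)

        ZT = Z.T
        for it in range(warmup + draws):
            # 1. joint update of all location parameters
            prior_prec[sl_j] = 1.0 / sig2_a
            prior_prec[sl_o] = 1.0 / sig2_b
            w = lam / (sig2_y * se2)
            A = (ZT * w) @ Z
            A[np.diag_indices_from(A)] += prior_prec
            bvec = ZT @ (w * y)
            L = cholesky(A, lower=True)
            mean = cho_solve((L, True), bvec)
            zdraw = rng.standard_normal(P)
            coef = mean + np.linalg.solve(L.T, zdraw)

            resid = y - Z @ coef

            # 2. variance components of the random intercepts
            #    (uniform prior on sigma => truncated inverse gamma on tau)
            a_j = coef[sl_j]
            b_o = coef[sl_o]
            if J >= 2:
                sig2_a = _trunc_invgamma(rng, (J - 1) / 2.0,
                                         float(np.sum(a_j ** 2)) / 2.0, upper2)
            if O >= 2:
                sig2_b = _trunc_invgamma(rng, (O - 1) / 2.0,
                                         float(np.sum(b_o ** 2)) / 2.0, upper2)

            # 3. sigma_y and df by slice sampling against the Student-t
            #    marginal (mixing weights integrated out), which decouples
            #    them from lambda; lambda is re-imputed afterwards.
            def logp_sigy(x):
                s = np.exp(x)
                if not (0.0 < s < pr.sigma_upper):
                    return -np.inf
                return float(np.sum(_t_logpdf(resid, 0.0, s * se, df))) + x

            sig2_y = float(np.exp(_slice_sample(np.log(np.sqrt(sig2_y)),
                                                logp_sigy, rng))) ** 2
            sig_y_se = np.sqrt(sig2_y) * se

            def logp_df(x):
                v = np.exp(x)
                if not np.isfinite(v) or v <= 0 or v > 1e6:
                    return -np.inf
                ll = float(np.sum(_t_logpdf(resid, 0.0, sig_y_se, v)))
                return ll + pr.df_shape * x - pr.df_rate * v  # prior + Jacobian

            if pr.fix_df is None:
                df = float(np.exp(_slice_sample(np.log(df), logp_df, rng)))

            # 4. t mixing weights (auxiliary for the next location update)
            r2 = resid ** 2 / (sig2_y * se2)
            lam = rng.gamma((df + 1.0) / 2.0, 2.0 / (df + r2))

            if it >= warmup:
                k = it - warmup
                out_coef[k] = coef
                out_sig[k] = (np.sqrt(sig2_a), np.sqrt(sig2_b), np.sqrt(sig2_y))
                out_df[k] = df
        return out_coef, out_sig, out_df

    def fit(self, settings: SamplerSettings | None = None, **kwargs) -> "MetaResults":
        """Run the Gibbs sampler and return posterior draws.

        Keyword arguments override fields of :class:`SamplerSettings`.
        """
        if settings is None:
            settings = SamplerSettings(**kwargs)
        d = self.design
        root = np.random.SeedSequence(settings.seed)
        chains = []
        for child in root.spawn(settings.chains):
            rng = np.random.default_rng(child)
            chains.append(self._run_chain(rng, settings.draws, settings.warmup))
        coef = np.stack([c[0] for c in chains])    # (chain, draw, P)
        sig = np.stack([c[1] for c in chains])
        dfd = np.stack([c[2] for c in chains])
        return MetaResults(self, coef, sig, dfd, settings)


def fit_meta_regression(records: Sequence[IDRecord], spec: ModelSpec,
                        settings: SamplerSettings | None = None,
                        **kwargs) -> "MetaResults":
    """Build the design and fit the chosen model variant."""
    return IDMetaRegression(records, spec).fit(settings, **kwargs)


@dataclass(frozen=True)
class PredictiveDraw:
    """Posterior-predictive summary of ID at one design point."""

    stage: int
    f_coef: float
    group: int | None
    fst: float | None
    se_ref: float
    mean: float
    q025: float
    q05: float
    q95: float
    q975: float

    def __post_init__(self):
        qs = (self.q025, self.q05, self.q95, self.q975)
        if any(b < a for a, b in zip(qs, qs[1:])):
            raise ValueError("predictive quantiles out of order")


class MetaResults:
    """Posterior draws and diagnostics for one fitted model variant.

    Draw arrays are shaped (chain, draw, ...); the expanded effect vectors
    (full sum-to-zero beta, gamma, delta, epsilon) are exposed through
    :attr:`params`, and the pointwise log-likelihood matrix used for LOO
    through :meth:`log_likelihood`.
    """

    def __init__(self, model: IDMetaRegression, coef, sig, dfd,
                 settings: SamplerSettings):
        self.model = model
        self.design = model.design
        self.spec = model.spec
        self.settings = settings
        self._coef = coef            # (chain, draw, P)
        self._sig = sig              # (chain, draw, 3) -> sigma_a, sigma_b, sigma_y
        self._df = dfd               # (chain, draw)
        self.params = self._expand_params()
        self._loglik = None
        self.diagnostics = self._diagnose()

    # -- parameter expansion -------------------------------------------------

    def _expand_params(self) -> dict:
        d = self.design
        bl = d.blocks
        C, D, _ = self._coef.shape
        p = {}
        p["mu"] = self._coef[..., bl["mu"]][..., 0]
        C4 = _contrast(4)
        if self.spec.f_as_factor:
            nf = len(d.f_level_list)
            p["alpha"] = self._coef[..., bl["alpha"]] @ _contrast(nf).T
            p["epsilon"] = self._coef[..., bl["epsilon"]] @ _contrast(4 * nf).T
        else:
            p["alpha"] = self._coef[..., bl["alpha"]][..., 0]
            p["epsilon"] = self._coef[..., bl["epsilon"]] @ C4.T
        p["beta"] = self._coef[..., bl["beta"]] @ C4.T
        if self.spec.variant in (1, 2):
            p["gamma"] = self._coef[..., bl["gamma"]] @ _contrast(2).T
            delta_flat = self._coef[..., bl["delta"]] @ _contrast(8).T
            p["delta"] = delta_flat.reshape(C, D, 4, 2)
        else:
            p["gamma"] = self._coef[..., bl["gamma"]][..., 0]
            p["delta"] = self._coef[..., bl["delta"]] @ C4.T
        p["a"] = self._coef[..., bl["study"]]
        p["b"] = self._coef[..., bl["species"]]
        p["sigma_a"] = self._sig[..., 0]
        p["sigma_b"] = self._sig[..., 1]
        p["sigma_y"] = self._sig[..., 2]
        p["df"] = self._df
        return p

    # -- pointwise log likelihood --------------------------------------------

    def log_likelihood(self) -> np.ndarray:
        """(chain, draw, observation) log density of each y_i per draw."""
        if self._loglik is None:
            d = self.design
            theta = np.einsum("cdp,np->cdn", self._coef, d.Z)
            scale = self.params["sigma_y"][..., None] * d.se[None, None, :]
            df = self.params["df"][..., None]
            self._loglik = _t_logpdf(d.y[None, None, :], theta, scale, df)
        return self._loglik

    def to_inference_data(self):
        """Package draws and pointwise log likelihood for arviz."""
        import arviz as az

        post = {
            "mu": self.params["mu"],
            "alpha": self.params["alpha"],
            "beta": self.params["beta"],
            "gamma": self.params["gamma"],
            "delta": self.params["delta"],
            "epsilon": self.params["epsilon"],
            "sigma_a": self.params["sigma_a"],
            "sigma_b": self.params["sigma_b"],
            "sigma_y": self.params["sigma_y"],
            "df": self.params["df"],
        }
        return az.from_dict(posterior=post,
                            log_likelihood={"y": self.log_likelihood()})

    # -- diagnostics ---------------------------------------------------------

    def _diagnose(self) -> dict:
        import arviz as az

        names = ["mu", "sigma_a", "sigma_b", "sigma_y"]
        if self.spec.priors.fix_df is None:
            names.append("df")
        scalars = {k: self.params[k] for k in names}
        if self.params["alpha"].ndim == 2:
            scalars["alpha"] = self.params["alpha"]
        idata = az.from_dict(posterior=scalars)
        rhat = az.rhat(idata)
        ess = az.ess(idata)
        max_rhat = float(max(np.nanmax(np.atleast_1d(rhat[k].values))
                             for k in scalars))
        min_ess = float(min(np.nanmin(np.atleast_1d(ess[k].values))
                            for k in scalars))
        diag = {"max_rhat": max_rhat, "min_ess": min_ess,
                "ok": max_rhat <= 1.01 and min_ess >= 100}
        if not diag["ok"]:
            warnings.warn(f"meta-regression convergence suspect: {diag}")
        return diag

    # -- summaries -----------------------------------------------------------

    def _flat(self, name) -> np.ndarray:
        v = self.params[name]
        return v.reshape(-1, *v.shape[2:])

    def parameter_table(self) -> pd.DataFrame:
        """Long table of scalar location/scale parameters with intervals."""
        rows = []

        def emit(label, draws):
            q = np.quantile(draws, [0.025, 0.05, 0.5, 0.95, 0.975])
            rows.append({"parameter": label, "mean": float(draws.mean()),
                         "sd": float(draws.std(ddof=1)),
                         "q025": q[0], "q05": q[1], "median": q[2],
                         "q95": q[3], "q975": q[4]})

        emit("mu", self._flat("mu"))
        alpha = self._flat("alpha")
        if alpha.ndim == 1:
            emit("alpha", alpha)
        else:
            for k in range(alpha.shape[1]):
                emit(f"alpha[{k + 1}]", alpha[:, k])
        beta = self._flat("beta")
        for l in range(4):
            emit(f"beta[{l + 1}]", beta[:, l])
        gamma = self._flat("gamma")
        if gamma.ndim == 1:
            emit("gamma", gamma)
        else:
            for m in range(gamma.shape[1]):
                emit(f"gamma[{m + 1}]", gamma[:, m])
        delta = self._flat("delta")
        if delta.ndim == 3:
            for l in range(4):
                for m in range(2):
                    emit(f"delta[{l + 1},{m + 1}]", delta[:, l, m])
        else:
            for l in range(delta.shape[1]):
                emit(f"delta[{l + 1}]", delta[:, l])
        eps = self._flat("epsilon")
        for l in range(eps.shape[1]):
            emit(f"epsilon[{l + 1}]", eps[:, l])
        for s in ("sigma_a", "sigma_b", "sigma_y", "df"):
            emit(s, self._flat(s))
        return pd.DataFrame(rows)

    def summary(self) -> pd.DataFrame:
        """Posterior summary with significance labels, one row per parameter."""
        tab = self.parameter_table()
        tab["label"] = [
            "significant" if (r.q025 > 0 or r.q975 < 0)
            else "marginal" if (r.q05 > 0 or r.q95 < 0)
            else "ns"
            for r in tab.itertuples()
        ]
        return tab

    def classify_effects(self) -> pd.DataFrame:
        """Significance labels for the location parameters.

        A parameter is *significant* if zero lies outside its central 95%
        credible interval, *marginal* if outside the 90% interval only,
        else *ns*.
        """
        tab = self.summary()
        scales = {"sigma_a", "sigma_b", "sigma_y", "df"}
        tab = tab[~tab["parameter"].isin(scales)].reset_index(drop=True)
        return tab[["parameter", "mean", "q025", "q05", "q95", "q975", "label"]]

    # -- prediction ----------------------------------------------------------

    def predict_id(self, stage: int, f_coef: float, group: int | None = None,
                   fst: float | None = None, se_ref: float = 0.1,
                   seed: int = 0) -> PredictiveDraw:
        """Posterior-predictive ID at a design point, averaging over
        study and species effects (a = b = 0).

        For variants 1-2 supply ``group`` (1 well-connected, 2 fragmented);
        for variant 3 supply ``fst`` (species effect on Fst).  ``se_ref``
        is the reported-SE at which the predictive t noise is evaluated;
        as se_ref -> 0 the predictive mean tends to the posterior mean of
        the linear predictor.
        """
        if stage not in LIFE_STAGES:
            raise ValueError(f"stage must be in {LIFE_STAGES}")
        if not se_ref > 0:
            raise ValueError("se_ref must be > 0")
        p = self.params
        l = stage - 1
        mu = self._flat("mu")
        beta = self._flat("beta")[:, l]
        eps = self._flat("epsilon")
        if self.spec.f_as_factor:
            levels = self.design.f_level_list
            if round(f_coef, 6) not in levels:
                raise ValueError(f"f_coef {f_coef} not a model level {levels}")
            k = levels.index(round(f_coef, 6))
            alpha_term = self._flat("alpha")[:, k]
            eps_term = eps.reshape(len(eps), 4, len(levels))[:, l, k]
        else:
            alpha_term = self._flat("alpha") * f_coef
            eps_term = eps[:, l] * f_coef
        if self.spec.variant in (1, 2):
            if group not in (1, 2):
                raise ValueError("variants 1-2 need group in {1, 2}")
            gam = self._flat("gamma")[:, group - 1]
            del_ = self._flat("delta")[:, l, group - 1]
        else:
            if fst is None:
                raise ValueError("variant 3 needs an fst covariate value")
            gam = self._flat("gamma") * fst
            del_ = self._flat("delta")[:, l] * fst
        theta = mu + alpha_term + beta + gam + del_ + eps_term
        sigy = self._flat("sigma_y")
        dfv = self._flat("df")
        rng = np.random.default_rng(seed)
        ydraw = theta + sigy * se_ref * rng.standard_t(dfv)
        q = np.quantile(ydraw, [0.025, 0.05, 0.95, 0.975])
        return PredictiveDraw(
            stage=stage, f_coef=f_coef, group=group, fst=fst, se_ref=se_ref,
            mean=float(theta.mean()),
            q025=float(q[0]), q05=float(q[1]), q95=float(q[2]), q975=float(q[3]))


def classify_effects(fit: MetaResults) -> pd.DataFrame:
    """Functional façade over :meth:`MetaResults.classify_effects`."""
    return fit.classify_effects()


def predict_id(fit: MetaResults, stage: int, f_coef: float, **kwargs) -> PredictiveDraw:
    """Functional façade over :meth:`MetaResults.predict_id`."""
    return fit.predict_id(stage, f_coef, **kwargs)
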