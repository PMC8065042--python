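"""Synthetic ID and Fst datasets from the analysis' own generative model.

The generator reproduces the *statistical* model assumed by the
meta-regression — Student-t residuals scaled by the reported standard
error, normal study and species intercepts, additive stage, connectivity
and interaction effects on the linear predictor — and, for the Fst table,
a beta-distributed response with logit-scale marker and species effects.
It exists so that every downstream stage (regression, clustering, model
comparison) is testable end-to-end and supports parameter-recovery
experiments; it does not simulate the underlying biology (embryo
abortion, purging) in any mechanistic sense.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.special import expit

from .data import IDRecord, FstRecord, F_LEVELS, LIFE_STAGES

__all__ = [
    "TrueParams",
    "SimDesign",
    "sum_to_zero",
    "simulate_id_dataset",
    "simulate_fst_dataset",
]


def sum_to_zero(x: np.ndarray) -> np.ndarray:
    """Project an effect vector onto the sum-to-zero constraint surface."""
    x = np.asarray(x, dtype=float)
    return x - x.mean()


@dataclass(frozen=True)
class TrueParams:
    """True parameter set of the ID meta-regression, used as simulation truth.

    ``beta`` (life stage, 4), ``gamma`` (connectivity, 2), ``delta``
    (stage x connectivity, 4x2) and ``epsilon`` (stage-specific F slope, 4)
    each sum to zero; ``alpha`` and ``epsilon`` multiply the inbreeding
    coefficient F.  ``sigma_y`` scales the reported SEs into the Student-t
    residual scale and ``df`` is the t degrees of freedom.
    """

    mu: float = 0.2
    alpha: float = 0.5
    beta: tuple = (0.0, 0.0, 0.0, 0.0)
    gamma: tuple = (0.0, 0.0)
    delta: tuple = ((0.0, 0.0),) * 4
    epsilon: tuple = (0.0, 0.0, 0.0, 0.0)
    sigma_a: float = 0.1
    sigma_b: float = 0.1
    sigma_y: float = 1.0
    df: float = 10.0

    def validate(self, tol: float = 1e-8) -> "TrueParams":
        b = np.asarray(self.beta, float)
        g = np.asarray(self.gamma, float)
        d = np.asarray(self.delta, float)
        e = np.asarray(self.epsilon, float)
        if b.shape != (4,) or g.shape != (2,) or d.shape != (4, 2) or e.shape != (4,):
            raise ValueError("effect shapes must be beta(4), gamma(2), delta(4x2), epsilon(4)")
        for name, v in (("beta", b), ("gamma", g), ("delta", d), ("epsilon", e)):
            if abs(v.sum()) > tol:
                raise ValueError(f"{name} must sum to zero (got {v.sum():g})")
        for name, v in (("sigma_a", self.sigma_a), ("sigma_b", self.sigma_b),
                        ("sigma_y", self.sigma_y), ("df", self.df)):
            if not v > 0:
                raise ValueError(f"{name} must be > 0 (got {v})")
        return self

    @staticmethod
    def centered(mu=0.2, alpha=0.5, beta=(0.4, -0.3, 0.0, -0.1),
                 gamma=(0.1, -0.1), delta=None, epsilon=(0.3, -0.2, -0.05, -0.05),
                 sigma_a=0.1, sigma_b=0.1, sigma_y=1.0, df=10.0) -> "TrueParams":
        """Build a valid parameter set, projecting effects to sum to zero."""
        if delta is None:
            delta = np.zeros((4, 2))
        d = np.asarray(delta, float)
        d = d - d.mean()
        return TrueParams(
            mu=mu, alpha=alpha,
            beta=tuple(sum_to_zero(beta)),
            gamma=tuple(sum_to_zero(gamma)),
            delta=tuple(map(tuple, d)),
            epsilon=tuple(sum_to_zero(epsilon)),
            sigma_a=sigma_a, sigma_b=sigma_b, sigma_y=sigma_y, df=df,
        ).validate()


@dataclass(frozen=True)
class SimDesign:
    """Layout of a simulated ID dataset.

    ``n_rows`` observations are spread round-robin over the stage x F
    design cells; species are split evenly between the two connectivity
    groups; each study contributes rows for a single species (mirroring the
    real study structure).  Reported SEs are drawn from a log-normal law
    with the given log-scale median and log-sd (positive by construction;
    the published record never states an SE-generating law, so this default
    is a stand-in chosen to resemble the spread of reported errors).
    """

    n_studies: int = 30
    n_species: int = 15
    n_rows: int = 600
    stages: tuple = LIFE_STAGES
    f_levels: tuple = F_LEVELS
    se_median: float = 0.1
    se_log_sd: float = 0.5
    seed: int = 0

    def validate(self) -> "SimDesign":
        if self.n_studies < self.n_species:
            raise ValueError("need at least one study per species")
        if self.n_rows < self.n_studies:
            raise ValueError("need at least one row per study")
        if not self.stages or not self.f_levels:
            raise ValueError("at least one stage and one F level required")
        if self.se_median <= 0 or self.se_log_sd < 0:
            raise ValueError("SE law parameters must be positive")
        return self


def simulate_id_dataset(params: TrueParams, design: SimDesign) -> list[IDRecord]:
    """Draw an ID table from the meta-regression's generative model.

    For each row i the linear predictor is
    Theta_i = mu + alpha F_i + beta_l + gamma_m + delta_lm + epsilon_l F_i
    + a_j + b_o, with study intercepts a_j ~ N(0, sigma_a^2) and species
    intercepts b_o ~ N(0, sigma_b^2), and the response is drawn from a
    location-scale Student-t with location Theta_i, scale sigma_y * SE_i
    and df degrees of freedom.
    """
    params.validate()
    design.validate()
    rng = np.random.default_rng(design.seed)

    n = design.n_rows
    beta = np.asarray(params.beta)
    gamma = np.asarray(params.gamma)
    delta = np.asarray(params.delta)
    epsilon = np.asarray(params.epsilon)

    # species -> connectivity group (first half well-connected)
    species_group = np.where(np.arange(design.n_species) < design.n_species / 2, 1, 2)
    study_species = np.arange(design.n_studies) % design.n_species
    row_study = np.arange(n) % design.n_studies

    cells = [(l, f) for l in design.stages for f in design.f_levels]
    row_cell = [cells[i % len(cells)] for i in range(n)]

    a = rng.normal(0.0, params.sigma_a, design.n_studies)
    b = rng.normal(0.0, params.sigma_b, design.n_species)
    se = rng.lognormal(np.log(design.se_median), design.se_log_sd, n)

    records = []
    for i in range(n):
        l, f = row_cell[i]
        j = row_study[i]
        o = study_species[j]
        m = species_group[o]
        theta = (params.mu + params.alpha * f + beta[l - 1] + gamma[m - 1]
                 + delta[l - 1, m - 1] + epsilon[l - 1] * f + a[j] + b[o])
        y = theta + params.sigma_y * se[i] * rng.standard_t(params.df)
        records.append(IDRecord(
            id_value=float(y),
            se=float(se[i]),
            species=f"sp{o:02d}",
            study=f"study{j:02d}",
            life_stage=int(l),
            f_coef=float(f),
            connectivity=int(m),
        ))
    return records


def simulate_fst_dataset(species_effects: Mapping[str, float],
                         marker_effects: Mapping[str, float],
                         phi: float,
                         n_per_species: int | Mapping[str, int] = 2,
                         intercept: float = -2.0,
                         seed: int = 0) -> list[FstRecord]:
    """Draw an Fst table from the beta-regression generative model.

    Each estimate is Beta(mu*phi, (1-mu)*phi) with
    logit(mu) = intercept + marker effect + species effect; marker types
    cycle through ``marker_effects`` within each species.
    """
    if not phi > 0:
        raise ValueError(f"phi must be > 0 (got {phi})")
    rng = np.random.default_rng(seed)
    markers = list(marker_effects)
    records = []
    for s, s_eff in species_effects.items():
        k = n_per_species[s] if isinstance(n_per_species, Mapping) else n_per_species
        for i in range(k):
            m = markers[i % len(markers)]
            mu = float(expit(intercept + marker_effects[m] + s_eff))
            fst = float(rng.beta(mu * phi, (1.0 - mu) * phi))
            # open-interval guard for extreme draws at tiny precision
            fst = min(max(fst, 1e-12), 1 - 1e-12)
            records.append(FstRecord(species=s, fst=fst, marker_type=m))
    return records
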