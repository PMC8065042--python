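"""Predictive model comparison and report tables.

Out-of-sample fit of each model variant is estimated by Pareto-smoothed
importance-sampling leave-one-out cross-validation (PSIS-LOO) computed
from the stored pointwise log-likelihood matrix: for each observation the
importance ratios are tail-smoothed by a generalized Pareto fit to the
largest 20% of ratios, and elpd_loo_i is the log of the smoothed
importance-weighted predictive density.  LOOIC = -2 * elpd_loo; higher
elpd (lower LOOIC) is better.  Per-observation Pareto-k values above 0.7
flag unreliable importance sampling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .data import IDRecord
from .meta import MetaResults

__all__ = [
    "LooResult",
    "ComparisonTable",
    "compute_loo",
    "compare_models",
    "forest_table",
    "posterior_density_table",
]

PARETO_K_THRESHOLD = 0.7


@dataclass(frozen=True)
class LooResult:
    """PSIS-LOO estimate of expected log pointwise predictive density."""

    elpd_loo: float
    se_elpd: float
    p_loo: float
    looic: float
    pointwise: pd.DataFrame      # columns: elpd_i, pareto_k
    n_bad_k: int

    @property
    def n(self) -> int:
        return len(self.pointwise)


def compute_loo(fit: MetaResults) -> LooResult:
    """PSIS-LOO from a fitted model's pointwise log likelihood."""
    import arviz as az

    idata = fit.to_inference_data()
    res = az.loo(idata, pointwise=True)
    elpd = float(res.elpd_loo)
    pointwise = pd.DataFrame({
        "elpd_i": np.asarray(res.loo_i.values, dtype=float),
        "pareto_k": np.asarray(res.pareto_k.values, dtype=float),
    })
    n_bad = int((pointwise["pareto_k"] > PARETO_K_THRESHOLD).sum())
    return LooResult(
        elpd_loo=elpd,
        se_elpd=float(res.se),
        p_loo=float(res.p_loo),
        looic=-2.0 * elpd,
        pointwise=pointwise,
        n_bad_k=n_bad,
    )


@dataclass(frozen=True)
class ComparisonTable:
    """Ranking of model variants by elpd_loo with pairwise differences."""

    table: pd.DataFrame          # per model: elpd_loo, se, p_loo, looic, sigma_y
    pairwise: pd.DataFrame       # model_a, model_b, d_elpd, se_d

    @property
    def best(self) -> str:
        return self.table.index[0]


def compare_models(loos: Sequence[LooResult],
                   names: Sequence[str] | None = None,
                   fits: Sequence[MetaResults] | None = None) -> ComparisonTable:
    """Rank models by elpd_loo and compute pairwise elpd differences.

    All LOO results must be computed on the same observation set.  The
    pairwise difference SE comes from the pointwise elpd differences:
    se = sqrt(n * var(elpd_i^A - elpd_i^B)).
    """
    if not loos:
        raise ValueError("no LOO results to compare")
    ns = {l.n for l in loos}
    if len(ns) != 1:
        raise ValueError(f"LOO results cover different observation sets: n = {sorted(ns)}")
    n = ns.pop()
    names = list(names) if names else [f"model{i + 1}" for i in range(len(loos))]
    if len(names) != len(loos):
        raise ValueError("one name per LOO result required")

    rows = {}
    for i, (name, loo) in enumerate(zip(names, loos)):
        row = {"elpd_loo": loo.elpd_loo, "se_elpd": loo.se_elpd,
               "p_loo": loo.p_loo, "looic": loo.looic, "n_bad_k": loo.n_bad_k}
        if fits is not None:
            sy = fits[i].params["sigma_y"]
            row["sigma_y_mean"] = float(sy.mean())
            row["sigma_y_sd"] = float(sy.std(ddof=1))
        rows[name] = row
    table = pd.DataFrame(rows).T.sort_values("elpd_loo", ascending=False)

    pair_rows = []
    for i, ni in enumerate(names):
        for j, nj in enumerate(names):
            if i == j:
                continue
            di = loos[i].pointwise["elpd_i"].values - loos[j].pointwise["elpd_i"].values
            pair_rows.append({
                "model_a": ni, "model_b": nj,
                "d_elpd": float(di.sum()),
                "se_d": float(np.sqrt(n * np.var(di, ddof=1))),
            })
    return ComparisonTable(table=table, pairwise=pd.DataFrame(pair_rows))


def forest_table(records: Sequence[IDRecord],
                 group_by: str | None = None):
    """Per-estimate table for forest plotting.

    Each row carries the ID estimate with its 95% normal-approximation
    interval (id +/- 1.96 se) plus the study-specific covariate levels,
    sorted by species then life stage (stable order).  With ``group_by``
    (an IDRecord field such as ``connectivity``), returns a dict of
    tables keyed by that field's values.
    """
    df = pd.DataFrame({
        "species": [r.species for r in records],
        "study": [r.study for r in records],
        "life_stage": [r.life_stage for r in records],
        "f_coef": [r.f_coef for r in records],
        "connectivity": [r.connectivity for r in records],
        "id_value": [r.id_value for r in records],
        "se": [r.se for r in records],
    })
    df["ci_low"] = df["id_value"] - 1.96 * df["se"]
    df["ci_high"] = df["id_value"] + 1.96 * df["se"]
    df = df.sort_values(["species", "life_stage"], kind="stable").reset_index(drop=True)
    if group_by is None:
        return df
    return {k: g.reset_index(drop=True) for k, g in df.groupby(group_by, dropna=False)}


def posterior_density_table(fit: MetaResults) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Long-format posterior draws per parameter plus 90% interval markers.

    Returns ``(draws, intervals)``: ``draws`` has one row per (parameter,
    draw) over the group-level regression coefficients; ``intervals``
    carries the 5/95% quantiles and the mean per parameter.
    """
    tab = fit.parameter_table().set_index("parameter")
    keep = [p for p in tab.index
            if p.split("[")[0] in ("alpha", "beta", "gamma", "delta", "epsilon")]
    long_rows = []
    flat = {
        "alpha": fit._flat("alpha"), "beta": fit._flat("beta"),
        "gamma": fit._flat("gamma"), "delta": fit._flat("delta"),
        "epsilon": fit._flat("epsilon"),
    }
    for p in keep:
        base = p.split("[")[0]
        arr = flat[base]
        if "[" in p:
            idx = p[p.index("[") + 1:-1]
            ix = tuple(int(t) - 1 for t in idx.split(","))
            vals = arr[(slice(None),) + ix]
        else:
            vals = arr
        long_rows.append(pd.DataFrame({"parameter": p, "value": vals}))
    draws = pd.concat(long_rows, ignore_index=True)
    intervals = tab.loc[keep, ["mean", "q05", "q95"]].reset_index()
    return draws, intervals


def plot_forest(table: pd.DataFrame, ax=None):
    """Minimal static rendering of a forest table (optional)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 0.25 * len(table) + 1))
    y = np.arange(len(table))[::-1]
    ax.hlines(y, table["ci_low"], table["ci_high"], color="0.4", lw=1)
    ax.plot(table["id_value"], y, "s", ms=3, color="k")
    ax.axvline(0.0, color="0.8", lw=0.8)
    ax.set_yticks(y)
    ax.set_yticklabels(table["species"] + " / " + table["study"], fontsize=6)
    ax.set_xlabel("inbreeding depression")
    return ax
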