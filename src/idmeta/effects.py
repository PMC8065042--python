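"""Effect sizes, life-stage mapping, homogeneity testing and pedigree F.

Stage-specific inbreeding depression is delta = 1 - w_self/w_out, the
relative fitness loss of inbred progeny against an outcrossed reference
(Husband & Schemske's convention: positive when inbreds do worse).  Its
standard error is obtained from the reported SEs of the two fitness means
by a first-order delta-method (Taylor) approximation of the ratio.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data import IDRecord, F_LEVELS, LIFE_STAGES

__all__ = [
    "FitnessPair",
    "QResult",
    "compute_id",
    "taylor_se",
    "assign_life_stage",
    "cochran_q",
    "summarize_dataset",
    "pedigree_inbreeding",
    "crossing_design_f",
    "EXCLUDED_TRAITS",
    "TRAIT_STAGES",
]


@dataclass(frozen=True)
class FitnessPair:
    """Mean fitness of an outcrossed and an inbred population, with SEs."""

    w_out: float
    se_out: float
    w_self: float
    se_self: float

    def __post_init__(self):
        if not (self.w_out > 0):
            raise ValueError(f"w_out must be > 0: {self.w_out}")
        if self.se_out < 0 or self.se_self < 0:
            raise ValueError("standard errors must be >= 0")
        if self.w_self < 0:
            raise ValueError(f"w_self must be >= 0: {self.w_self}")


@dataclass(frozen=True)
class QResult:
    """Cochran's homogeneity statistic with its chi-square reference."""

    q: float
    df: int
    p_value: float


def compute_id(pair: FitnessPair, printed_orientation: bool = False) -> float:
    """Stage-specific inbreeding depression from a fitness pair.

    Default orientation is 1 - w_self/w_out (positive when inbred progeny
    are less fit; at most 1, negative values denote outbreeding
    depression).  ``printed_orientation=True`` gives the transposed ratio
    1 - w_out/w_self, retained only for comparison purposes.
    """
    if printed_orientation:
        if pair.w_self == 0:
            raise ValueError("w_self = 0: printed-orientation ID undefined")
        return 1.0 - pair.w_out / pair.w_self
    return 1.0 - pair.w_self / pair.w_out


def taylor_se(pair: FitnessPair) -> float:
    """First-order delta-method SE of the fitness ratio w_self/w_out.

    Assumes the two means are independent; the SE of delta equals the SE of
    the ratio: (w_s/w_o) * sqrt((se_s/w_s)^2 + (se_o/w_o)^2).
    """
    if pair.w_self == 0:
        if pair.se_self == 0 and pair.se_out == 0:
            return 0.0
        raise ValueError("w_self = 0 with nonzero SEs: ratio SE undefined")
    r = pair.w_self / pair.w_out
    return abs(r) * np.sqrt((pair.se_self / pair.w_self) ** 2
                            + (pair.se_out / pair.w_out) ** 2)


#: Trait vocabulary -> life stage.  Stage 1 is embryonic (seed quality),
#: stage 2 first-year germination; height/diameter/survival map to stage 3
#: or 4 depending on whether the population has reached reproductive age.
TRAIT_STAGES: Mapping[str, int] = {
    "percent_sound_seeds": 1,
    "sound_seeds_per_cone": 1,
    "total_sound_seeds": 1,
    "germination_percent": 2,
    "hypocotyl_height": 2,
    "germination_rate_days": 2,
    "height": 0,      # age-dependent
    "diameter": 0,    # age-dependent
    "survival": 0,    # age-dependent
}

#: Traits rejected outright: powers of height/diameter inflate apparent ID.
EXCLUDED_TRAITS = frozenset({"stem_volume", "sectional_area"})

#: Age (growing seasons) at which populations are considered reproductive.
REPRODUCTIVE_AGE = 12


def assign_life_stage(trait_label: str, age_years: float | None = None) -> int:
    """Map a fitness trait (and measurement age) to a life-stage code 1-4.

    Raises on unknown traits, on excluded traits (stem volume, sectional
    area) and on age-dependent traits with no age given.
    """
    if trait_label in EXCLUDED_TRAITS:
        raise ValueError(f"excluded trait: {trait_label!r} is not an admissible "
                         "fitness measure (power of height/diameter)")
    if trait_label not in TRAIT_STAGES:
        known = sorted(TRAIT_STAGES) + sorted(EXCLUDED_TRAITS)
        raise ValueError(f"unknown trait {trait_label!r}; vocabulary: {known}")
    stage = TRAIT_STAGES[trait_label]
    if stage:
        return stage
    if age_years is None:
        raise ValueError(f"trait {trait_label!r} needs age_years to resolve "
                         "adult vegetative vs adult reproductive")
    return 4 if age_years >= REPRODUCTIVE_AGE else 3


def cochran_q(values: Sequence[float], ses: Sequence[float]) -> QResult:
    """Cochran's Q homogeneity test with inverse-variance weights.

    Q = sum w_i (y_i - ybar)^2 with w_i = 1/se_i^2 and ybar the weighted
    mean; under homogeneity Q ~ chi-square with N-1 degrees of freedom.
    """
    y = np.asarray(values, dtype=float)
    se = np.asarray(ses, dtype=float)
    if y.shape != se.shape or y.ndim != 1:
        raise ValueError("values and ses must be matching 1-D sequences")
    if y.size < 2:
        raise ValueError("need at least 2 estimates for a homogeneity test")
    if np.any(se <= 0):
        raise ValueError("all standard errors must be > 0")
    w = 1.0 / se**2
    ybar = np.sum(w * y) / np.sum(w)
    q = float(np.sum(w * (y - ybar) ** 2))
    df = y.size - 1
    p = float(stats.chi2.sf(q, df))
    return QResult(q=q, df=df, p_value=p)


def summarize_dataset(records: Sequence[IDRecord],
                      percentiles: Sequence[float] = (10, 50, 90)) -> dict:
    """Counts by design cell and percentiles of the ID estimates.

    Returns a dict with ``n`` (total), ``by_f``, ``by_stage``,
    ``by_f_group`` count tables and ``percentiles`` of the ID values
    (linear interpolation between order statistics).
    """
    df = pd.DataFrame({
        "id_value": [r.id_value for r in records],
        "f_coef": [r.f_coef for r in records],
        "life_stage": [r.life_stage for r in records],
        "connectivity": [r.connectivity for r in records],
    })
    if df.empty:
        raise ValueError("no records to summarize")
    pct = {p: float(np.percentile(df["id_value"], p)) for p in percentiles}
    by_f = df.groupby("f_coef").size().to_dict()
    by_stage = df.groupby("life_stage").size().to_dict()
    by_fg = (df.dropna(subset=["connectivity"])
               .groupby(["f_coef", "connectivity"]).size().to_dict())
    return {
        "n": len(df),
        "by_f": by_f,
        "by_stage": by_stage,
        "by_f_group": by_fg,
        "percentiles": pct,
    }


# ---------------------------------------------------------------------------
# Pedigree inbreeding coefficients


def _kinship(a, b, ped, cache):
    """Malécot kinship coefficient by the recursive tabular method."""
    if a is None or b is None:
        return 0.0
    key = (a, b) if a <= b else (b, a)
    if key in cache:
        return cache[key]
    # recurse through the younger individual's parents
    order = {k: i for i, k in enumerate(ped)}
    if order.get(a, -1) < order.get(b, -1):
        a, b = b, a
    if a == b:
        s, d = ped[a]
        val = 0.5 * (1.0 + _kinship(s, d, ped, cache))
    else:
        s, d = ped[a]
        val = 0.5 * (_kinship(s, b, ped, cache) + _kinship(d, b, ped, cache))
    cache[key] = val
    return val


def pedigree_inbreeding(pedigree: Mapping[str, tuple], individual: str) -> float:
    """Wright's inbreeding coefficient of ``individual`` from a pedigree.

    ``pedigree`` maps each individual to ``(sire, dam)``; founders use
    ``None`` for unknown parents and must precede their offspring in the
    mapping's iteration order.  F equals the kinship of the parents.
    """
    if individual not in pedigree:
        raise KeyError(f"individual {individual!r} not in pedigree")
    s, d = pedigree[individual]
    return _kinship(s, d, dict(pedigree), {})


#: Crossing designs realisable in conifer breeding trials and the
#: inbreeding coefficients their pedigrees produce.
_DESIGNS = ("half_sib", "full_sib", "selfing", "double_selfing")


def crossing_design_f(design: str) -> float:
    """Inbreeding coefficient implied by a crossing design's pedigree.

    Builds the pedigree of the design explicitly (unrelated, non-inbred
    founders) and evaluates Wright's F, rather than returning a constant.
    """
    if design == "half_sib":
        ped = {"g": (None, None), "d1": (None, None), "d2": (None, None),
               "p1": ("g", "d1"), "p2": ("g", "d2"), "x": ("p1", "p2")}
    elif design == "full_sib":
        ped = {"s": (None, None), "d": (None, None),
               "p1": ("s", "d"), "p2": ("s", "d"), "x": ("p1", "p2")}
    elif design == "selfing":
        ped = {"p": (None, None), "x": ("p", "p")}
    elif design == "double_selfing":
        ped = {"p": (None, None), "s1": ("p", "p"), "x": ("s1", "s1")}
    else:
        raise ValueError(f"unknown crossing design {design!r}; one of {_DESIGNS}")
    return pedigree_inbreeding(ped, "x")
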