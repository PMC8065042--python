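"""Shared fixtures: small synthetic datasets and fitted models.

Expensive posterior fits are session-scoped so several test modules can
interrogate the same draws.
"""

import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from idmeta import (
    TrueParams, SimDesign, simulate_id_dataset,
    PartitionResult, ModelSpec, fit_meta_regression,
)

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


def two_group_partition(n_species: int) -> PartitionResult:
    """First half well-connected (1), second half fragmented (2)."""
    names = [f"sp{o:02d}" for o in range(n_species)]
    assign = {s: (1 if o < n_species / 2 else 2) for o, s in enumerate(names)}
    return PartitionResult(
        assignment=assign,
        prob_fragmented={s: float(g == 2) for s, g in assign.items()},
        group_fst_means={}, n_reps=0, method="manual")


#: Simulation truth used across recovery checks: values of the size and
#: sign structure typical of conifer ID compilations (strong embryonic
#: effect, positive F slope concentrated at the embryonic stage, residual
#: scale just above 1, moderately heavy tails).
RECOVERY_TRUTH = TrueParams.centered(
    mu=0.2, alpha=0.6,
    beta=(0.4, -0.3, 0.0, -0.1),
    gamma=(0.1, -0.1),
    delta=((0.15, -0.15), (-0.1, 0.1), (0.0, 0.0), (-0.05, 0.05)),
    epsilon=(0.3, -0.2, -0.05, -0.05),
    sigma_a=0.1, sigma_b=0.08, sigma_y=1.2, df=8.0,
)


@pytest.fixture(scope="session")
def small_records():
    """40-row synthetic ID dataset over 8 studies / 4 species."""
    return simulate_id_dataset(
        RECOVERY_TRUTH, SimDesign(n_studies=8, n_species=4, n_rows=40, seed=5))


@pytest.fixture(scope="session")
def small_fit(small_records):
    """Variant-2 fit of the 40-row dataset (shared across modules)."""
    spec = ModelSpec(variant=2, partition=two_group_partition(4))
    return fit_meta_regression(small_records, spec,
                               chains=2, draws=600, warmup=500, seed=7)


@pytest.fixture(scope="session")
def medium_fit_and_truth():
    """Variant-2 fit of a 600-row dataset with known truth."""
    design = SimDesign(n_studies=30, n_species=15, n_rows=600, seed=11)
    records = simulate_id_dataset(RECOVERY_TRUTH, design)
    spec = ModelSpec(variant=2, partition=two_group_partition(15))
    fit = fit_meta_regression(records, spec, chains=2, draws=800, warmup=600, seed=3)
    return fit, RECOVERY_TRUTH
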