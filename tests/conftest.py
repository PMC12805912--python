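"""Shared fixtures: expensive MCMC fits are session-scoped and reused."""

import numpy as np
import pytest

from nichepart import (
    GroupTruth,
    MixedModelConfig,
    default_study_design,
    fit_group,
    run_analysis,
    simulate_isotopes,
)
from nichepart.isotope_data import StandardizedDataset

RECOVERY_G_TRACE = 1.0
RECOVERY_R_TRACE = 2.0


def make_group_truth(
    n_individuals=60,
    g_trace=RECOVERY_G_TRACE,
    r_trace=RECOVERY_R_TRACE,
    n_tissues=4,
    species="sp",
    season="breeding",
    mu=(0.0, 0.0),
):
    """Isotropic-covariance group truth on the standardised scale."""
    tissues = [f"t{k}" for k in range(n_tissues)]
    return GroupTruth(
        species=species,
        season=season,
        n_individuals=n_individuals,
        mu=mu,
        G_true=np.diag([g_trace / 2] * 2),
        R_true=np.diag([r_trace / 2] * 2),
        tissue_offsets={t: (0.0, 0.0) for t in tissues},
    )


@pytest.fixture(scope="session")
def recovery_posterior():
    """Reduced-scale fit of a 60-individual x 4-tissue simulated group.

    Truth: trace(G) = 1, trace(R) = 2 (so IS = 1/3).  20,000 iterations,
    burn-in 2,000, thinning 10, three chains.
    """
    truth = make_group_truth()
    records = simulate_isotopes([truth], seed=1)
    data = StandardizedDataset.identity(records)
    config = MixedModelConfig.test_scale(seed=7)
    return fit_group(data, "sp", "breeding", config)


@pytest.fixture(scope="session")
def default_analysis():
    """Full pipeline on the default two-species study design (modest MCMC)."""
    records = simulate_isotopes(default_study_design(), seed=42)
    config = MixedModelConfig(
        n_iterations=4000, burn_in=1000, thin=10, n_chains=2, seed=5
    )
    return run_analysis(records, config)
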