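"""Shared fixtures: small synthetic datasets and session-scoped simulations.

Everything is generated programmatically under fixed seeds; the heavier
session fixtures (calibration grid, long-range-dispersal scenarios,
structured simulation) are lazy, so they only run when a test requests
them.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import pytest

from driftscape import fstats as fs
from driftscape import synthdata as sd
from driftscape import spacesim as sim


# ---------------------------------------------------------------------------
# Drift-tree helpers
# ---------------------------------------------------------------------------

def counts_from_calls(ph: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pseudohaploid (derived, called) counts from a calls block."""
    nonmissing = ph != -1
    return (ph == 2).sum(axis=1), nonmissing.sum(axis=1)


@pytest.fixture(scope="session")
def standard_panel():
    """Leaf frequencies, right-panel counts, blocks for a 20k-site tree.

    Rights are 6 pseudohaploid individuals per panel population at 5%
    missingness, the configuration used by the outlier workflow.
    """
    rng = np.random.default_rng(2024)
    n_sites = 20_000
    tree = sd.standard_tree()
    ancestral = sd.sample_ancestral_freqs(n_sites, rng)
    freqs = sd.drift_along_tree(tree, ancestral, rng)
    sites = sd.make_site_table(n_sites)
    blocks = fs.make_blocks(sites)
    counts = {}
    for r in tree.right_leaves:
        dip = sd.genotypes_from_freqs(freqs[r], 6, rng)
        counts[r] = counts_from_calls(sd.pseudohaploidize(dip, 0.05, rng))
    return {
        "tree": tree,
        "freqs": freqs,
        "counts": counts,
        "blocks": blocks,
        "rights": list(tree.right_leaves),
        "n_sites": n_sites,
        "rng": rng,
    }


@pytest.fixture(scope="session")
def workflow_fixture():
    """The standard 6-region / 8-right / 50k-site fixture with ~3% migrants."""
    spec = sd.standard_fixture_spec(seed=5)
    return sd.build_fixture(spec)


@pytest.fixture(scope="session")
def workflow_result(workflow_fixture):
    """The outlier workflow run once on the standard fixture."""
    import warnings
    from driftscape.outlier_pipeline import run_outlier_workflow

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_outlier_workflow(
            workflow_fixture.matrix,
            workflow_fixture.metadata,
            workflow_fixture.right_groups,
        )


# ---------------------------------------------------------------------------
# Simulation session fixtures (shared across acceptance tests)
# ---------------------------------------------------------------------------

#: Desk-scale base configuration used by the simulation study in the tests:
#: 2,000 sites keeps the site-sampling noise of the far-quartile FST around
#: +/-0.001 while one generation costs tens of milliseconds.
SIM_BASE = sim.SimConfig(
    N=1_000, n_sites=2_000, burnin_gens=600, lrd_gens=120,
    record_every=5, seed=0,
)


@pytest.fixture(scope="session")
def calibration():
    """Grid-search calibration of (N, sigma_disp) against fst_max ~ 0.03."""
    calibrated, table = sim.calibrate_dispersal(SIM_BASE)
    return calibrated, table


@pytest.fixture(scope="session")
def lrd_scenarios(calibration):
    """LRD scenario report: p_lr in {0, 0.04, 0.08}, 5 matched seeds.

    sigma_lr is set to 10x the calibrated base dispersal, preserving the
    scale separation between long-range and local dispersal.
    """
    calibrated, _ = calibration
    cfg = dataclasses.replace(
        calibrated, sigma_lr=10.0 * calibrated.sigma_disp, lrd_gens=120,
        record_every=5,
    )
    return sim.run_lrd_scenarios(cfg, p_lrs=(0.0, 0.04, 0.08), seeds=(1, 2, 3, 4, 5))


@pytest.fixture(scope="session")
def structured_sim():
    """A spatially structured end state for PCA checks (N=1000, 4k sites)."""
    cfg = sim.SimConfig(N=1_000, n_sites=4_000, sigma_disp=0.10,
                        burnin_gens=600, lrd_gens=0, seed=23)
    result = sim.run_simulation(cfg)
    return cfg, result.final_state
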