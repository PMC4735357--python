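"""Shared fixtures: synthetic communities and their binning results."""

import numpy as np
import pytest

import contourbin as cb

FIVE_SPECIES = {
    "sp1": (0.35, 0.35, 800_000),
    "sp2": (0.45, 0.25, 700_000),
    "sp3": (0.55, 0.20, 900_000),
    "sp4": (0.65, 0.15, 600_000),
    "sp5": (0.42, 0.05, 750_000),
}
TOTAL_FRAGMENTS = 2_000_000


def five_species_specs():
    return [
        cb.SpeciesSpec(name, gc, glen, ab)
        for name, (gc, ab, glen) in FIVE_SPECIES.items()
    ]


def run_binning_stages(community, min_posterior=0.5):
    """Run feature -> KDE -> init -> EM -> assignment on a community."""
    table = cb.build_feature_table(community.records, community.counts)
    grid = cb.binned_kde2d(table)
    level = cb.default_level(grid)
    init = cb.initial_binning(table, grid, level)
    fitted = cb.fit_em(table, init)
    assignments = cb.hard_assign(fitted, table.ids, min_posterior=min_posterior)
    return {
        "table": table, "grid": grid, "level": level, "init": init,
        "fitted": fitted, "assignments": assignments,
    }


@pytest.fixture(scope="session")
def five_species_community():
    return cb.simulate_community(five_species_specs(), TOTAL_FRAGMENTS, seed=1)


@pytest.fixture(scope="session")
def five_species_result(five_species_community):
    return run_binning_stages(five_species_community)


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)
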