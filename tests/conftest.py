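"""Shared fixtures: one default simulation reused across test modules."""

import logging

import pytest

from crossneuro.io_core import RunConfig
from crossneuro.synthetic_data import (
    ModuleSpec,
    SimDesign,
    SubtypeSpec,
    simulate,
)

logging.getLogger("crossneuro").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def default_sim():
    """One draw of the standard two-species benchmark design (seed 0)."""
    design = SimDesign(seed=0)
    tables, hmaps, truth = simulate(design)
    return design, tables, hmaps, truth


@pytest.fixture(scope="session")
def human_table(default_sim):
    return default_sim[1]["human"]


@pytest.fixture()
def config():
    return RunConfig(seed=0)


def coexpression_design(seed: int, n_pseudo_target: int = 500) -> SimDesign:
    """Single-species design sized for ~``n_pseudo_target`` pseudocells of
    10 cells: 3 planted 50-gene modules at loading 1.0."""
    cells_per_subtype = (n_pseudo_target * 10) // 2 + 20
    return SimDesign(
        species=("human",),
        reference="human",
        n_genes=500,
        shared_subtypes=[SubtypeSpec("Inc_SST"), SubtypeSpec("Inc_PVALB")],
        specific_subtypes={},
        cells_per_subtype=cells_per_subtype,
        n_batches=2,
        planted_modules=[ModuleSpec(50, 1.0) for _ in range(3)],
        planted_regulons=[],
        disease_effect=1.0,
        seed=seed,
    )


@pytest.fixture(scope="session")
def coexpr_sim():
    """Module-recovery-scale simulation (3x50-gene modules, ~500 pseudocells)."""
    design = coexpression_design(seed=0)
    tables, _, truth = simulate(design)
    return design, tables["human"], truth
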