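"""Shared fixtures: toy layouts for fast unit tests and a session-scoped
full-genome simulated assay (propensities + euploid panel + trained GAS
model) reused by the integration and acceptance tests."""

from __future__ import annotations

import numpy as np
import pytest

import realcsf as r
from realcsf.genome import Chromosome, GenomeLayout


@pytest.fixture(scope="session")
def toy_layout() -> GenomeLayout:
    """Four 25-Mb metacentric chromosomes -> 200 half-Mb intervals, 8 arms."""
    chroms = tuple(
        Chromosome(
            name=f"toy{i}",
            length=25_000_000,
            centromere_start=12_000_000,
            centromere_end=13_000_000,
            acrocentric_p_arm=False,
        )
        for i in range(1, 5)
    )
    return GenomeLayout(chromosomes=chroms)


@pytest.fixture(scope="session")
def toy_grid(toy_layout):
    return r.build_interval_grid(toy_layout, 500_000)


@pytest.fixture(scope="session")
def toy_assay(toy_grid):
    """Propensities + 20-sample euploid panel on the toy grid."""
    prop = r.simulate_propensities(toy_grid, 0.5, seed=11)
    samples = r.simulate_euploid_panel(toy_grid, prop, n_samples=20, depth=1_000_000, seed=12)
    panel = r.build_reference_panel(samples, toy_grid, k_components=5)
    return {"grid": toy_grid, "prop": prop, "panel": panel, "panel_samples": samples}


@pytest.fixture(scope="session")
def hg19_layout():
    return r.load_default_layout()


@pytest.fixture(scope="session")
def hg19_grid(hg19_layout):
    return r.build_interval_grid(hg19_layout)


@pytest.fixture(scope="session")
def hg19_assay(hg19_grid):
    """Full-genome simulated assay at the study conditions: heterogeneous
    amplicon efficiencies (log-SD 0.5), a 20-sample euploid panel at depth
    1e6, k=5 PCA components, default focal windows registered."""
    windows = r.load_default_focal_windows(hg19_grid)
    prop = r.simulate_propensities(hg19_grid, 0.5, seed=100)
    samples = r.simulate_euploid_panel(hg19_grid, prop, n_samples=20, depth=1_000_000, seed=200)
    panel = r.build_reference_panel(samples, hg19_grid, k_components=5, windows=windows)
    return {"grid": hg19_grid, "prop": prop, "panel": panel, "windows": windows}


@pytest.fixture(scope="session")
def gas_model(hg19_assay):
    """The shipped training recipe: seed-17 curriculum of 100 euploid and
    100 aneuploid simulated samples, pipeline Z_w features, RBF-SVM."""
    a = hg19_assay
    X, y = r.make_gas_curriculum(a["grid"], a["prop"], a["panel"], 100, 100, seed=17)
    return r.train_gas(X, y, list(a["grid"].arm_names), seed=17)


def euploid_profile(assay, seed: int, depth: int = 1_000_000):
    cfg = r.SimulationConfig(seed=seed, depth=depth)
    v, _ = r.simulate_interval_vector(cfg, assay["prop"], assay["grid"], f"eu{seed}")
    return v
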