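"""Shared fixtures: small simulated populations and sample designs."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from tddseq.simulate import (
    SampleDesign,
    SimConfig,
    build_ground_truth,
    build_loci,
    simulate_counts,
)

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=30,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return SimConfig(n_mirna=12, n_sirna=8, mirna_groups=(4, 3, 2, 3),
                     sirna_groups=(3, 4, 1), seed=7)


@pytest.fixture(scope="session")
def small_truth(small_config):
    return build_ground_truth(small_config)


@pytest.fixture(scope="session")
def small_loci(small_truth):
    return build_loci(small_truth, seed=7)


def make_designs(genotypes, library_types, n_clones=3, depth=20_000,
                 efficiency=1.0) -> list[SampleDesign]:
    designs = []
    for g in genotypes:
        for c in range(1, n_clones + 1):
            for lib in library_types:
                designs.append(SampleDesign(genotype=g, library_type=lib,
                                            clone_id=f"{g}_c{c}", depth=depth,
                                            efficiency=efficiency))
    return designs


@pytest.fixture(scope="session")
def small_counts(small_truth, small_config):
    designs = make_designs(["WT", "dora"], ["total", "periodate", "ago1_ip"])
    return simulate_counts(small_truth, designs, small_config)


def lognormal_count_table(rng: np.random.Generator, n_rows: int = 30,
                          n_clones: int = 3, mean: float = 500.0,
                          sigma: float = 0.2
                          ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """A null two-genotype count table with log-normal clone noise."""
    ids = [f"{g}_c{i}" for g in ("WT", "dora") for i in range(1, n_clones + 1)]
    base = rng.uniform(0.2, 5.0, size=n_rows)[:, None] * mean
    values = rng.poisson(base * np.exp(sigma * rng.standard_normal(
        (n_rows, 2 * n_clones))))
    counts = pd.DataFrame(values, columns=ids,
                          index=[f"sp{i:03d}" for i in range(n_rows)])
    samples = pd.DataFrame({
        "genotype": [i.split("_")[0] for i in ids],
        "library_type": "total",
        "clone_id": ids,
    }, index=pd.Index(ids, name="sample_id"))
    return counts, samples
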