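"""Shared fixtures: small simulated populations and toy pedigrees."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from sprucegs.pedigree import Pedigree
from sprucegs.simdata import SimConfig, simulate_population

settings.register_profile("ci", derandomize=True, max_examples=25,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tiny_pedigree() -> Pedigree:
    """Three generations, six individuals, one inbred mating (C x D are
    full sibs, F is their inbred offspring)."""
    return Pedigree.from_records([
        ("A", None, None), ("B", None, None),
        ("C", "A", "B"), ("D", "A", "B"),
        ("E", "A", None), ("F", "C", "D"),
    ])


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return SimConfig(
        n_groups=2, founders_per_group=(8, 8), crosses_per_group=(10, 11),
        parent_use_range=(1, 4), offspring_per_cross_range=(8, 12),
        n_sites=2, n_blocks_per_site=4, n_markers=400, n_causal=80,
        trait_names=("T1",), h2_per_trait_site=((0.4, 0.4),),
        r12_per_trait=(0.8,), block_sd=0.5, missing_rate=0.02, seed=42,
    )


@pytest.fixture(scope="session")
def small_pop(small_config):
    """Two-group, two-site population with a little missingness."""
    return simulate_population(small_config)


@pytest.fixture(scope="session")
def complete_pop(small_config):
    """Same layout without missing calls (for K and model fits)."""
    return simulate_population(small_config.replace(missing_rate=0.0, seed=43))


@pytest.fixture(scope="session")
def clean_geno(complete_pop):
    """QC-filtered complete panel of the no-missingness population."""
    from sprucegs.qc import run_qc

    cleaned, _ = run_qc(complete_pop.genotypes, complete_pop.pedigree, seed=0)
    return cleaned


@pytest.fixture(scope="session")
def adjusted_pheno(complete_pop):
    from sprucegs.polygenic import adjust_phenotypes

    adj, _ = adjust_phenotypes(complete_pop.phenotypes, ["T1"])
    return adj


@pytest.fixture(scope="session")
def random_pedigree():
    """200-individual random two-generation-plus pedigree."""
    rng = np.random.default_rng(7)
    records = [(f"F{i}", None, None) for i in range(40)]
    ids = [r[0] for r in records]
    for i in range(160):
        s, d = rng.choice(len(ids), size=2, replace=False)
        records.append((f"I{i}", ids[s], ids[d]))
        ids.append(f"I{i}")
    return Pedigree.from_records(records)
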