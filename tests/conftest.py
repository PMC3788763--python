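"""Shared fixtures: scaled-down sampling designs and reference tables.

Heavy fixtures are session-scoped so the calibration experiments (scenario
recovery, parameter coverage, prior-posterior agreement) share one reference
table instead of re-simulating it per test.
"""

from __future__ import annotations

import numpy as np
import pytest

import coalabc as ca
from coalabc.synthetic import SC1_TRUTH, StudyTemplate

# Desk-scale sampling design used by the simulation-heavy experiments:
# smaller samples and locus than the study template, same three-population
# structure.  Chosen once; every experiment in the suite uses it.
TEST_SAMPLES = (("SAG", 50), ("NAG", 30), ("NC", 15))
TEST_LOCUS = 800


@pytest.fixture(scope="session")
def small_config() -> ca.SampleConfig:
    return ca.SampleConfig(TEST_SAMPLES, TEST_LOCUS)


@pytest.fixture(scope="session")
def small_template(small_config) -> StudyTemplate:
    return StudyTemplate(sample_config=small_config)


@pytest.fixture(scope="session")
def divergence_specs():
    return [ca.build_scenario(s) for s in ("Sc1", "Sc2", "Sc3", "Sc4", "Sc5", "Sc6")]


@pytest.fixture(scope="session")
def sc1():
    return ca.build_scenario("Sc1")


@pytest.fixture(scope="session")
def reference_table(divergence_specs, small_config) -> ca.ReferenceTable:
    """10^4 prior simulations per divergence scenario at desk scale."""
    return ca.build_reference_table(divergence_specs, 10_000, small_config, seed=20_260_101)


@pytest.fixture(scope="session")
def sc1_truth_alignment(small_template):
    """One pseudo-observed dataset under Sc1 with the posterior-mode preset."""
    aln, truth = ca.generate_pseudo_observed(
        "Sc1", params=SC1_TRUTH, template=small_template, seed=424_242
    )
    return aln, truth


def random_alignment(rng: np.random.Generator, n_max: int = 10, l_max: int = 50):
    """A random small labelled alignment for oracle-equivalence checks."""
    n_pops = 3
    sizes = rng.integers(2, max(3, n_max // n_pops) + 1, n_pops)
    length = int(rng.integers(2, l_max + 1))
    pops = [p for p, k in zip(("SAG", "NAG", "NC"), sizes) for _ in range(k)]
    # low-diversity alphabet usage so haplotype collisions actually occur
    base = rng.integers(0, 4, length)
    mat = np.tile(base, (len(pops), 1))
    n_mut = int(rng.integers(0, len(pops) * length // 4 + 1))
    rows = rng.integers(0, len(pops), n_mut)
    cols = rng.integers(0, length, n_mut)
    vals = rng.integers(0, 4, n_mut)
    mat[rows, cols] = vals
    return ca.HaplotypeAlignment(
        [f"i{i}" for i in range(len(pops))], pops, mat.astype(np.uint8)
    )
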