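import numpy as np
import pytest

from cr1kit.simulate import SimConfig, default_families, simulate


@pytest.fixture(scope="session")
def families():
    return default_families(np.random.default_rng(5), 2)


@pytest.fixture(scope="session")
def small_sim(families):
    """A 3-species cohort with mild divergence, reused across unit tests."""
    config = SimConfig(
        tree="((A:1,B:1):1,C:2);",
        families=families,
        rng_seed=11,
        ancestral_genome_length=150_000,
        n_scaffolds=2,
        total_insertions=40,
        prob_full_length=0.5,
        substitution_rate=0.002,
    )
    assemblies, truths = simulate(config)
    return config, assemblies, truths


@pytest.fixture(scope="session")
def clean_sim(families):
    """Substitution-free cohort with spaced loci: the exact-recovery regime."""
    config = SimConfig(
        tree="((A:1,B:1):1,C:2);",
        families=families,
        rng_seed=23,
        ancestral_genome_length=250_000,
        n_scaffolds=2,
        total_insertions=50,
        prob_full_length=0.3,
        retained_length_range=(300, 600),
        substitution_rate=0.0,
        min_insertion_spacing_bp=1300,
        allow_nested=False,
    )
    assemblies, truths = simulate(config)
    return config, assemblies, truths
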