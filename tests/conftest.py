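import pytest

from mitoscan.synthetic import MitovirusSpec, generate_dataset

#: reduced-scale spec for fast per-module tests: same architecture, shorter
#: genomes (the full-scale defaults are exercised in the acceptance tests)
SMALL_SPEC = dict(
    n_species=4,
    strains_per_species=3,
    protein_len=(150, 200),
    ntr5_len=(60, 120),
    ntr3_len=(10, 40),
    trp_count=(4, 8),
)


def small_spec(seed: int, **overrides) -> MitovirusSpec:
    kw = {**SMALL_SPEC, **overrides}
    return MitovirusSpec(seed=seed, **kw)


@pytest.fixture(scope="session")
def small_dataset():
    """Reduced-scale synthetic strain collection with truth records."""
    return generate_dataset(small_spec(5))


@pytest.fixture(scope="session")
def default_dataset():
    """Full-scale (study-condition) synthetic strain collection."""
    return generate_dataset(MitovirusSpec(seed=11))


@pytest.fixture(scope="session")
def default_delimit(default_dataset):
    """Full delimitation run on the study-condition dataset (shared: the
    identity matrix is the expensive step)."""
    from mitoscan.pipeline import run_delimit

    seqs, _ = default_dataset
    return run_delimit(seqs)
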