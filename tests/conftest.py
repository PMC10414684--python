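import pytest

from helminthamp.synthetic_fixtures import FixtureSpec, generate


@pytest.fixture(scope="session")
def default_bundle():
    """One ground-truthed synthetic dataset shared by the whole suite:
    8 AMP families × 4 genomes at 5 % mutation, 2 GO-blocklisted decoy
    families, 20 decoys, 12 planted known-AMP copies."""
    return generate(FixtureSpec(seed=11))


@pytest.fixture(scope="session")
def dirty_bundle():
    """Dataset with pathological proteins for the precursor filters."""
    return generate(FixtureSpec(seed=23, n_duplicates=17, n_invalid=6, n_long=5))
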