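import pytest

from cypmod.profilehmm import build_profile
from cypmod.synthetic import GeneratorParams, generate_seed


@pytest.fixture(scope="session")
def default_seed():
    """Default synthetic annotated seed (20 rows, fixed seed)."""
    return generate_seed(GeneratorParams())


@pytest.fixture(scope="session")
def seed_alignment(default_seed):
    return default_seed[0]


@pytest.fixture(scope="session")
def seed_annotation(default_seed):
    return default_seed[1]


@pytest.fixture(scope="session")
def seed_truth(default_seed):
    return default_seed[2]


@pytest.fixture(scope="session")
def default_profile(seed_alignment, seed_annotation):
    return build_profile(seed_alignment, seed_annotation)


@pytest.fixture(scope="session")
def small_seed():
    """A small, fast seed for rebuild-heavy tests."""
    return generate_seed(
        GeneratorParams(
            n_rows=8,
            scr_len_range=(6, 7),
            linker_len_range=(1, 3),
            rng_seed=7,
        )
    )
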