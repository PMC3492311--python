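import random

import pytest

from attbdeconv.pipeline import demo_sim_config
from attbdeconv.screen_sim import simulate_screen


@pytest.fixture(scope="session")
def small_screen(tmp_path_factory):
    """One-library screen with the planted driver, moderate coverage.

    Shared across modules: detection, resolution, counting and pipeline
    tests all validate against this bundle's ground truth.
    """
    config, genome, genes = demo_sim_config(
        seed=11, n_libraries=1, fragments_per_library=3000
    )
    out = tmp_path_factory.mktemp("small_screen")
    bundle = simulate_screen(config, genome, genes, out)
    return config, genome, genes, bundle


@pytest.fixture()
def rng():
    return random.Random(20240917)


def random_dna(rng: random.Random, n: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(n))
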