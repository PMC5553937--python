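import numpy as np
import pytest

from tcrnet import (
    Clonotype,
    Cohort,
    Repertoire,
    default_config,
    generate_cohort,
    generate_repertoire,
)


@pytest.fixture
def toy_repertoire() -> Repertoire:
    """Hand-built repertoire with nt variants and usage tallies."""
    return Repertoire(
        "toy",
        [
            Clonotype("CASSF", 6, nt_variants={"TGTGCCAGCAGCTTT": 4, "TGCGCCAGCAGCTTC": 2},
                      v_usage={"TRBV1": 4, "TRBV2": 2}, j_usage={"TRBJ2-7": 6}),
            Clonotype("CASTF", 3, v_usage={"TRBV1": 3}, j_usage={"TRBJ2-7": 3}),
            Clonotype("CATTF", 1, v_usage={"TRBV5": 1}, j_usage={"TRBJ1-1": 1}),
        ],
    )


@pytest.fixture(scope="session")
def mouse_config():
    return default_config("mouse")


@pytest.fixture(scope="session")
def human_config():
    return default_config("human")


@pytest.fixture(scope="session")
def small_repertoire(mouse_config) -> Repertoire:
    """One simulated repertoire, 4000 draws (session-cached)."""
    return generate_repertoire(mouse_config, 4000, seed=101, individual_id="m0")


@pytest.fixture(scope="session")
def small_cohort(mouse_config) -> Cohort:
    """8 simulated individuals x 3000 draws (session-cached)."""
    return generate_cohort(mouse_config, 8, 3000, seed=2024)


@pytest.fixture(scope="session")
def small_human_cohort(human_config) -> Cohort:
    return generate_cohort(human_config, 5, 3000, seed=4048)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
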