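import numpy as np
import pytest

from rapidsel.libcode import LibraryArchitecture
from rapidsel.simsel import FamilySpec, SelectionSimConfig

UPSTREAM = "GGATTAAGGAGGTGATATTT"


@pytest.fixture
def arch() -> LibraryArchitecture:
    return LibraryArchitecture(upstream_anchor=UPSTREAM)


@pytest.fixture
def arch_d() -> LibraryArchitecture:
    return LibraryArchitecture(upstream_anchor=UPSTREAM, initiator_symbol="y")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


@pytest.fixture
def small_config() -> SelectionSimConfig:
    return SelectionSimConfig(
        seed=7,
        families=(
            FamilySpec("FWTLYGPIAKDEQRS", mutation_rate=0.05, fitness=8.0, initial_fraction=0.05),
            FamilySpec("MNHVVKPGWDEITAK", mutation_rate=0.05, fitness=4.0, initial_fraction=0.02),
        ),
        rounds=4,
        reads_per_round=2_000,
    )


def random_peptide(rng: np.random.Generator, length: int = 17) -> str:
    aas = "ACDEFGHIKLMNPQRSTVWY"
    return "".join(aas[i] for i in rng.integers(0, 20, size=length))
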