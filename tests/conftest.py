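import numpy as np
import pytest

from nichenull import AbundanceMatrix


def random_abundance(
    rng: np.random.Generator,
    n_species: int = 5,
    n_sites: int = 10,
    zero_frac: float = 0.3,
) -> AbundanceMatrix:
    """Random non-negative matrix with a controllable share of zero cells;
    every species is guaranteed at least one occurrence."""
    values = rng.gamma(1.5, 2.0, size=(n_species, n_sites))
    values[rng.random((n_species, n_sites)) < zero_frac] = 0.0
    for j in range(n_species):
        if values[j].sum() == 0:
            values[j, rng.integers(n_sites)] = rng.gamma(1.5, 2.0)
    return AbundanceMatrix(
        species_ids=[f"sp{j}" for j in range(n_species)],
        site_ids=[f"site{i}" for i in range(n_sites)],
        values=values,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
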