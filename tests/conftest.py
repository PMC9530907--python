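import numpy as np
import pytest

from geiblock import PhenotypeTable


def make_table(values, genotype_ids=None, environment_ids=None) -> PhenotypeTable:
    """Build a table from a (possibly NaN-holed) array; NaN means missing."""
    values = np.asarray(values, dtype=float)
    g, e = values.shape
    if genotype_ids is None:
        genotype_ids = [f"g{i + 1}" for i in range(g)]
    if environment_ids is None:
        environment_ids = [f"e{j + 1}" for j in range(e)]
    return PhenotypeTable(genotype_ids, environment_ids, values, ~np.isnan(values))


def random_masked_table(rng: np.random.Generator, g: int, e: int,
                        missing_rate: float = 0.25) -> PhenotypeTable:
    """Random table keeping every row and column observed."""
    while True:
        values = rng.normal(0.0, 3.0, size=(g, e))
        mask = rng.random((g, e)) >= missing_rate
        if mask.any(axis=1).all() and mask.any(axis=0).all():
            values[~mask] = np.nan
            return make_table(values)


@pytest.fixture
def table_2x2() -> PhenotypeTable:
    return make_table([[1.0, 2.0], [3.0, 5.0]])


@pytest.fixture
def table_2x2_masked() -> PhenotypeTable:
    return make_table([[1.0, np.nan], [3.0, 4.0]])
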