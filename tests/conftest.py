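import numpy as np
import pytest

from rarecodon._codes import synonymous_families
from rarecodon.orfeome import CodonUsageTable
from rarecodon.synth import SyntheticSpec, generate_orfeome, generate_usage_table


@pytest.fixture(scope="session")
def toy_table() -> CodonUsageTable:
    """Uniform families except Lys (AAA 0.75 / AAG 0.25) and Phe
    (TTT 0.6 / TTC 0.4) — small enough for hand-computed window sums."""
    fams = synonymous_families("standard")
    freq = {}
    for aa, cs in fams.items():
        for c in cs:
            freq[c] = 1.0 / len(cs)
    freq["AAA"], freq["AAG"] = 0.75, 0.25
    freq["TTT"], freq["TTC"] = 0.6, 0.4
    return CodonUsageTable(freq=freq)


@pytest.fixture(scope="session")
def skewed_table() -> CodonUsageTable:
    return generate_usage_table(skew=1.5, seed=100)


@pytest.fixture(scope="session")
def small_synthetic():
    """60-gene synthetic ORFeome with planted terminal and interior clusters."""
    spec = SyntheticSpec(n_genes=60, seed=123)
    orfeome, truth = generate_orfeome(spec)
    return spec, orfeome, truth


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
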