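import numpy as np
import pytest

from tumorcascade import PhantomSpec, generate_case, generate_cohort, normalize_case


@pytest.fixture(scope="session")
def phantom_case():
    """One deterministic phantom with all three tumor subregions."""
    return generate_case(PhantomSpec(seed=3))


@pytest.fixture(scope="session")
def normalized_case(phantom_case):
    volume, labels = phantom_case
    return normalize_case(volume), labels


@pytest.fixture(scope="session")
def small_cohort():
    """Six normalized phantoms (mixed HGG/LGG-like), for cohort-level checks."""
    cases = generate_cohort(6, seed=21, lgg_fraction=0.3)
    return [(normalize_case(v), l, s) for v, l, s in cases]


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
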