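import numpy as np
import pytest

from methamark import (
    Alignment,
    DesignConfig,
    FamilyModel,
    design_pairs,
    fixture_primer_pairs,
    simulate_family,
    simulate_reference_set,
)


@pytest.fixture(scope="session")
def primer_pairs():
    return fixture_primer_pairs()


@pytest.fixture(scope="session")
def family():
    """A default simulated marker-gene family (codon-aware, two conserved blocks)."""
    return simulate_family(FamilyModel(seed=11))


@pytest.fixture(scope="session")
def refset(family):
    return simulate_reference_set(family)


#: design constraints for amplicons sequenced as 250-bp read pairs: the
#: product must be long enough to yield a >= 30 aa peptide and short
#: enough that the mates overlap
SEQUENCING_DESIGN = DesignConfig(min_product_bp=250, max_product_bp=480)


@pytest.fixture(scope="session")
def designed_pair(family):
    pairs = design_pairs(Alignment(family.records), SEQUENCING_DESIGN, top_n=1)
    assert pairs, "default family must admit a primer pair"
    return pairs[0]


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
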