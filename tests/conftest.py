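import pytest

from its2delim import synth
from its2delim.fold import fold_its2


@pytest.fixture(scope="session")
def base_cassette():
    """One constraint-compliant synthetic cassette with planted truth."""
    return synth.gen_its2_cassette(seed=11)


@pytest.fixture(scope="session")
def folded_base(base_cassette):
    rec, truth = base_cassette
    return fold_its2(rec)


@pytest.fixture(scope="session")
def v9_panel():
    return synth.gen_v9_panel(seed=0)


@pytest.fixture(scope="session")
def species_scenario():
    """A base species, a conspecific loop variant, and two species-level
    mutants that together carry 4 CBCs and 8 HCBCs in the conserved region."""
    return synth.gen_species_panel(seed=0)
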