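import pytest

from sxm import (
    ZoneSpec,
    compound_thermo_profile,
    formulas_from_table,
    generate_formulas,
    parse_formula,
    profile_batch,
)


@pytest.fixture(scope="session")
def glucose():
    return parse_formula("C6H12O6", label="glucose")


@pytest.fixture(scope="session")
def glucose_profile(glucose):
    return compound_thermo_profile(glucose)


@pytest.fixture(scope="session")
def random_formulas():
    """1,000 seeded FTICR-like CHNOPS formulae (shared across the suite)."""
    return formulas_from_table(generate_formulas(ZoneSpec(n_compounds=1000, seed=42)))


@pytest.fixture(scope="session")
def random_profiles(random_formulas):
    return profile_batch(random_formulas)
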