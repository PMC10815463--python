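import pytest

from argdx import load_fixture, parse_findings


@pytest.fixture(scope="session")
def kb_discharge():
    """Vaginal-discharge STI table, selections as printed (D = 8)."""
    return load_fixture("sti_discharge.yaml")


@pytest.fixture(scope="session")
def kb_discharge_prose():
    """Variant whose root row keeps AW, following the running prose."""
    return load_fixture("sti_discharge_prose.yaml")


@pytest.fixture(scope="session")
def kb_burning():
    """Burning/itching STI table with the HIV column (D = 10)."""
    return load_fixture("sti_burning.yaml")


@pytest.fixture(scope="session")
def kb_registry_default():
    """The seven-group default disease registry, no tables."""
    return load_fixture("registry_default.yaml")


@pytest.fixture(scope="session")
def discharge_phases():
    """The three progressive finding sets of the worked discharge example."""
    f1 = parse_findings(["vaginal_discharge"])
    f2 = f1 | parse_findings(
        ["quantity(VD, profuse)", "Texture (VD, thin)", "Colour (VD, green)"]
    )
    f3 = f2 | parse_findings(["Texture (VD, frothy)"])
    return (f1, f2, f3)


@pytest.fixture(scope="session")
def burning_phases():
    g1 = parse_findings(["burning"])
    g2 = g1 | parse_findings(["intermenstrual_bleeding"])
    g3 = g2 | parse_findings(["lumps(small_cauliflower)"])
    return (g1, g2, g3)
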