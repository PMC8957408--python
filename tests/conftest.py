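import pytest

from cardiotriage import (
    FuzzySet,
    FuzzyVariable,
    build_index,
    canonical_variables,
    enumerate_rules,
)


@pytest.fixture(scope="session")
def variables():
    return canonical_variables()


@pytest.fixture(scope="session")
def canonical_base(variables):
    """Full 82,944-rule Cartesian base; built once per session."""
    return enumerate_rules(variables)


@pytest.fixture(scope="session")
def canonical_index(canonical_base):
    return build_index(canonical_base)


def make_toy_variables():
    """Two crisp + one fuzzy toy variables for fast structural tests."""
    color = FuzzyVariable(
        name="color",
        domain=(0, 1),
        units="code",
        sets=(
            FuzzySet("red", "crisp", (0, 0), severity=2),
            FuzzySet("blue", "crisp", (1, 1), severity=1),
        ),
        is_constant=True,
    )
    size = FuzzyVariable(
        name="size",
        domain=(0, 10),
        units="cm",
        sets=(
            FuzzySet("small", "ramp_down", (2, 6), severity=1),
            FuzzySet("medium", "triangle", (2, 5, 8), severity=2),
            FuzzySet("large", "ramp_up", (4, 8), severity=3),
        ),
    )
    return [color, size]


@pytest.fixture()
def toy_variables():
    return make_toy_variables()


@pytest.fixture()
def toy_base(toy_variables):
    return enumerate_rules(toy_variables)
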