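import numpy as np
import pytest

from glycosim import glycans
from glycosim.notation import parse_linear
from glycosim.rules import EnzymeRule, ScaleFactorTable, default_mammalian_rules
from glycosim.simulator import GolgiModel

MAN5_STR = glycans.MAN5
COMPLEX_STR = (
    "GlcNAc4.1GlcNAc4.1Man(3.1Man2.1GlcNAc4.1Gal:)_m6.1Man2.1GlcNAc4.1Gal6.2Sia:@"
)


@pytest.fixture(scope="session")
def ruleset():
    return default_mammalian_rules()


@pytest.fixture(scope="session")
def rules(ruleset):
    return ruleset[0]


@pytest.fixture(scope="session")
def scale_table(ruleset):
    return ruleset[1]


@pytest.fixture
def man5():
    return parse_linear(MAN5_STR)


@pytest.fixture
def man8():
    return parse_linear(glycans.MAN8)


@pytest.fixture
def man9():
    return parse_linear(glycans.MAN9)


@pytest.fixture
def complex_glycan():
    return parse_linear(COMPLEX_STR)


def rule_by_enzyme(rules, enzyme):
    return next(r for r in rules if r.enzyme == enzyme)


def toy_absorbing_rules(sugars_linkages):
    """One enzyme per (sugar, linkage): adds that residue to a bare GlcNAc
    root.  Any addition destroys the 'leaf root' pattern, so every product
    state is absorbing -- a clean finite CTMC for analytic oracles."""
    rules = [
        EnzymeRule(
            enzyme=f"E{i}",
            match={"sugar": "GlcNAc", "leaf": True},
            action={"add": {"sugar": sugar, "linkage": linkage}},
        )
        for i, (sugar, linkage) in enumerate(sugars_linkages)
    ]
    return rules, ScaleFactorTable([])


def toy_model(rules, table, rates, n_cisternae=1, residence=10.0):
    """Single-species toy GolgiModel starting from a bare GlcNAc root."""
    return GolgiModel(
        n_cisternae=n_cisternae,
        residence_times=[residence] * n_cisternae,
        rates=rates,
        input_distribution={"GlcNAc:@": 1.0},
        rules=rules,
        scale_factors=table,
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
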