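"""Shared fixtures: hand-built toy universes and seeded synthetic cases."""

from fractions import Fraction

import pytest
from hypothesis import settings

import metnetrand as mn
from metnetrand.universe_io import Environment, Reaction, ReactionUniverse

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

ONE = Fraction(1)

GLYCOLYSIS_EQUATIONS = {
    "HEX1": "glc-D + atp -> g6p + adp + h",
    "PGI": "g6p <=> f6p",
    "PFK": "f6p + atp -> fdp + adp + h",
}
GLYCOLYSIS_CURRENCY = ["atp", "adp", "h"]


@pytest.fixture(scope="session")
def glycolysis_universe():
    """Three glycolytic steps plus a minimal scaffold (exchange + biomass on fdp)."""
    rxns = [mn.parse_reaction_equation(eq, rid=r) for r, eq in GLYCOLYSIS_EQUATIONS.items()]
    rxns.append(Reaction("EX_glc", {"glc-D": -ONE}, True, "exchange"))
    rxns.append(Reaction("BM", {"fdp": -ONE}, False, "biomass"))
    return ReactionUniverse(rxns)


@pytest.fixture(scope="session")
def glycolysis_genotype():
    return frozenset(GLYCOLYSIS_EQUATIONS)


@pytest.fixture(scope="session")
def glycolysis_currency():
    return mn.CurrencyList(list(GLYCOLYSIS_CURRENCY))


def chain_universe(stoich_ab=1):
    """EX_A (uptake) -> A -> B -> biomass; ``stoich_ab`` A consumed per B."""
    rxns = [
        Reaction("R_AB", {"A": -Fraction(stoich_ab), "B": ONE}, False, "metabolic"),
        Reaction("EX_A", {"A": -ONE}, True, "exchange"),
        Reaction("BM", {"B": -ONE}, False, "biomass"),
    ]
    return ReactionUniverse(rxns)


@pytest.fixture
def toy_chain():
    return chain_universe()


@pytest.fixture(scope="session")
def medium_A():
    return Environment(carbon_source="A", carbon_uptake_bound=10.0)


def cap_toy_universe():
    """Ten metabolic reactions over eight metabolites; used with a metabolite cap."""
    eqs = [
        ("r0", "m0 -> m1"), ("r1", "m1 -> m2"), ("r2", "m0 + m2 -> m3"),
        ("r3", "m3 -> m4 + m5"), ("r4", "m4 -> m0"), ("r5", "m5 + m1 -> m6"),
        ("r6", "m6 -> m7"), ("r7", "m7 + m0 -> m2"), ("r8", "m2 -> m5"),
        ("r9", "m3 + m6 -> m1"),
    ]
    rxns = [mn.parse_reaction_equation(e, rid=r) for r, e in eqs]
    rxns.append(Reaction("EX_x", {"x": -ONE}, True, "exchange"))
    rxns.append(Reaction("BM", {"x": -ONE}, False, "biomass"))
    return ReactionUniverse(rxns)


def viability_toy_universe():
    """Ten metabolic reactions with several alternative routes from A to the
    biomass precursor C; viability on minimal-A discriminates subsets."""
    eqs = [
        ("r0", "A -> B"), ("r1", "A -> D"), ("r2", "D -> B"),
        ("r3", "B -> C"), ("r4", "D -> C"), ("r5", "B -> D"),
        ("r6", "C -> E"), ("r7", "E -> B"), ("r8", "A -> E"),
        ("r9", "E -> C"),
    ]
    rxns = [mn.parse_reaction_equation(e, rid=r) for r, e in eqs]
    rxns.append(Reaction("EX_A", {"A": -ONE}, True, "exchange"))
    rxns.append(Reaction("BM", {"C": -ONE}, False, "biomass"))
    return ReactionUniverse(rxns)


@pytest.fixture(scope="session")
def synthetic_case():
    """Default-sized synthetic universe with planted ground truth (seed 0)."""
    spec = mn.SyntheticUniverseSpec(seed=0)
    universe, currency, truth = mn.generate_universe(spec)
    return spec, universe, currency, truth
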